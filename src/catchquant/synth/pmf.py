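"""Synthetic potential-of-mean-force profiles with a prescribed well depth."""

from __future__ import annotations

import numpy as np

from ..mdcontacts import PmfProfile


def gen_pmf_profile(
    delta_g: float,
    xi_min: float = 0.1,
    xi_max: float = 2.0,
    n_points: int = 100,
    well_position: float = 0.35,
    well_width: float = 0.15,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> PmfProfile:
    """Morse-shaped PMF: a well of depth ``delta_g`` rising to a zero plateau.

    The curve is ``delta_g * ((1 - exp(-(xi - x0)/w))**2 - 1)``: minimum
    ``-delta_g`` at ``well_position``, asymptotically flat (unbound) at large
    separation.  Optional Gaussian noise emulates histogram-reweighting
    jitter.
    """
    if delta_g < 0:
        raise ValueError("delta_g must be non-negative")
    xi = np.linspace(xi_min, xi_max, n_points)
    energy = delta_g * ((1.0 - np.exp(-(xi - well_position) / well_width)) ** 2 - 1.0)
    if noise_sd > 0:
        energy = energy + np.random.default_rng(seed).normal(0, noise_sd, size=xi.shape)
    return PmfProfile(xi=xi, energy=energy)
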