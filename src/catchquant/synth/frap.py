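"""Synthetic photobleaching-recovery series.

The bleached-region intensity follows the single-exponential recovery

    R(t) = R_f - (R_f - R_0) exp(-k t)

multiplied by a global acquisition-bleach decay exp(-b t) that equally
affects the unbleached focal-adhesion and cytosol control regions, so double
normalisation (pre-bleach baseline, then control ratio) cancels it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..frap_dynamics import FrapSeries


@dataclass(frozen=True)
class FrapSpec:
    r_f: float = 0.8  # final recovery (mobile-fraction proxy)
    r_0: float = 0.1  # initial post-bleach recovery
    k: float = np.log(2) / 30.0  # recovery rate, 1/s
    bleach_rate: float = 0.0005  # global acquisition bleaching, 1/s
    dt: float = 5.0  # sampling interval, s (pre- and post-bleach)
    t_max: float = 300.0  # post-bleach duration, s
    n_prebleach: int = 4
    baseline: float = 1000.0  # pre-bleach counts in the bleach region
    control_level: float = 800.0  # unbleached-FA control counts
    cytosol_level: float = 400.0
    noise_sd: float = 0.0  # Gaussian noise, fraction of baseline
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.r_0 <= self.r_f <= 1.0:
            raise ValueError("require 0 <= R_0 <= R_f <= 1")
        if self.k < 0 or self.bleach_rate < 0:
            raise ValueError("rates must be non-negative")


def recovery_curve(t: np.ndarray, r_f: float, r_0: float, k: float) -> np.ndarray:
    """Closed-form single-exponential recovery."""
    return r_f - (r_f - r_0) * np.exp(-k * np.asarray(t, dtype=float))


def gen_frap_series(spec: FrapSpec) -> FrapSeries:
    """Generate bleach-region and control traces for one photobleaching run.

    Time is measured from the bleach event; pre-bleach frames sit at negative
    times.  The global decay applies from the first acquired frame onward.
    """
    rng = np.random.default_rng(spec.seed)
    t_pre = -spec.dt * np.arange(spec.n_prebleach, 0, -1)
    t_post = np.arange(0.0, spec.t_max + spec.dt / 2, spec.dt)
    times = np.concatenate([t_pre, t_post])
    decay = np.exp(-spec.bleach_rate * (times - times[0]))
    recovery = np.concatenate([np.ones_like(t_pre), recovery_curve(t_post, spec.r_f, spec.r_0, spec.k)])
    bleach = spec.baseline * recovery * decay
    fa_control = spec.control_level * decay
    cyto_control = spec.cytosol_level * decay
    if spec.noise_sd > 0:
        bleach = bleach + rng.normal(0, spec.noise_sd * spec.baseline, size=times.shape)
        fa_control = fa_control + rng.normal(0, spec.noise_sd * spec.control_level, size=times.shape)
        cyto_control = cyto_control + rng.normal(0, spec.noise_sd * spec.cytosol_level, size=times.shape)
    return FrapSeries(
        times=times,
        bleach=bleach,
        fa_control=fa_control,
        cyto_control=cyto_control,
        n_prebleach=spec.n_prebleach,
        truth={"r_f": spec.r_f, "r_0": spec.r_0, "k": spec.k, "tau_half": np.log(2) / spec.k if spec.k > 0 else np.inf},
    )
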