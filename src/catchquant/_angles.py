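"""Axial (180-degree periodic) angle arithmetic.

Orientations of adhesions and fibers are axes, not vectors: theta and
theta + pi describe the same structure.  All helpers here treat angles as
axial quantities; means use the double-angle unit-vector method so that
averaging {theta, theta + pi} returns theta instead of cancelling.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fold_axial",
    "axial_difference",
    "axial_mean",
    "axial_std",
]


def fold_axial(theta: np.ndarray | float) -> np.ndarray | float:
    """Fold angle(s) in radians into the half-open interval (-pi/2, pi/2]."""
    folded = -((-np.asarray(theta) + np.pi / 2) % np.pi - np.pi / 2)
    return folded if np.ndim(theta) else float(folded)


def axial_difference(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray | float:
    """Unsigned axial separation |a - b| folded to [0, pi/2]."""
    d = np.abs(fold_axial(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)))
    d = np.minimum(d, np.pi - d)  # guard the +pi/2 boundary
    return d if np.ndim(d) else float(d)


def axial_mean(theta: np.ndarray, weights: np.ndarray | None = None) -> tuple[float, float]:
    """Mean orientation of axial angles (radians).

    Returns ``(mean, resultant_length)`` where the mean is computed on doubled
    angles and halved back, and the resultant length (in [0, 1]) measures how
    concentrated the orientations are (0 = isotropic, 1 = perfectly aligned).
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("axial_mean of empty set")
    w = np.ones_like(theta) if weights is None else np.asarray(weights, dtype=float)
    c = float(np.sum(w * np.cos(2.0 * theta)) / np.sum(w))
    s = float(np.sum(w * np.sin(2.0 * theta)) / np.sum(w))
    return fold_axial(0.5 * np.arctan2(s, c)), float(np.hypot(c, s))


def axial_std(theta: np.ndarray) -> float:
    """Spread of axial orientations, in radians.

    RMS axial deviation about the axial mean.  When the double-angle
    resultant vanishes (e.g. two equal populations 90 degrees apart) the mean
    direction is degenerate; the reference orientation is then chosen to
    minimise the RMS deviation, which yields pi/4 (45 degrees) for the equal
    0/90-degree case instead of an arbitrary value.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.size == 0:
        raise ValueError("axial_std of empty set")
    mu, resultant = axial_mean(theta)
    if resultant < 1e-9:
        candidates = np.linspace(-np.pi / 2, np.pi / 2, 361)
        devs = axial_difference(theta[None, :], candidates[:, None])
        rms = np.sqrt(np.mean(devs**2, axis=1))
        return float(rms.min())
    dev = axial_difference(theta, mu)
    return float(np.sqrt(np.mean(dev**2)))
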