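"""Three-channel sensitized-emission FRET quantification.

A measurement is a registered triplet of images taken under donor excitation
(donor channel ``I_d`` and FRET channel ``I_f``) and acceptor excitation
(acceptor channel ``I_a``).  Spectral bleed-through of each fluorophore into
the FRET channel is calibrated from single-fluorophore samples
(``d_bt = I_f / I_d`` binned by donor intensity, ``a_bt = I_f / I_a`` binned
by acceptor intensity); the corrected FRET signal is

    F_c = I_f - d_bt * I_d - a_bt * I_a

and, with the proportionality constant G relating sensitized emission to
donor quenching, pixelwise efficiency is

    E = (F_c / G) / (I_d + F_c / G).

G is obtained from two donor-acceptor fusion constructs of constant (high
and low) efficiency as G = -d(F_c/I_a) / d(I_d/I_a).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.registration import phase_cross_correlation

__all__ = [
    "ImageTriplet",
    "FretCalibration",
    "EfficiencyMap",
    "preprocess_triplet",
    "calibrate_bleedthrough",
    "calibrate_g",
    "fret_efficiency_map",
]


@dataclass
class ImageTriplet:
    """Registered donor / FRET / acceptor channel images."""

    donor: np.ndarray
    fret: np.ndarray
    acceptor: np.ndarray
    pixel_size_um: float = 0.108

    def __post_init__(self):
        self.donor = np.asarray(self.donor, dtype=float)
        self.fret = np.asarray(self.fret, dtype=float)
        self.acceptor = np.asarray(self.acceptor, dtype=float)
        if not (self.donor.shape == self.fret.shape == self.acceptor.shape):
            raise ValueError("channel dimensions differ")


@dataclass
class FretCalibration:
    """Bleed-through coefficients and G factor.

    Scalar summaries are intensity-weighted means of per-bin medians; the
    bin tables are retained for optional intensity-dependent application.
    """

    d_bt: float
    a_bt: float
    g: float = 1.0
    d_bt_bins: pd.DataFrame | None = field(default=None, repr=False)
    a_bt_bins: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        if self.d_bt < 0 or self.a_bt < 0:
            raise ValueError("bleed-through coefficients must be non-negative")
        if self.g <= 0:
            raise ValueError("G must be positive")


@dataclass
class EfficiencyMap:
    """Pixelwise corrected FRET and efficiency with a validity mask."""

    f_c: np.ndarray
    efficiency: np.ndarray
    valid: np.ndarray


def _corner_background(img: np.ndarray, frac: float = 0.05) -> float:
    h, w = img.shape
    ph, pw = max(2, int(frac * h)), max(2, int(frac * w))
    patches = [img[:ph, :pw], img[:ph, -pw:], img[-ph:, :pw], img[-ph:, -pw:]]
    return float(np.median(np.concatenate([p.ravel() for p in patches])))


def preprocess_triplet(
    raw: ImageTriplet,
    dark: ImageTriplet | None = None,
    flat: ImageTriplet | None = None,
    background_mask: np.ndarray | None = None,
    max_shift_frac: float = 0.1,
) -> ImageTriplet:
    """Dark/flat correction, translational registration, background subtraction.

    Each channel is dark-subtracted, divided by its mean-normalised flat
    field, registered to the acceptor channel by integer-pixel
    cross-correlation, and background-subtracted (median of a user mask or of
    the four image corners).  Registration shifts beyond ``max_shift_frac``
    of the image size raise an error.
    """
    chans = {}
    for name in ("donor", "fret", "acceptor"):
        img = getattr(raw, name).copy()
        if dark is not None:
            d = getattr(dark, name)
            if d.shape != img.shape:
                raise ValueError("dark frame dimensions differ from image")
            img = img - d
        if flat is not None:
            f = getattr(flat, name)
            if f.shape != img.shape:
                raise ValueError("flat field dimensions differ from image")
            img = img / (f / f.mean())
        chans[name] = img
    ref = chans["acceptor"]
    limit = max_shift_frac * min(ref.shape)
    for name in ("donor", "fret"):
        shift, _, _ = phase_cross_correlation(ref, chans[name], upsample_factor=1)
        if np.any(np.abs(shift) > limit):
            raise RuntimeError(f"registration shift {shift} exceeds {max_shift_frac:.0%} of image")
        if np.any(shift != 0):
            chans[name] = ndimage.shift(chans[name], shift, order=0, mode="nearest")
    for name in chans:
        if background_mask is not None:
            bg = float(np.median(chans[name][background_mask]))
        else:
            bg = _corner_background(chans[name])
        chans[name] = chans[name] - bg
    return ImageTriplet(donor=chans["donor"], fret=chans["fret"], acceptor=chans["acceptor"],
                        pixel_size_um=raw.pixel_size_um)


def _binned_ratio(numer: np.ndarray, denom: np.ndarray, n_bins: int, min_level: float) -> pd.DataFrame:
    sel = denom > min_level
    if not np.any(sel):
        raise ValueError("no usable pixels above the intensity floor")
    x = denom[sel]
    r = numer[sel] / x
    edges = np.linspace(x.min(), x.max() * (1 + 1e-12), n_bins + 1)
    idx = np.clip(np.digitize(x, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if not np.any(m):
            warnings.warn(f"empty intensity bin {b} dropped", stacklevel=2)
            continue
        rows.append(
            {"bin": b, "center": 0.5 * (edges[b] + edges[b + 1]),
             "coefficient": float(np.median(r[m])), "weight": float(x[m].sum()), "n": int(m.sum())}
        )
    return pd.DataFrame(rows)


def _summary(bins: pd.DataFrame) -> float:
    return float(np.average(bins["coefficient"], weights=bins["weight"]))


def calibrate_bleedthrough(
    donor_only: ImageTriplet,
    acceptor_only: ImageTriplet,
    n_bins: int = 10,
    min_level: float = 0.0,
) -> FretCalibration:
    """Bleed-through coefficients from single-fluorophore samples.

    ``d_bt`` is the per-bin median of ``I_f / I_d`` on a donor-only sample
    (binned by donor intensity) and ``a_bt`` the analogue on an acceptor-only
    sample; scalar summaries are intensity-weighted means of the bin medians.
    """
    d_bins = _binned_ratio(donor_only.fret, donor_only.donor, n_bins, min_level)
    a_bins = _binned_ratio(acceptor_only.fret, acceptor_only.acceptor, n_bins, min_level)
    return FretCalibration(d_bt=_summary(d_bins), a_bt=_summary(a_bins),
                           d_bt_bins=d_bins, a_bt_bins=a_bins)


def _coefficient_image(intensity: np.ndarray, scalar: float,
                       bins: pd.DataFrame | None, mode: str | None) -> np.ndarray | float:
    if mode is None or bins is None or len(bins) < 2:
        return scalar
    centers = bins["center"].to_numpy()
    coefs = bins["coefficient"].to_numpy()
    if mode == "nearest":
        idx = np.abs(intensity[..., None] - centers).argmin(axis=-1)
        return coefs[idx]
    if mode == "linear":
        return np.interp(intensity, centers, coefs)
    raise ValueError("binned mode must be None, 'nearest' or 'linear'")


def corrected_fret(triplet: ImageTriplet, calibration: FretCalibration,
                   binned: str | None = None) -> np.ndarray:
    """Bleed-through-corrected FRET image F_c = I_f - d_bt I_d - a_bt I_a."""
    d_bt = _coefficient_image(triplet.donor, calibration.d_bt, calibration.d_bt_bins, binned)
    a_bt = _coefficient_image(triplet.acceptor, calibration.a_bt, calibration.a_bt_bins, binned)
    return triplet.fret - d_bt * triplet.donor - a_bt * triplet.acceptor


def calibrate_g(
    low_construct: ImageTriplet,
    high_construct: ImageTriplet,
    calibration: FretCalibration,
    min_level: float = 0.0,
) -> float:
    """G factor from two fusion constructs of constant (different) efficiency.

    For each construct the scalar pair (F_c / I_a, I_d / I_a) is taken as the
    median over pixels with usable acceptor signal; G is the negative slope
    between the two constructs.
    """
    points = []
    for trip in (low_construct, high_construct):
        f_c = corrected_fret(trip, calibration)
        sel = trip.acceptor > min_level
        if not np.any(sel):
            raise ValueError("no usable pixels in a G-calibration construct")
        points.append((float(np.median(f_c[sel] / trip.acceptor[sel])),
                       float(np.median(trip.donor[sel] / trip.acceptor[sel]))))
    (fa_lo, da_lo), (fa_hi, da_hi) = points
    if np.isclose(da_hi, da_lo):
        raise ValueError("degenerate construct pair: identical I_d / I_a")
    return -(fa_hi - fa_lo) / (da_hi - da_lo)


def fret_efficiency_map(
    triplet: ImageTriplet,
    calibration: FretCalibration,
    clamp_negative: bool = True,
    binned: str | None = None,
) -> EfficiencyMap:
    """Pixelwise FRET efficiency E = (F_c/G) / (I_d + F_c/G).

    Negative corrected-FRET pixels are clamped to zero by default (keeping
    near-zero-efficiency statistics unbiased around E = 0 rather than
    discarding those pixels); pixels where the denominator is non-positive
    are masked invalid.
    """
    f_c = corrected_fret(triplet, calibration, binned=binned)
    if clamp_negative:
        f_c = np.maximum(f_c, 0.0)
    sens = f_c / calibration.g
    denom = triplet.donor + sens
    valid = denom > 0
    e = np.zeros_like(denom)
    np.divide(sens, denom, out=e, where=valid)
    return EfficiencyMap(f_c=f_c, efficiency=e, valid=valid)
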