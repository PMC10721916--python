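"""Intra-adhesion tension distribution: line profiles and the spatial
variation index (SVI).

Molecular tension sensors report load as *reduced* FRET, so the
inverse-efficiency-weighted centroid of an adhesion shifts toward its
high-tension end.  The SVI compares that weighted centroid with the
geometric centroid, both measured as distances from the cell centroid (the
mean of adhesion geometric centroids) and normalised by the adhesion's
major-axis length:

    SVI = (|r_w - r_cell| - |r_geo - r_cell|) / FA_major

Positive values mean tension is skewed distally (away from the cell
center).  Line profiles sample efficiency and acceptor intensity along the
adhesion's major axis, averaged across a band of half the minor-axis
thickness, with cubic smoothing-spline noise reduction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from skimage.measure import profile_line

__all__ = ["FaProfile", "SviRecord", "fa_line_profile", "spatial_variation_index", "svi_table"]


@dataclass
class FaProfile:
    positions: np.ndarray  # px along the major axis, centred on the centroid
    efficiency: np.ndarray
    efficiency_smooth: np.ndarray
    acceptor: np.ndarray | None = None
    acceptor_smooth: np.ndarray | None = None
    line_thickness: float = 1.0


@dataclass
class SviRecord:
    fa_id: int
    geo_centroid: tuple[float, float]
    weighted_centroid: tuple[float, float]
    cell_centroid: tuple[float, float]
    fa_major: float
    svi: float


def fa_line_profile(
    efficiency_map: np.ndarray,
    record: pd.Series,
    acceptor: np.ndarray | None = None,
    smoothing_lam: float | None = None,
) -> FaProfile:
    """Band-averaged profile along an adhesion's major axis.

    Samples at 1 px steps between the centroid +/- half the major-axis
    length, averaging across a line thickness of half the minor-axis length.
    The smoothing parameter of the cubic spline defaults to generalised
    cross-validation.
    """
    major = float(record["fa_major"])
    if major < 3:
        raise ValueError("adhesion too short for a line profile (major axis < 3 px)")
    cx, cy, theta = float(record["cx"]), float(record["cy"]), float(record["orientation"])
    half = major / 2.0
    src = (cy - half * np.sin(theta), cx - half * np.cos(theta))  # (row, col)
    dst = (cy + half * np.sin(theta), cx + half * np.cos(theta))
    thickness = max(1, int(round(float(record["fa_minor"]) / 2.0)))
    e_prof = profile_line(efficiency_map, src, dst, linewidth=thickness, order=1,
                          mode="constant", reduce_func=np.mean)
    positions = np.arange(e_prof.size, dtype=float) - (e_prof.size - 1) / 2.0
    e_smooth = make_smoothing_spline(positions, e_prof, lam=smoothing_lam)(positions)
    a_prof = a_smooth = None
    if acceptor is not None:
        a_prof = profile_line(np.asarray(acceptor, dtype=float), src, dst, linewidth=thickness,
                              order=1, mode="constant", reduce_func=np.mean)
        a_smooth = make_smoothing_spline(positions, a_prof, lam=smoothing_lam)(positions)
    return FaProfile(positions=positions, efficiency=e_prof, efficiency_smooth=e_smooth,
                     acceptor=a_prof, acceptor_smooth=a_smooth, line_thickness=thickness)


def spatial_variation_index(
    xs: np.ndarray,
    ys: np.ndarray,
    efficiency: np.ndarray,
    cell_centroid: tuple[float, float],
    fa_major: float,
    fa_id: int = 0,
    efficiency_floor: float = 1e-3,
    exclude_nonpositive: bool = False,
) -> SviRecord:
    """SVI of one adhesion from its pixel coordinates and efficiencies.

    Weights are inverse efficiencies.  Non-positive efficiencies are floored
    at ``efficiency_floor`` by default (excluding them instead biases dim
    adhesions); with ``exclude_nonpositive`` those pixels are dropped with a
    warning, and an all-nonpositive adhesion is an error.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    e = np.asarray(efficiency, dtype=float)
    if exclude_nonpositive:
        keep = e > 0
        if not keep.all():
            warnings.warn(f"excluded {int((~keep).sum())} non-positive-efficiency pixels", stacklevel=2)
        if not keep.any():
            raise ValueError("no positive-efficiency pixels in adhesion")
        xs, ys, e = xs[keep], ys[keep], e[keep]
    w = 1.0 / np.maximum(e, efficiency_floor)
    x_geo, y_geo = float(xs.mean()), float(ys.mean())
    x_w = float(np.sum(w * xs) / np.sum(w))
    y_w = float(np.sum(w * ys) / np.sum(w))
    xc, yc = cell_centroid
    svi = (np.hypot(x_w - xc, y_w - yc) - np.hypot(x_geo - xc, y_geo - yc)) / fa_major
    return SviRecord(fa_id=fa_id, geo_centroid=(x_geo, y_geo), weighted_centroid=(x_w, y_w),
                     cell_centroid=(float(xc), float(yc)), fa_major=float(fa_major), svi=float(svi))


def svi_table(labels: np.ndarray, efficiency_map: np.ndarray, records: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """SVI for every adhesion of a cell; cell centroid from the records' centroids."""
    cell_centroid = (float(records["cx"].mean()), float(records["cy"].mean()))
    rows = []
    for _, rec in records.iterrows():
        ys, xs = np.nonzero(labels == rec["id"])
        r = spatial_variation_index(xs, ys, efficiency_map[ys, xs], cell_centroid,
                                    rec["fa_major"], fa_id=int(rec["id"]), **kwargs)
        rows.append({"id": r.fa_id, "svi": r.svi,
                     "x_geo": r.geo_centroid[0], "y_geo": r.geo_centroid[1],
                     "x_weighted": r.weighted_centroid[0], "y_weighted": r.weighted_centroid[1],
                     "fa_major": r.fa_major})
    return pd.DataFrame(rows)
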