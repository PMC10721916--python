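"""Stress-fiber orientation fields and adhesion-fiber coalignment.

Per-pixel fiber orientation comes from the structure tensor of the actin
image (Gaussian-derivative gradients, Gaussian tensor averaging).  The
dominant eigenvector of the tensor points along the intensity *gradient*,
i.e. across a fiber; the reported orientation is the structure axis
perpendicular to it, folded to (-pi/2, pi/2], so that a stripe pattern at
angle phi reads back phi.  The gradient-energy magnitude (larger eigenvalue
l1) thresholds fiber masks.  Coalignment tessellates the cell into Voronoi
regions around adhesion centroids and compares each region's axial-mean
fiber orientation with its adhesion's orientation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from ._angles import axial_difference, axial_mean, axial_std, fold_axial
from ._raster import voronoi_labels

__all__ = ["OrientationField", "sf_orientation_field", "sf_mask", "fa_sf_coalignment"]


@dataclass
class OrientationField:
    theta: np.ndarray  # radians, axial, defined where l1 > 0
    l1: np.ndarray  # dominant eigenvalue (gradient energy)
    convention: str = "structure axis (perpendicular to the dominant-gradient eigenvector)"


def sf_orientation_field(
    image: np.ndarray,
    sigma_gradient: float = 1.0,
    sigma_tensor: float = 2.0,
) -> OrientationField:
    """Structure-tensor orientation of fibrous texture, pixel by pixel."""
    img = np.asarray(image, dtype=float)
    ix = ndimage.gaussian_filter(img, sigma_gradient, order=(0, 1))
    iy = ndimage.gaussian_filter(img, sigma_gradient, order=(1, 0))
    jxx = ndimage.gaussian_filter(ix * ix, sigma_tensor)
    jxy = ndimage.gaussian_filter(ix * iy, sigma_tensor)
    jyy = ndimage.gaussian_filter(iy * iy, sigma_tensor)
    l1 = 0.5 * (jxx + jyy) + np.sqrt((0.5 * (jxx - jyy)) ** 2 + jxy**2)
    theta_gradient = 0.5 * np.arctan2(2.0 * jxy, jxx - jyy)
    theta = fold_axial(theta_gradient + np.pi / 2)
    theta = np.where(l1 > 0, theta, np.nan)
    return OrientationField(theta=theta, l1=l1)


def sf_mask(
    field: OrientationField,
    threshold: float | None = None,
    quantile: float = 0.75,
) -> tuple[np.ndarray, float]:
    """Fiber mask by thresholding gradient energy, plus the per-cell
    orientation spread.

    The threshold defaults to a quantile of the positive l1 values.  The
    spread is the axial standard deviation (degrees) of masked orientations;
    NaN (with a warning) for an empty mask.
    """
    l1 = field.l1
    if threshold is None:
        positive = l1[l1 > 0]
        if positive.size == 0:
            warnings.warn("gradient energy is zero everywhere; empty fiber mask", stacklevel=2)
            return np.zeros_like(l1, dtype=bool), float("nan")
        threshold = float(np.quantile(positive, quantile))
    mask = l1 > threshold
    if not mask.any():
        warnings.warn("threshold above the gradient-energy maximum; empty fiber mask", stacklevel=2)
        return mask, float("nan")
    sd = np.degrees(axial_std(field.theta[mask]))
    return mask, float(sd)


def fa_sf_coalignment(
    field: OrientationField,
    mask: np.ndarray,
    records: pd.DataFrame,
    cell_mask: np.ndarray,
) -> tuple[pd.DataFrame, dict]:
    """Voronoi-region fiber density and adhesion-fiber misalignment.

    The cell is partitioned into nearest-centroid (Voronoi) regions of the
    adhesions.  Per region: fiber density as percent mask area, the
    double-angle axial mean of masked fiber orientations, and the
    misalignment ``theta_rel = |theta_SF - theta_FA|`` folded to
    [0, 90] degrees.  Regions without fiber pixels carry NaN misalignment
    and are excluded from the cell mean (their count is reported).
    """
    if len(records) == 0:
        raise ValueError("no adhesions supplied")
    centroids = records[["cx", "cy"]].to_numpy(dtype=float)
    regions = voronoi_labels(cell_mask.shape, centroids, cell_mask.astype(bool))
    rows = []
    for j, (_, rec) in enumerate(records.iterrows(), start=1):
        region = regions == j
        region_px = int(region.sum())
        sf_px = int((region & mask).sum())
        density = 100.0 * sf_px / region_px if region_px else np.nan
        if sf_px:
            mean_theta, _ = axial_mean(field.theta[region & mask])
            theta_rel = np.degrees(axial_difference(mean_theta, float(rec["orientation"])))
        else:
            mean_theta, theta_rel = np.nan, np.nan
        rows.append({"id": rec["id"], "region_px": region_px, "sf_density_pct": density,
                     "mean_sf_orientation": mean_theta, "theta_fa": float(rec["orientation"]),
                     "theta_rel_deg": theta_rel})
    table = pd.DataFrame(rows)
    valid = table["theta_rel_deg"].notna()
    summary = {
        "mean_theta_rel_deg": float(table.loc[valid, "theta_rel_deg"].mean()) if valid.any() else float("nan"),
        "mean_sf_density_pct": float(table["sf_density_pct"].mean()),
        "n_regions": int(len(table)),
        "n_regions_without_fibers": int((~valid).sum()),
    }
    return table, summary
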