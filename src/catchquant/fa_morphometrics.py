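"""Focal-adhesion segmentation, equivalent-ellipse morphometrics, context
features and maturity classification.

Morphometrics follow the equivalent-ellipse construction: second-order
central moments of each adhesion's binary pixel set form a covariance matrix
whose eigenvalues give the axis lengths and whose principal eigenvector
gives the orientation.  Moments are area-normalised (divided by the pixel
count) and axis lengths scaled so that ``fa_major`` / ``fa_minor`` equal the
full axis lengths (px) of the equivalent ellipse; the axis ratio and
orientation are unaffected by this normalisation.

Context features situate each adhesion within its cell: orientation relative
to the cell's mean adhesion orientation, radial orientation against the
cell-centroid direction, mean distance to the four nearest neighbours, and
normalised distance from the cell edge.  A depth-limited decision tree over
six features (area, axis ratio, the four context features) separates
immature protrusion-associated (PR) from mature stress-fiber-associated (SF)
adhesions.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from sklearn.tree import DecisionTreeClassifier
from skimage import morphology
from skimage.filters import apply_hysteresis_threshold, gaussian
from skimage.segmentation import watershed

from ._angles import axial_mean, fold_axial

__all__ = [
    "segment_fas",
    "cytoplasm_mask",
    "fa_morphometrics",
    "fa_context_features",
    "classify_fa_maturity",
    "MATURITY_FEATURES",
]

MATURITY_FEATURES = ("area", "axis_ratio", "d4fa", "theta_relative", "theta_radial", "d_nce")


def segment_fas(
    image: np.ndarray,
    cell_mask: np.ndarray | None = None,
    dog_sigmas: tuple[float, float] = (1.5, 8.0),
    low_mads: float = 4.0,
    high_mads: float = 8.0,
    min_area_px: int = 9,
    marker_depth_frac: float = 0.3,
) -> np.ndarray:
    """Label adhesions in an acceptor-channel image.

    Difference-of-Gaussians enhancement, hysteresis thresholding against
    robust background statistics (median + k x MAD inside the cell), then a
    marker-based watershed whose markers are h-maxima of the response
    (suppression depth a fraction of the foreground dynamic range), so that
    touching adhesions with distinct intensity peaks split while noise bumps
    on a single adhesion's plateau do not.  Connected foreground left without
    a marker keeps its own label.  Deterministic for fixed parameters; a
    blank image yields zero labels.
    """
    img = np.asarray(image, dtype=float)
    cell = np.ones(img.shape, dtype=bool) if cell_mask is None else cell_mask.astype(bool)
    response = gaussian(img, dog_sigmas[0]) - gaussian(img, dog_sigmas[1])
    vals = response[cell]
    if vals.size == 0 or np.ptp(vals) == 0:
        return np.zeros(img.shape, dtype=int)
    med = np.median(vals)
    mad = np.median(np.abs(vals - med)) or 1e-12
    binary = apply_hysteresis_threshold(response, med + low_mads * mad, med + high_mads * mad)
    binary &= cell
    if not np.any(binary):
        return np.zeros(img.shape, dtype=int)
    depth = marker_depth_frac * max(float(np.percentile(response[binary], 95) - med), 10 * mad)
    markers, _ = ndimage.label(morphology.h_maxima(np.where(binary, response, med), depth))
    labels = watershed(-response, markers, mask=binary) if markers.max() else np.zeros(img.shape, int)
    # connected foreground that received no marker (e.g. dim adhesions) keeps its own label
    leftover, n_extra = ndimage.label(binary & (labels == 0))
    labels = labels + np.where(leftover > 0, leftover + labels.max(), 0)
    sizes = np.bincount(labels.ravel())
    small = np.where(sizes < min_area_px)[0]
    labels[np.isin(labels, small)] = 0
    # relabel contiguously 1..K
    ids = np.unique(labels)
    ids = ids[ids > 0]
    relabelled = np.zeros_like(labels)
    for new, old in enumerate(ids, start=1):
        relabelled[labels == old] = new
    return relabelled


def cytoplasm_mask(
    labels: np.ndarray,
    cell_mask: np.ndarray,
    dilation_radius: int = 10,
) -> np.ndarray:
    """Cytoplasm as the in-cell complement of the dilated adhesion mask.

    The adhesion mask is dilated by a disk of the given radius (the
    configurable reading of a "scale factor of 10" exclusion margin) before
    inversion within the cell boundary.
    """
    fa = labels > 0
    dilated = ndimage.binary_dilation(fa, structure=morphology.disk(dilation_radius))
    cyto = cell_mask.astype(bool) & ~dilated
    if cell_mask.astype(bool).any() and not cyto.any():
        warnings.warn("dilated adhesion mask covers the whole cell; cytoplasm mask is empty", stacklevel=2)
    return cyto


def _region_moments(xs: np.ndarray, ys: np.ndarray) -> tuple[float, float, float, float, float]:
    cx, cy = float(xs.mean()), float(ys.mean())
    dx, dy = xs - cx, ys - cy
    return cx, cy, float(np.mean(dx * dx)), float(np.mean(dy * dy)), float(np.mean(dx * dy))


def _orientation(u20: float, u02: float, u11: float, eps: float = 1e-12) -> tuple[float, bool]:
    """Equivalent-ellipse orientation from second-order central moments.

    The printed moment quotients are tangents of the major-axis angle; the
    arctangent is applied, branching on sign(u20 - u02) for conditioning,
    with circular regions (u20 = u02, u11 = 0) flagged degenerate.
    """
    disc = np.sqrt((u20 - u02) ** 2 + 4.0 * u11**2)
    if disc < eps:
        return 0.0, True
    if abs(u11) < eps:
        return (0.0, False) if u20 >= u02 else (np.pi / 2, False)
    if u20 >= u02:
        theta = np.arctan(2.0 * u11 / (u20 - u02 + disc))
    else:
        theta = np.arctan((u02 - u20 + disc) / (2.0 * u11))
    return float(fold_axial(theta)), False


def fa_morphometrics(
    labels: np.ndarray,
    efficiency_map: np.ndarray | None = None,
    acceptor: np.ndarray | None = None,
) -> pd.DataFrame:
    """Equivalent-ellipse morphometrics for every labelled adhesion.

    Returns one row per label: area, centroid, normalised central moments,
    full axis lengths, axis ratio, orientation (radians, axial), degeneracy
    flag, and mean efficiency / acceptor intensity where maps are provided.
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("label mask contains no adhesions")
    rows = []
    for i in ids:
        ys, xs = np.nonzero(labels == i)
        n = xs.size
        if n == 1:
            rows.append(
                {"id": int(i), "area": 1, "cx": float(xs[0]), "cy": float(ys[0]),
                 "u20": 0.0, "u02": 0.0, "u11": 0.0, "fa_major": 1.0, "fa_minor": 1.0,
                 "axis_ratio": 1.0, "orientation": 0.0, "degenerate_orientation": True}
            )
        else:
            cx, cy, u20, u02, u11 = _region_moments(xs.astype(float), ys.astype(float))
            disc = np.sqrt((u20 - u02) ** 2 + 4.0 * u11**2)
            major = 2.0 * np.sqrt(2.0 * ((u20 + u02) + disc))
            minor = 2.0 * np.sqrt(max(2.0 * ((u20 + u02) - disc), 0.0))
            theta, degen = _orientation(u20, u02, u11)
            rows.append(
                {"id": int(i), "area": int(n), "cx": cx, "cy": cy,
                 "u20": u20, "u02": u02, "u11": u11,
                 "fa_major": major, "fa_minor": minor,
                 "axis_ratio": major / minor if minor > 0 else np.inf,
                 "orientation": theta, "degenerate_orientation": degen}
            )
        if efficiency_map is not None:
            rows[-1]["mean_efficiency"] = float(efficiency_map[labels == i].mean())
        if acceptor is not None:
            rows[-1]["mean_acceptor"] = float(np.asarray(acceptor, dtype=float)[labels == i].mean())
    return pd.DataFrame(rows)


def fa_context_features(
    records: pd.DataFrame,
    cell_mask: np.ndarray,
    n_neighbors: int = 4,
) -> pd.DataFrame:
    """Per-adhesion context features within a cell.

    * ``theta_relative``: orientation minus the cell's mean adhesion
      orientation (axial mean; folded to (-pi/2, pi/2]).
    * ``theta_radial``: angle of the cell-centroid-to-adhesion vector minus
      the adhesion orientation (axially folded).  The cell centroid is the
      mean of adhesion centroids.
    * ``d4fa``: mean distance to the 4 nearest adhesion centroids (fewer,
      with a flag, when the cell has under 5 adhesions).
    * ``d_nce``: distance to the nearest cell-edge point over (that distance
      plus the distance to the cell centroid); 1 at the centroid, 0 on the
      boundary.
    """
    cx = records["cx"].to_numpy(dtype=float)
    cy = records["cy"].to_numpy(dtype=float)
    theta = records["orientation"].to_numpy(dtype=float)
    k = len(records)
    mean_theta, _ = axial_mean(theta)
    cell_cx, cell_cy = float(cx.mean()), float(cy.mean())

    if k > 1:
        tree = cKDTree(np.column_stack([cx, cy]))
        m = min(n_neighbors, k - 1)
        dists, _ = tree.query(np.column_stack([cx, cy]), k=m + 1)
        d4 = dists[:, 1:].mean(axis=1)
        d4_flag = m < n_neighbors
    else:
        d4 = np.full(k, np.nan)
        d4_flag = True
    if d4_flag:
        warnings.warn("fewer than 5 adhesions: d4fa uses available neighbours", stacklevel=2)

    edge_dist = ndimage.distance_transform_edt(cell_mask.astype(bool))
    iy = np.clip(np.round(cy).astype(int), 0, cell_mask.shape[0] - 1)
    ix = np.clip(np.round(cx).astype(int), 0, cell_mask.shape[1] - 1)
    d_edge = edge_dist[iy, ix]
    d_cc = np.hypot(cx - cell_cx, cy - cell_cy)
    with np.errstate(invalid="ignore"):
        d_nce = np.where(d_edge + d_cc > 0, d_edge / (d_edge + d_cc), 1.0)

    theta_subcell = np.arctan2(cy - cell_cy, cx - cell_cx)
    out = pd.DataFrame(
        {
            "id": records["id"].to_numpy(),
            "area": records["area"].to_numpy(),
            "axis_ratio": records["axis_ratio"].to_numpy(),
            "theta_relative": fold_axial(theta - mean_theta),
            "theta_radial": fold_axial(theta_subcell - theta),
            "d4fa": d4,
            "d_nce": d_nce,
            "d4fa_partial": d4_flag,
        }
    )
    return out


def classify_fa_maturity(
    features: pd.DataFrame,
    labels: np.ndarray | None = None,
    model: DecisionTreeClassifier | None = None,
    max_depth: int = 4,
    seed: int = 0,
):
    """Train or apply the PR/SF maturity decision tree.

    With ``labels`` given, fits a depth-limited tree (seeded, deterministic)
    and returns ``(predictions, model)``; with ``model`` given, returns
    ``(predictions, model)`` from the supplied tree.
    """
    missing = [f for f in MATURITY_FEATURES if f not in features.columns]
    if missing:
        raise ValueError(f"missing feature columns: {missing}")
    x = features.loc[:, list(MATURITY_FEATURES)].to_numpy(dtype=float)
    if model is None:
        if labels is None:
            raise ValueError("either a labelled training set or a model is required")
        classes = np.unique(labels)
        if len(classes) < 2:
            raise ValueError("training set contains a single class")
        if not set(classes) <= {"PR", "SF"}:
            raise ValueError("labels must be 'PR' or 'SF'")
        model = DecisionTreeClassifier(max_depth=max_depth, random_state=seed)
        model.fit(x, np.asarray(labels))
    return model.predict(x), model
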