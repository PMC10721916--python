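"""Synthetic cell scenes: FRET triplets and actin fiber images.

The FRET forward model inverts the sensitized-emission equations: given a
per-pixel expression level X and true efficiency E, the noiseless channels

    I_a = X,   I_d = X (1 - E),   I_f = G X E + d_bt I_d + a_bt I_a

round-trip exactly through bleed-through correction and the efficiency
equation.  Adhesions are filled ellipses with a smooth (flat-top
super-Gaussian) intensity falloff; fibers are parallel stripe bundles of
stated angle, thickness and areal coverage.  Noise is Poisson shot noise
plus additive Gaussian read noise, both seeded and optional.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .._raster import (
    along_major_axis,
    default_cell_polygon,
    elliptical_radius,
    polygon_mask,
    voronoi_labels,
)
from ..fretquant import ImageTriplet

#: FRET efficiency of the unloaded tension-sensor module (calibration preset).
UNLOADED_SENSOR_EFFICIENCY = 0.286


@dataclass(frozen=True)
class FaSpec:
    """One rendered adhesion: an ellipse with uniform (or ramped) efficiency."""

    center: tuple[float, float]  # (x, y) px
    axes: tuple[float, float]  # full major/minor axis lengths, px
    orientation: float  # radians from +x toward +y
    efficiency: float = UNLOADED_SENSOR_EFFICIENCY
    peak: float = 8000.0  # counts
    efficiency_gradient: float = 0.0  # dE per px along the major axis

    def __post_init__(self):
        if not 0.0 <= self.efficiency < 1.0:
            raise ValueError("true efficiency must lie in [0, 1)")
        if self.axes[0] < self.axes[1]:
            raise ValueError("major axis must be >= minor axis")


@dataclass(frozen=True)
class FiberSpec:
    """A bundle of parallel fibers filling a region at a given angle."""

    angle: float  # radians
    thickness: float = 3.0  # px
    coverage: float = 0.3  # target foreground area fraction
    fa_index: int | None = None  # restrict to this adhesion's Voronoi region

    def __post_init__(self):
        if not 0.0 < self.coverage <= 1.0:
            raise ValueError("coverage must lie in (0, 1]")
        if self.thickness <= 0:
            raise ValueError("thickness must be positive")


@dataclass(frozen=True)
class SceneSpec:
    shape: tuple[int, int] = (200, 200)
    cell_polygon: np.ndarray | None = None
    fas: Sequence[FaSpec] = ()
    fibers: Sequence[FiberSpec] = ()
    d_bt: float = 0.6
    a_bt: float = 0.2
    g_factor: float = 2.0
    cyto_efficiency: float = UNLOADED_SENSOR_EFFICIENCY
    cyto_level: float = 300.0  # cytoplasmic expression, counts
    poisson_noise: bool = True
    read_noise_sd: float = 3.0  # counts
    seed: int = 0

    def polygon(self) -> np.ndarray:
        if self.cell_polygon is not None:
            return np.asarray(self.cell_polygon, dtype=float)
        return default_cell_polygon(self.shape)


def _noiseless_scene(spec: SceneSpec):
    """Expression level X, efficiency map E, cell mask and FA truth."""
    cell = polygon_mask(spec.shape, spec.polygon())
    x_img = np.where(cell, spec.cyto_level, 0.0)
    e_img = np.where(cell, spec.cyto_efficiency, 0.0)
    labels = np.zeros(spec.shape, dtype=int)
    rows = []
    for i, fa in enumerate(spec.fas, start=1):
        rho = elliptical_radius(spec.shape, fa.center, fa.axes, fa.orientation)
        profile = fa.peak * np.exp(-(rho**4))
        x_img += np.where(cell, profile, 0.0)
        inside = (rho <= 1.0) & cell
        labels[inside] = i
        e_fa = fa.efficiency
        if fa.efficiency_gradient != 0.0:
            s = along_major_axis(spec.shape, fa.center, fa.orientation)
            e_fa = np.clip(fa.efficiency + fa.efficiency_gradient * s, 1e-3, 0.999)[inside]
        e_img[inside] = e_fa
        rows.append(
            {"id": i, "cx": fa.center[0], "cy": fa.center[1],
             "major": fa.axes[0], "minor": fa.axes[1], "orientation": fa.orientation,
             "efficiency": fa.efficiency, "efficiency_gradient": fa.efficiency_gradient,
             "peak": fa.peak, "area_px": int(inside.sum())}
        )
    truth = pd.DataFrame(rows)
    return x_img, e_img, cell, labels, truth


def _apply_noise(img: np.ndarray, spec: SceneSpec, rng: np.random.Generator) -> np.ndarray:
    out = img.astype(float)
    if spec.poisson_noise:
        out = rng.poisson(np.maximum(out, 0.0)).astype(float)
    if spec.read_noise_sd > 0:
        out = out + rng.normal(0.0, spec.read_noise_sd, size=out.shape)
    return out


def gen_fret_scene(spec: SceneSpec) -> tuple[ImageTriplet, dict]:
    """Render a three-channel FRET scene with known ground truth.

    Returns the triplet and a ground-truth dict with the per-adhesion table
    (centroid, axes, orientation, efficiency), the label mask, cell mask and
    noiseless efficiency map.
    """
    rng = np.random.default_rng(spec.seed)
    x_img, e_img, cell, labels, truth = _noiseless_scene(spec)
    donor = x_img * (1.0 - e_img)
    acceptor = x_img.copy()
    fret = spec.g_factor * x_img * e_img + spec.d_bt * donor + spec.a_bt * acceptor
    triplet = ImageTriplet(
        donor=_apply_noise(donor, spec, rng),
        fret=_apply_noise(fret, spec, rng),
        acceptor=_apply_noise(acceptor, spec, rng),
    )
    ground_truth = {
        "fa_table": truth,
        "labels": labels,
        "cell_mask": cell,
        "efficiency": e_img,
        "expression": x_img,
    }
    return triplet, ground_truth


def gen_calibration_scenes(spec: SceneSpec) -> tuple[ImageTriplet, ImageTriplet]:
    """Matching single-fluorophore scenes (donor-only, acceptor-only).

    The same cell/adhesion geometry expresses a single fluorophore, so the
    FRET channel carries pure bleed-through: ``I_f = d_bt I_d`` in the
    donor-only scene and ``I_f = a_bt I_a`` in the acceptor-only scene.
    """
    rng = np.random.default_rng(spec.seed + 1)
    x_img, _, _, _, _ = _noiseless_scene(spec)
    zeros = np.zeros_like(x_img)
    donor_only = ImageTriplet(
        donor=_apply_noise(x_img, spec, rng),
        fret=_apply_noise(spec.d_bt * x_img, spec, rng),
        acceptor=_apply_noise(zeros, spec, rng),
    )
    acceptor_only = ImageTriplet(
        donor=_apply_noise(zeros, spec, rng),
        fret=_apply_noise(spec.a_bt * x_img, spec, rng),
        acceptor=_apply_noise(x_img, spec, rng),
    )
    return donor_only, acceptor_only


def gen_actin_scene(spec: SceneSpec, amplitude: float = 5000.0, blur_sigma: float = 0.8):
    """Render an actin channel of oriented stripe bundles with ground truth.

    Global fibers (``fa_index`` None) fill the whole cell; region-bound
    fibers fill the Voronoi region of their adhesion (nearest-centroid raster
    tessellation).  Returns ``(image, fa_table, truth)`` where truth lists,
    per fiber entry, the planted angle and the realised foreground coverage
    of its region, plus the binary fiber mask and region labels.
    """
    rng = np.random.default_rng(spec.seed + 2)
    cell = polygon_mask(spec.shape, spec.polygon())
    h, w = spec.shape
    yy, xx = np.mgrid[0:h, 0:w]
    fa_rows = [
        {"id": i, "cx": fa.center[0], "cy": fa.center[1], "orientation": fa.orientation,
         "major": fa.axes[0], "minor": fa.axes[1]}
        for i, fa in enumerate(spec.fas, start=1)
    ]
    fa_table = pd.DataFrame(fa_rows)
    if len(spec.fas) > 0:
        centroids = fa_table[["cx", "cy"]].to_numpy()
        regions = voronoi_labels(spec.shape, centroids, cell)
    else:
        regions = cell.astype(int)
    fiber_mask = np.zeros(spec.shape, dtype=bool)
    truth_rows = []
    for k, fiber in enumerate(spec.fibers):
        region = cell if fiber.fa_index is None else (regions == fiber.fa_index + 1)
        spacing = fiber.thickness / fiber.coverage
        phase = rng.uniform(0, spacing)
        t = -xx * np.sin(fiber.angle) + yy * np.cos(fiber.angle) + phase
        stripes = (t % spacing) < fiber.thickness
        planted = stripes & region
        fiber_mask |= planted
        truth_rows.append(
            {"fiber": k, "fa_index": fiber.fa_index, "angle": fiber.angle,
             "target_coverage": fiber.coverage,
             "realised_coverage": planted.sum() / max(region.sum(), 1)}
        )
    image = amplitude * ndimage.gaussian_filter(fiber_mask.astype(float), blur_sigma)
    image += np.where(cell, 50.0, 0.0)
    image = _apply_noise(image, replace(spec, poisson_noise=False), rng)
    truth = {
        "fibers": pd.DataFrame(truth_rows),
        "fiber_mask": fiber_mask,
        "regions": regions,
        "cell_mask": cell,
    }
    return image, fa_table, truth
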