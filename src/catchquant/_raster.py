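"""Shared rasterisation helpers (cell masks, ellipse fields, Voronoi labels).

Image coordinates follow the array convention used throughout the package:
``x`` is the column index, ``y`` the row index, and angles are measured from
the +x axis toward +y.  Generators and analysers share this convention, so
orientations round-trip without sign juggling.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree
from skimage.draw import polygon2mask


def default_cell_polygon(shape: tuple[int, int], margin_frac: float = 0.06, n_vertices: int = 48) -> np.ndarray:
    """Elliptical cell outline inset from the frame, as (x, y) vertices."""
    h, w = shape
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    ry, rx = (0.5 - margin_frac) * h, (0.5 - margin_frac) * w
    t = np.linspace(0, 2 * np.pi, n_vertices, endpoint=False)
    return np.column_stack([cx + rx * np.cos(t), cy + ry * np.sin(t)])


def polygon_mask(shape: tuple[int, int], polygon_xy: np.ndarray) -> np.ndarray:
    """Binary mask of a polygon given as (x, y) vertices."""
    poly = np.asarray(polygon_xy, dtype=float)
    return polygon2mask(shape, poly[:, ::-1])  # polygon2mask wants (row, col)


def elliptical_radius(shape: tuple[int, int], center_xy, axes, orientation: float) -> np.ndarray:
    """Normalised elliptical radius field: 1 on the ellipse outline.

    ``axes`` are the full major/minor axis lengths (px); ``orientation`` is
    the major-axis angle in radians.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    dx = xx - center_xy[0]
    dy = yy - center_xy[1]
    c, s = np.cos(orientation), np.sin(orientation)
    u = dx * c + dy * s  # along major axis
    v = -dx * s + dy * c
    a, b = axes[0] / 2.0, axes[1] / 2.0
    return np.sqrt((u / a) ** 2 + (v / b) ** 2)


def along_major_axis(shape: tuple[int, int], center_xy, orientation: float) -> np.ndarray:
    """Signed distance (px) of each pixel along an axis through a centre."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    return (xx - center_xy[0]) * np.cos(orientation) + (yy - center_xy[1]) * np.sin(orientation)


def voronoi_labels(shape: tuple[int, int], centroids_xy: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Raster Voronoi tessellation: each masked pixel labelled 1..K by nearest seed.

    Pixels outside ``mask`` (or none, if mask is None) are labelled 0.
    """
    centroids = np.atleast_2d(np.asarray(centroids_xy, dtype=float))
    h, w = shape
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    yy, xx = np.nonzero(mask)
    tree = cKDTree(centroids)
    _, nearest = tree.query(np.column_stack([xx, yy]))
    labels = np.zeros(shape, dtype=int)
    labels[yy, xx] = nearest + 1
    return labels
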