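"""Rasterize planar contour rings into binary voxel masks.

A voxel is inside iff its *center* lies inside an odd number of rings assigned
to that voxel's slice (even-odd rule). The crossing test uses a half-open edge
convention — left/bottom boundary inclusive, right/top exclusive — so an
axis-aligned rectangle whose edges pass exactly through voxel-center lines
covers exactly ``width x height`` voxel centers, deterministically.
"""

from __future__ import annotations

import numpy as np

from .geometry import BinaryMask, Contour, ImageGeometry

__all__ = ["rasterize", "points_in_ring"]


def points_in_ring(px: np.ndarray, py: np.ndarray, ring_xy: np.ndarray) -> np.ndarray:
    """Even-odd (crossing-number) point-in-polygon test, vectorized over points.

    Parameters
    ----------
    px, py
        Broadcastable arrays of query-point coordinates (mm).
    ring_xy
        ``(n, 2)`` array of ring vertices; the ring closes implicitly.

    Returns a boolean array of the broadcast shape. Points exactly on a left
    or bottom edge count as inside; on a right or top edge, outside.
    """
    ring_xy = np.asarray(ring_xy, dtype=float)
    x1 = ring_xy[:, 0]
    y1 = ring_xy[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)

    px = np.asarray(px, dtype=float)[..., None]
    py = np.asarray(py, dtype=float)[..., None]

    # An edge is crossed by the rightward ray from (px, py) iff the edge spans
    # py half-openly and the intersection lies strictly right of px.
    spans = (y1 > py) != (y2 > py)
    with np.errstate(divide="ignore", invalid="ignore"):
        x_at = x1 + (py - y1) * (x2 - x1) / np.where(y2 != y1, y2 - y1, np.nan)
    crossings = spans & (px < x_at)
    return (crossings.sum(axis=-1) % 2).astype(bool)


def rasterize(contour: Contour, geometry: ImageGeometry) -> BinaryMask:
    """Rasterize a planar contour onto a voxel grid.

    Each ring is assigned to the nearest slice plane (exact half-spacing ties
    go to the lower-index slice); a ring z outside the grid's z extent is an
    error. Multiple rings on one slice combine by XOR, so nested rings carve
    holes and disjoint rings form separate components.
    """
    xs = geometry.axis_coords(0)
    ys = geometry.axis_coords(1)
    gx, gy = np.meshgrid(xs, ys, indexing="ij")

    voxels = np.zeros(geometry.shape, dtype=bool)
    for ring in contour.rings:
        z = float(ring[0, 2])
        k = geometry.z_index(z)  # raises if z is out of the grid's extent
        inside = points_in_ring(gx, gy, ring[:, :2])
        voxels[:, :, k] ^= inside
    return BinaryMask(geometry, voxels)
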