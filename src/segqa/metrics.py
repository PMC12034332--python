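"""Geometric agreement indices between binary masks.

Three indices quantify how far two delineations of one organ differ:

* **DSC** — Dice similarity coefficient, ``2|A n B| / (|A| + |B|)`` by voxel
  count; 1 means identical volumes.
* **HD** — maximum Hausdorff distance: the larger of the two directed maxima
  of nearest-surface distances, in mm. Sensitive to a single outlying slice
  or an isolated mis-delineated region.
* **MDTA** — mean distance to agreement: the pooled symmetric average of all
  nearest-surface distances, in mm.

Surfaces are the centers of mask voxels that are 6-face-adjacent to a false
or out-of-volume voxel, so every distance is an exact Euclidean distance
between voxel centers in patient mm coordinates. This point-cloud dialect is
deterministic and directly checkable against an all-pairs computation; it is
one of several reasonable surface-distance conventions in use and is stated
as ours, not asserted as universal.

An empty mask on either side makes the distances undefined: the pair is
reported with ``status="undefined_empty"`` rather than an invented number,
because a vanished organ is exactly what screening must surface.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .geometry import BinaryMask

__all__ = [
    "SurfacePointSet",
    "MetricTriple",
    "dice",
    "extract_surface",
    "hausdorff_max",
    "mean_distance_to_agreement",
    "metric_triple",
    "EmptyMaskError",
]

COMPUTED = "computed"
UNDEFINED_EMPTY = "undefined_empty"


class EmptyMaskError(ValueError):
    """An operation that requires a nonempty mask received an empty one."""


@dataclass
class SurfacePointSet:
    """Boundary-voxel centers (mm) extracted from one mask."""

    points: np.ndarray  # (n, 3) float64, mm
    source_mask: Optional[BinaryMask] = None

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class MetricTriple:
    """The (DSC, MDTA, HD) evidence for one structure pair."""

    dsc: float
    mdta_mm: float
    hd_mm: float
    status: str = COMPUTED

    @classmethod
    def undefined(cls) -> "MetricTriple":
        return cls(float("nan"), float("nan"), float("nan"), UNDEFINED_EMPTY)

    @property
    def is_computed(self) -> bool:
        return self.status == COMPUTED


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice similarity coefficient by voxel count; symmetric.

    Defined when at least one mask is nonempty (one empty side gives 0.0);
    both empty raises — callers wanting a total function use
    :func:`metric_triple`, which reports ``undefined_empty``.
    """
    a.require_same_grid(b)
    na = a.count()
    nb = b.count()
    if na == 0 and nb == 0:
        raise EmptyMaskError("DSC of two empty masks is undefined")
    inter = int(np.logical_and(a.voxels, b.voxels).sum())
    return 2.0 * inter / (na + nb)


def extract_surface(m: BinaryMask) -> SurfacePointSet:
    """Boundary voxels of a mask as mm-coordinate voxel centers.

    A true voxel is on the surface iff any of its six face neighbors is false
    or lies outside the volume (the volume edge counts as outside).
    """
    if m.is_empty:
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    v = m.voxels
    padded = np.pad(v, 1, mode="constant", constant_values=False)
    core = padded[1:-1, 1:-1, 1:-1]
    interior = (
        padded[:-2, 1:-1, 1:-1]
        & padded[2:, 1:-1, 1:-1]
        & padded[1:-1, :-2, 1:-1]
        & padded[1:-1, 2:, 1:-1]
        & padded[1:-1, 1:-1, :-2]
        & padded[1:-1, 1:-1, 2:]
    )
    surf = core & ~interior
    idx = np.argwhere(surf).astype(float)
    pts = np.asarray(m.geometry.origin) + idx * np.asarray(m.geometry.spacing)
    return SurfacePointSet(points=pts, source_mask=m)


def _nearest_dists(query: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Distance from each query point to its nearest target point (mm)."""
    tree = cKDTree(target)
    d, _ = tree.query(query, k=1)
    return np.atleast_1d(d)


def hausdorff_max(sa: SurfacePointSet, sb: SurfacePointSet) -> float:
    """Maximum (symmetric) Hausdorff distance between two surfaces, mm.

    This is the true maximum over both directed maxima, not a percentile
    variant: the screening threshold of one slice thickness only makes sense
    for the maximum.
    """
    if len(sa) == 0 or len(sb) == 0:
        raise EmptyMaskError("Hausdorff distance requires two nonempty surfaces")
    d_ab = _nearest_dists(sa.points, sb.points)
    d_ba = _nearest_dists(sb.points, sa.points)
    return float(max(d_ab.max(), d_ba.max()))


def mean_distance_to_agreement(sa: SurfacePointSet, sb: SurfacePointSet) -> float:
    """Pooled symmetric mean surface distance, mm.

    All nearest distances from both directions are pooled and divided once by
    ``|sa| + |sb|`` (not the mean of the two directed averages; the directed
    variant is a one-line change kept out of the default deliberately).
    """
    if len(sa) == 0 or len(sb) == 0:
        raise EmptyMaskError("MDTA requires two nonempty surfaces")
    d_ab = _nearest_dists(sa.points, sb.points)
    d_ba = _nearest_dists(sb.points, sa.points)
    return float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))


def metric_triple(a: BinaryMask, b: BinaryMask) -> MetricTriple:
    """Bundle DSC, MDTA and HD for one mask pair.

    If either mask is empty the triple is reported with status
    ``undefined_empty`` — the pair is never silently dropped.
    """
    a.require_same_grid(b)
    if a.is_empty or b.is_empty:
        return MetricTriple.undefined()
    d = dice(a, b)
    sa = extract_surface(a)
    sb = extract_surface(b)
    d_ab = _nearest_dists(sa.points, sb.points)
    d_ba = _nearest_dists(sb.points, sa.points)
    hd = float(max(d_ab.max(), d_ba.max()))
    mdta = float((d_ab.sum() + d_ba.sum()) / (len(sa) + len(sb)))
    return MetricTriple(dsc=d, mdta_mm=mdta, hd_mm=hd, status=COMPUTED)
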