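"""Core spatial types: image grids, planar contours, binary masks, structure sets.

Every physical distance in the package is anchored to an :class:`ImageGeometry`:
a regular voxel grid with strictly positive spacing and a constant slice
thickness. All lengths are millimetres in patient coordinates; user-facing
configuration in centimetres is converted exactly once at parse time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Union

import numpy as np

__all__ = [
    "ImageGeometry",
    "Contour",
    "BinaryMask",
    "StructureSet",
    "GeometryMismatchError",
]


class GeometryMismatchError(ValueError):
    """Raised when two masks that must share a grid do not.

    Cross-geometry comparison is rejected rather than silently resampled:
    version comparisons are only meaningful on identical CT grids.
    """


@dataclass(frozen=True)
class ImageGeometry:
    """A regular voxel grid in patient coordinates.

    Parameters
    ----------
    shape
        Voxel counts ``(nx, ny, nz)``.
    spacing
        Millimetres per voxel along each axis; all strictly positive. The
        z spacing is the (constant) slice thickness.
    origin
        Millimetre position of the *center* of voxel ``(0, 0, 0)``.
    axis_convention
        Tag for the fixed patient-coordinate frame; informational only, but
        two geometries with different tags never compare equal.
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_convention: str = "LPS"

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or len(self.spacing) != 3 or len(self.origin) != 3:
            raise ValueError("shape, spacing and origin must have length 3")
        if any(n <= 0 for n in self.shape):
            raise ValueError(f"all voxel counts must be positive, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"all spacings must be strictly positive, got {self.spacing}")

    # -- coordinate helpers -------------------------------------------------

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def z_planes(self) -> np.ndarray:
        """Millimetre z positions of the slice planes."""
        return self.axis_coords(2)

    def z_index(self, z_mm: float) -> int:
        """Index of the slice plane nearest ``z_mm``.

        Exact half-spacing ties resolve to the lower-index slice. A z farther
        than half a slice spacing from every plane (i.e. outside the grid's
        z extent) is an error.
        """
        dz = self.spacing[2]
        q = (z_mm - self.origin[2]) / dz
        frac = q - np.floor(q)
        if np.isclose(frac, 0.5, rtol=0.0, atol=1e-9):
            idx = int(np.floor(q))
        else:
            idx = int(np.floor(q + 0.5))
        if idx < 0 or idx >= self.shape[2]:
            raise ValueError(
                f"z={z_mm} mm lies farther than half a slice spacing from any "
                f"slice plane (planes span {self.origin[2]}"
                f"..{self.origin[2] + dz * (self.shape[2] - 1)} mm)"
            )
        return idx

    def to_json_dict(self) -> dict:
        return {
            "shape": list(self.shape),
            "spacing_mm": list(self.spacing),
            "origin_mm": list(self.origin),
            "axis_convention": self.axis_convention,
        }

    @classmethod
    def from_json_dict(cls, d: Mapping) -> "ImageGeometry":
        return cls(
            shape=tuple(d["shape"]),
            spacing=tuple(d["spacing_mm"]),
            origin=tuple(d.get("origin_mm", (0.0, 0.0, 0.0))),
            axis_convention=d.get("axis_convention", "LPS"),
        )

    def save_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load_json(cls, path) -> "ImageGeometry":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


@dataclass
class Contour:
    """Planar contour rings for one organ, in patient mm coordinates.

    ``rings`` is a list of closed vertex rings; each ring is an ``(n, 3)``
    float array whose vertices all share one z value. Several rings may sit on
    one slice (disjoint regions are representable — an isolated mis-delineated
    region is a real failure mode that must survive the round trip).
    """

    organ_name: str
    rings: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for ring in self.rings:
            arr = np.asarray(ring, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3:
                raise ValueError("each ring must be an (n, 3) array of mm coordinates")
            if arr.shape[0] < 3:
                raise ValueError("each ring needs at least 3 vertices")
            if not np.allclose(arr[:, 2], arr[0, 2], rtol=0.0, atol=1e-6):
                raise ValueError("all vertices within a ring must share one z value")
            cleaned.append(arr)
        self.rings = cleaned

    @property
    def is_empty(self) -> bool:
        return len(self.rings) == 0


@dataclass
class BinaryMask:
    """A boolean voxel volume on a fixed grid; True means inside the structure.

    An all-False mask is valid and must be branched on explicitly by callers
    (a vanished organ is the most severe modification, never an exception
    buried downstream).
    """

    geometry: ImageGeometry
    voxels: np.ndarray

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.shape != self.geometry.shape:
            raise ValueError(
                f"voxel array shape {self.voxels.shape} does not match geometry "
                f"shape {self.geometry.shape}"
            )

    @property
    def is_empty(self) -> bool:
        return not bool(self.voxels.any())

    def count(self) -> int:
        return int(self.voxels.sum())

    def volume_mm3(self) -> float:
        return self.count() * float(np.prod(self.geometry.spacing))

    def z_extent_mm(self) -> tuple[float, float]:
        """(min, max) z of the centers of true voxels. Error on empty mask."""
        if self.is_empty:
            raise ValueError("empty mask has no z extent")
        zidx = np.nonzero(self.voxels.any(axis=(0, 1)))[0]
        planes = self.geometry.z_planes()
        return float(planes[zidx[0]]), float(planes[zidx[-1]])

    def same_grid(self, other: "BinaryMask") -> bool:
        return self.geometry == other.geometry

    def require_same_grid(self, other: "BinaryMask") -> None:
        if not self.same_grid(other):
            raise GeometryMismatchError(
                "masks are defined on different image geometries; resampling is "
                "not performed implicitly"
            )

    def copy(self) -> "BinaryMask":
        return BinaryMask(self.geometry, self.voxels.copy())


Structure = Union[Contour, BinaryMask]


@dataclass
class StructureSet:
    """Named organ structures for one patient under one version label."""

    patient_id: str
    version_label: str
    geometry: ImageGeometry
    structures: dict[str, Structure] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def add(self, name: str, structure: Structure) -> None:
        if name in self.structures:
            raise ValueError(f"duplicate organ name {name!r} in structure set")
        self.structures[name] = structure

    def organ_names(self) -> list[str]:
        return list(self.structures)

    def get_mask(self, name: str) -> BinaryMask:
        """Return the organ's binary mask, rasterizing a contour on demand."""
        from .raster import rasterize  # local import to avoid a cycle

        s = self.structures[name]
        if isinstance(s, BinaryMask):
            return s
        mask = rasterize(s, self.geometry)
        self.structures[name] = mask  # cache
        return mask
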