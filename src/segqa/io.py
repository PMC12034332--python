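"""Reading and writing structure sets.

Two on-disk forms are supported:

* **DICOM RT Structure Set** (read only): planar contours parsed with
  pydicom, in patient mm coordinates; the referenced image geometry must be
  supplied separately (as an :class:`ImageGeometry` or its JSON file) since a
  structure set alone does not carry the voxel grid.
* **Mask volume** (read/write, the canonical container): a NIfTI volume via
  nibabel with a JSON sidecar mapping labels to organ names. The writer emits
  a 4-D per-organ stack so overlapping organs round-trip bit-exactly; 3-D
  integer label maps are also readable.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import nibabel as nib
import numpy as np
import pydicom

from .geometry import BinaryMask, Contour, ImageGeometry, StructureSet

__all__ = ["read_structure_set", "write_structure_set", "MissingGeometryError"]


class MissingGeometryError(ValueError):
    """The referenced image geometry was not supplied or not found."""


GeometrySource = Union[ImageGeometry, str, Path, None]


def _resolve_geometry(geometry_source: GeometrySource) -> Optional[ImageGeometry]:
    if geometry_source is None:
        return None
    if isinstance(geometry_source, ImageGeometry):
        return geometry_source
    return ImageGeometry.load_json(geometry_source)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    for suffix in (".nii.gz", ".nii"):
        if name.endswith(suffix):
            return path.with_name(name[: -len(suffix)] + ".json")
    return path.with_suffix(".json")


def _affine(geometry: ImageGeometry) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = geometry.spacing
    aff[:3, 3] = geometry.origin
    return aff


def _is_dicom(path: Path) -> bool:
    if path.suffix.lower() == ".dcm":
        return True
    try:
        with open(path, "rb") as fh:
            fh.seek(128)
            return fh.read(4) == b"DICM"
    except OSError:
        return False


def read_structure_set(path, geometry_source: GeometrySource = None) -> StructureSet:
    """Read a structure set from DICOM RT-Struct or a mask volume.

    Organ names are passed through verbatim — canonicalization is the cohort
    preparation step's job. Structures with zero contour points are included
    as empty, with a note in ``StructureSet.warnings``, never dropped.
    """
    path = Path(path)
    if _is_dicom(path):
        return _read_rtstruct(path, geometry_source)
    return _read_mask_volume(path, geometry_source)


def _read_rtstruct(path: Path, geometry_source: GeometrySource) -> StructureSet:
    geometry = _resolve_geometry(geometry_source)
    if geometry is None:
        raise MissingGeometryError(
            f"missing geometry: reading the RT structure set {path} requires the "
            "referenced image geometry (ImageGeometry or its JSON file)"
        )
    ds = pydicom.dcmread(path)
    roi_names = {
        int(roi.ROINumber): str(roi.ROIName)
        for roi in getattr(ds, "StructureSetROISequence", [])
    }
    patient_id = str(getattr(ds, "PatientID", "unknown"))
    version_label = str(getattr(ds, "StructureSetLabel", "unknown"))
    ss = StructureSet(patient_id=patient_id, version_label=version_label, geometry=geometry)

    for roi_contour in getattr(ds, "ROIContourSequence", []):
        number = int(roi_contour.ReferencedROINumber)
        name = roi_names.get(number, f"roi_{number}")
        rings = []
        for item in getattr(roi_contour, "ContourSequence", []):
            data = np.asarray(item.ContourData, dtype=float).reshape(-1, 3)
            if data.shape[0] >= 3:
                rings.append(data)
        if not rings:
            ss.warnings.append(f"structure {name!r} has zero contour points; kept as empty")
        ss.add(name, Contour(organ_name=name, rings=rings))
    return ss


def _read_mask_volume(path: Path, geometry_source: GeometrySource) -> StructureSet:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MissingGeometryError(
            f"missing geometry: mask volume {path} has no JSON sidecar {sidecar}"
        )
    with open(sidecar) as fh:
        meta = json.load(fh)

    geometry = _resolve_geometry(geometry_source)
    if geometry is None:
        if "geometry" not in meta:
            raise MissingGeometryError(
                f"missing geometry: sidecar {sidecar} carries no geometry block"
            )
        geometry = ImageGeometry.from_json_dict(meta["geometry"])

    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    labels = {int(k): str(v) for k, v in meta.get("labels", {}).items()}

    ss = StructureSet(
        patient_id=str(meta.get("patient_id", "unknown")),
        version_label=str(meta.get("version_label", "unknown")),
        geometry=geometry,
    )
    if data.ndim == 4:  # per-organ stack; label k -> channel k-1
        if data.shape[:3] != geometry.shape:
            raise ValueError(f"mask volume shape {data.shape[:3]} != geometry {geometry.shape}")
        for label in sorted(labels):
            name = labels[label]
            vox = data[..., label - 1].astype(bool)
            if not vox.any():
                ss.warnings.append(f"structure {name!r} is empty in {path.name}")
            ss.add(name, BinaryMask(geometry, vox))
    elif data.ndim == 3:  # integer label map; overlap not representable
        if data.shape != geometry.shape:
            raise ValueError(f"mask volume shape {data.shape} != geometry {geometry.shape}")
        for label in sorted(labels):
            name = labels[label]
            vox = data == label
            if not vox.any():
                ss.warnings.append(f"structure {name!r} is empty in {path.name}")
            ss.add(name, BinaryMask(geometry, vox))
    else:
        raise ValueError(f"unsupported mask volume dimensionality {data.ndim}")
    return ss


def write_structure_set(ss: StructureSet, path) -> None:
    """Write a structure set as a 4-D NIfTI organ stack plus JSON sidecar.

    Masks are preserved bit-exactly (contours are rasterized first); empty
    structures are written as all-zero channels, not dropped. Organ names
    that collide case-insensitively are rejected before anything is written.
    """
    path = Path(path)
    names = list(ss.structures)
    lowered = [n.lower() for n in names]
    if len(set(lowered)) != len(lowered):
        raise ValueError("duplicate organ names (case-insensitive) in structure set")

    nx, ny, nz = ss.geometry.shape
    stack = np.zeros((nx, ny, nz, max(len(names), 1)), dtype=np.uint8)
    labels = {}
    for i, name in enumerate(names):
        struct = ss.structures[name]
        if isinstance(struct, Contour) and struct.is_empty:
            mask_vox = np.zeros(ss.geometry.shape, dtype=bool)
        else:
            mask_vox = ss.get_mask(name).voxels
        stack[..., i] = mask_vox.astype(np.uint8)
        labels[str(i + 1)] = name

    img = nib.Nifti1Image(stack, _affine(ss.geometry))
    img.header.set_zooms((*ss.geometry.spacing, 1.0))
    nib.save(img, str(path))

    meta = {
        "format": "stack",
        "patient_id": ss.patient_id,
        "version_label": ss.version_label,
        "labels": labels,
        "geometry": ss.geometry.to_json_dict(),
    }
    with open(_sidecar_path(path), "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
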