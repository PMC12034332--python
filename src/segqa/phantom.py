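"""Synthetic multi-version phantom cohorts.

Real validation of a segmentation-software update runs on a clinical cohort;
to make every pipeline stage testable without one, this module builds
cohorts of primitive-shape "patients" (spheres, ellipsoids, axis-aligned
tubes and boxes on a pelvis-scale grid) in three versions — ground truth,
pre-update ("old") and post-update ("new") — with controlled perturbations
between versions. Primitive shapes are chosen deliberately: their volumes
and distances are analytic, so every downstream metric has an oracle.

The perturbation taxonomy mirrors the failure modes updates actually
produce: a contour extended by one slice at its superior or inferior end;
a contour truncated by whole slices; an isolated spurious region far from
the organ; one organ's overlap carved out of another (e.g. a brainstem
region removed from the brain); plus plain translation, dilation and
erosion. Each perturbation affects a deterministic, seeded subset of
patients, so a fixture's expected-flag manifest is stable bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional, Sequence

import numpy as np
from scipy import ndimage

from .geometry import BinaryMask, ImageGeometry, StructureSet
from .prep import CropRule

__all__ = [
    "OrganShapeSpec",
    "PhantomSpec",
    "PerturbationSpec",
    "ScenarioBundle",
    "generate_cohort",
    "apply_perturbations",
    "scenario_update_failures",
    "DEFAULT_GEOMETRY",
]

# Big enough for a pelvis-like layout, small enough for seconds-scale tests;
# (1, 1, 2) mm mirrors a 2.0 mm CT slice-thickness protocol.
DEFAULT_GEOMETRY = ImageGeometry(shape=(96, 96, 60), spacing=(1.0, 1.0, 2.0))

ShapeKind = Literal["sphere", "ellipsoid", "tube", "box"]


@dataclass(frozen=True)
class OrganShapeSpec:
    """One primitive organ: a shape with a center and mm size.

    size semantics: sphere -> (radius,); ellipsoid -> (rx, ry, rz);
    tube (axis z) -> (radius, half_length); box -> (lx, ly, lz) full edges.
    """

    name: str
    shape: ShapeKind
    center_mm: tuple[float, float, float]
    size_mm: tuple[float, ...]

    def half_extent(self) -> np.ndarray:
        s = self.size_mm
        if self.shape == "sphere":
            return np.array([s[0]] * 3)
        if self.shape == "ellipsoid":
            return np.array(s[:3])
        if self.shape == "tube":
            return np.array([s[0], s[0], s[1]])
        if self.shape == "box":
            return np.array(s[:3]) / 2.0
        raise ValueError(f"unknown shape {self.shape!r}")


@dataclass(frozen=True)
class PhantomSpec:
    geometry: ImageGeometry = DEFAULT_GEOMETRY
    organs: tuple[OrganShapeSpec, ...] = ()
    seed: int = 0
    n_patients: int = 1
    inter_patient_jitter_mm: float = 0.0
    version_label: str = "ground_truth"


def _mask_for(shape: OrganShapeSpec, center: np.ndarray, geometry: ImageGeometry) -> np.ndarray:
    xs = geometry.axis_coords(0)[:, None, None] - center[0]
    ys = geometry.axis_coords(1)[None, :, None] - center[1]
    zs = geometry.axis_coords(2)[None, None, :] - center[2]
    s = shape.size_mm
    if shape.shape == "sphere":
        return xs**2 + ys**2 + zs**2 <= s[0] ** 2
    if shape.shape == "ellipsoid":
        return (xs / s[0]) ** 2 + (ys / s[1]) ** 2 + (zs / s[2]) ** 2 <= 1.0
    if shape.shape == "tube":
        return (xs**2 + ys**2 <= s[0] ** 2) & (np.abs(zs) <= s[1])
    if shape.shape == "box":
        return (np.abs(xs) <= s[0] / 2) & (np.abs(ys) <= s[1] / 2) & (np.abs(zs) <= s[2] / 2)
    raise ValueError(f"unknown shape {shape.shape!r}")


def generate_cohort(spec: PhantomSpec) -> list[StructureSet]:
    """Generate the ground-truth version of a phantom cohort.

    Per-patient organ centers are jittered by a uniform offset in
    ``[-jitter, +jitter]`` mm per axis, drawn from a per-patient child of the
    spec seed, so identical (spec, seed) always reproduce the identical
    cohort and adding patients never reshuffles existing ones. An organ whose
    analytic bounding box escapes the voxel-center extent after jitter is an
    error naming the organ.
    """
    geom = spec.geometry
    lo = np.asarray(geom.origin)
    hi = lo + (np.asarray(geom.shape) - 1) * np.asarray(geom.spacing)

    cohort: list[StructureSet] = []
    for i in range(spec.n_patients):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(i,)))
        ss = StructureSet(patient_id=f"P{i:03d}", version_label=spec.version_label, geometry=geom)
        for organ in spec.organs:
            j = spec.inter_patient_jitter_mm
            offset = rng.uniform(-j, j, size=3) if j > 0 else np.zeros(3)
            center = np.asarray(organ.center_mm) + offset
            half = organ.half_extent()
            if np.any(center - half < lo) or np.any(center + half > hi):
                raise ValueError(
                    f"organ {organ.name!r} escapes the volume for patient P{i:03d} "
                    f"after jitter (center {center.round(2).tolist()} mm)"
                )
            ss.add(organ.name, BinaryMask(geom, _mask_for(organ, center, geom)))
        cohort.append(ss)
    return cohort


PerturbationKind = Literal[
    "none", "translate", "dilate", "erode",
    "truncate_slices", "extend_slices", "add_isolated_blob", "carve_overlap",
]


@dataclass(frozen=True)
class PerturbationSpec:
    """One controlled modification of one organ in the "new" version.

    ``probability`` is the fraction of patients affected, realized exactly:
    ``round(probability * n_patients)`` patients are drawn without
    replacement from a generator seeded by ``seed``, so the affected subset
    is a pure function of (seed, n_patients).
    """

    organ_name: str
    kind: PerturbationKind = "none"
    magnitude_mm: float = 0.0          # translate / dilate / erode
    axis: int = 0                      # translate axis
    n_slices: int = 0                  # truncate_slices / extend_slices
    end: Literal["superior", "inferior"] = "superior"
    offset_mm: tuple[float, float, float] = (40.0, 0.0, 0.0)  # blob placement
    blob_radius_mm: float = 5.0
    other_organ: Optional[str] = None  # carve_overlap
    probability: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError("probability must lie in [0, 1]")


def _affected_indices(p: PerturbationSpec, n: int) -> np.ndarray:
    k = int(round(p.probability * n))
    if k == 0:
        return np.array([], dtype=int)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=p.seed))
    return np.sort(rng.choice(n, size=k, replace=False))


def _organ_slices(vox: np.ndarray) -> np.ndarray:
    return np.nonzero(vox.any(axis=(0, 1)))[0]


def _perturb_mask(mask: BinaryMask, p: PerturbationSpec, ss: StructureSet) -> np.ndarray:
    geom = mask.geometry
    v = mask.voxels.copy()
    spacing = np.asarray(geom.spacing)

    if p.kind == "translate":
        shift = int(round(p.magnitude_mm / spacing[p.axis]))
        if shift == 0:
            raise ValueError("translate magnitude below one voxel spacing is a silent no-op")
        out = np.zeros_like(v)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        if shift > 0:
            src[p.axis] = slice(0, v.shape[p.axis] - shift)
            dst[p.axis] = slice(shift, None)
        else:
            src[p.axis] = slice(-shift, None)
            dst[p.axis] = slice(0, v.shape[p.axis] + shift)
        out[tuple(dst)] = v[tuple(src)]
        return out

    if p.kind in ("dilate", "erode"):
        if p.kind == "dilate":
            dist = ndimage.distance_transform_edt(~v, sampling=spacing)
            out = v | (dist <= p.magnitude_mm + 1e-9)
        else:
            dist = ndimage.distance_transform_edt(v, sampling=spacing)
            out = dist > p.magnitude_mm + 1e-9
        if np.array_equal(out, v):
            raise ValueError(
                f"{p.kind} by {p.magnitude_mm} mm changes no voxel at spacing "
                f"{geom.spacing}; increase the magnitude past the voxel pitch"
            )
        return out

    if p.kind in ("truncate_slices", "extend_slices"):
        slices = _organ_slices(v)
        if len(slices) == 0:
            raise ValueError(f"organ {p.organ_name!r} is empty; cannot modify slices")
        if p.kind == "truncate_slices":
            if p.n_slices >= len(slices):
                raise ValueError(
                    f"truncation of {p.n_slices} slices >= organ slice count {len(slices)}"
                )
            doomed = slices[-p.n_slices:] if p.end == "superior" else slices[: p.n_slices]
            v[:, :, doomed] = False
            return v
        # extend: copy the terminal slice outward n times
        terminal = slices[-1] if p.end == "superior" else slices[0]
        step = 1 if p.end == "superior" else -1
        plate = v[:, :, terminal].copy()
        for k in range(1, p.n_slices + 1):
            target = terminal + step * k
            if target < 0 or target >= v.shape[2]:
                raise ValueError("slice extension runs off the volume")
            v[:, :, target] |= plate
        return v

    if p.kind == "add_isolated_blob":
        com = np.array(ndimage.center_of_mass(v)) * spacing + np.asarray(geom.origin)
        center = com + np.asarray(p.offset_mm)
        blob_spec = OrganShapeSpec("blob", "sphere", tuple(center), (p.blob_radius_mm,))
        blob = _mask_for(blob_spec, center, geom)
        if not blob.any():
            raise ValueError("isolated blob falls entirely outside the volume")
        if (blob & v).any():
            raise ValueError("blob offset too small: the added region touches the organ")
        return v | blob

    if p.kind == "carve_overlap":
        if p.other_organ is None:
            raise ValueError("carve_overlap needs other_organ")
        other = ss.get_mask(p.other_organ)
        if not (v & other.voxels).any():
            raise ValueError(
                f"carve_overlap of {p.other_organ!r} from {p.organ_name!r} removes no voxel"
            )
        return v & ~other.voxels

    raise ValueError(f"unknown perturbation kind {p.kind!r}")


def apply_perturbations(
    cohort: Sequence[StructureSet],
    perturbations: Sequence[PerturbationSpec],
    new_label: str = "new",
) -> list[StructureSet]:
    """Derive the post-update version of a cohort.

    Unperturbed organs (and unaffected patients) are bit-identical to the
    input; perturbed ones differ in at least one voxel — a perturbation that
    would change nothing raises instead of silently no-opping.
    """
    for p in perturbations:
        if p.kind != "none" and not any(p.organ_name in ss.structures for ss in cohort):
            raise ValueError(f"perturbation targets unknown organ {p.organ_name!r}")

    new_sets = []
    for ss in cohort:
        ns = StructureSet(patient_id=ss.patient_id, version_label=new_label,
                          geometry=ss.geometry)
        for name in ss.organ_names():
            ns.add(name, ss.get_mask(name).copy())
        new_sets.append(ns)

    n = len(cohort)
    for p in perturbations:
        if p.kind == "none":
            continue
        for idx in _affected_indices(p, n):
            ns = new_sets[idx]
            if p.organ_name not in ns.structures:
                continue
            vox = _perturb_mask(ns.get_mask(p.organ_name), p, cohort[idx])
            ns.structures[p.organ_name] = BinaryMask(ns.geometry, vox)
    return new_sets


# ---------------------------------------------------------------------------
# End-to-end scenario fixture
# ---------------------------------------------------------------------------

@dataclass
class ScenarioBundle:
    """Three-version cohort plus the manifest of organs that must (not) flag."""

    cohorts: dict[str, list[StructureSet]]  # labels: old, new, ground_truth
    manifest: dict
    crop_rules: list[CropRule]
    perturbations: list[PerturbationSpec]


def _scenario_organs() -> tuple[OrganShapeSpec, ...]:
    # Pelvis-plus-head toy layout on the 96 x 96 x 60 @ (1,1,2) mm grid.
    # Small tubular organs stand in for lens/optic nerve so the terminal
    # slice carries the full cross-section and a one-slice extension has a
    # deterministic, jitter-independent effect.
    return (
        OrganShapeSpec("brain", "sphere", (48.0, 60.0, 86.0), (26.0,)),
        OrganShapeSpec("brainstem", "tube", (48.0, 60.0, 50.0), (7.0, 22.0)),
        OrganShapeSpec("eye_globe_right", "sphere", (24.0, 24.0, 90.0), (9.0,)),
        OrganShapeSpec("eye_globe_left", "sphere", (72.0, 24.0, 90.0), (9.0,)),
        OrganShapeSpec("lens_right", "tube", (24.0, 24.0, 106.0), (5.0, 6.0)),
        OrganShapeSpec("lens_left", "tube", (72.0, 24.0, 106.0), (5.0, 6.0)),
        OrganShapeSpec("optic_nerve_right", "tube", (24.0, 44.0, 60.0), (2.5, 12.0)),
        OrganShapeSpec("prostate", "sphere", (48.0, 30.0, 30.0), (10.0,)),
        OrganShapeSpec("rectum", "tube", (30.0, 60.0, 32.0), (8.0, 28.0)),
        OrganShapeSpec("bladder", "ellipsoid", (48.0, 72.0, 30.0), (22.0, 20.0, 16.0)),
    )


def scenario_update_failures(seed: int, n_patients: int = 25) -> ScenarioBundle:
    """Bundled three-version cohort reproducing the classic update failure modes.

    Ground truth is the generated cohort; the pre-update version is taken as
    faithful to it (bit-identical), and the post-update version carries:

    * brain: brainstem overlap carved out (all patients),
    * lens (both) / optic nerve (right): one-slice terminal extension,
    * rectum: 10-slice inferior truncation (all) plus one patient with an
      isolated spurious region 40 mm from the organ,
    * bladder: 1 mm dilation (all patients).

    The manifest lists, for criteria A and B under per-organ-mean
    aggregation, which organs must and must not be flagged, plus the organ
    whose ground-truth HD comparison must reach significance.
    """
    spec = PhantomSpec(
        geometry=DEFAULT_GEOMETRY,
        organs=_scenario_organs(),
        seed=seed,
        n_patients=n_patients,
        inter_patient_jitter_mm=2.0,
    )
    gt = generate_cohort(spec)
    old = [StructureSet(ss.patient_id, "old", ss.geometry,
                        {n: ss.get_mask(n).copy() for n in ss.organ_names()})
           for ss in gt]

    perturbations = [
        PerturbationSpec("brain", "carve_overlap", other_organ="brainstem",
                         probability=1.0, seed=seed + 1),
        PerturbationSpec("lens_right", "extend_slices", n_slices=1, end="superior",
                         probability=1.0, seed=seed + 2),
        PerturbationSpec("lens_left", "extend_slices", n_slices=1, end="superior",
                         probability=1.0, seed=seed + 3),
        PerturbationSpec("optic_nerve_right", "extend_slices", n_slices=1, end="inferior",
                         probability=1.0, seed=seed + 4),
        PerturbationSpec("rectum", "truncate_slices", n_slices=10, end="inferior",
                         probability=1.0, seed=seed + 5),
        PerturbationSpec("rectum", "add_isolated_blob", offset_mm=(40.0, 0.0, 0.0),
                         blob_radius_mm=5.0, probability=1.0 / n_patients, seed=seed + 6),
        PerturbationSpec("bladder", "dilate", magnitude_mm=1.0,
                         probability=1.0, seed=seed + 7),
    ]
    new = apply_perturbations(old, perturbations, new_label="new")

    must_flag_a = ["bladder", "brain", "lens_left", "lens_right",
                   "optic_nerve_right", "rectum"]
    must_flag_b = ["brain", "rectum"]
    all_organs = [o.name for o in spec.organs]
    manifest = {
        "version_pair": ["old", "new"],
        "gt_label": "ground_truth",
        "aggregation": "per_organ_mean",
        "criteria_A": {
            "must_flag": must_flag_a,
            "must_not_flag": sorted(set(all_organs) - set(must_flag_a)),
        },
        "criteria_B": {
            "must_flag": must_flag_b,
            "must_not_flag": sorted(set(all_organs) - set(must_flag_b)),
        },
        "truncated_organ": "rectum",
    }
    return ScenarioBundle(
        cohorts={"ground_truth": gt, "old": old, "new": new},
        manifest=manifest,
        crop_rules=[CropRule("rectum", "prostate", 10.0, 10.0)],
        perturbations=perturbations,
    )
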