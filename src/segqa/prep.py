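"""Cohort preparation: pair organs across versions and apply preprocessing.

Vendor and clinician structure names drift between software versions, so
matching goes through a raw-name -> canonical-name map and is
case-insensitive after mapping. The one substantive preprocessing step is an
anchored z-crop: superior/inferior delineation extent of the rectum varies
between observers, so before comparison the rectum is limited to a window of
1 cm above and below the prostate. The window is computed once per patient
from a single designated anchor version and applied identically to every
version, so genuine version differences inside the window survive while
extent variation outside it is excluded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .geometry import BinaryMask, StructureSet

__all__ = [
    "OrganPairing",
    "CropRule",
    "organ_inventory",
    "match_structures",
    "crop_to_anchor",
    "apply_crop_rules",
]


def organ_inventory() -> dict[str, list[str]]:
    """The shipped canonical organ inventory, by anatomical region (28 organs)."""
    with resources.files("segqa.data").joinpath("organs.json").open() as fh:
        return json.load(fh)


@dataclass
class OrganPairing:
    """One patient x canonical organ across all versions.

    ``masks`` maps version label -> BinaryMask for versions where the organ
    exists; ``missing_in`` lists version labels lacking it. Pairings with
    missing versions are excluded from metric computation but always counted
    in reports — inventory drift between software versions must be surfaced,
    not crashed on.
    """

    patient_id: str
    organ_name: str
    masks: dict[str, BinaryMask] = field(default_factory=dict)
    missing_in: list[str] = field(default_factory=list)

    def has(self, label: str) -> bool:
        return label in self.masks


@dataclass(frozen=True)
class CropRule:
    """Limit a target organ's z extent to a margin around an anchor organ."""

    target_organ: str
    anchor_organ: str
    superior_margin_mm: float = 10.0
    inferior_margin_mm: float = 10.0

    def __post_init__(self) -> None:
        if self.superior_margin_mm < 0 or self.inferior_margin_mm < 0:
            raise ValueError("crop margins must be >= 0")


def _canonical(name: str, name_map: Mapping[str, str]) -> str:
    # exact raw match first, then case-insensitive raw match
    if name in name_map:
        return name_map[name].lower()
    lowered = {k.lower(): v for k, v in name_map.items()}
    if name.lower() in lowered:
        return lowered[name.lower()].lower()
    return name.lower()


def match_structures(
    sets: Sequence[StructureSet],
    name_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[OrganPairing], list[str]]:
    """Pair organs across versions for every patient.

    Returns ``(pairings, unknown_names)`` where ``unknown_names`` lists raw
    names absent from the shipped inventory after mapping (passed through and
    paired anyway, but reported — never silently dropped). Two raw names
    mapping to one canonical name within a single structure set are ambiguous
    and raise.
    """
    name_map = dict(name_map or {})
    inventory = {o for organs in organ_inventory().values() for o in organs}

    by_patient: dict[str, list[StructureSet]] = {}
    for ss in sets:
        by_patient.setdefault(ss.patient_id, []).append(ss)

    pairings: list[OrganPairing] = []
    unknown: list[str] = []
    for patient_id in sorted(by_patient):
        patient_sets = by_patient[patient_id]
        labels = [ss.version_label for ss in patient_sets]
        canonical_by_set: list[dict[str, str]] = []
        for ss in patient_sets:
            seen: dict[str, str] = {}
            for raw in ss.organ_names():
                canon = _canonical(raw, name_map)
                if canon in seen:
                    raise ValueError(
                        f"ambiguous mapping in {ss.version_label}/{patient_id}: both "
                        f"{seen[canon]!r} and {raw!r} map to {canon!r}"
                    )
                seen[canon] = raw
                if canon not in inventory and canon not in unknown:
                    unknown.append(canon)
            canonical_by_set.append(seen)

        all_canon = sorted({c for seen in canonical_by_set for c in seen})
        for canon in all_canon:
            pairing = OrganPairing(patient_id=patient_id, organ_name=canon)
            for ss, seen in zip(patient_sets, canonical_by_set):
                if canon in seen:
                    pairing.masks[ss.version_label] = ss.get_mask(seen[canon])
                else:
                    pairing.missing_in.append(ss.version_label)
            pairings.append(pairing)
    return pairings, unknown


def crop_to_anchor(target: BinaryMask, anchor: BinaryMask, rule: CropRule) -> BinaryMask:
    """Zero all target voxels outside the anchor-derived z window.

    The window is ``[anchor_zmin - inferior_margin, anchor_zmax +
    superior_margin]`` in mm (z extent over anchor's true-voxel centers); a
    slice survives iff its plane z lies in the closed interval, so a 10 mm
    margin on 2 mm slices keeps exactly five extra slices on each side. An
    empty anchor is an error; a target emptied by the crop is returned empty.
    """
    target.require_same_grid(anchor)
    if anchor.is_empty:
        raise ValueError("anchor required for crop: anchor mask is empty")
    zmin, zmax = anchor.z_extent_mm()
    lo = zmin - rule.inferior_margin_mm
    hi = zmax + rule.superior_margin_mm
    planes = target.geometry.z_planes()
    # tiny float slack so window edges computed from exact mm land inclusively
    keep = (planes >= lo - 1e-9) & (planes <= hi + 1e-9)
    voxels = target.voxels.copy()
    voxels[:, :, ~keep] = False
    return BinaryMask(target.geometry, voxels)


def apply_crop_rules(
    pairings: Iterable[OrganPairing],
    rules: Sequence[CropRule],
    anchor_version_priority: Sequence[str] = ("ground_truth", "old"),
) -> list[OrganPairing]:
    """Apply crop rules patient-wise, one window per patient per rule.

    The window is derived from a single designated version's anchor — ground
    truth when present, else the first available by priority, else any
    version the anchor exists in — and the same window is applied to every
    version's target so the crop never confounds the version comparison.
    Patients whose anchor organ is absent everywhere keep their target uncropped.
    """
    pairings = list(pairings)
    by_patient: dict[str, dict[str, OrganPairing]] = {}
    for p in pairings:
        by_patient.setdefault(p.patient_id, {})[p.organ_name] = p

    out: list[OrganPairing] = []
    for p in pairings:
        rule = next((r for r in rules if r.target_organ.lower() == p.organ_name), None)
        if rule is None:
            out.append(p)
            continue
        anchor_pairing = by_patient[p.patient_id].get(rule.anchor_organ.lower())
        anchor_mask = None
        if anchor_pairing is not None:
            for label in anchor_version_priority:
                m = anchor_pairing.masks.get(label)
                if m is not None and not m.is_empty:
                    anchor_mask = m
                    break
            if anchor_mask is None:
                for m in anchor_pairing.masks.values():
                    if not m.is_empty:
                        anchor_mask = m
                        break
        if anchor_mask is None:
            out.append(p)
            continue
        cropped = OrganPairing(p.patient_id, p.organ_name, missing_in=list(p.missing_in))
        for label, mask in p.masks.items():
            cropped.masks[label] = crop_to_anchor(mask, anchor_mask, rule)
        out.append(cropped)
    return out
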