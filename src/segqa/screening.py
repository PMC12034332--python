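"""Criteria-based screening of version-pair metric triples.

Two shipped criteria sets:

* **A** (strict): DSC 0.99, MDTA 0.05 cm, HD 0.2 cm — designed so that any
  contour touched at all by a software update is caught; 0.2 cm is one CT
  slice at the protocol's 2.0 mm thickness.
* **B** (standard): DSC 0.9, MDTA 0.2 cm, HD 1.0 cm — the conventional
  "nearly identical" thresholds.

A contour is *notably modified* if any single index fails its threshold.
Values exactly at a threshold do not violate: criteria are written as target
values, so violation is by strict inequality. A pair whose metrics are
undefined because a mask is empty always flags — a vanished organ is the
severest modification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np

from .metrics import COMPUTED, MetricTriple, UNDEFINED_EMPTY, metric_triple
from .prep import OrganPairing

__all__ = [
    "CriteriaSet",
    "CRITERIA_A",
    "CRITERIA_B",
    "ScreeningVerdict",
    "OrganSummary",
    "evaluate_criteria",
    "screen_cohort",
]


@dataclass(frozen=True)
class CriteriaSet:
    """Thresholds for the three indices plus the any-violation flagging rule."""

    name: str
    dsc_min: float
    mdta_max_mm: float
    hd_max_mm: float

    def __post_init__(self) -> None:
        if not (0.0 < self.dsc_min <= 1.0):
            raise ValueError("dsc_min must lie in (0, 1]")
        if self.mdta_max_mm < 0:
            raise ValueError("mdta_max_mm must be >= 0")
        if self.hd_max_mm < self.mdta_max_mm:
            raise ValueError("hd_max_mm must be >= mdta_max_mm")

    @classmethod
    def from_cm(cls, name: str, dsc_min: float, mdta_max_cm: float, hd_max_cm: float) -> "CriteriaSet":
        """User-facing configs state distances in cm; converted here, once."""
        return cls(name, dsc_min, mdta_max_cm * 10.0, hd_max_cm * 10.0)


CRITERIA_A = CriteriaSet("A", dsc_min=0.99, mdta_max_mm=0.5, hd_max_mm=2.0)
CRITERIA_B = CriteriaSet("B", dsc_min=0.9, mdta_max_mm=2.0, hd_max_mm=10.0)


@dataclass
class ScreeningVerdict:
    patient_id: str
    organ_name: str
    criteria_name: str
    flagged: bool
    violated: tuple[str, ...]  # subset of ("dsc", "mdta", "hd")
    triple: MetricTriple


@dataclass
class OrganSummary:
    """Per-organ aggregation across patients for one version pair."""

    organ_name: str
    n_patients: int
    n_undefined: int
    mean_dsc: float
    mean_mdta_mm: float
    mean_hd_mm: float
    flagged: bool
    violated: tuple[str, ...]


def evaluate_criteria(triple: MetricTriple, criteria: CriteriaSet,
                      patient_id: str = "", organ_name: str = "") -> ScreeningVerdict:
    """Judge one metric triple against one criteria set.

    Violations: ``dsc < dsc_min``, ``mdta > mdta_max``, ``hd > hd_max`` (all
    strict); flagged is their OR. An undefined (empty-mask) triple flags with
    all three indices marked.
    """
    if triple.status == UNDEFINED_EMPTY:
        return ScreeningVerdict(patient_id, organ_name, criteria.name,
                                flagged=True, violated=("dsc", "mdta", "hd"), triple=triple)
    violated = []
    if triple.dsc < criteria.dsc_min:
        violated.append("dsc")
    if triple.mdta_mm > criteria.mdta_max_mm:
        violated.append("mdta")
    if triple.hd_mm > criteria.hd_max_mm:
        violated.append("hd")
    return ScreeningVerdict(patient_id, organ_name, criteria.name,
                            flagged=bool(violated), violated=tuple(violated), triple=triple)


Aggregation = Literal["per_organ_mean", "per_patient"]


def screen_cohort(
    pairings: Iterable[OrganPairing],
    version_pair: tuple[str, str],
    criteria: CriteriaSet,
    aggregation: Aggregation = "per_organ_mean",
) -> tuple[list[ScreeningVerdict], list[OrganSummary]]:
    """Screen every patient x organ for one version pair.

    Per-patient verdicts are always produced. The organ-level flag depends on
    ``aggregation``: under ``per_organ_mean`` the organ flags iff the *mean*
    triple across patients violates (the reading used for per-organ bar
    summaries); under ``per_patient`` iff any single patient violates, which
    exposes worst cases that a mean hides. Organs missing or empty in either
    version produce undefined verdicts, which flag unconditionally and force
    the organ-level flag under both aggregations.
    """
    pairings = list(pairings)
    if not pairings:
        raise ValueError("empty cohort: no organ pairings to screen")
    label_a, label_b = version_pair

    verdicts: list[ScreeningVerdict] = []
    by_organ: dict[str, list[MetricTriple]] = {}
    undefined_count: dict[str, int] = {}
    for p in pairings:
        ma = p.masks.get(label_a)
        mb = p.masks.get(label_b)
        if ma is None or mb is None or ma.is_empty or mb.is_empty:
            triple = MetricTriple.undefined()
        else:
            triple = metric_triple(ma, mb)
        verdicts.append(evaluate_criteria(triple, criteria, p.patient_id, p.organ_name))
        by_organ.setdefault(p.organ_name, []).append(triple)
        if triple.status == UNDEFINED_EMPTY:
            undefined_count[p.organ_name] = undefined_count.get(p.organ_name, 0) + 1

    summaries: list[OrganSummary] = []
    for organ in sorted(by_organ):
        triples = by_organ[organ]
        computed = [t for t in triples if t.status == COMPUTED]
        n_undef = undefined_count.get(organ, 0)
        if computed:
            mean_triple = MetricTriple(
                dsc=float(np.mean([t.dsc for t in computed])),
                mdta_mm=float(np.mean([t.mdta_mm for t in computed])),
                hd_mm=float(np.mean([t.hd_mm for t in computed])),
            )
        else:
            mean_triple = MetricTriple.undefined()

        if aggregation == "per_organ_mean":
            verdict = evaluate_criteria(mean_triple, criteria)
            flagged = verdict.flagged or n_undef > 0
            violated = verdict.violated if verdict.flagged else ()
        elif aggregation == "per_patient":
            per = [evaluate_criteria(t, criteria) for t in triples]
            flagged = any(v.flagged for v in per)
            violated = tuple(sorted({i for v in per for i in v.violated}))
        else:
            raise ValueError(f"unknown aggregation {aggregation!r}")
        if n_undef > 0:
            violated = tuple(sorted(set(violated) | {"dsc", "mdta", "hd"}))
        summaries.append(OrganSummary(
            organ_name=organ,
            n_patients=len(triples),
            n_undefined=n_undef,
            mean_dsc=mean_triple.dsc,
            mean_mdta_mm=mean_triple.mdta_mm,
            mean_hd_mm=mean_triple.hd_mm,
            flagged=flagged,
            violated=violated,
        ))
    return verdicts, summaries
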