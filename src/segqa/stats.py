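"""Ground-truth re-evaluation and paired version statistics.

Organs flagged by screening are re-measured against expert ground-truth
contours, and per-organ, per-metric differences between software versions are
tested with the two-sided Wilcoxon signed-rank test at alpha = 0.05. The test
is always two-sided: updates were observed to both improve and degrade
contours, and the question is "did this organ change", not "did it improve".

Zero differences (version-identical contours, which are common here) are
handled by a configurable policy: ``drop`` (classic Wilcoxon, the default)
discards them before ranking; ``keep`` uses the zero-inclusive Pratt
variant. The exact null distribution is used when the effective sample size
is at most 25 and the absolute differences carry no tied ranks; otherwise the
normal approximation with tie correction. No multiple-testing correction is
applied by default (raw per-organ, per-metric p-values are reported); a Holm
adjustment is available but off.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .metrics import COMPUTED, MetricTriple, metric_triple
from .prep import OrganPairing

__all__ = [
    "PairedMetricSeries",
    "StatResult",
    "ground_truth_metrics",
    "wilcoxon_signed_rank",
    "holm_adjust",
    "build_summary_table",
]

METRIC_NAMES = ("dsc", "mdta", "hd")


@dataclass
class PairedMetricSeries:
    """Per-patient paired values of one metric for one organ, two versions.

    Only patients with a *computed* triple in both versions enter; pairs are
    aligned by patient.
    """

    organ_name: str
    metric_name: str
    version_a: str
    version_b: str
    values_a: np.ndarray
    values_b: np.ndarray

    def __post_init__(self) -> None:
        self.values_a = np.asarray(self.values_a, dtype=float)
        self.values_b = np.asarray(self.values_b, dtype=float)
        if self.values_a.shape != self.values_b.shape or self.values_a.ndim != 1:
            raise ValueError("paired value arrays must be 1-D and equal length")
        if len(self.values_a) < 1:
            raise ValueError("a paired series needs at least one patient")

    @property
    def n(self) -> int:
        return len(self.values_a)


@dataclass
class StatResult:
    organ_name: str
    metric_name: str
    version_a: str
    version_b: str
    n: int
    mean_a: float
    mean_b: float
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    p_value: float  # nan when not testable
    significant: bool
    testable: bool
    method: str  # "exact" | "approx" | "degenerate" | "none"
    zero_policy: str
    alpha: float


def ground_truth_metrics(
    pairings: Iterable[OrganPairing],
    gt_label: str,
    version_labels: Optional[Sequence[str]] = None,
    organs: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Metric triples of each version against ground truth, per patient x organ.

    Returns a tidy frame with columns patient_id, organ, version, dsc,
    mdta_mm, hd_mm, status. Organs missing from ground truth are excluded
    from computation but still appear with status ``missing_gt`` so the
    report can surface them. ``organs`` restricts to a flagged subset
    (pipeline mode); None evaluates everything (standalone mode).
    """
    pairings = list(pairings)
    if version_labels is None:
        labels = sorted({lbl for p in pairings for lbl in p.masks} - {gt_label})
    else:
        labels = [l for l in version_labels if l != gt_label]
    if not any(p.has(gt_label) for p in pairings):
        raise ValueError(f"ground-truth label {gt_label!r} absent from cohort")

    wanted = None if organs is None else {o.lower() for o in organs}
    rows = []
    for p in pairings:
        if wanted is not None and p.organ_name not in wanted:
            continue
        gt = p.masks.get(gt_label)
        for label in labels:
            m = p.masks.get(label)
            if gt is None:
                rows.append((p.patient_id, p.organ_name, label,
                             np.nan, np.nan, np.nan, "missing_gt"))
                continue
            if m is None or m.is_empty or gt.is_empty:
                t = MetricTriple.undefined()
            else:
                t = metric_triple(m, gt)
            rows.append((p.patient_id, p.organ_name, label,
                         t.dsc, t.mdta_mm, t.hd_mm, t.status))
    return pd.DataFrame(
        rows, columns=["patient_id", "organ", "version", "dsc", "mdta_mm", "hd_mm", "status"]
    )


def _has_tied_ranks(abs_d: np.ndarray) -> bool:
    return len(np.unique(abs_d)) != len(abs_d)


def wilcoxon_signed_rank(
    series: PairedMetricSeries,
    alpha: float = 0.05,
    zero_policy: Literal["drop", "keep"] = "drop",
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test on one paired metric series.

    Means and ranges are computed over exactly the paired patients. All-zero
    differences give p = 1 (no evidence of change); zero effective sample
    size under the drop policy yields a not-testable result, never a
    fabricated p-value.
    """
    a, b = series.values_a, series.values_b
    d = a - b

    base = dict(
        organ_name=series.organ_name, metric_name=series.metric_name,
        version_a=series.version_a, version_b=series.version_b,
        n=series.n,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        range_a=(float(a.min()), float(a.max())),
        range_b=(float(b.min()), float(b.max())),
        zero_policy=zero_policy, alpha=alpha,
    )

    if np.all(d == 0):
        return StatResult(p_value=1.0, significant=False, testable=True,
                          method="degenerate", **base)

    nonzero = d[d != 0]
    if zero_policy == "drop":
        n_eff = len(nonzero)
        scipy_zero = "wilcox"
        exact_ok = n_eff <= 25 and not _has_tied_ranks(np.abs(nonzero))
    elif zero_policy == "keep":
        n_eff = len(d)
        scipy_zero = "pratt"
        # exact null with zero-inclusive ranking is not well defined; approx.
        exact_ok = False
    else:
        raise ValueError(f"unknown zero_policy {zero_policy!r}")

    if n_eff == 0:
        return StatResult(p_value=float("nan"), significant=False, testable=False,
                          method="none", **base)

    method = "exact" if exact_ok else "approx"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sps.wilcoxon(a, b, zero_method=scipy_zero,
                           alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return StatResult(p_value=p, significant=bool(p < alpha), testable=True,
                      method=method, **base)


def holm_adjust(results: Sequence[StatResult], alpha: float = 0.05) -> list[StatResult]:
    """Holm step-down adjustment across a family of results (optional, off by
    default in the pipeline: raw per-test p-values are the primary output)."""
    testable = [r for r in results if r.testable and np.isfinite(r.p_value)]
    m = len(testable)
    order = np.argsort([r.p_value for r in testable])
    adjusted = {}
    running = 0.0
    for rank, idx in enumerate(order):
        r = testable[idx]
        adj = min(1.0, (m - rank) * r.p_value)
        running = max(running, adj)
        adjusted[id(r)] = running
    out = []
    for r in results:
        if id(r) in adjusted:
            p = adjusted[id(r)]
            out.append(StatResult(**{**r.__dict__, "p_value": p,
                                     "significant": bool(p < alpha)}))
        else:
            out.append(r)
    return out


def series_from_table(table: pd.DataFrame, organ: str, metric: str,
                      version_a: str, version_b: str) -> Optional[PairedMetricSeries]:
    """Build a paired series from a ground_truth_metrics table.

    Pairs only patients whose triple is computed in BOTH versions; returns
    None when no such patient exists.
    """
    col = {"dsc": "dsc", "mdta": "mdta_mm", "hd": "hd_mm"}[metric]
    sub = table[(table["organ"] == organ) & (table["status"] == COMPUTED)]
    wide = sub.pivot_table(index="patient_id", columns="version", values=col, aggfunc="first")
    if version_a not in wide.columns or version_b not in wide.columns:
        return None
    wide = wide[[version_a, version_b]].dropna()
    if wide.empty:
        return None
    return PairedMetricSeries(
        organ_name=organ, metric_name=metric,
        version_a=version_a, version_b=version_b,
        values_a=wide[version_a].to_numpy(), values_b=wide[version_b].to_numpy(),
    )


def compare_versions(
    table: pd.DataFrame,
    version_pairs: Sequence[tuple[str, str]],
    alpha: float = 0.05,
    zero_policy: Literal["drop", "keep"] = "drop",
) -> list[StatResult]:
    """Wilcoxon tests for every organ x metric x version pair in the table."""
    results = []
    for organ in sorted(table["organ"].unique()):
        for metric in METRIC_NAMES:
            for va, vb in version_pairs:
                series = series_from_table(table, organ, metric, va, vb)
                if series is None:
                    continue
                results.append(wilcoxon_signed_rank(series, alpha=alpha,
                                                    zero_policy=zero_policy))
    return results


def _cell(mean: float, lo: float, hi: float) -> str:
    return f"{mean:.2f} ({lo:.2f}–{hi:.2f})"


def build_summary_table(results: Sequence[StatResult]) -> pd.DataFrame:
    """Render results as one row per organ: per-version "mean (min-max)" cells
    and per-version-pair p-values; missing combinations shown as "-". Distances
    are reported in cm in this human-facing table (full precision stays in the
    machine-readable results)."""
    if not results:
        raise ValueError("no results to summarize")
    organs = sorted({r.organ_name for r in results})
    versions: list[str] = []
    pairs: list[tuple[str, str]] = []
    for r in results:
        for v in (r.version_a, r.version_b):
            if v not in versions:
                versions.append(v)
        if (r.version_a, r.version_b) not in pairs:
            pairs.append((r.version_a, r.version_b))

    def scale(metric: str, x: float) -> float:
        return x / 10.0 if metric in ("mdta", "hd") else x  # mm -> cm

    rows = []
    for organ in organs:
        row: dict[str, str] = {"organ": organ}
        for metric in METRIC_NAMES:
            rs = [r for r in results if r.organ_name == organ and r.metric_name == metric]
            for v in versions:
                cell = "–"
                for r in rs:
                    if r.version_a == v:
                        cell = _cell(scale(metric, r.mean_a),
                                     scale(metric, r.range_a[0]), scale(metric, r.range_a[1]))
                        break
                    if r.version_b == v:
                        cell = _cell(scale(metric, r.mean_b),
                                     scale(metric, r.range_b[0]), scale(metric, r.range_b[1]))
                        break
                row[f"{metric} {v}"] = cell
            for va, vb in pairs:
                match = [r for r in rs if (r.version_a, r.version_b) == (va, vb)]
                key = f"{metric} p({va} vs {vb})"
                if not match or not match[0].testable:
                    row[key] = "–"
                else:
                    r = match[0]
                    mark = "*" if r.significant else ""
                    row[key] = f"{r.p_value:.3g}{mark}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("organ")
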