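"""Univariate case/non-case screens.

Marker distributions (log MoMs) are compared with the Wilcoxon rank-sum
(Mann–Whitney) test, categorical maternal characteristics with the Pearson
chi-square test, and marker–cervical-length interactions with the Pearson
correlation.  Markers significant at ``p < alpha`` (two-tailed by default)
feed the downstream logistic risk models.  No multiple-testing correction is
applied across the five-marker panel; reports carry the raw p-values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CL, MAP, RNA_MARKERS, SubjectRecord, in_stratum
from .mom import MoMProfile

#: Direction of the one-tailed tests: cases are expected to have a shorter
#: cervix and a higher mean arterial pressure.
ONE_TAILED_DIRECTION = {CL: "less", MAP: "greater"}


@dataclass(frozen=True)
class AssociationResult:
    """Outcome of one univariate comparison."""

    label: str
    statistic: float
    p_value: float
    tails: int
    group_medians: Mapping[str, float] = field(default_factory=dict)
    n: Mapping[str, int] = field(default_factory=dict)
    warning: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def wilcoxon_rank_sum(
    case_values: Sequence[float],
    noncase_values: Sequence[float],
    alternative: str = "two-sided",
    label: str = "",
) -> AssociationResult:
    """Rank-sum comparison of case vs non-case values (typically log MoMs).

    Uses exact enumeration when the smaller group has ≤ 8 observations and the
    pooled sample is tie-free, otherwise the normal approximation with
    continuity and tie correction.  ``alternative`` is 'two-sided', 'less' or
    'greater', oriented as case vs non-case.
    """
    x = np.asarray(case_values, float)
    y = np.asarray(noncase_values, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    tails = 2 if alternative == "two-sided" else 1
    medians = {"case": float(np.median(x)), "noncase": float(np.median(y))}
    ns = {"case": int(x.size), "noncase": int(y.size)}

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return AssociationResult(
            label, float(x.size * y.size / 2.0), 1.0, tails, medians, ns,
            warning="all values identical; rank test is uninformative",
        )
    tie_free = np.unique(pooled).size == pooled.size
    method = "exact" if (min(x.size, y.size) <= 8 and tie_free) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method=method, use_continuity=True
    )
    return AssociationResult(label, float(res.statistic), float(res.pvalue),
                             tails, medians, ns)


def chi_square_test(table: Sequence[Sequence[float]], label: str = "") -> AssociationResult:
    """Pearson chi-square on an r×k contingency table (no Yates correction)."""
    counts = np.asarray(table, float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2x2")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("table entries must be non-negative integers")
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError("contingency table has a zero margin")
    res = stats.chi2_contingency(counts, correction=False)
    return AssociationResult(label, float(res.statistic), float(res.pvalue), 2,
                             n={"total": int(counts.sum())})


def pearson_correlation(
    x: Sequence[float], y: Sequence[float], label: str = ""
) -> AssociationResult:
    """Pearson r with two-sided p from the t distribution (n − 2 df)."""
    xa = np.asarray(x, float)
    ya = np.asarray(y, float)
    if xa.size != ya.size:
        raise ValueError("paired samples must have equal length")
    if xa.size < 3:
        raise ValueError("correlation requires n >= 3 pairs")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise ValueError("zero variance in one of the samples")
    res = stats.pearsonr(xa, ya)
    return AssociationResult(label, float(res.statistic), float(res.pvalue), 2,
                             n={"pairs": int(xa.size)})


def select_significant_markers(
    results: Mapping[str, AssociationResult], alpha: float = 0.05
) -> List[str]:
    """Markers/factors whose comparison reached ``p < alpha``."""
    return [name for name, res in results.items() if res.p_value < alpha]


def percent(numerator: float, denominator: float, ndigits: int = 1) -> float:
    """Percentage rounded to the table's printed precision."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, ndigits)


def column_percentages(table: Sequence[Sequence[float]], ndigits: int = 0) -> np.ndarray:
    """Each cell as a percentage of its column total (demographic-table shape)."""
    counts = np.asarray(table, float)
    totals = counts.sum(axis=0)
    if np.any(totals == 0):
        raise ValueError("zero column margin")
    return np.round(100.0 * counts / totals, ndigits)


def marker_screen(
    profiles: Sequence[MoMProfile],
    records: Sequence[SubjectRecord],
    case_stratum: str,
    markers: Iterable[str] = RNA_MARKERS,
    extra_one_tailed: Iterable[str] = (),
) -> Dict[str, AssociationResult]:
    """Run the rank-sum screen of every marker for one case definition.

    RNAs are tested two-tailed; markers listed in ``extra_one_tailed`` (CL or
    MAP) one-tailed in their expected direction.  Controls are the non-case
    group.  Markers absent in a subject (missing or below detection) drop that
    subject from the marker's comparison.
    """
    by_id = {r.subject_id: r for r in records}
    results: Dict[str, AssociationResult] = {}
    tested = list(markers) + list(extra_one_tailed)
    for marker in tested:
        case_vals, control_vals = [], []
        for prof in profiles:
            if marker not in prof.log10_mom:
                continue
            rec = by_id[prof.subject_id]
            if in_stratum(rec.outcome, case_stratum):
                case_vals.append(prof.log10_mom[marker])
            elif in_stratum(rec.outcome, "NONCASE"):
                control_vals.append(prof.log10_mom[marker])
        if not case_vals or not control_vals:
            warnings.warn(f"{marker}: empty group for {case_stratum}; skipped")
            continue
        alternative = ONE_TAILED_DIRECTION.get(marker, "two-sided")
        if marker not in ONE_TAILED_DIRECTION:
            alternative = "two-sided"
        results[marker] = wilcoxon_rank_sum(
            case_vals, control_vals, alternative=alternative,
            label=f"{marker} {case_stratum} vs NONCASE",
        )
    return results


def screen_table(results: Mapping[str, AssociationResult]) -> pd.DataFrame:
    """Marker-table-shaped summary: median MoM per group, group sizes, p."""
    rows = []
    for marker, res in results.items():
        rows.append({
            "marker": marker,
            "case_median_mom": round(10 ** res.group_medians["case"], 2),
            "noncase_median_mom": round(10 ** res.group_medians["noncase"], 2),
            "n_case": res.n["case"],
            "n_noncase": res.n["noncase"],
            "tails": res.tails,
            "p_value": res.p_value,
        })
    return pd.DataFrame(rows)
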