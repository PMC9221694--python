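"""Screening performance: AUC and detection rates at fixed false-positive rates.

The AUC is the Mann–Whitney probability that a random case scores above a
random control (ties get half credit), with a 95% CI from the DeLong
paired-placement variance estimator (Hanley–McNeil available as an
alternative).  Detection rates are read off at fixed FPRs of 10/20/30% by
thresholding at the corresponding upper percentiles of the control risk
scores: the threshold for FPR f is the (1−f) empirical percentile (linear
interpolation between order statistics) and a subject screens positive when
strictly above it, so the observed control exceedance never surpasses the
nominal FPR beyond 1/n_control granularity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectRecord, in_stratum
from .mom import MoMProfile
from .risk import MissingPredictorError, RiskModel, score

DEFAULT_FPRS: Tuple[float, ...] = (0.10, 0.20, 0.30)


@dataclass(frozen=True)
class ScreeningResult:
    outcome: str
    model_label: str
    auc: float
    auc_ci: Tuple[float, float]
    thresholds: Mapping[float, float]
    detection_rates: Mapping[float, float]
    control_exceedance: Mapping[float, float]
    n_cases: int
    n_controls: int
    n_unscored: int = 0

    def to_row(self) -> dict:
        row = {
            "outcome": self.outcome,
            "model": self.model_label,
            "auc": round(self.auc, 3),
            "auc_ci_lo": round(self.auc_ci[0], 3),
            "auc_ci_hi": round(self.auc_ci[1], 3),
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
        }
        for f in sorted(self.detection_rates):
            row[f"dr_at_fpr_{int(round(100 * f))}"] = round(
                100 * self.detection_rates[f], 1
            )
        return row


def _placements(cases: np.ndarray, controls: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Per-observation placement values (probability of beating the other group)."""
    v10 = np.empty(cases.size)
    for i, c in enumerate(cases):
        v10[i] = (np.sum(controls < c) + 0.5 * np.sum(controls == c)) / controls.size
    v01 = np.empty(controls.size)
    for j, c in enumerate(controls):
        v01[j] = (np.sum(cases > c) + 0.5 * np.sum(cases == c)) / cases.size
    return v10, v01


def auc_mann_whitney(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    ci_method: str = "delong",
    conf_level: float = 0.95,
) -> Tuple[float, Tuple[float, float]]:
    """AUC = (concordant pairs + ½·ties) / (n_case·n_control), with 95% CI.

    ``ci_method`` is 'delong' (default) or 'hanley-mcneil'; the interval is
    truncated to (0, 1).
    """
    cases = np.asarray(case_scores, float)
    controls = np.asarray(control_scores, float)
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both score groups must be non-empty")
    v10, v01 = _placements(cases, controls)
    auc = float(v10.mean())

    z = stats.norm.ppf(0.5 + conf_level / 2.0)
    if ci_method == "delong":
        s10 = v10.var(ddof=1) if cases.size > 1 else 0.0
        s01 = v01.var(ddof=1) if controls.size > 1 else 0.0
        se = np.sqrt(s10 / cases.size + s01 / controls.size)
    elif ci_method == "hanley-mcneil":
        q1 = auc / (2 - auc)
        q2 = 2 * auc**2 / (1 + auc)
        m, n = cases.size, controls.size
        var = (auc * (1 - auc) + (m - 1) * (q1 - auc**2) + (n - 1) * (q2 - auc**2)) / (m * n)
        se = np.sqrt(max(var, 0.0))
    else:
        raise ValueError(f"unknown ci_method {ci_method!r}")
    lo = max(0.0, auc - z * se)
    hi = min(1.0, auc + z * se)
    return auc, (lo, hi)


def dr_at_fixed_fpr(
    case_scores: Sequence[float],
    control_scores: Sequence[float],
    fprs: Sequence[float] = DEFAULT_FPRS,
) -> Tuple[Dict[float, float], Dict[float, float], Dict[float, float]]:
    """Thresholds and detection rates at fixed FPRs via control percentiles.

    Returns ``(thresholds, detection_rates, control_exceedance)`` keyed by
    FPR.  The threshold at FPR f is the (1−f) percentile of the control
    scores; DR is the fraction of cases strictly above it.
    """
    cases = np.asarray(case_scores, float)
    controls = np.asarray(control_scores, float)
    if controls.size < 10:
        raise ValueError("need at least 10 controls to anchor percentiles")
    if cases.size == 0:
        raise ValueError("empty case group")
    if np.ptp(controls) == 0:
        warnings.warn("constant control scores; DR is the case fraction above them")
    thresholds: Dict[float, float] = {}
    drs: Dict[float, float] = {}
    exceed: Dict[float, float] = {}
    for f in fprs:
        if not 0.0 < f < 1.0:
            raise ValueError(f"FPR {f} outside (0, 1)")
        thr = float(np.percentile(controls, 100.0 * (1.0 - f)))
        thresholds[f] = thr
        drs[f] = float(np.mean(cases > thr))
        exceed[f] = float(np.mean(controls > thr))
    return thresholds, drs, exceed


def evaluate_model(
    model: RiskModel,
    profiles: Sequence[MoMProfile],
    records: Sequence[SubjectRecord],
    case_stratum: Optional[str] = None,
    control_stratum: str = "NONCASE",
    fprs: Sequence[float] = DEFAULT_FPRS,
    ci_method: str = "delong",
    label: Optional[str] = None,
) -> ScreeningResult:
    """Score a cohort with a risk model and summarize screening performance.

    Cases are the subjects of ``case_stratum`` (the model's outcome by
    default); controls are the non-case group (neither preterm birth nor
    preeclampsia).  Scoring is missingness-aware; subjects without a usable
    variant are dropped and counted in ``n_unscored``.
    """
    case_stratum = case_stratum or model.outcome
    case_scores, control_scores = [], []
    unscored = 0
    for prof, rec in zip(profiles, records):
        is_case = in_stratum(rec.outcome, case_stratum)
        is_control = in_stratum(rec.outcome, control_stratum)
        if not (is_case or is_control):
            continue
        try:
            p = score(model, prof, rec).p
        except MissingPredictorError:
            unscored += 1
            continue
        (case_scores if is_case else control_scores).append(p)
    if not case_scores:
        raise ValueError(f"{case_stratum}: no scorable cases")
    auc, ci = auc_mann_whitney(case_scores, control_scores, ci_method=ci_method)
    thresholds, drs, exceed = dr_at_fixed_fpr(case_scores, control_scores, fprs)
    return ScreeningResult(
        outcome=case_stratum,
        model_label=label or ", ".join(model.predictor_names),
        auc=auc,
        auc_ci=ci,
        thresholds=thresholds,
        detection_rates=drs,
        control_exceedance=exceed,
        n_cases=len(case_scores),
        n_controls=len(control_scores),
        n_unscored=unscored,
    )


def results_table(results: Sequence[ScreeningResult]) -> pd.DataFrame:
    """Performance-table-shaped report (one row per outcome × model)."""
    return pd.DataFrame([r.to_row() for r in results])
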