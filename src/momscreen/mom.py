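"""Multiple-of-the-median (MoM) normalization.

Every marker is expressed as a multiple of the median expected in unaffected
pregnancies at the subject's covariates.  The expected median is either the
overall reference median (CONSTANT form) or a regression on gestational age
at sampling and maternal weight when either shows a significant association
with the marker (LOG_LINEAR form, ``10**(a + b*days + c*w)``, fit by least
squares on log10 values — the median of a log-normal is its geometric mean).
The LINEAR form (``a + b*kg``) exists for the published cervical-length and
mean-arterial-pressure median models, which are shipped as packaged fixtures
together with the published RNA medians.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
import yaml

from .cohort import ALL_MARKERS, SubjectRecord

#: Covariates a median regression may use.
MEDIAN_COVARIATES = ("ga_days", "weight_kg")


class MedianForm(str, Enum):
    CONSTANT = "CONSTANT"
    LINEAR = "LINEAR"
    LOG_LINEAR = "LOG_LINEAR"


@dataclass(frozen=True)
class MedianModel:
    """Expected-median function of (gestational age, maternal weight)."""

    marker: str
    form: MedianForm
    intercept: float
    ga_days_coef: float = 0.0
    weight_coef: float = 0.0
    weight_transform: str = "log10"  # LOG_LINEAR weight term: "log10" or "identity"
    covariates_used: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.form is MedianForm.CONSTANT:
            if self.ga_days_coef or self.weight_coef or self.covariates_used:
                raise ValueError("CONSTANT median model cannot carry covariate terms")
            if self.intercept <= 0:
                raise ValueError("CONSTANT median must be positive")
        if self.weight_transform not in ("log10", "identity"):
            raise ValueError(f"unknown weight transform {self.weight_transform!r}")

    def predict_median(self, ga_days: float, weight_kg: float) -> float:
        if self.form is MedianForm.CONSTANT:
            return self.intercept
        if self.form is MedianForm.LINEAR:
            med = self.intercept + self.ga_days_coef * ga_days + self.weight_coef * weight_kg
        else:
            w = math.log10(weight_kg) if self.weight_transform == "log10" else weight_kg
            med = 10.0 ** (self.intercept + self.ga_days_coef * ga_days + self.weight_coef * w)
        if med <= 0:
            raise ValueError(
                f"{self.marker}: non-positive predicted median {med} at "
                f"ga={ga_days} d, weight={weight_kg} kg"
            )
        return med


@dataclass
class MoMProfile:
    """Per-subject MoM values; absent markers stay absent."""

    subject_id: str
    mom: Dict[str, float] = field(default_factory=dict)
    log10_mom: Dict[str, float] = field(default_factory=dict)
    below_detection: frozenset = frozenset()


def published_median_models() -> Dict[str, MedianModel]:
    """The packaged published median-model fixtures for all seven markers."""
    text = resources.files("momscreen.data").joinpath("median_models.yaml").read_text()
    raw = yaml.safe_load(text)
    models = {}
    for marker, cfg in raw.items():
        form = MedianForm(cfg["form"])
        used = []
        if cfg.get("ga_days_coef"):
            used.append("ga_days")
        if cfg.get("weight_coef"):
            used.append("weight_kg")
        models[marker] = MedianModel(
            marker=marker,
            form=form,
            intercept=float(cfg["intercept"]),
            ga_days_coef=float(cfg.get("ga_days_coef", 0.0)),
            weight_coef=float(cfg.get("weight_coef", 0.0)),
            weight_transform=cfg.get("weight_transform", "log10"),
            covariates_used=() if form is MedianForm.CONSTANT else tuple(used),
        )
    return models


def _detected_arrays(
    reference: Sequence[SubjectRecord], marker: str
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    vals, ga, wt = [], [], []
    for rec in reference:
        m = rec.measurement(marker)
        if not m.missing:
            vals.append(m.value)
            ga.append(rec.ga_sampling_days)
            wt.append(rec.maternal_weight_kg)
    return np.asarray(vals, float), np.asarray(ga, float), np.asarray(wt, float)


def fit_median_model(
    reference: Sequence[SubjectRecord],
    marker: str,
    alpha: float = 0.05,
    covariates: Sequence[str] = MEDIAN_COVARIATES,
    weight_transform: str = "log10",
    min_subjects: int = 20,
) -> MedianModel:
    """Fit a marker's expected-median model on the reference (non-case) group.

    log10 expression is regressed on the requested covariates; if no slope is
    significant at ``alpha`` (two-tailed t-test), the overall reference median
    is returned as a CONSTANT model, otherwise a LOG_LINEAR model is refit
    with only the significant terms.  Pass ``covariates=()`` to force the
    CONSTANT form.
    """
    unknown = set(covariates) - set(MEDIAN_COVARIATES)
    if unknown:
        raise ValueError(f"unknown median covariates {sorted(unknown)}")
    vals, ga, wt = _detected_arrays(reference, marker)
    if vals.size < min_subjects:
        raise ValueError(
            f"{marker}: {vals.size} detected reference values; need >= {min_subjects}"
        )
    if np.any(vals <= 0):
        raise ValueError(f"{marker}: non-positive expression in reference group")

    constant = MedianModel(marker, MedianForm.CONSTANT, float(np.median(vals)))
    if not covariates:
        return constant

    logv = np.log10(vals)
    wcol = np.log10(wt) if weight_transform == "log10" else wt
    cols = {"ga_days": ga, "weight_kg": wcol}
    # degenerate inputs: no spread in the response, or a covariate with no
    # variation, cannot support a covariate association
    covariates = [c for c in covariates if np.ptp(cols[c]) > 0]
    if np.ptp(logv) == 0 or not covariates:
        return constant
    X = sm.add_constant(
        np.column_stack([cols[c] for c in covariates]), has_constant="add"
    )
    fit = sm.OLS(logv, X).fit()
    significant = [
        c for i, c in enumerate(covariates) if fit.pvalues[i + 1] < alpha
    ]
    if not significant:
        return constant

    Xs = sm.add_constant(
        np.column_stack([cols[c] for c in significant]), has_constant="add"
    )
    refit = sm.OLS(logv, Xs).fit()
    coefs = dict(zip(significant, refit.params[1:]))
    return MedianModel(
        marker=marker,
        form=MedianForm.LOG_LINEAR,
        intercept=float(refit.params[0]),
        ga_days_coef=float(coefs.get("ga_days", 0.0)),
        weight_coef=float(coefs.get("weight_kg", 0.0)),
        weight_transform=weight_transform,
        covariates_used=tuple(significant),
    )


def fit_all_median_models(
    reference: Sequence[SubjectRecord],
    markers: Iterable[str],
    alpha: float = 0.05,
    **kwargs,
) -> Dict[str, MedianModel]:
    return {m: fit_median_model(reference, m, alpha=alpha, **kwargs) for m in markers}


def to_mom(subject: SubjectRecord, models: Mapping[str, MedianModel]) -> MoMProfile:
    """Convert one subject's raw measurements to MoM at their own covariates."""
    mom: Dict[str, float] = {}
    log10_mom: Dict[str, float] = {}
    below: set = set()
    for marker in ALL_MARKERS:
        meas = subject.measurement(marker)
        if meas.below_detection:
            below.add(marker)
            continue
        if meas.value is None:
            continue
        if marker not in models:
            raise KeyError(f"no median model for measured marker {marker}")
        med = models[marker].predict_median(
            subject.ga_sampling_days, subject.maternal_weight_kg
        )
        m = meas.value / med
        mom[marker] = m
        log10_mom[marker] = math.log10(m) if m > 0 else -math.inf
    return MoMProfile(subject.subject_id, mom, log10_mom, frozenset(below))


def cohort_to_mom(
    cohort: Sequence[SubjectRecord], models: Mapping[str, MedianModel]
) -> List[MoMProfile]:
    return [to_mom(s, models) for s in cohort]


def reference_median_mom(profiles: Iterable[MoMProfile], marker: str) -> float:
    """Sample median MoM (midpoint interpolation for even n).

    Equals 1.0 exactly when the marker's CONSTANT model was fit on the same
    group the profiles come from.
    """
    values = [p.mom[marker] for p in profiles if marker in p.mom]
    if not values:
        raise ValueError(f"no detected MoM values for {marker}")
    return float(np.median(values))
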