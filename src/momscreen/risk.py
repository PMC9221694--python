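"""Logistic risk models over log10 MoMs and clinical characteristics.

The linear predictor is ``x = intercept + Σ coef·term`` where each term is a
log10 marker MoM, a 0/1 clinical indicator, or a continuous covariate; risk is
the logistic probability ``p = e^x / (1 + e^x)``.  The module fits models by
maximum likelihood, carries the four published best-fit equations as packaged
fixtures, and manages missingness-pattern sub-models: when a marker is below
detection (or CL/MAP was never measured) a sub-equation fit on the remaining
predictors is used for that subject.

Clinical encodings follow the published equations: ``other_race`` is 1 for
women not self-identified non-Hispanic Black; ``earliest_prior_ptb_weeks`` is
the gestation of the earliest prior preterm birth in weeks, 40 when there was
none; parity enters early-onset-preeclampsia models through the indicators
``nulliparous`` and ``parity_1_2`` (parity ≥ 3 is the reference level).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
import yaml
from scipy.special import expit

from .cohort import ALL_MARKERS, SubjectRecord, in_stratum
from .mom import MoMProfile

log = logging.getLogger(__name__)

#: name → transform for every predictor the models understand.
PREDICTOR_TRANSFORMS: Dict[str, str] = {
    **{m: "log10_mom" for m in ALL_MARKERS},
    "other_race": "indicator",
    "smoker": "indicator",
    "nulliparous": "indicator",
    "parity_1_2": "indicator",
    "prior_ptb": "indicator",
    "earliest_prior_ptb_weeks": "linear",
}

#: |standardized coefficient| beyond which a fit is flagged as quasi-separated.
SEPARATION_THRESHOLD = 15.0


class ConvergenceError(RuntimeError):
    """Logistic fit failed to converge."""


class MissingPredictorError(KeyError):
    """A subject lacks a predictor and no missingness variant covers them."""


@dataclass(frozen=True)
class Term:
    name: str
    transform: str
    coef: float

    def __post_init__(self) -> None:
        expected = PREDICTOR_TRANSFORMS.get(self.name)
        if expected is None:
            raise ValueError(f"unknown predictor {self.name!r}")
        if self.transform != expected:
            raise ValueError(
                f"{self.name}: transform {self.transform!r}, expected {expected!r}"
            )


@dataclass(frozen=True)
class RiskScore:
    """Linear predictor x, odds y = e^x, and risk p = y/(1+y)."""

    x: float

    @property
    def y(self) -> float:
        return math.exp(self.x)

    @property
    def p(self) -> float:
        return float(expit(self.x))


@dataclass
class RiskModel:
    outcome: str
    intercept: float
    terms: Tuple[Term, ...]
    #: available-marker-set → sub-model fit on those predictors only
    variants: Dict[FrozenSet[str], "RiskModel"] = field(default_factory=dict)
    # fit diagnostics (absent for published fixtures)
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None
    converged: bool = True
    separation: bool = False
    ridge_used: bool = False

    @property
    def marker_terms(self) -> FrozenSet[str]:
        return frozenset(t.name for t in self.terms if t.transform == "log10_mom")

    @property
    def predictor_names(self) -> Tuple[str, ...]:
        return tuple(t.name for t in self.terms)


def predictor_value(
    name: str, profile: MoMProfile, record: SubjectRecord
) -> Optional[float]:
    """Resolve one predictor; ``None`` when a marker MoM is unavailable."""
    transform = PREDICTOR_TRANSFORMS.get(name)
    if transform is None:
        raise KeyError(name)
    if transform == "log10_mom":
        return profile.log10_mom.get(name)
    if name == "other_race":
        return 0.0 if record.race_nhb else 1.0
    if name == "smoker":
        return 1.0 if record.smoker else 0.0
    if name == "nulliparous":
        return 1.0 if record.parity == 0 else 0.0
    if name == "parity_1_2":
        return 1.0 if record.parity in (1, 2) else 0.0
    if name == "prior_ptb":
        return 1.0 if record.prior_ptb else 0.0
    return float(record.earliest_prior_ptb_weeks)


def published_equation(name: str) -> RiskModel:
    """One of the four published best-fit equations.

    ``name`` ∈ {'SPTB_LE32', 'PTB_LT37', 'EOP_LT34', 'PE_ALL'}; coefficients
    are the printed values, applied as exact, deterministic arithmetic.
    """
    raw = _load_equations()
    if name not in raw:
        raise KeyError(f"unknown published equation {name!r}; have {sorted(raw)}")
    cfg = raw[name]
    terms = tuple(
        Term(t["name"], t["transform"], float(t["coef"])) for t in cfg["terms"]
    )
    return RiskModel(cfg["outcome"], float(cfg["intercept"]), terms)


def _load_equations() -> dict:
    text = resources.files("momscreen.data").joinpath("equations.yaml").read_text()
    return yaml.safe_load(text)


def score(model: RiskModel, profile: MoMProfile, record: SubjectRecord) -> RiskScore:
    """Risk score for one subject, dispatching on their missingness pattern.

    If the model carries missingness variants, the variant whose marker set is
    the largest subset of the subject's available markers is used; a model
    without variants requires every predictor to be present.
    """
    available = frozenset(
        t.name for t in model.terms
        if t.transform == "log10_mom" and t.name in profile.log10_mom
    )
    chosen = model
    if model.variants:
        candidates = [k for k in model.variants if k <= available]
        if not candidates:
            raise MissingPredictorError(
                f"{profile.subject_id}: no variant for available markers "
                f"{sorted(available)}"
            )
        key = max(candidates, key=lambda k: (len(k), tuple(sorted(k))))
        chosen = model.variants[key]
    x = chosen.intercept
    for term in chosen.terms:
        v = predictor_value(term.name, profile, record)
        if v is None:
            raise MissingPredictorError(
                f"{profile.subject_id}: predictor {term.name} unavailable"
            )
        x += term.coef * v
    return RiskScore(x)


def _design(
    profiles: Sequence[MoMProfile],
    records: Sequence[SubjectRecord],
    case_stratum: str,
    predictors: Sequence[str],
) -> Tuple[np.ndarray, np.ndarray]:
    """Complete-case design matrix and outcome vector (cases vs non-cases)."""
    rows, ys = [], []
    for prof, rec in zip(profiles, records):
        if prof.subject_id != rec.subject_id:
            raise ValueError("profiles and records are not aligned")
        if in_stratum(rec.outcome, case_stratum):
            y = 1.0
        elif in_stratum(rec.outcome, "NONCASE"):
            y = 0.0
        else:
            continue
        vals = [predictor_value(p, prof, rec) for p in predictors]
        if any(v is None for v in vals):
            continue
        rows.append(vals)
        ys.append(y)
    return np.asarray(rows, float), np.asarray(ys, float)


def _ridge_irls(
    X: np.ndarray, y: np.ndarray, lam: float, tol: float = 1e-8, maxiter: int = 100
) -> np.ndarray:
    """L2-penalized IRLS (intercept unpenalized); used as separation fallback."""
    Xc = np.column_stack([np.ones(len(y)), X])
    pen = lam * np.eye(Xc.shape[1])
    pen[0, 0] = 0.0
    beta = np.zeros(Xc.shape[1])
    for _ in range(maxiter):
        eta = Xc @ beta
        mu = expit(eta)
        w = np.clip(mu * (1 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        XtW = Xc.T * w
        new = np.linalg.solve(XtW @ Xc + pen, XtW @ z)
        if np.max(np.abs(new - beta)) < tol:
            return new
        beta = new
    return beta


def fit_logistic(
    profiles: Sequence[MoMProfile],
    records: Sequence[SubjectRecord],
    case_stratum: str,
    predictors: Sequence[str],
    min_cases: int = 10,
    ridge_on_separation: bool = True,
    ridge_lambda: float = 1e-4,
) -> RiskModel:
    """Maximum-likelihood logistic fit of cases (given stratum) vs non-cases.

    Subjects outside both groups, and subjects missing any predictor, are
    excluded.  Quasi-separation (any |coefficient| > 15 on standardized
    predictors, or an MLE failure) is flagged; when ``ridge_on_separation`` a
    lightly ridge-penalized fit (λ = 1e-4) replaces the diverging MLE.
    """
    for p in predictors:
        if p not in PREDICTOR_TRANSFORMS:
            raise ValueError(f"unknown predictor {p!r}")
    X, y = _design(profiles, records, case_stratum, predictors)
    n_cases = int(y.sum())
    if n_cases < min_cases:
        raise ValueError(
            f"{case_stratum}: {n_cases} complete-data cases; need >= {min_cases}"
        )

    params = None
    converged = True
    separated = False
    ridge_used = False
    if len(predictors) == 0:
        rate = float(np.mean(y))
        rate = min(max(rate, 1e-12), 1 - 1e-12)
        params = np.array([math.log(rate / (1 - rate))])
    else:
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(y, sm.add_constant(X)).fit(
                    method="newton", maxiter=100, tol=1e-8, disp=0
                )
            params = np.asarray(res.params, float)
            converged = bool(res.mle_retvals.get("converged", True))
        except Exception:
            converged = False
        if params is not None:
            scale = X.std(axis=0, ddof=0)
            scale[scale == 0] = 1.0
            separated = bool(np.any(np.abs(params[1:] * scale) > SEPARATION_THRESHOLD))
        if params is None or not converged or separated:
            separated = True
            if not ridge_on_separation:
                if params is None:
                    raise ConvergenceError(f"{case_stratum}: logistic MLE failed")
            else:
                params = _ridge_irls(X, y, ridge_lambda)
                ridge_used = True
                converged = True
                log.info("%s: quasi-separation; ridge fallback used", case_stratum)

    terms = tuple(
        Term(p, PREDICTOR_TRANSFORMS[p], float(c))
        for p, c in zip(predictors, params[1:])
    )
    return RiskModel(
        outcome=case_stratum,
        intercept=float(params[0]),
        terms=terms,
        n_cases=n_cases,
        n_controls=int(len(y) - n_cases),
        converged=converged,
        separation=separated,
        ridge_used=ridge_used,
    )


def fit_missingness_variants(
    profiles: Sequence[MoMProfile],
    records: Sequence[SubjectRecord],
    case_stratum: str,
    predictors: Sequence[str],
    min_cases_variant: int = 5,
    **fit_kwargs,
) -> RiskModel:
    """Full model plus a sub-model per observed marker-availability pattern.

    For each distinct set of available marker predictors seen in the training
    data, a sub-equation is fit using only those markers (clinical covariates
    always included).  Patterns with fewer than ``min_cases_variant``
    complete-data cases are skipped; scoring then falls back to the largest
    fitted subset.
    """
    marker_preds = frozenset(
        p for p in predictors if PREDICTOR_TRANSFORMS[p] == "log10_mom"
    )
    clinical = [p for p in predictors if p not in marker_preds]

    patterns = set()
    for prof in profiles:
        patterns.add(frozenset(m for m in marker_preds if m in prof.log10_mom))

    variants: Dict[FrozenSet[str], RiskModel] = {}
    attempted: set = set()
    queue = sorted(patterns, key=lambda p: (-len(p), tuple(sorted(p))))
    while queue:
        pattern = queue.pop(0)
        if pattern in attempted:
            continue
        attempted.add(pattern)
        sub_predictors = [p for p in predictors if p in pattern or p in clinical]
        try:
            variants[pattern] = fit_logistic(
                profiles, records, case_stratum, sub_predictors,
                min_cases=min_cases_variant, **fit_kwargs,
            )
        except ValueError as exc:
            # too few complete-data cases for this pattern: fall back to the
            # next-smaller predictor sets (spec'd degradation path)
            log.info("pattern %s skipped: %s", sorted(pattern), exc)
            queue.extend(pattern - {m} for m in sorted(pattern))
    if not variants:
        raise ValueError(f"{case_stratum}: no missingness pattern could be fit")

    full_key = max(variants, key=len)
    full = variants[full_key]
    return RiskModel(
        outcome=full.outcome,
        intercept=full.intercept,
        terms=full.terms,
        variants=variants,
        n_cases=full.n_cases,
        n_controls=full.n_controls,
        converged=full.converged,
        separation=full.separation,
        ridge_used=full.ridge_used,
    )


# --- serialization ---------------------------------------------------------

def _model_to_dict(model: RiskModel) -> dict:
    d = {
        "outcome": model.outcome,
        "intercept": model.intercept,
        "terms": [
            {"name": t.name, "transform": t.transform, "coef": t.coef}
            for t in model.terms
        ],
    }
    if model.n_cases is not None:
        d["n_cases"] = model.n_cases
        d["n_controls"] = model.n_controls
        d["separation"] = model.separation
        d["ridge_used"] = model.ridge_used
    if model.variants:
        d["variants"] = {
            ",".join(sorted(k)) if k else "(none)": _model_to_dict(v)
            for k, v in model.variants.items()
        }
    return d


def _model_from_dict(d: dict) -> RiskModel:
    variants = {}
    for key, sub in d.get("variants", {}).items():
        markers = frozenset() if key == "(none)" else frozenset(key.split(","))
        variants[markers] = _model_from_dict(sub)
    return RiskModel(
        outcome=d["outcome"],
        intercept=float(d["intercept"]),
        terms=tuple(
            Term(t["name"], t["transform"], float(t["coef"])) for t in d["terms"]
        ),
        variants=variants,
        n_cases=d.get("n_cases"),
        n_controls=d.get("n_controls"),
        separation=d.get("separation", False),
        ridge_used=d.get("ridge_used", False),
    )


def save_models(models: Mapping[str, RiskModel], path) -> None:
    payload = {label: _model_to_dict(m) for label, m in models.items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_models(path) -> Dict[str, RiskModel]:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return {label: _model_from_dict(d) for label, d in payload.items()}
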