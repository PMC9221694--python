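"""End-to-end orchestration of the screening analysis.

One call runs the full chain on a cohort table (or a freshly simulated
cohort): expected-median fitting → MoM conversion → univariate marker screens
→ significant-marker selection → logistic risk models (fit from the data or
the published equations) → AUC / detection-rate evaluation.  Every stage's
output is written as delimited text under the configured output directory,
together with the serialized models and a log recording the seed, package
versions and every analysis setting, so a report is reproducible from
(input, config) alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from . import __version__
from .association import (
    AssociationResult,
    marker_screen,
    screen_table,
    select_significant_markers,
)
from .cohort import CL, MAP, RNA_MARKERS, CohortSpec, SubjectRecord
from .io import read_cohort, write_cohort
from .mom import (
    MedianForm,
    cohort_to_mom,
    fit_median_model,
    published_median_models,
)
from .performance import ScreeningResult, evaluate_model, results_table
from .risk import RiskModel, fit_missingness_variants, published_equation, save_models
from .simulate import generate_cohort

log = logging.getLogger(__name__)

#: Case definitions analysed on each arm of the study.
PTB_STRATA = ("SPTB_LE32", "PTB_LT37")
PE_STRATA = ("EOP_LT34", "PREECLAMPSIA")

#: Clinical covariates entering each stratum's fitted risk model.
CLINICAL_TERMS: Mapping[str, Tuple[str, ...]] = {
    "SPTB_LE32": ("other_race", "earliest_prior_ptb_weeks"),
    "PTB_LT37": ("other_race", "smoker", "earliest_prior_ptb_weeks"),
    "EOP_LT34": ("nulliparous", "parity_1_2"),
    "PREECLAMPSIA": ("nulliparous", "parity_1_2"),
}

#: Published equation name per stratum.
PUBLISHED_BY_STRATUM: Mapping[str, str] = {
    "SPTB_LE32": "SPTB_LE32",
    "PTB_LT37": "PTB_LT37",
    "EOP_LT34": "EOP_LT34",
    "PREECLAMPSIA": "PE_ALL",
}


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input source."""

    input_path: Optional[Path] = None
    simulate: Optional[CohortSpec] = None
    outdir: Path = Path("momscreen_out")
    alpha: float = 0.05
    fprs: Tuple[float, ...] = (0.10, 0.20, 0.30)
    median_mode: str = "fit"  # "fit" or "fixtures"
    equation_mode: str = "fit"  # "fit" or "published"
    seed: int = 0

    def validate(self) -> None:
        if (self.input_path is None) == (self.simulate is None):
            raise ValueError("exactly one of input_path / simulate must be set")
        if not all(0.0 < f < 1.0 for f in self.fprs):
            raise ValueError("FPRs must lie in (0, 1)")
        if self.median_mode not in ("fit", "fixtures"):
            raise ValueError(f"unknown median_mode {self.median_mode!r}")
        if self.equation_mode not in ("fit", "published"):
            raise ValueError(f"unknown equation_mode {self.equation_mode!r}")


def run_full_analysis(config: RunConfig) -> Dict[str, object]:
    """Execute the full pipeline; returns the in-memory report bundle."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: List[str] = [
        f"momscreen {__version__}",
        _version_line(),
        f"seed: {config.seed}",
        f"alpha: {config.alpha}",
        f"fprs: {list(config.fprs)}",
        f"median_mode: {config.median_mode}",
        f"equation_mode: {config.equation_mode}",
    ]

    # --- input -------------------------------------------------------------
    if config.simulate is not None:
        spec = config.simulate
        spec.seed = config.seed
        cohort = generate_cohort(spec)
        write_cohort(cohort, outdir / "cohort.csv")
        log_lines.append(f"input: simulated cohort n={spec.n_subjects}")
    else:
        cohort = read_cohort(config.input_path)
        log_lines.append(f"input: {config.input_path} ({len(cohort)} subjects)")
    noncases = [s for s in cohort if s.outcome.value == "NONCASE"]

    # --- expected medians & MoM --------------------------------------------
    if config.median_mode == "fixtures":
        models_median = published_median_models()
    else:
        fixtures = published_median_models()
        models_median = {}
        for marker in RNA_MARKERS:
            models_median[marker] = fit_median_model(
                noncases, marker, alpha=config.alpha
            )
        # CL/MAP keep the published LINEAR fixtures (no LINEAR fitting path)
        models_median[CL] = fixtures[CL]
        models_median[MAP] = fixtures[MAP]
    for marker, mm in models_median.items():
        log_lines.append(
            f"median model {marker}: {mm.form.value}"
            + (f" covariates={list(mm.covariates_used)}"
               if mm.form is not MedianForm.CONSTANT else "")
        )
    profiles = cohort_to_mom(cohort, models_median)

    # --- univariate screens -------------------------------------------------
    screens: Dict[str, Dict[str, AssociationResult]] = {}
    for stratum in PTB_STRATA:
        screens[stratum] = marker_screen(
            profiles, cohort, stratum, RNA_MARKERS, extra_one_tailed=(CL,)
        )
    for stratum in PE_STRATA:
        screens[stratum] = marker_screen(
            profiles, cohort, stratum, RNA_MARKERS, extra_one_tailed=(MAP,)
        )
    association_tables = {}
    for stratum, results in screens.items():
        table = screen_table(results)
        table.to_csv(outdir / f"association_{stratum}.csv", index=False)
        association_tables[stratum] = table

    # --- risk models ---------------------------------------------------------
    risk_models: Dict[str, RiskModel] = {}
    for stratum in (*PTB_STRATA, *PE_STRATA):
        if config.equation_mode == "published":
            risk_models[stratum] = published_equation(PUBLISHED_BY_STRATUM[stratum])
            log_lines.append(f"model {stratum}: published equation")
            continue
        significant = select_significant_markers(screens[stratum], config.alpha)
        predictors = [*significant, *CLINICAL_TERMS[stratum]]
        log_lines.append(
            f"model {stratum}: significant markers {significant or '(none)'}"
        )
        try:
            model = fit_missingness_variants(profiles, cohort, stratum, predictors)
        except ValueError as exc:
            log_lines.append(f"model {stratum} skipped: {exc}")
            continue
        for pattern, sub in model.variants.items():
            log_lines.append(
                f"  variant [{','.join(sorted(pattern)) or 'no markers'}]: "
                f"{sub.n_cases} cases / {sub.n_controls} controls"
                + (" [quasi-separation; ridge]" if sub.ridge_used else "")
            )
        risk_models[stratum] = model
    save_models(risk_models, outdir / "models.yaml")

    # --- performance ---------------------------------------------------------
    screening: List[ScreeningResult] = []
    for stratum, model in risk_models.items():
        try:
            screening.append(
                evaluate_model(model, profiles, cohort, case_stratum=stratum,
                               fprs=config.fprs)
            )
        except ValueError as exc:
            log_lines.append(f"evaluation {stratum} skipped: {exc}")
    perf = results_table(screening)
    perf.to_csv(outdir / "performance.csv", index=False)
    for res in screening:
        if res.n_unscored:
            log_lines.append(
                f"evaluation {res.outcome}: {res.n_unscored} subjects unscorable "
                "(missing predictor, no matching variant)"
            )

    (outdir / "run.log").write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    return {
        "cohort": cohort,
        "profiles": profiles,
        "median_models": models_median,
        "association": association_tables,
        "risk_models": risk_models,
        "performance": perf,
        "log": log_lines,
    }


def _version_line() -> str:
    import numpy, pandas, scipy, statsmodels

    return (
        f"numpy {numpy.__version__}, scipy {scipy.__version__}, "
        f"pandas {pandas.__version__}, statsmodels {statsmodels.__version__}"
    )
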