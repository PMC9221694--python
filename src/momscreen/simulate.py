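"""Synthetic cohort generator.

Emulates the statistical structure of the source screening cohort so the full
pipeline is testable without any patient data: outcome labels are drawn from
the published prevalences, covariates from the published frequencies, and
each marker's log10 MoM from a normal distribution centred on its group's
published median MoM.  Raw measurement values are reconstructed by
multiplying the MoM by the published expected-median model at the subject's
own covariates, so that downstream median-model fitting and MoM conversion
see realistic raw-scale data.  The lowest quantiles of the NAMPT and APOA1
raw values are flagged below the detection limit, matching the missing counts
observed in the study.

All randomness flows from ``CohortSpec.seed``; identical specs give identical
cohorts.
"""

from __future__ import annotations

import math
from typing import Dict, List, Mapping, Optional

import numpy as np

from .cohort import (
    CL,
    GA_SAMPLING_DAYS,
    MAP,
    NO_PRIOR_PTB_WEEKS,
    Outcome,
    RNA_MARKERS,
    RawMeasurement,
    CohortSpec,
    SubjectRecord,
)
from .mom import MedianModel, published_median_models


def _prior_ptb_group(outcome: Outcome) -> str:
    if outcome is Outcome.SPTB_LE32:
        return "SPTB_LE32"
    if outcome is Outcome.PTB_LT37:
        return "PTB_LT37"
    return "NONCASE"


def generate_cohort(
    spec: CohortSpec,
    median_models: Optional[Mapping[str, MedianModel]] = None,
) -> List[SubjectRecord]:
    """Draw a reproducible synthetic cohort from ``spec``."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    models = dict(median_models) if median_models else published_median_models()

    outcomes_pool = list(spec.prevalences) + [Outcome.NONCASE]
    probs = [spec.prevalences[o] for o in spec.prevalences] + [spec.noncase_prevalence]
    outcome_idx = rng.choice(len(outcomes_pool), size=spec.n_subjects, p=probs)

    lo_kg, hi_kg = spec.weight_range_kg
    subjects: List[SubjectRecord] = []
    raw_values: Dict[str, List[float]] = {m: [] for m in RNA_MARKERS}

    for i in range(spec.n_subjects):
        outcome = outcomes_pool[outcome_idx[i]]
        ga_days = int(rng.integers(GA_SAMPLING_DAYS[0], GA_SAMPLING_DAYS[1] + 1))
        weight = float(rng.normal(spec.weight_mean_kg, spec.weight_sd_kg))
        while not lo_kg <= weight <= hi_kg:
            weight = float(rng.normal(spec.weight_mean_kg, spec.weight_sd_kg))
        race_nhb = bool(rng.random() < spec.race_nhb_freq)
        smoker = bool(rng.random() < spec.smoker_freq)

        u = rng.random()
        if u < spec.parity_dist["0"]:
            parity = 0
        elif u < spec.parity_dist["0"] + spec.parity_dist["1_2"]:
            parity = int(rng.integers(1, 3))
        else:
            parity = 3 + int(rng.poisson(1.0))

        group = _prior_ptb_group(outcome)
        prior_ptb = bool(rng.random() < spec.prior_ptb_freq[group])
        if prior_ptb:
            parity = max(parity, 1)
            if rng.random() < spec.early_prior_ptb_freq[group]:
                earliest = float(rng.uniform(16.0, 32.0))
            else:
                earliest = float(rng.uniform(33.0, 36.0))
        else:
            earliest = NO_PRIOR_PTB_WEEKS

        effects = spec.marker_effects[outcome]
        markers: Dict[str, RawMeasurement] = {}
        for m in RNA_MARKERS:
            l10 = rng.normal(math.log10(effects[m]), spec.log10_mom_sd[m])
            raw = (10.0 ** l10) * models[m].predict_median(ga_days, weight)
            markers[m] = RawMeasurement(raw)
            raw_values[m].append(raw)

        cl_cm = None
        if rng.random() < spec.cl_available_frac:
            l10 = rng.normal(math.log10(effects[CL]), spec.log10_mom_sd[CL])
            cl_cm = (10.0 ** l10) * models[CL].predict_median(ga_days, weight)
        map_mmhg = None
        if rng.random() < spec.map_available_frac:
            l10 = rng.normal(math.log10(effects[MAP]), spec.log10_mom_sd[MAP])
            map_mmhg = (10.0 ** l10) * models[MAP].predict_median(ga_days, weight)

        subjects.append(
            SubjectRecord(
                subject_id=f"S{i:05d}",
                ga_sampling_days=ga_days,
                maternal_weight_kg=weight,
                race_nhb=race_nhb,
                smoker=smoker,
                parity=parity,
                prior_ptb=prior_ptb,
                earliest_prior_ptb_weeks=earliest,
                outcome=outcome,
                markers=markers,
                cl_cm=cl_cm,
                map_mmhg=map_mmhg,
            )
        )

    # detection-limit censoring: the lowest fraction of each affected marker's
    # raw values across the cohort fall below the assay floor
    for marker, frac in spec.detection_censor_frac.items():
        if frac <= 0:
            continue
        values = np.asarray(raw_values[marker])
        k = int(round(frac * values.size))
        if k == 0:
            continue
        censored_idx = np.argsort(values, kind="stable")[:k]
        for idx in censored_idx:
            subjects[idx].markers[marker] = RawMeasurement(None, below_detection=True)

    return subjects
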