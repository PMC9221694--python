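"""Shared fixtures and simulation helpers for the test suite."""

from __future__ import annotations

import math
from typing import List, Sequence, Tuple

import numpy as np
import pytest
from hypothesis import settings as _hypothesis_settings

import momscreen as ms
from momscreen.risk import RiskModel

# property tests are derandomized; skip the on-disk example database
_hypothesis_settings.register_profile("no_db", database=None)
_hypothesis_settings.load_profile("no_db")


@pytest.fixture(scope="session")
def study_cohort() -> List[ms.SubjectRecord]:
    """A cohort at the study size (n = 289)."""
    return ms.generate_cohort(ms.CohortSpec(n_subjects=289, seed=11))


@pytest.fixture(scope="session")
def big_cohort() -> List[ms.SubjectRecord]:
    """A large cohort for Monte-Carlo calibration checks."""
    return ms.generate_cohort(ms.CohortSpec(n_subjects=20000, seed=23))


@pytest.fixture(scope="session")
def fixture_medians():
    return ms.published_median_models()


@pytest.fixture(scope="session")
def study_profiles(study_cohort, fixture_medians):
    return ms.cohort_to_mom(study_cohort, fixture_medians)


def make_subject(
    subject_id: str = "T0",
    outcome: ms.Outcome = ms.Outcome.NONCASE,
    race_nhb: bool = True,
    smoker: bool = False,
    parity: int = 0,
    prior_ptb: bool = False,
    earliest: float = ms.NO_PRIOR_PTB_WEEKS,
    ga_days: int = 129,
    weight_kg: float = 80.0,
    **kwargs,
) -> ms.SubjectRecord:
    """A minimal valid subject for unit tests."""
    return ms.SubjectRecord(
        subject_id=subject_id,
        ga_sampling_days=ga_days,
        maternal_weight_kg=weight_kg,
        race_nhb=race_nhb,
        smoker=smoker,
        parity=parity,
        prior_ptb=prior_ptb,
        earliest_prior_ptb_weeks=earliest,
        outcome=outcome,
        **kwargs,
    )


def simulate_from_equation(
    equation: RiskModel,
    n: int,
    rng: np.random.Generator,
    log10_mom_sd: float = 0.5,
) -> Tuple[List[ms.MoMProfile], List[ms.SubjectRecord]]:
    """Draw subjects whose outcome follows a published risk equation.

    Marker log10 MoMs are N(0, sd); clinical covariates are drawn with enough
    spread to identify every coefficient (other-race 15%, prior PTB 50% with
    earliest gestation U(16, 36) weeks, parity spanning all three levels).
    The binary outcome is Bernoulli(p) under the equation, so refitting the
    same predictors should recover the generating coefficients.
    """
    marker_names = sorted(equation.marker_terms)
    profiles: List[ms.MoMProfile] = []
    records: List[ms.SubjectRecord] = []
    for i in range(n):
        log10_moms = {m: float(rng.normal(0.0, log10_mom_sd)) for m in marker_names}
        prior = bool(rng.random() < 0.5)
        earliest = float(rng.uniform(16, 36)) if prior else ms.NO_PRIOR_PTB_WEEKS
        parity = int(rng.choice([0, 1, 3], p=[0.3, 0.4, 0.3]))
        if prior:
            parity = max(parity, 1)
        rec = make_subject(
            subject_id=f"Q{i:06d}",
            race_nhb=bool(rng.random() < 0.85),
            smoker=bool(rng.random() < 0.27),
            parity=parity,
            prior_ptb=prior,
            earliest=earliest,
            ga_days=int(rng.integers(112, 147)),
            weight_kg=float(rng.uniform(50, 120)),
        )
        prof = ms.MoMProfile(
            rec.subject_id,
            {m: 10.0 ** v for m, v in log10_moms.items()},
            dict(log10_moms),
        )
        p = ms.score(equation, prof, rec).p
        case = rng.random() < p
        rec.outcome = (
            ms.Outcome(equation.outcome) if case else ms.Outcome.NONCASE
        )
        profiles.append(prof)
        records.append(rec)
    return profiles, records
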