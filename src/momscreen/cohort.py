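"""Domain types for a mid-trimester screening cohort.

A cohort is a list of :class:`SubjectRecord`: one pregnant woman enrolled at
16.0–20.9 weeks' gestation, with clinical covariates, an adverse-outcome label,
and raw measurements of five plasma cell-free RNA markers plus the optional
sonographic cervical length (CL, cm) and mean arterial pressure (MAP, mmHg).
:class:`CohortSpec` parameterizes the synthetic generator in
:mod:`momscreen.simulate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Dict, Mapping, Optional, Tuple

#: qPCR panel markers (relative expression units).
RNA_MARKERS: Tuple[str, ...] = ("PSME2", "NAMPT", "APOA1", "APOA4", "LET7G")
#: Sonographic cervical length, cm.
CL = "CL_CM"
#: Mean arterial pressure at sampling, mmHg.
MAP = "MAP_MMHG"
#: Every measurement that is MoM-normalized downstream.
ALL_MARKERS: Tuple[str, ...] = RNA_MARKERS + (CL, MAP)

#: Sentinel gestation (weeks) recorded when there was no prior preterm birth.
NO_PRIOR_PTB_WEEKS = 40.0
#: Enrollment window for blood sampling, days of gestation (16.0–20.9 weeks).
GA_SAMPLING_DAYS = (112, 146)


class Outcome(str, Enum):
    """Finest-grained pregnancy outcome label.

    Strata are nested: ``SPTB_LE32`` (spontaneous PTB / PPROM delivering at
    ≤ 32 weeks) is a subset of the PTB < 37 weeks stratum, and ``EOP_LT34``
    (early-onset preeclampsia delivering < 34 weeks) is a subset of the
    preeclampsia stratum.  Use :func:`in_stratum` for stratum membership.
    """

    NONCASE = "NONCASE"
    PTB_LT37 = "PTB_LT37"
    SPTB_LE32 = "SPTB_LE32"
    PREECLAMPSIA = "PREECLAMPSIA"
    EOP_LT34 = "EOP_LT34"


#: Stratum label → set of outcome labels counted inside it.
STRATA: Mapping[str, frozenset] = {
    "NONCASE": frozenset({Outcome.NONCASE}),
    "PTB_LT37": frozenset({Outcome.PTB_LT37, Outcome.SPTB_LE32}),
    "SPTB_LE32": frozenset({Outcome.SPTB_LE32}),
    "PREECLAMPSIA": frozenset({Outcome.PREECLAMPSIA, Outcome.EOP_LT34}),
    "EOP_LT34": frozenset({Outcome.EOP_LT34}),
}


def in_stratum(outcome: Outcome, stratum: str) -> bool:
    """True if ``outcome`` belongs to the (possibly nested) ``stratum``."""
    try:
        return outcome in STRATA[stratum]
    except KeyError:
        raise ValueError(f"unknown stratum {stratum!r}") from None


@dataclass(frozen=True)
class RawMeasurement:
    """One raw marker measurement with its detection flag.

    ``below_detection`` measurements carry no usable value (``value is None``).
    """

    value: Optional[float]
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.below_detection and self.value is not None:
            object.__setattr__(self, "value", None)
        if self.value is not None and not (self.value >= 0 and math.isfinite(self.value)):
            raise ValueError(f"measurement value must be finite and >= 0, got {self.value}")

    @property
    def missing(self) -> bool:
        return self.value is None


@dataclass
class SubjectRecord:
    """One enrolled singleton pregnancy."""

    subject_id: str
    ga_sampling_days: int
    maternal_weight_kg: float
    race_nhb: bool  # self-identified non-Hispanic Black
    smoker: bool
    parity: int
    prior_ptb: bool
    earliest_prior_ptb_weeks: float
    outcome: Outcome
    markers: Dict[str, RawMeasurement] = field(default_factory=dict)
    cl_cm: Optional[float] = None
    map_mmhg: Optional[float] = None

    def __post_init__(self) -> None:
        lo, hi = GA_SAMPLING_DAYS
        if not lo <= self.ga_sampling_days <= hi:
            raise ValueError(
                f"{self.subject_id}: sampling GA {self.ga_sampling_days} d outside "
                f"enrollment window [{lo}, {hi}]"
            )
        if self.maternal_weight_kg <= 0:
            raise ValueError(f"{self.subject_id}: non-positive maternal weight")
        if self.parity < 0:
            raise ValueError(f"{self.subject_id}: negative parity")
        if self.prior_ptb:
            if self.parity < 1:
                raise ValueError(f"{self.subject_id}: prior PTB implies parity >= 1")
            if not 16.0 <= self.earliest_prior_ptb_weeks <= 36.0:
                raise ValueError(
                    f"{self.subject_id}: earliest prior PTB gestation "
                    f"{self.earliest_prior_ptb_weeks} outside [16, 36] weeks"
                )
        elif self.earliest_prior_ptb_weeks != NO_PRIOR_PTB_WEEKS:
            raise ValueError(
                f"{self.subject_id}: earliest_prior_ptb_weeks must be "
                f"{NO_PRIOR_PTB_WEEKS} when there was no prior PTB"
            )
        for v, name in ((self.cl_cm, "cl_cm"), (self.map_mmhg, "map_mmhg")):
            if v is not None and v <= 0:
                raise ValueError(f"{self.subject_id}: non-positive {name}")

    def measurement(self, marker: str) -> RawMeasurement:
        """Uniform access to RNA markers and the CL/MAP fields."""
        if marker == CL:
            return RawMeasurement(self.cl_cm)
        if marker == MAP:
            return RawMeasurement(self.map_mmhg)
        if marker in self.markers:
            return self.markers[marker]
        if marker in RNA_MARKERS:
            return RawMeasurement(None)
        raise KeyError(marker)


def _default_prevalences() -> Dict[Outcome, float]:
    # Finest-category rates; the printed strata are PTB<37 w 25.3% (of which
    # ≤32 w is 10.4% of the cohort), preeclampsia 7.6% with EOP 2.1%.
    return {
        Outcome.SPTB_LE32: 0.104,
        Outcome.PTB_LT37: 0.253 - 0.104,
        Outcome.EOP_LT34: 0.021,
        Outcome.PREECLAMPSIA: 0.076 - 0.021,
    }


def _default_marker_effects() -> Dict[Outcome, Dict[str, float]]:
    # Group-specific median MoMs of the study cohort (RNA/CL for the PTB
    # strata; RNA/MAP for the preeclampsia strata). Non-case medians are 1.0
    # by construction except the two regressed markers, which printed 1.03
    # (Let-7g) and 1.01 (MAP).
    return {
        Outcome.NONCASE: {
            "PSME2": 1.00, "NAMPT": 1.00, "APOA1": 1.00, "APOA4": 1.00,
            "LET7G": 1.03, CL: 1.00, MAP: 1.01,
        },
        Outcome.SPTB_LE32: {
            "PSME2": 4.09, "NAMPT": 1.46, "APOA1": 1.91, "APOA4": 2.01,
            "LET7G": 8.84, CL: 0.74, MAP: 1.01,
        },
        Outcome.PTB_LT37: {
            "PSME2": 1.86, "NAMPT": 1.47, "APOA1": 1.66, "APOA4": 0.88,
            "LET7G": 2.15, CL: 0.89, MAP: 1.01,
        },
        Outcome.PREECLAMPSIA: {
            "PSME2": 2.31, "NAMPT": 1.69, "APOA1": 1.62, "APOA4": 1.26,
            "LET7G": 0.58, CL: 1.00, MAP: 1.06,
        },
        Outcome.EOP_LT34: {
            "PSME2": 3.61, "NAMPT": 3.64, "APOA1": 15.84, "APOA4": 2.19,
            "LET7G": 5.36, CL: 1.00, MAP: 1.08,
        },
    }


def _default_sds() -> Dict[str, float]:
    # The source cohort reports no marker spread; these are free parameters
    # chosen as plausible assay-scale log10 scatter (see docs/methods.md).
    sds = {m: 0.35 for m in RNA_MARKERS}
    sds[CL] = 0.10
    sds[MAP] = 0.03
    return sds


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort generator.

    Defaults reproduce the published cohort's shape: outcome prevalences and
    covariate frequencies from the demographic tables, group median MoMs from
    the marker tables, and detection-limit censoring matching the observed
    missing NAMPT/APOA1 counts.
    """

    n_subjects: int = 289
    seed: int = 0
    prevalences: Dict[Outcome, float] = field(default_factory=_default_prevalences)
    # covariate frequencies
    race_nhb_freq: float = 0.85
    smoker_freq: float = 0.273
    parity_dist: Dict[str, float] = field(
        default_factory=lambda: {"0": 0.17, "1_2": 0.57, "3p": 0.26}
    )
    #: P(prior PTB | outcome stratum); non-PTB strata use the non-case rate.
    prior_ptb_freq: Dict[str, float] = field(
        default_factory=lambda: {"SPTB_LE32": 0.83, "PTB_LT37": 0.79, "NONCASE": 0.43}
    )
    #: P(earliest prior PTB ≤ 32 w | prior PTB, stratum).
    early_prior_ptb_freq: Dict[str, float] = field(
        default_factory=lambda: {"SPTB_LE32": 0.92, "PTB_LT37": 0.74, "NONCASE": 0.65}
    )
    marker_effects: Dict[Outcome, Dict[str, float]] = field(
        default_factory=_default_marker_effects
    )
    log10_mom_sd: Dict[str, float] = field(default_factory=_default_sds)
    detection_censor_frac: Dict[str, float] = field(
        default_factory=lambda: {"NAMPT": 0.05, "APOA1": 0.02}
    )
    # fraction of subjects with the optional sonographic / blood-pressure
    # measurements (154/289 had CL; MAP was available for 173/192 non-cases)
    cl_available_frac: float = 154 / 289
    map_available_frac: float = 0.90
    weight_mean_kg: float = 80.0
    weight_sd_kg: float = 18.0
    weight_range_kg: Tuple[float, float] = (40.0, 180.0)

    def validate(self) -> None:
        if self.n_subjects <= 0:
            raise ValueError("n_subjects must be positive")
        if any(p < 0 for p in self.prevalences.values()):
            raise ValueError("prevalences must be non-negative")
        if sum(self.prevalences.values()) > 1.0 + 1e-12:
            raise ValueError("prevalences sum above 1")
        if any(sd <= 0 for sd in self.log10_mom_sd.values()):
            raise ValueError("log10 MoM sds must be positive")
        for name, frac in self.detection_censor_frac.items():
            if not 0 <= frac < 1:
                raise ValueError(f"detection_censor_frac[{name}] outside [0, 1)")
        if abs(sum(self.parity_dist.values()) - 1.0) > 1e-9:
            raise ValueError("parity_dist must sum to 1")
        for frac in (self.cl_available_frac, self.map_available_frac,
                     self.race_nhb_freq, self.smoker_freq):
            if not 0 <= frac <= 1:
                raise ValueError("frequencies must lie in [0, 1]")

    @property
    def noncase_prevalence(self) -> float:
        return 1.0 - sum(self.prevalences.values())
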