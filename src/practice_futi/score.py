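"""The PRACTICE score: a points-based admission rule for febrile UTI.

The score is a modification of the Pneumonia Severity Index with every
laboratory variable removed, leaving twelve bedside predictors: age (minus
10 points for women), nursing-home residency, five comorbidities and five
vital-sign / mental-status flags. The total is the plain sum of the points
of all characteristics that apply, so it ranges from 8 (an 18-year-old
woman with no risk factors) upward with no upper bound.

Risk classes and the attached admission recommendations:

======================  ==============  ====================
total points            risk class      recommendation
======================  ==============  ====================
< 75                    low             home-based management
75 - 100 (inclusive)    intermediate    consider home-based
> 100                   high            hospital admission
======================  ==============  ====================

Scores of exactly 75 and exactly 100 are intermediate; the bounds are
configurable through :class:`RiskThresholds`.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import DataCompletenessError, EligibilityError, InfeasibleConstraintError

__all__ = [
    "Sex",
    "RiskClass",
    "Recommendation",
    "PatientPresentation",
    "ScoreWeights",
    "RiskThresholds",
    "ScoreResult",
    "FLAG_FIELDS",
    "compute_score",
    "classify_risk",
    "minimum_score",
    "score_frame",
]


class Sex(str, Enum):
    MALE = "M"
    FEMALE = "F"


class RiskClass(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"


class Recommendation(str, Enum):
    HOME = "home"
    CONSIDER_HOME = "consider_home"
    ADMIT = "admit"


#: The eleven binary characteristics, in table order. Each name doubles as the
#: corresponding :class:`ScoreWeights` field name.
FLAG_FIELDS: tuple[str, ...] = (
    "nursing_home_resident",
    "malignancy",
    "congestive_heart_failure",
    "cerebrovascular_disease",
    "liver_cirrhosis",
    "renal_disease",
    "altered_mental_status",
    "respiratory_rate_ge_30",
    "systolic_bp_lt_90",
    "pulse_ge_125",
    "temperature_ge_40",
)

#: Vital-sign dichotomization cut-offs applied by
#: :meth:`PatientPresentation.from_vitals` (measurements at ED presentation).
RESPIRATORY_RATE_CUTOFF = 30.0   # breaths/min, flag if >= cutoff
SYSTOLIC_BP_CUTOFF = 90.0        # mmHg, flag if < cutoff
PULSE_CUTOFF = 125.0             # beats/min, flag if >= cutoff
TEMPERATURE_CUTOFF = 40.0        # deg C, flag if >= cutoff

MINIMUM_AGE = 18  # trial eligibility: adults only


@dataclass(frozen=True)
class ScoreWeights:
    """Allocated points for each characteristic.

    Attributes mirror :data:`FLAG_FIELDS`; ``female_age_offset`` is applied
    exactly once to the age term for women.
    """

    nursing_home_resident: int = 10
    malignancy: int = 30
    congestive_heart_failure: int = 10
    cerebrovascular_disease: int = 10
    liver_cirrhosis: int = 20
    renal_disease: int = 10
    altered_mental_status: int = 20
    respiratory_rate_ge_30: int = 20
    systolic_bp_lt_90: int = 20
    pulse_ge_125: int = 10
    temperature_ge_40: int = 15
    female_age_offset: int = -10

    def flag_weight(self, name: str) -> int:
        if name not in FLAG_FIELDS:
            raise KeyError(f"unknown characteristic: {name!r}")
        return getattr(self, name)


DEFAULT_WEIGHTS = ScoreWeights()


@dataclass(frozen=True)
class RiskThresholds:
    """Class boundaries: scores < ``low_upper`` are low risk, scores >
    ``high_lower`` are high risk, everything in between (inclusive) is
    intermediate."""

    low_upper: int = 75
    high_lower: int = 100

    def __post_init__(self) -> None:
        if not self.low_upper < self.high_lower:
            raise ValueError(
                f"low_upper ({self.low_upper}) must be below high_lower ({self.high_lower})"
            )


DEFAULT_THRESHOLDS = RiskThresholds()

_RECOMMENDATION_FOR_CLASS: dict[RiskClass, Recommendation] = {
    RiskClass.LOW: Recommendation.HOME,
    RiskClass.INTERMEDIATE: Recommendation.CONSIDER_HOME,
    RiskClass.HIGH: Recommendation.ADMIT,
}


@dataclass(frozen=True)
class PatientPresentation:
    """Clinical characteristics of one adult at ED presentation.

    Fractional ages are floored to completed years. Every flag must be an
    actual boolean; ``None`` (unknown) raises :class:`DataCompletenessError`
    naming the field, and ``age < 18`` raises :class:`EligibilityError`.
    """

    age: int
    sex: Sex
    nursing_home_resident: bool = False
    malignancy: bool = False
    congestive_heart_failure: bool = False
    cerebrovascular_disease: bool = False
    liver_cirrhosis: bool = False
    renal_disease: bool = False
    altered_mental_status: bool = False
    respiratory_rate_ge_30: bool = False
    systolic_bp_lt_90: bool = False
    pulse_ge_125: bool = False
    temperature_ge_40: bool = False

    def __post_init__(self) -> None:
        if self.age is None or (isinstance(self.age, float) and not math.isfinite(self.age)):
            raise DataCompletenessError("age")
        object.__setattr__(self, "age", int(math.floor(self.age)))
        if self.age < MINIMUM_AGE:
            raise EligibilityError(
                f"age {self.age} is below the eligibility minimum of {MINIMUM_AGE} years"
            )
        try:
            object.__setattr__(self, "sex", Sex(self.sex))
        except ValueError:
            raise DataCompletenessError(
                "sex", f"sex must be one of {[s.value for s in Sex]}, got {self.sex!r}"
            ) from None
        for name in FLAG_FIELDS:
            value = getattr(self, name)
            if isinstance(value, (bool, np.bool_)):
                object.__setattr__(self, name, bool(value))
            else:
                raise DataCompletenessError(
                    name, f"characteristic {name!r} must be a boolean, got {value!r}"
                )

    @classmethod
    def from_vitals(
        cls,
        age: int,
        sex: Sex | str,
        *,
        respiratory_rate: float | None = None,
        systolic_bp: float | None = None,
        pulse: float | None = None,
        temperature: float | None = None,
        **flags: bool,
    ) -> "PatientPresentation":
        """Build a presentation from raw vital-sign measurements.

        Applies the table cut-offs (respiratory rate >= 30/min, systolic
        blood pressure < 90 mmHg, pulse >= 125/min, temperature >= 40.0 degC)
        to measurements taken at ED presentation. Raw values, when given,
        take precedence over the corresponding pre-dichotomized flags.
        """
        if respiratory_rate is not None:
            flags["respiratory_rate_ge_30"] = respiratory_rate >= RESPIRATORY_RATE_CUTOFF
        if systolic_bp is not None:
            flags["systolic_bp_lt_90"] = systolic_bp < SYSTOLIC_BP_CUTOFF
        if pulse is not None:
            flags["pulse_ge_125"] = pulse >= PULSE_CUTOFF
        if temperature is not None:
            flags["temperature_ge_40"] = temperature >= TEMPERATURE_CUTOFF
        return cls(age=age, sex=sex, **flags)


@dataclass(frozen=True)
class ScoreResult:
    """Total points with a per-item breakdown and the attached risk class."""

    total: int
    breakdown: tuple[tuple[str, int], ...]
    risk_class: RiskClass
    recommendation: Recommendation


def classify_risk(
    total: int, thresholds: RiskThresholds = DEFAULT_THRESHOLDS
) -> tuple[RiskClass, Recommendation]:
    """Map a total score to its risk class and admission recommendation."""
    if isinstance(total, float):
        if not math.isfinite(total):
            raise ValueError("total must be finite")
        if total != int(total):
            raise ValueError("total must be an integer number of points")
        total = int(total)
    if not isinstance(total, (int, np.integer)):
        raise TypeError(f"total must be an integer, got {type(total).__name__}")
    if total < thresholds.low_upper:
        risk = RiskClass.LOW
    elif total > thresholds.high_lower:
        risk = RiskClass.HIGH
    else:
        risk = RiskClass.INTERMEDIATE
    return risk, _RECOMMENDATION_FOR_CLASS[risk]


def compute_score(
    patient: PatientPresentation,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> ScoreResult:
    """Sum the points for every characteristic that applies.

    The age term is the age in completed years, minus 10 for women; each
    true flag contributes its allocated points. Deterministic; the breakdown
    lists every contributing item and sums exactly to ``total``.
    """
    breakdown: list[tuple[str, int]] = [("age", patient.age)]
    if patient.sex is Sex.FEMALE:
        breakdown.append(("female_age_offset", weights.female_age_offset))
    for name in FLAG_FIELDS:
        if getattr(patient, name):
            breakdown.append((name, weights.flag_weight(name)))
    total = sum(points for _, points in breakdown)
    risk, recommendation = classify_risk(total, thresholds)
    return ScoreResult(
        total=total,
        breakdown=tuple(breakdown),
        risk_class=risk,
        recommendation=recommendation,
    )


def minimum_score(
    min_age: int = MINIMUM_AGE,
    sex: Sex | str | None = None,
    forced_flags: Mapping[str, bool] | None = None,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
) -> int:
    """Minimum achievable total over the eligible characteristic space.

    Exhaustive search over sex (unless constrained) and all combinations of
    the binary characteristics not pinned by ``forced_flags``, evaluated at
    the minimum eligible age. Because the age term is monotone in age this
    is the global minimum over all ages >= ``min_age``.
    """
    if min_age < MINIMUM_AGE:
        raise EligibilityError(
            f"min_age {min_age} is below the eligibility minimum of {MINIMUM_AGE}"
        )
    forced_flags = dict(forced_flags or {})
    for name in forced_flags:
        if name not in FLAG_FIELDS:
            raise InfeasibleConstraintError(f"unknown characteristic in constraints: {name!r}")
    sexes: Iterable[Sex]
    if sex is None:
        sexes = tuple(Sex)
    else:
        try:
            sexes = (Sex(sex),)
        except ValueError:
            raise InfeasibleConstraintError(f"unknown sex constraint: {sex!r}") from None
    free = [name for name in FLAG_FIELDS if name not in forced_flags]
    best: int | None = None
    for sx in sexes:
        for values in itertools.product((False, True), repeat=len(free)):
            flags = dict(zip(free, values))
            flags.update(forced_flags)
            total = compute_score(
                PatientPresentation(age=min_age, sex=sx, **flags), weights
            ).total
            if best is None or total < best:
                best = total
    assert best is not None
    return best


def score_frame(
    patients: pd.DataFrame,
    weights: ScoreWeights = DEFAULT_WEIGHTS,
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Vectorized scoring of a patient table.

    Expects columns ``age``, ``sex`` (``M``/``F``) and the eleven flag
    columns named as in :data:`FLAG_FIELDS` (0/1 or boolean). Returns a copy
    with ``total``, ``risk_class`` and ``recommendation`` columns appended.
    """
    missing = [c for c in ("age", "sex", *FLAG_FIELDS) if c not in patients.columns]
    if missing:
        raise DataCompletenessError(missing)
    age = np.floor(patients["age"].to_numpy(dtype=float)).astype(int)
    if (age < MINIMUM_AGE).any():
        bad = patients.index[age < MINIMUM_AGE].tolist()
        raise EligibilityError(f"age below {MINIMUM_AGE} at row(s) {bad}")
    sex = patients["sex"].astype(str).str.upper()
    if not sex.isin([s.value for s in Sex]).all():
        raise DataCompletenessError("sex", "sex column must contain only M/F")
    total = age + (sex == Sex.FEMALE.value).to_numpy() * weights.female_age_offset
    total = total.astype(int)
    for name in FLAG_FIELDS:
        col = patients[name].to_numpy()
        if pd.isna(col).any():
            raise DataCompletenessError(name, f"column {name!r} contains missing values")
        total = total + col.astype(bool).astype(int) * weights.flag_weight(name)
    out = patients.copy()
    out["total"] = total
    classes = np.where(
        total < thresholds.low_upper,
        RiskClass.LOW.value,
        np.where(total > thresholds.high_lower, RiskClass.HIGH.value, RiskClass.INTERMEDIATE.value),
    )
    out["risk_class"] = classes
    out["recommendation"] = [
        _RECOMMENDATION_FOR_CLASS[RiskClass(c)].value for c in classes
    ]
    return out
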