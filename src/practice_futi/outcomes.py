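"""Per-episode endpoint classification for febrile urinary tract infection.

Endpoints follow the trial definitions: a *complicated course* is the
composite of 30-day death, ICU admission or hospitalization longer than
10 days; *clinical cure* at the post-treatment visit means being alive and
afebrile with resolved or clearly improved symptoms and no additional
antimicrobials for relapse; *bacteriologic cure* means the follow-up urine
culture grows below the sex-specific colony-count threshold with
disappearance of leucocyturia.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .errors import DataCompletenessError
from .score import Sex

__all__ = [
    "EpisodeOutcome",
    "CureCriteria",
    "DEFAULT_CURE_CRITERIA",
    "complicated_course",
    "clinical_cure",
    "bacteriologic_cure",
    "complicated_uti_flag",
]

#: "Absence of fever" at test-of-cure reuses the inclusion threshold of 38.0 degC.
AFEBRILE_TEMPERATURE = 38.0

#: Days of hospitalization above which the course counts as complicated (strict).
PROLONGED_STAY_DAYS = 10

#: Minimum improvement on the 0-5 symptom severity scale that counts as
#: resolution when symptoms have not disappeared entirely.
MIN_SEVERITY_IMPROVEMENT = 2

_FOLLOWUP_WINDOW_DAYS = 92  # 3-month follow-up cap on attributable hospital days


@dataclass(frozen=True)
class CureCriteria:
    """Colony-count thresholds (cfu/mL, exclusive upper bounds) for
    bacteriologic cure."""

    female_cfu_threshold: float = 1e4
    male_cfu_threshold: float = 1e3

    def __post_init__(self) -> None:
        if not self.male_cfu_threshold < self.female_cfu_threshold:
            raise ValueError("male threshold must be below the female threshold")

    def threshold_for(self, sex: Sex | str) -> float:
        return (
            self.male_cfu_threshold if Sex(sex) is Sex.MALE else self.female_cfu_threshold
        )


DEFAULT_CURE_CRITERIA = CureCriteria()


@dataclass(frozen=True)
class EpisodeOutcome:
    """Observed endpoints for one patient episode over 90 days of follow-up.

    ``hospital_days_90d`` counts all hospitalization days attributable to the
    index episode within the follow-up window. Optional fields default to
    ``None`` (unknown); operations that need them raise
    :class:`DataCompletenessError` when absent.
    """

    primary_admission: Optional[bool] = None
    secondary_admission: Optional[bool] = None
    icu_admission: Optional[bool] = None
    death_30d: Optional[bool] = None
    death_90d: Optional[bool] = None
    hospital_days_90d: Optional[int] = None
    afebrile_at_followup: Optional[bool] = None
    symptom_severity_baseline: Optional[int] = None
    symptom_severity_followup: Optional[int] = None
    additional_antimicrobials_for_relapse: Optional[bool] = None
    followup_culture_cfu_per_ml: Optional[float] = None
    leucocyturia_at_followup: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.death_30d and self.death_90d is False:
            raise ValueError("death within 30 days implies death within 90 days")
        for name in ("symptom_severity_baseline", "symptom_severity_followup"):
            v = getattr(self, name)
            if v is not None and not 0 <= v <= 5:
                raise ValueError(f"{name} must lie in 0..5, got {v}")
        if self.hospital_days_90d is not None and not (
            0 <= self.hospital_days_90d <= _FOLLOWUP_WINDOW_DAYS
        ):
            raise ValueError(
                f"hospital_days_90d must lie in 0..{_FOLLOWUP_WINDOW_DAYS}, "
                f"got {self.hospital_days_90d}"
            )
        if (
            self.followup_culture_cfu_per_ml is not None
            and self.followup_culture_cfu_per_ml < 0
        ):
            raise ValueError("followup_culture_cfu_per_ml must be non-negative")


def _require(outcome: EpisodeOutcome, *names: str) -> None:
    missing = [n for n in names if getattr(outcome, n) is None]
    if missing:
        raise DataCompletenessError(missing)


def complicated_course(outcome: EpisodeOutcome) -> bool:
    """Composite adverse endpoint: 30-day death, ICU admission, or more than
    10 days of hospitalization attributable to the index episode.

    The day count is strict: exactly 10 days is not complicated.
    """
    _require(outcome, "death_30d", "icu_admission", "hospital_days_90d")
    return bool(
        outcome.death_30d
        or outcome.icu_admission
        or outcome.hospital_days_90d > PROLONGED_STAY_DAYS
    )


def clinical_cure(outcome: EpisodeOutcome) -> bool:
    """Alive and afebrile at the post-treatment visit, with symptoms either
    absent (severity 0) or improved by at least 2 points on the 0-5 scale,
    and no additional antimicrobial therapy for relapse."""
    _require(
        outcome,
        "death_30d",
        "afebrile_at_followup",
        "symptom_severity_baseline",
        "symptom_severity_followup",
        "additional_antimicrobials_for_relapse",
    )
    if outcome.death_30d:
        return False
    symptoms_resolved = (
        outcome.symptom_severity_followup == 0
        or outcome.symptom_severity_baseline - outcome.symptom_severity_followup
        >= MIN_SEVERITY_IMPROVEMENT
    )
    return bool(
        outcome.afebrile_at_followup
        and symptoms_resolved
        and not outcome.additional_antimicrobials_for_relapse
    )


def bacteriologic_cure(
    sex: Sex | str,
    followup_cfu_per_ml: Optional[float],
    leucocyturia_at_followup: Optional[bool],
    criteria: CureCriteria = DEFAULT_CURE_CRITERIA,
) -> Optional[bool]:
    """Eradication of the entry uropathogen: follow-up growth below the
    sex-specific threshold (strict) combined with disappearance of
    leucocyturia.

    Returns ``None`` (not evaluable, distinct from failure) when the culture
    or leucocyturia result is absent — sterile/contaminated follow-up
    cultures are excluded from cure denominators rather than counted as
    failures.
    """
    if followup_cfu_per_ml is None or leucocyturia_at_followup is None:
        return None
    if followup_cfu_per_ml < 0:
        raise ValueError("followup_cfu_per_ml must be non-negative")
    return bool(
        followup_cfu_per_ml < criteria.threshold_for(sex) and not leucocyturia_at_followup
    )


def complicated_uti_flag(
    sex: Sex | str,
    postmenopausal: Optional[bool],
    urinary_tract_abnormality: Optional[bool],
) -> bool:
    """A UTI episode is *complicated* in men, in postmenopausal women, and in
    women with any structural or functional urinary-tract abnormality;
    otherwise uncomplicated."""
    if Sex(sex) is Sex.MALE:
        return True
    missing = []
    if postmenopausal is None:
        missing.append("postmenopausal")
    if urinary_tract_abnormality is None:
        missing.append("urinary_tract_abnormality")
    if missing:
        raise DataCompletenessError(missing)
    return bool(postmenopausal or urinary_tract_abnormality)
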