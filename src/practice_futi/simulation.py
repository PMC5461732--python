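"""Synthetic cohorts and a stepped-wedge trial simulator with interim monitoring.

The cohort generator is calibrated to the impact trial's realized cohort:
risk-class mix 232/370 low, 93/370 intermediate, 45/370 high, with per-class
30/90-day mortality, ICU-admission probability and length-of-stay medians
taken from the combined-arm outcome table. Within a class, patient
characteristics are drawn from class-specific proposal distributions and
accepted by rejection when the computed score lands in the class interval,
which guarantees score/class consistency without inverting the score.

The trial simulator reproduces the design machinery: clusters cross from a
physician-discretion control policy to score-guided admission in random
sequential order (all but a configurable number of clusters cross), home
treated patients draw secondary admissions under arm-specific rates, and a
safety monitor performs interim analyses of the secondary-admission risk
difference against a stopping threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import InfeasibleConstraintError
from .evaluation import TwoByTwo, pearson_chi2, fisher_exact
from .score import (
    DEFAULT_THRESHOLDS,
    DEFAULT_WEIGHTS,
    FLAG_FIELDS,
    RiskClass,
    RiskThresholds,
    ScoreWeights,
)

__all__ = [
    "ClassDemographics",
    "CohortModel",
    "ControlPolicy",
    "InterventionPolicy",
    "TrialDesign",
    "MonitorConfig",
    "InterimDecision",
    "TrialRecord",
    "OperatingCharacteristics",
    "generate_cohort",
    "interim_check",
    "run_trial",
    "operating_characteristics",
]

SeedLike = Union[int, np.random.Generator, None]

_CLASSES = (RiskClass.LOW.value, RiskClass.INTERMEDIATE.value, RiskClass.HIGH.value)


def _rng(seed: SeedLike) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


@dataclass(frozen=True)
class ClassDemographics:
    """Proposal distribution for patient characteristics within one risk class.

    Ages are drawn from a clipped normal (integer years); sex and each of
    the eleven binary characteristics are independent Bernoulli draws.
    These are proposals only — acceptance is by the computed score falling
    inside the class interval.
    """

    age_mean: float
    age_sd: float
    age_min: int
    age_max: int
    female_prob: float
    flag_probs: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 18 <= self.age_min <= self.age_max:
            raise ValueError("require 18 <= age_min <= age_max")
        if not 0.0 <= self.female_prob <= 1.0:
            raise ValueError("female_prob must lie in [0, 1]")
        probs = dict(self.flag_probs)
        for name in FLAG_FIELDS:
            p = probs.setdefault(name, 0.0)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"flag probability {name} out of [0, 1]")
        unknown = set(probs) - set(FLAG_FIELDS)
        if unknown:
            raise ValueError(f"unknown characteristic(s) in flag_probs: {sorted(unknown)}")
        object.__setattr__(self, "flag_probs", probs)


_DEFAULT_DEMOGRAPHICS: dict[str, ClassDemographics] = {
    # Young-to-middle-aged, mostly female, little comorbidity: scores < 75.
    RiskClass.LOW.value: ClassDemographics(
        age_mean=52.0,
        age_sd=16.0,
        age_min=18,
        age_max=74,
        female_prob=0.62,
        flag_probs={
            "nursing_home_resident": 0.01,
            "malignancy": 0.02,
            "congestive_heart_failure": 0.04,
            "cerebrovascular_disease": 0.04,
            "liver_cirrhosis": 0.004,
            "renal_disease": 0.04,
            "altered_mental_status": 0.005,
            "respiratory_rate_ge_30": 0.01,
            "systolic_bp_lt_90": 0.01,
            "pulse_ge_125": 0.04,
            "temperature_ge_40": 0.05,
        },
    ),
    # Elderly with moderate comorbidity: scores 75-100.
    RiskClass.INTERMEDIATE.value: ClassDemographics(
        age_mean=80.0,
        age_sd=9.0,
        age_min=18,
        age_max=100,
        female_prob=0.55,
        flag_probs={
            "nursing_home_resident": 0.05,
            "malignancy": 0.05,
            "congestive_heart_failure": 0.12,
            "cerebrovascular_disease": 0.12,
            "liver_cirrhosis": 0.01,
            "renal_disease": 0.12,
            "altered_mental_status": 0.02,
            "respiratory_rate_ge_30": 0.04,
            "systolic_bp_lt_90": 0.04,
            "pulse_ge_125": 0.08,
            "temperature_ge_40": 0.08,
        },
    ),
    # Old, heavily comorbid, unstable vitals: scores > 100.
    RiskClass.HIGH.value: ClassDemographics(
        age_mean=88.0,
        age_sd=9.0,
        age_min=18,
        age_max=105,
        female_prob=0.50,
        flag_probs={
            "nursing_home_resident": 0.12,
            "malignancy": 0.18,
            "congestive_heart_failure": 0.18,
            "cerebrovascular_disease": 0.18,
            "liver_cirrhosis": 0.02,
            "renal_disease": 0.18,
            "altered_mental_status": 0.12,
            "respiratory_rate_ge_30": 0.10,
            "systolic_bp_lt_90": 0.10,
            "pulse_ge_125": 0.12,
            "temperature_ge_40": 0.12,
        },
    ),
}


@dataclass(frozen=True)
class CohortModel:
    """Per-risk-class prevalence and outcome probabilities for the generator.

    Defaults reproduce the trial cohort (control and intervention arms
    combined): class mix 232/93/45 of 370; 30-day mortality 0%/4%/11%;
    90-day mortality 0%/6%/13%; ICU admission 1%/2%/9%; median hospital
    stay 4/5/6 days with interquartile ranges 3/4/4 days.
    """

    class_prevalence: tuple[float, float, float] = (232 / 370, 93 / 370, 45 / 370)
    mortality_30d: tuple[float, float, float] = (0.0, 0.04, 0.11)
    mortality_90d: tuple[float, float, float] = (0.0, 0.06, 0.13)
    icu_prob: tuple[float, float, float] = (0.01, 0.02, 0.09)
    median_stay_days: tuple[float, float, float] = (4.0, 5.0, 6.0)
    stay_iqr_days: tuple[float, float, float] = (3.0, 4.0, 4.0)
    demographics: Mapping[str, ClassDemographics] = field(
        default_factory=lambda: dict(_DEFAULT_DEMOGRAPHICS)
    )
    thresholds: RiskThresholds = DEFAULT_THRESHOLDS
    weights: ScoreWeights = DEFAULT_WEIGHTS

    def __post_init__(self) -> None:
        prev = np.asarray(self.class_prevalence, dtype=float)
        if prev.shape != (3,) or (prev < 0).any() or not math.isclose(prev.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("class_prevalence must be 3 non-negative values summing to 1")
        for name in ("mortality_30d", "mortality_90d", "icu_prob"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (3,) or (arr < 0).any() or (arr > 1).any():
                raise ValueError(f"{name} must be 3 probabilities")
        if (np.asarray(self.mortality_90d) < np.asarray(self.mortality_30d)).any():
            raise ValueError("90-day mortality cannot be below 30-day mortality")
        missing = [c for c in _CLASSES if c not in self.demographics]
        if missing:
            raise ValueError(f"demographics missing for class(es): {missing}")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortModel":
        d = dict(d)
        if "demographics" in d:
            d["demographics"] = {
                k: v if isinstance(v, ClassDemographics) else ClassDemographics(**v)
                for k, v in d["demographics"].items()
            }
        if "thresholds" in d and not isinstance(d["thresholds"], RiskThresholds):
            d["thresholds"] = RiskThresholds(**d["thresholds"])
        for key in ("class_prevalence", "mortality_30d", "mortality_90d", "icu_prob",
                    "median_stay_days", "stay_iqr_days"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def class_interval(self, risk_class: str) -> tuple[int, float]:
        """Closed score interval [lo, hi] for a class (hi may be +inf)."""
        t = self.thresholds
        if risk_class == RiskClass.LOW.value:
            return (-10**9, t.low_upper - 1)
        if risk_class == RiskClass.INTERMEDIATE.value:
            return (t.low_upper, t.high_lower)
        if risk_class == RiskClass.HIGH.value:
            return (t.high_lower + 1, math.inf)
        raise ValueError(f"unknown risk class {risk_class!r}")


def _lognormal_sigma(median: float, iqr: float) -> float:
    # For LN(mu, sigma): IQR width = median * 2*sinh(z75*sigma), z75 = 0.6745.
    z75 = 1.3489795003921634 / 2.0
    return math.asinh(iqr / (2.0 * median)) / z75


def _sample_class_patients(
    rng: np.random.Generator, model: CohortModel, risk_class: str, count: int
) -> pd.DataFrame:
    """Rejection-sample ``count`` patients whose score lies in the class interval."""
    if count == 0:
        return pd.DataFrame()
    demo = model.demographics[risk_class]
    lo, hi = model.class_interval(risk_class)
    w = model.weights
    flag_names = list(FLAG_FIELDS)
    flag_weights = np.array([w.flag_weight(f) for f in flag_names])
    chunks: list[dict[str, np.ndarray]] = []
    accepted = 0
    attempts = 0
    while accepted < count:
        attempts += 1
        if attempts > 200:
            raise InfeasibleConstraintError(
                f"cannot generate patients whose score falls in class "
                f"{risk_class!r} from the configured demographics"
            )
        batch = max(1024, 3 * (count - accepted))
        age = np.clip(
            np.rint(rng.normal(demo.age_mean, demo.age_sd, batch)),
            demo.age_min,
            demo.age_max,
        ).astype(int)
        female = rng.random(batch) < demo.female_prob
        flags = rng.random((batch, len(flag_names))) < np.array(
            [demo.flag_probs[f] for f in flag_names]
        )
        total = age + female * w.female_age_offset + flags @ flag_weights
        ok = (total >= lo) & (total <= hi)
        n_ok = int(ok.sum())
        if n_ok == 0:
            continue
        take = min(n_ok, count - accepted)
        idx = np.flatnonzero(ok)[:take]
        chunk = {
            "age": age[idx],
            "sex": np.where(female[idx], "F", "M"),
            "score": total[idx].astype(int),
        }
        for j, f in enumerate(flag_names):
            chunk[f] = flags[idx, j]
        chunks.append(chunk)
        accepted += take
    out = {
        key: np.concatenate([c[key] for c in chunks]) for key in chunks[0]
    }
    df = pd.DataFrame(out)
    df["risk_class"] = risk_class
    return df


def generate_cohort(model: CohortModel, n: int, seed: SeedLike = None) -> pd.DataFrame:
    """Draw ``n`` synthetic patients with latent outcome draws.

    Each patient gets a risk class from the configured prevalences,
    characteristics consistent with that class (the computed score always
    lies in the class interval), and latent outcome draws: 30/90-day death,
    ICU admission, and a length of stay from a discretized log-normal
    matched to the class median and IQR (realized only if admitted).
    Reproducible given the seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    rng = _rng(seed)
    labels = rng.choice(3, size=n, p=np.asarray(model.class_prevalence, dtype=float))
    parts = []
    for k, cls in enumerate(_CLASSES):
        cnt = int((labels == k).sum())
        if cnt:
            part = _sample_class_patients(rng, model, cls, cnt)
            part["_k"] = k
            parts.append(part)
    df = pd.concat(parts, ignore_index=True)
    # Interleave classes back into an iid patient stream.
    positions = np.empty(n, dtype=int)
    offset = 0
    for k in range(3):
        idx = np.flatnonzero(labels == k)
        positions[offset : offset + idx.size] = idx
        offset += idx.size
    df.index = positions
    df = df.sort_index().reset_index(drop=True)
    k = df.pop("_k").to_numpy()

    m30 = np.asarray(model.mortality_30d)[k]
    m90 = np.asarray(model.mortality_90d)[k]
    death30 = rng.random(n) < m30
    with np.errstate(divide="ignore", invalid="ignore"):
        extra = np.where(m30 < 1.0, (m90 - m30) / (1.0 - m30), 0.0)
    death90 = death30 | (rng.random(n) < extra)
    icu = rng.random(n) < np.asarray(model.icu_prob)[k]
    med = np.asarray(model.median_stay_days)[k]
    sigma = np.array(
        [_lognormal_sigma(m, i) for m, i in zip(model.median_stay_days, model.stay_iqr_days)]
    )[k]
    los = np.maximum(1, np.rint(rng.lognormal(np.log(med), sigma))).astype(int)

    df.insert(0, "patient_id", np.arange(1, n + 1))
    df["death30"] = death30
    df["death90"] = death90
    df["icu"] = icu
    df["los_days"] = los
    return df


@dataclass(frozen=True)
class ControlPolicy:
    """Physician-discretion admission during control periods.

    Defaults: 92% of patients admitted regardless of class; home-treated
    patients face a 1/17 secondary-admission risk. ``per_class_admit`` may
    refine the admission probability by risk class.
    """

    admit_prob: float = 0.92
    per_class_admit: Optional[Mapping[str, float]] = None
    secondary_admission_prob: float = 1 / 17

    def admit_probability(self, risk_class: np.ndarray) -> np.ndarray:
        if self.per_class_admit is None:
            return np.full(risk_class.shape, self.admit_prob)
        return np.array([self.per_class_admit[c] for c in risk_class])


@dataclass(frozen=True)
class InterventionPolicy:
    """Score-guided admission with physician overrule.

    Low-risk patients go home unless the physician overrules (default
    50/153); intermediate-risk patients are admitted with the observed
    frequency 29/35; high-risk patients are admitted unless they insist on
    home treatment (default 2/19). Home-treated patients face a 10/37
    secondary-admission risk.
    """

    low_overrule_prob: float = 50 / 153
    intermediate_admit_prob: float = 29 / 35
    high_home_prob: float = 2 / 19
    secondary_admission_prob: float = 10 / 37

    def admit_probability(self, risk_class: np.ndarray) -> np.ndarray:
        probs = {
            RiskClass.LOW.value: self.low_overrule_prob,
            RiskClass.INTERMEDIATE.value: self.intermediate_admit_prob,
            RiskClass.HIGH.value: 1.0 - self.high_home_prob,
        }
        return np.array([probs[c] for c in risk_class])


@dataclass(frozen=True)
class TrialDesign:
    """Stepped-wedge design parameters.

    ``n_clusters`` centers all start in control; one cluster crosses to the
    intervention at the start of each successive period, in random order,
    until ``n_never_crossing`` clusters remain on control for the whole
    trial. ``accrual_per_period`` patients enter per cluster per period.
    """

    n_clusters: int = 7
    n_periods: int = 7
    accrual_per_period: int = 8
    cluster_accrual: Optional[Sequence[int]] = None  # per-cluster override
    n_never_crossing: int = 1
    policy_control: ControlPolicy = field(default_factory=ControlPolicy)
    policy_intervention: InterventionPolicy = field(default_factory=InterventionPolicy)
    alpha_one_tailed: float = 0.025
    power: float = 0.90
    margin: float = 0.025

    def __post_init__(self) -> None:
        if self.n_clusters < 1 or self.n_periods < 1 or self.accrual_per_period < 1:
            raise ValueError("cluster, period and accrual counts must be positive")
        if not 0 <= self.n_never_crossing <= self.n_clusters:
            raise ValueError("n_never_crossing out of range")
        if self.cluster_accrual is not None and len(self.cluster_accrual) != self.n_clusters:
            raise ValueError("cluster_accrual must list one accrual per cluster")

    @classmethod
    def from_dict(cls, d: Mapping) -> "TrialDesign":
        d = dict(d)
        if "policy_control" in d and not isinstance(d["policy_control"], ControlPolicy):
            d["policy_control"] = ControlPolicy(**d["policy_control"])
        if "policy_intervention" in d and not isinstance(
            d["policy_intervention"], InterventionPolicy
        ):
            d["policy_intervention"] = InterventionPolicy(**d["policy_intervention"])
        return cls(**d)

    def accrual_for(self, cluster: int) -> int:
        if self.cluster_accrual is not None:
            return int(self.cluster_accrual[cluster])
        return self.accrual_per_period


@dataclass(frozen=True)
class MonitorConfig:
    """Safety-monitor configuration.

    The monitored metric is the absolute risk difference (intervention
    minus control, percentage points) in secondary admissions among
    home-treated patients with score <= ``eligible_max_score``. An interim
    analysis fires when the cumulative number of intervention-arm inclusions
    reaches each entry of ``interim_schedule``; the monitor advises stopping
    when the difference reaches ``stopping_threshold_pp``.
    """

    stopping_threshold_pp: float = 20.0
    interim_schedule: tuple[int, ...] = (133,)
    eligible_max_score: int = 100

    def __post_init__(self) -> None:
        if self.stopping_threshold_pp <= 0:
            raise ValueError("stopping threshold must be positive")
        if any(t <= 0 for t in self.interim_schedule):
            raise ValueError("interim triggers must be positive patient counts")
        object.__setattr__(self, "interim_schedule", tuple(sorted(self.interim_schedule)))

    @classmethod
    def from_dict(cls, d: Mapping) -> "MonitorConfig":
        d = dict(d)
        if "interim_schedule" in d:
            d["interim_schedule"] = tuple(d["interim_schedule"])
        return cls(**d)


@dataclass(frozen=True)
class InterimDecision:
    """One interim look: observed counts, risk difference, stop advice."""

    control_events: int
    control_n: int
    intervention_events: int
    intervention_n: int
    diff_pp: Optional[float]
    stop: bool
    trigger: Optional[int] = None

    @property
    def control_rate(self) -> Optional[float]:
        return self.control_events / self.control_n if self.control_n else None

    @property
    def intervention_rate(self) -> Optional[float]:
        return self.intervention_events / self.intervention_n if self.intervention_n else None


def interim_check(
    control_events: int,
    control_n: int,
    intervention_events: int,
    intervention_n: int,
    threshold_pp: float = 20.0,
    trigger: Optional[int] = None,
) -> InterimDecision:
    """One-shot safety check on supplied secondary-admission counts.

    Computes the absolute risk difference (intervention minus control) in
    percentage points and advises stopping when it reaches the threshold.
    Empty denominators make the difference not evaluable and never stop the
    trial.
    """
    if control_n and intervention_n:
        diff = 100.0 * (
            intervention_events / intervention_n - control_events / control_n
        )
        stop = diff >= threshold_pp
    else:
        diff, stop = None, False
    return InterimDecision(
        control_events=int(control_events),
        control_n=int(control_n),
        intervention_events=int(intervention_events),
        intervention_n=int(intervention_n),
        diff_pp=diff,
        stop=stop,
        trigger=trigger,
    )


@dataclass
class TrialRecord:
    """Result of one simulated trial."""

    patients: pd.DataFrame
    crossover_order: tuple[int, ...]
    crossover_period: tuple[float, ...]
    interims: list[InterimDecision]
    stopped: bool
    stop_period: Optional[int]
    planned_n: int

    @property
    def n_control(self) -> int:
        return int((~self.patients["intervention"]).sum())

    @property
    def n_intervention(self) -> int:
        return int(self.patients["intervention"].sum())

    def _arm(self, intervention: bool) -> pd.DataFrame:
        return self.patients[self.patients["intervention"] == intervention]

    def admission_rate(self, intervention: bool) -> Optional[float]:
        arm = self._arm(intervention)
        return float(arm["admitted"].mean()) if len(arm) else None

    def secondary_counts(self, intervention: bool, max_score: Optional[int] = None):
        """(events, n) among home-treated patients in one arm, optionally
        restricted to scores <= max_score."""
        arm = self._arm(intervention)
        home = arm[~arm["admitted"]]
        if max_score is not None:
            home = home[home["score"] <= max_score]
        return int(home["secondary_admission"].sum()), int(len(home))

    def summary(self) -> dict:
        out = {
            "n_total": int(len(self.patients)),
            "planned_n": self.planned_n,
            "n_control": self.n_control,
            "n_intervention": self.n_intervention,
            "stopped": self.stopped,
            "stop_period": self.stop_period,
            "n_interims": len(self.interims),
        }
        for arm, name in ((False, "control"), (True, "intervention")):
            sub = self._arm(arm)
            out[f"{name}_admitted"] = int(sub["admitted"].sum())
            rate = self.admission_rate(arm)
            out[f"{name}_admission_rate"] = rate
            ev, n = self.secondary_counts(arm)
            out[f"{name}_secondary_events"] = ev
            out[f"{name}_home_n"] = n
        return out


def run_trial(
    design: TrialDesign,
    model: CohortModel,
    monitor: MonitorConfig,
    seed: SeedLike = None,
) -> TrialRecord:
    """Simulate one stepped-wedge trial with interim safety monitoring.

    The full patient stream is generated up front in chronological order
    (period-major, cluster within period); the monitor then scans the
    stream, firing each interim when the cumulative intervention inclusions
    reach its trigger and truncating accrual at a stop. This makes the
    trajectory of a given seed independent of the stopping threshold.
    """
    rng = _rng(seed)
    order = rng.permutation(design.n_clusters)
    n_crossing = design.n_clusters - design.n_never_crossing
    crossover = np.full(design.n_clusters, math.inf)
    for position, cluster in enumerate(order[:n_crossing]):
        crossover[cluster] = position + 1

    cluster_col, period_col = [], []
    for period in range(design.n_periods):
        for cluster in range(design.n_clusters):
            m = design.accrual_for(cluster)
            cluster_col.extend([cluster] * m)
            period_col.extend([period] * m)
    n_total = len(cluster_col)

    patients = generate_cohort(model, n_total, rng)
    patients["cluster"] = np.asarray(cluster_col)
    patients["period"] = np.asarray(period_col)
    patients["intervention"] = patients["period"] >= crossover[patients["cluster"]]

    interv = patients["intervention"].to_numpy()
    classes = patients["risk_class"].to_numpy()
    p_admit = np.where(
        interv,
        design.policy_intervention.admit_probability(classes),
        design.policy_control.admit_probability(classes),
    )
    admitted = rng.random(n_total) < p_admit
    p_secondary = np.where(
        interv,
        design.policy_intervention.secondary_admission_prob,
        design.policy_control.secondary_admission_prob,
    )
    secondary = ~admitted & (rng.random(n_total) < p_secondary)
    patients["admitted"] = admitted
    patients["secondary_admission"] = secondary

    # Monitor scan over the chronological stream.
    cum_interv = np.cumsum(interv)
    scores = patients["score"].to_numpy()
    interims: list[InterimDecision] = []
    stopped = False
    stop_idx: Optional[int] = None
    for trigger in monitor.interim_schedule:
        if cum_interv[-1] < trigger:
            break
        idx = int(np.searchsorted(cum_interv, trigger))
        upto = slice(0, idx + 1)
        eligible = ~admitted[upto] & (scores[upto] <= monitor.eligible_max_score)
        in_arm = interv[upto]
        decision = interim_check(
            control_events=int(secondary[upto][eligible & ~in_arm].sum()),
            control_n=int((eligible & ~in_arm).sum()),
            intervention_events=int(secondary[upto][eligible & in_arm].sum()),
            intervention_n=int((eligible & in_arm).sum()),
            threshold_pp=monitor.stopping_threshold_pp,
            trigger=trigger,
        )
        interims.append(decision)
        if decision.stop:
            stopped = True
            stop_idx = idx
            break

    if stop_idx is not None:
        patients = patients.iloc[: stop_idx + 1].reset_index(drop=True)
    stop_period = int(patients["period"].iloc[-1]) if stopped else None

    return TrialRecord(
        patients=patients,
        crossover_order=tuple(int(c) for c in order),
        crossover_period=tuple(float(c) for c in crossover),
        interims=interims,
        stopped=stopped,
        stop_period=stop_period,
        planned_n=n_total,
    )


@dataclass(frozen=True)
class OperatingCharacteristics:
    """Monte-Carlo summary over repeated simulated trials."""

    reps: int
    early_stop_prob: float
    early_stop_se: float
    power: float
    power_se: float
    mean_admission_reduction_pp: float
    admission_reduction_se_pp: float

    def as_dict(self) -> dict:
        return {
            "reps": self.reps,
            "early_stop_prob": self.early_stop_prob,
            "early_stop_se": self.early_stop_se,
            "power": self.power,
            "power_se": self.power_se,
            "mean_admission_reduction_pp": self.mean_admission_reduction_pp,
            "admission_reduction_se_pp": self.admission_reduction_se_pp,
        }


def operating_characteristics(
    design: TrialDesign,
    model: CohortModel,
    monitor: MonitorConfig,
    reps: int,
    seed: SeedLike = None,
) -> tuple[OperatingCharacteristics, list[TrialRecord]]:
    """Monte-Carlo operating characteristics of a design.

    ``power`` is the fraction of trials whose final two-sided Pearson
    chi-square on primary admission (control vs intervention) is significant
    at the 0.05 level (Fisher's exact test when a margin is degenerate);
    ``early_stop_prob`` is the fraction stopped by the safety monitor;
    the admission reduction is control minus intervention admission rate in
    percentage points. Returns the summary and the individual records.
    """
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if isinstance(seed, np.random.Generator):
        seed = int(seed.integers(2**31))
    seeds = np.random.SeedSequence(seed).spawn(reps)
    records: list[TrialRecord] = []
    stops = np.zeros(reps, dtype=bool)
    significant = np.zeros(reps, dtype=bool)
    reductions = np.full(reps, np.nan)
    for i, ss in enumerate(seeds):
        rec = run_trial(design, model, monitor, np.random.default_rng(ss))
        records.append(rec)
        stops[i] = rec.stopped
        rc, ri = rec.admission_rate(False), rec.admission_rate(True)
        if rc is not None and ri is not None:
            reductions[i] = 100.0 * (rc - ri)
            table = TwoByTwo.from_rates(
                int(rec._arm(False)["admitted"].sum()),
                rec.n_control,
                int(rec._arm(True)["admitted"].sum()),
                rec.n_intervention,
            )
            try:
                p = pearson_chi2(table).p_value
            except ValueError:
                p = fisher_exact(table)
            significant[i] = p < 0.05
    valid = ~np.isnan(reductions)
    mean_red = float(np.nanmean(reductions)) if valid.any() else float("nan")
    red_se = (
        float(np.nanstd(reductions, ddof=1) / math.sqrt(valid.sum()))
        if valid.sum() > 1
        else float("nan")
    )
    p_stop = float(stops.mean())
    p_sig = float(significant.mean())
    return (
        OperatingCharacteristics(
            reps=reps,
            early_stop_prob=p_stop,
            early_stop_se=math.sqrt(p_stop * (1 - p_stop) / reps),
            power=p_sig,
            power_se=math.sqrt(p_sig * (1 - p_sig) / reps),
            mean_admission_reduction_pp=mean_red,
            admission_reduction_se_pp=red_se,
        ),
        records,
    )
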