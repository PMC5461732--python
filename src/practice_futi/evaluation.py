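"""Discrimination metrics, predictive values and two-proportion inference.

These are the validation and analysis tools for the admission rule: ROC AUC
(Mann-Whitney construction), NPV/PPV at a score cut-off, Pearson chi-square
and Fisher's exact test on 2x2 tables, the Wald risk difference with
confidence interval, the non-inferiority sample-size formula, and the
per-risk-class outcome table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import NotEvaluableError
from .score import RiskClass

__all__ = [
    "TwoByTwo",
    "PredictiveValues",
    "Chi2Result",
    "RiskDifference",
    "roc_auc",
    "predictive_values",
    "pearson_chi2",
    "fisher_exact",
    "choose_test",
    "risk_difference",
    "round_half_up",
    "noninferiority_sample_size",
    "risk_class_outcome_table",
]


def round_half_up(x: float) -> int:
    """Round to the nearest integer, halves away from zero toward +inf.

    Report tables print whole percentage points with this convention
    (92, 72, 57 ...); underlying values are kept at full precision.
    """
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class TwoByTwo:
    """A 2x2 contingency table; rows are groups, columns event / no-event.

    ``a``/``b`` are the events and non-events in group 1, ``c``/``d`` in
    group 2.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"count {name} must be a non-negative integer, got {v}")
        if self.total == 0:
            raise ValueError("table must contain at least one observation")

    @classmethod
    def from_rates(cls, events1: int, n1: int, events2: int, n2: int) -> "TwoByTwo":
        """Build from events-out-of-n per group (``events1/n1`` vs ``events2/n2``)."""
        if events1 > n1 or events2 > n2:
            raise ValueError("events cannot exceed group size")
        return cls(events1, n1 - events1, events2, n2 - events2)

    @property
    def row1(self) -> int:
        return self.a + self.b

    @property
    def row2(self) -> int:
        return self.c + self.d

    @property
    def col_event(self) -> int:
        return self.a + self.c

    @property
    def col_noevent(self) -> int:
        return self.b + self.d

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)

    def expected(self) -> np.ndarray:
        """Expected counts under independence; requires positive margins."""
        if min(self.row1, self.row2, self.col_event, self.col_noevent) == 0:
            raise ValueError("a zero margin leaves expected counts undefined")
        rows = np.array([self.row1, self.row2], dtype=float)
        cols = np.array([self.col_event, self.col_noevent], dtype=float)
        return np.outer(rows, cols) / self.total


@dataclass(frozen=True)
class PredictiveValues:
    """NPV/PPV and sensitivity/specificity at a score cut-off.

    A value is ``None`` when its denominator is empty (for instance NPV with
    no predicted negatives); callers must treat that as not evaluable rather
    than zero.
    """

    cutoff: int
    npv: Optional[float]
    ppv: Optional[float]
    sensitivity: Optional[float]
    specificity: Optional[float]
    tp: int
    fp: int
    tn: int
    fn: int


@dataclass(frozen=True)
class Chi2Result:
    statistic: float
    p_value: float
    df: int = 1


@dataclass(frozen=True)
class RiskDifference:
    """Difference of row event proportions (group1 - group2) with a Wald CI.

    ``difference`` and the CI bounds are proportions; ``percentage_points``
    is the report-level whole-point rounding of ``100 * difference``.
    """

    difference: float
    ci_low: float
    ci_high: float
    confidence: float
    p1: float
    p2: float

    @property
    def percentage_points(self) -> int:
        return round_half_up(100.0 * self.difference)


def _as_bool_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels, dtype=bool)
    if arr.ndim != 1:
        raise ValueError("labels must be one-dimensional")
    return arr


def roc_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Area under the ROC curve by the Mann-Whitney rank construction.

    Equals the probability that a random positive outscores a random
    negative, with ties counted as one half. Requires both classes present.
    """
    y = _as_bool_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC is undefined with a single class of labels")
    ranks = stats.rankdata(s)  # mid-ranks handle ties
    rank_sum_pos = ranks[y].sum()
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def predictive_values(
    scores: Sequence[float], labels: Sequence[bool], cutoff: int
) -> PredictiveValues:
    """NPV, PPV, sensitivity and specificity with *positive* = score >= cutoff."""
    y = _as_bool_labels(labels)
    s = np.asarray(scores, dtype=float)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have the same length")
    if y.all() or (~y).all():
        raise ValueError("predictive values need both classes of labels present")
    predicted_pos = s >= cutoff
    tp = int((predicted_pos & y).sum())
    fp = int((predicted_pos & ~y).sum())
    tn = int((~predicted_pos & ~y).sum())
    fn = int((~predicted_pos & y).sum())

    def ratio(num: int, den: int) -> Optional[float]:
        return num / den if den > 0 else None

    return PredictiveValues(
        cutoff=cutoff,
        npv=ratio(tn, tn + fn),
        ppv=ratio(tp, tp + fp),
        sensitivity=ratio(tp, tp + fn),
        specificity=ratio(tn, tn + fp),
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
    )


def pearson_chi2(table: TwoByTwo) -> Chi2Result:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction.

    The statistic equals the square of the pooled two-proportion z
    statistic.
    """
    table.expected()  # raises on zero margins
    statistic, p, df, _ = stats.chi2_contingency(table.as_array(), correction=False)
    return Chi2Result(statistic=float(statistic), p_value=float(p), df=int(df))


def fisher_exact(table: TwoByTwo) -> float:
    """Two-tailed Fisher exact p by the probability-mass method: the sum of
    hypergeometric probabilities of all tables with the observed margins
    that are no more probable than the observed one."""
    _, p = stats.fisher_exact(table.as_array(), alternative="two-sided")
    return float(min(p, 1.0))


def choose_test(table: TwoByTwo) -> str:
    """Select ``"fisher"`` when any expected count falls below 5, else
    ``"pearson"``. Returns the name; callers may override."""
    try:
        expected = table.expected()
    except ValueError:
        return "fisher"
    return "fisher" if (expected < 5).any() else "pearson"


def risk_difference(table: TwoByTwo, confidence: float = 0.95) -> RiskDifference:
    """Difference in event proportions between the two rows with a Wald
    normal-approximation confidence interval."""
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must lie in (0, 1)")
    if table.row1 == 0 or table.row2 == 0:
        raise ValueError("both groups must be non-empty")
    p1 = table.a / table.row1
    p2 = table.c / table.row2
    diff = p1 - p2
    se = math.sqrt(p1 * (1 - p1) / table.row1 + p2 * (1 - p2) / table.row2)
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    return RiskDifference(
        difference=diff,
        ci_low=diff - z * se,
        ci_high=diff + z * se,
        confidence=confidence,
        p1=p1,
        p2=p2,
    )


def noninferiority_sample_size(
    p_control: float,
    margin: float,
    alpha_one_tailed: float = 0.025,
    power: float = 0.90,
) -> int:
    """Per-arm sample size for a one-tailed non-inferiority test of two
    proportions by the standard normal-approximation formula.

    Under the alternative that both arms share the event rate ``p_control``,
    the smallest n per arm giving the requested power to reject the null of
    an event-rate excess of ``margin`` or more in the intervention arm:

        n = (z_alpha + z_power)^2 * 2 * p * (1 - p) / margin^2

    rounded up. This is the textbook design formula; small-n designs should
    be checked against exact binomial simulation.
    """
    if not 0.0 < p_control < 1.0:
        raise ValueError("p_control must lie strictly inside (0, 1)")
    if margin <= 0.0:
        raise ValueError("margin must be positive")
    if not 0.0 < alpha_one_tailed < 0.5:
        raise ValueError("alpha_one_tailed must lie in (0, 0.5)")
    if not 0.0 < power < 1.0:
        raise ValueError("power must lie in (0, 1)")
    z_a = stats.norm.ppf(1.0 - alpha_one_tailed)
    z_b = stats.norm.ppf(power)
    n = (z_a + z_b) ** 2 * 2.0 * p_control * (1.0 - p_control) / margin**2
    if not math.isfinite(n):
        raise ValueError("requested power is unreachable for these inputs")
    return int(math.ceil(n))


#: Outcome columns consumed by :func:`risk_class_outcome_table`.
_OUTCOME_COLS = ("death30", "death90", "icu")

_CLASS_ORDER = [RiskClass.LOW.value, RiskClass.INTERMEDIATE.value, RiskClass.HIGH.value]


def risk_class_outcome_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-risk-class outcome summary in the shape of the trial report.

    Expects a scored cohort with a ``risk_class`` column plus boolean
    outcome columns ``death30``, ``death90``, ``icu`` and (optionally, for
    admitted patients) ``los_days``. Emits one row per risk class plus a
    total row, with n, event counts, event rates and the median length of
    stay with its interquartile range.
    """
    required = ["risk_class", *_OUTCOME_COLS]
    if cohort.empty:
        return pd.DataFrame(
            columns=["risk_class", "n"]
            + [f"{c}_{s}" for c in _OUTCOME_COLS for s in ("n", "rate")]
            + ["los_median", "los_iqr"]
        )
    missing = [c for c in required if c not in cohort.columns]
    if missing:
        raise NotEvaluableError(f"cohort lacks column(s): {missing}")
    rows = []
    groups = [(c, cohort[cohort["risk_class"] == c]) for c in _CLASS_ORDER]
    groups.append(("total", cohort))
    for name, sub in groups:
        n = len(sub)
        row: dict[str, object] = {"risk_class": name, "n": n}
        for col in _OUTCOME_COLS:
            events = int(sub[col].astype(bool).sum()) if n else 0
            row[f"{col}_n"] = events
            row[f"{col}_rate"] = events / n if n else float("nan")
        if "los_days" in sub.columns and n:
            los = sub["los_days"].dropna()
        else:
            los = pd.Series(dtype=float)
        if len(los):
            q1, med, q3 = np.percentile(los, [25, 50, 75])
            row["los_median"] = float(med)
            row["los_iqr"] = float(q3 - q1)
        else:
            row["los_median"] = float("nan")
            row["los_iqr"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
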