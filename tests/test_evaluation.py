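"""Discrimination metrics and two-proportion inference, each checked against
an independent oracle: brute-force pair counting for the AUC, full
hypergeometric enumeration for Fisher's test, the pooled two-proportion z
statistic for the chi-square, and exact binomial simulation for the
non-inferiority sample size."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from practice_futi import (
    CohortModel,
    TwoByTwo,
    choose_test,
    fisher_exact,
    generate_cohort,
    noninferiority_sample_size,
    pearson_chi2,
    predictive_values,
    risk_class_outcome_table,
    risk_difference,
    roc_auc,
    round_half_up,
)

# ---------------------------------------------------------------- oracles


def auc_bruteforce(scores, labels):
    """All-pairs probability that a positive outscores a negative, ties half."""
    pos = [s for s, y in zip(scores, labels) if y]
    neg = [s for s, y in zip(scores, labels) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def fisher_oracle(table: TwoByTwo) -> float:
    """Two-tailed p by explicit hypergeometric enumeration (probability-mass
    method: sum every table with the observed margins that is no more
    probable than the observed one)."""
    r1, col, n = table.row1, table.col_event, table.total
    def prob(x):
        return (
            math.comb(r1, x)
            * math.comb(n - r1, col - x)
            / math.comb(n, col)
        )
    lo, hi = max(0, col - (n - r1)), min(col, r1)
    p_obs = prob(table.a)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


def pooled_z(table: TwoByTwo) -> float:
    p1, p2 = table.a / table.row1, table.c / table.row2
    p = table.col_event / table.total
    se = math.sqrt(p * (1 - p) * (1 / table.row1 + 1 / table.row2))
    return (p1 - p2) / se


def random_tables(rng, count, max_n=40, positive_margins=False):
    out = []
    while len(out) < count:
        vals = rng.integers(0, max_n, size=4)
        try:
            t = TwoByTwo(*map(int, vals))
        except ValueError:
            continue
        if positive_margins and min(t.row1, t.row2, t.col_event, t.col_noevent) == 0:
            continue
        out.append(t)
    return out


# ---------------------------------------------------------------- ROC AUC


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores, labels, expected",
        [
            ([1, 2, 3, 4], [False, False, True, True], 1.0),
            ([5, 5, 5, 5], [False, True, False, True], 0.5),
            # brute-force pair count: 3 wins + 1 tie over 4 pairs
            ([1, 2, 2, 3], [False, True, False, True], 0.875),
        ],
    )
    def test_worked_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 25))
            scores = rng.integers(0, 8, n).astype(float)
            labels = rng.random(n) < 0.5
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                auc_bruteforce(scores, labels), abs=1e-12
            )

    def test_matches_sklearn_cross_check(self, rng):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        for _ in range(20):
            n = int(rng.integers(6, 40))
            scores = rng.normal(size=n)
            labels = rng.random(n) < 0.4
            if labels.all() or not labels.any():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                sklearn_metrics.roc_auc_score(labels, scores)
            )

    def test_invariant_under_monotone_transform(self, rng):
        scores = rng.integers(0, 50, 80).astype(float)
        labels = rng.random(80) < 0.3
        transformed = np.exp(scores / 10.0) + 3
        assert roc_auc(scores, labels) == pytest.approx(roc_auc(transformed, labels))

    def test_negated_scores_complement(self, rng):
        scores = rng.integers(0, 10, 60).astype(float)
        labels = rng.random(60) < 0.5
        assert roc_auc(scores, labels) + roc_auc(-scores, labels) == pytest.approx(1.0)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError):
            roc_auc([1, 2, 3], [True, True, True])


# ---------------------------------------------------- predictive values


class TestPredictiveValues:
    def test_all_negative_labels_give_npv_one(self):
        pv = predictive_values([10, 50, 120, 130], [False, False, False, True], 100)
        assert pv.npv == 1.0

    def test_cutoff_below_support_makes_npv_not_evaluable(self):
        pv = predictive_values([50, 60, 70], [True, False, False], 10)
        assert pv.npv is None
        assert pv.ppv == pytest.approx(1 / 3)

    def test_counts_against_hand_example(self):
        scores = [120, 110, 90, 80, 130, 60]
        labels = [True, False, True, False, True, False]
        pv = predictive_values(scores, labels, 100)
        assert (pv.tp, pv.fp, pv.fn, pv.tn) == (2, 1, 1, 2)
        assert pv.ppv == pytest.approx(2 / 3)
        assert pv.npv == pytest.approx(2 / 3)
        assert pv.sensitivity == pytest.approx(2 / 3)
        assert pv.specificity == pytest.approx(2 / 3)

    def test_npv_on_synthetic_cohort_near_one(self):
        # per-class 30-day mortality 0/4/11% means deaths below the 100-point
        # cut-off can come only from the intermediate class: NPV stays near 1
        cohort = generate_cohort(CohortModel(), 20000, seed=42)
        pv = predictive_values(
            cohort["score"].to_numpy(), cohort["death30"].to_numpy(), 100
        )
        negatives = cohort[cohort["score"] < 100]
        direct = 1.0 - negatives["death30"].mean()
        assert pv.npv == pytest.approx(direct, abs=1e-12)
        assert pv.npv > 0.97


# ------------------------------------------------------- chi-square / Fisher


class TestPearsonChi2:
    def test_headline_table_is_highly_significant(self):
        res = pearson_chi2(TwoByTwo(219, 18, 96, 37))
        assert res.p_value < 0.001

    def test_identical_proportions_give_zero_statistic(self):
        res = pearson_chi2(TwoByTwo(10, 10, 10, 10))
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_uniform_scaling_doubles_statistic(self):
        base = pearson_chi2(TwoByTwo(5, 5, 5, 5)).statistic
        doubled = pearson_chi2(TwoByTwo(10, 10, 10, 10)).statistic
        assert doubled == pytest.approx(2 * base)
        s1 = pearson_chi2(TwoByTwo(8, 3, 4, 9)).statistic
        s2 = pearson_chi2(TwoByTwo(16, 6, 8, 18)).statistic
        assert s2 == pytest.approx(2 * s1)

    def test_equals_squared_pooled_z(self, rng):
        for table in random_tables(rng, 40, positive_margins=True):
            assert pearson_chi2(table).statistic == pytest.approx(
                pooled_z(table) ** 2, rel=1e-9
            )

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_chi2(TwoByTwo(0, 5, 0, 7))


class TestFisherExact:
    def test_degenerate_column_gives_p_one(self):
        assert fisher_exact(TwoByTwo(0, 12, 0, 9)) == pytest.approx(1.0)

    def test_matches_enumeration_oracle(self, rng):
        tables = random_tables(rng, 40) + [TwoByTwo(1, 16, 10, 27)]
        for table in tables:
            assert fisher_exact(table) == pytest.approx(fisher_oracle(table), rel=1e-7)

    def test_p_within_probability_bounds(self, rng):
        for table in random_tables(rng, 20):
            p = fisher_exact(table)
            assert 0.0 < p <= 1.0

    def test_enumeration_masses_sum_to_one(self):
        table = TwoByTwo(6, 4, 3, 7)
        r1, col, n = table.row1, table.col_event, table.total
        lo, hi = max(0, col - (n - r1)), min(col, r1)
        total = sum(
            math.comb(r1, x) * math.comb(n - r1, col - x) / math.comb(n, col)
            for x in range(lo, hi + 1)
        )
        assert total == pytest.approx(1.0)


def test_choose_test_prefers_fisher_for_small_expected_counts():
    assert choose_test(TwoByTwo(1, 16, 10, 27)) == "fisher"
    assert choose_test(TwoByTwo(219, 18, 96, 37)) == "pearson"


# ------------------------------------------------------- risk difference


class TestRiskDifference:
    @pytest.mark.parametrize(
        "events1, n1, events2, n2, expected_pp",
        [
            (219, 237, 96, 133, 20),   # primary-admission reduction
            (10, 35, 1, 17, 23),       # secondary-admission excess at the interim
            (7, 21, 7, 21, 0),
        ],
    )
    def test_whole_point_report_values(self, events1, n1, events2, n2, expected_pp):
        rd = risk_difference(TwoByTwo.from_rates(events1, n1, events2, n2))
        assert rd.percentage_points == expected_pp

    def test_ci_contains_point_estimate(self, rng):
        for table in random_tables(rng, 25, positive_margins=True):
            rd = risk_difference(table)
            assert rd.ci_low <= rd.difference <= rd.ci_high

    def test_ci_width_shrinks_with_n_at_fixed_proportions(self):
        narrow = risk_difference(TwoByTwo.from_rates(30, 100, 20, 100))
        wide = risk_difference(TwoByTwo.from_rates(3, 10, 2, 10))
        assert (narrow.ci_high - narrow.ci_low) < (wide.ci_high - wide.ci_low)

    def test_zero_row_total_is_an_error(self):
        with pytest.raises(ValueError):
            risk_difference(TwoByTwo(0, 0, 3, 4))

    def test_half_up_rounding_convention(self):
        assert round_half_up(22.5) == 23
        assert round_half_up(22.49) == 22
        assert round_half_up(91.5) == 92


# ------------------------------------------- non-inferiority sample size


class TestNoninferioritySampleSize:
    def test_huge_margin_needs_tiny_n(self):
        assert noninferiority_sample_size(0.5, 0.5) < 30

    def test_monotone_in_margin_and_power(self):
        margins = [0.01, 0.025, 0.05, 0.1]
        sizes = [noninferiority_sample_size(0.05, m) for m in margins]
        assert sizes == sorted(sizes, reverse=True)
        powers = [0.5, 0.8, 0.9, 0.95]
        sizes = [noninferiority_sample_size(0.05, 0.025, power=p) for p in powers]
        assert sizes == sorted(sizes)

    def test_power_verified_by_exact_binomial_simulation(self):
        # trial design inputs: 5% control rate, 2.5% margin, alpha 0.025, 90% power
        p, margin, alpha, target = 0.05, 0.025, 0.025, 0.90
        n = noninferiority_sample_size(p, margin, alpha, target)
        rng = np.random.default_rng(7)
        reps = 10_000
        pc = rng.binomial(n, p, reps) / n
        pi = rng.binomial(n, p, reps) / n
        se = np.sqrt(pc * (1 - pc) / n + pi * (1 - pi) / n)
        z = (pi - pc - margin) / se
        power = float((z < -stats.norm.ppf(1 - alpha)).mean())
        # binomial Monte-Carlo error at 1e4 reps is ~0.003; allow 0.02 for the
        # normal approximation in the design formula
        assert power == pytest.approx(target, abs=0.02)

    @pytest.mark.parametrize("kwargs", [
        {"p_control": 0.0, "margin": 0.1},
        {"p_control": 0.05, "margin": 0.0},
        {"p_control": 0.05, "margin": 0.1, "power": 1.0},
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            noninferiority_sample_size(**kwargs)


# ------------------------------------------------- per-class outcome table


class TestRiskClassOutcomeTable:
    def test_empty_cohort_gives_empty_table(self):
        import pandas as pd

        assert risk_class_outcome_table(pd.DataFrame()).empty

    def test_single_low_risk_survivor(self):
        import pandas as pd

        cohort = pd.DataFrame(
            [{"risk_class": "low", "death30": False, "death90": False, "icu": False,
              "los_days": 3}]
        )
        table = risk_class_outcome_table(cohort)
        low = table[table["risk_class"] == "low"].iloc[0]
        assert low["n"] == 1
        assert low["death30_rate"] == 0.0
        assert low["death90_rate"] == 0.0
        assert low["icu_rate"] == 0.0
        assert low["los_median"] == 3.0

    def test_synthetic_cohort_class_sizes(self):
        # multinomial check: 370 patients against prevalences 232/93/45 of 370
        cohort = generate_cohort(CohortModel(), 370, seed=99)
        table = risk_class_outcome_table(cohort).set_index("risk_class")
        for cls, expected in (("low", 232), ("intermediate", 93), ("high", 45)):
            p = expected / 370
            bound = 2.576 * math.sqrt(370 * p * (1 - p))  # 99% binomial band
            assert abs(table.loc[cls, "n"] - expected) <= bound
        assert table.loc["total", "n"] == 370
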