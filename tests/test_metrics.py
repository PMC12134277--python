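"""Confusion metrics, AUC equivalences, Wilcoxon exactness, pooling."""

import itertools
import math

import numpy as np
import pytest

from eisrisk._exceptions import InvalidArgumentError
from eisrisk.metrics import (
    BinaryConfusion,
    accuracy,
    multiclass_auc,
    pool_trials,
    roc_auc,
    sensitivity,
    specificity,
    wilcoxon_signed_rank,
)
from eisrisk.network import ScoreSet
from eisrisk.thresholds import DecisionSet, ThresholdPolicy


def pairwise_auc_oracle(pos, neg):
    """Tie-corrected pairwise probability, computed by brute force."""
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def exact_wilcoxon_oracle(diffs):
    """Two-sided exact p by enumerating every sign assignment of the ranks."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.argsort(np.argsort(np.abs(d))) + 1.0
    w_obs = ranks[d > 0].sum()
    dist = []
    for signs in itertools.product([0, 1], repeat=n):
        dist.append(sum(r for s, r in zip(signs, ranks) if s))
    dist = np.array(dist)
    p_le = np.mean(dist <= w_obs)
    p_ge = np.mean(dist >= w_obs)
    return min(1.0, 2 * min(p_le, p_ge))


class TestConfusionRates:
    def test_accuracy_formula(self):
        cm = BinaryConfusion(tp=7, tn=85, fp=5, fn=3)
        assert accuracy(cm) == pytest.approx(0.92)

    def test_boundary_values(self):
        assert accuracy(BinaryConfusion(5, 5, 0, 0)) == 1.0
        assert accuracy(BinaryConfusion(0, 0, 5, 5)) == 0.0

    def test_sensitivity_and_specificity(self):
        cm = BinaryConfusion(tp=9, tn=95, fp=5, fn=1)
        assert sensitivity(cm) == pytest.approx(0.9)
        assert specificity(cm) == pytest.approx(0.95)

    def test_undefined_rates_surface_as_nan_sentinel(self):
        cm = BinaryConfusion(tp=0, tn=10, fp=2, fn=0)  # no positive cases
        assert math.isnan(sensitivity(cm))
        cm = BinaryConfusion(tp=3, tn=0, fp=0, fn=1)  # no negative cases
        assert math.isnan(specificity(cm))
        with pytest.raises(InvalidArgumentError):
            accuracy(BinaryConfusion(0, 0, 0, 0))

    def test_from_labels(self):
        y = np.array(["p", "p", "n", "n", "n"])
        pred = np.array(["p", "n", "n", "p", "n"])
        cm = BinaryConfusion.from_labels(y, pred, positive="p")
        assert (cm.tp, cm.fn, cm.fp, cm.tn) == (1, 1, 1, 2)


class TestRocAuc:
    @pytest.mark.parametrize(
        "pos,neg,expected",
        [
            ([0.9, 0.8], [0.1, 0.2], 1.0),
            ([0.5], [0.5], 0.5),
            ([0.6, 0.2], [0.4, 0.3], 0.5),  # 2 of 4 pairwise wins
        ],
    )
    def test_known_values(self, pos, neg, expected):
        assert roc_auc(pos, neg) == pytest.approx(expected)

    def test_matches_pairwise_oracle_with_ties(self, rng):
        for _ in range(50):
            pos = rng.choice(np.linspace(0, 1, 7), size=rng.integers(2, 30))
            neg = rng.choice(np.linspace(0, 1, 7), size=rng.integers(2, 30))
            assert roc_auc(pos, neg) == pytest.approx(
                pairwise_auc_oracle(pos, neg), abs=1e-9
            )

    def test_empty_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            roc_auc([], [0.5])


def make_score_set(probs, y, classes):
    return ScoreSet(probs=np.asarray(probs, float), y_true=np.asarray(y), classes=classes)


class TestMulticlassAuc:
    def test_mean_of_one_vs_rest(self, rng):
        n = 60
        probs = rng.dirichlet(np.ones(3), size=n)
        y = rng.choice(["a", "b", "c"], size=n)
        ss = make_score_set(probs, y, ("a", "b", "c"))
        expected = np.mean(
            [
                pairwise_auc_oracle(probs[y == c, i], probs[y != c, i])
                for i, c in enumerate(("a", "b", "c"))
            ]
        )
        assert multiclass_auc(ss) == pytest.approx(expected, abs=1e-9)

    def test_reduces_to_binary_auc_for_two_classes(self, rng):
        n = 40
        p1 = rng.uniform(size=n)
        probs = np.c_[p1, 1 - p1]
        y = rng.choice(["a", "b"], size=n)
        ss = make_score_set(probs, y, ("a", "b"))
        binary = roc_auc(p1[y == "a"], p1[y != "a"])
        assert multiclass_auc(ss) == pytest.approx(binary, abs=1e-9)

    def test_perfect_scores_give_unit_auc(self):
        probs = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        ss = make_score_set(probs, ["a", "b", "c"], ("a", "b", "c"))
        assert multiclass_auc(ss) == 1.0

    def test_random_scores_sit_at_chance(self):
        rng = np.random.default_rng(12)
        n = 300
        probs = rng.dirichlet(np.ones(3), size=n)
        y = rng.choice(["a", "b", "c"], size=n)
        ss = make_score_set(probs, y, ("a", "b", "c"))
        assert multiclass_auc(ss) == pytest.approx(0.5, abs=0.05)

    def test_missing_class_rejected_unless_allowed(self, rng):
        probs = rng.dirichlet(np.ones(3), size=10)
        ss = make_score_set(probs, ["a"] * 5 + ["b"] * 5, ("a", "b", "c"))
        with pytest.raises(InvalidArgumentError):
            multiclass_auc(ss)
        assert 0 <= multiclass_auc(ss, allow_missing=True) <= 1


class TestWilcoxon:
    def test_three_positive_differences(self):
        res = wilcoxon_signed_rank([2, 3, 4], [1, 1, 1])
        assert res.p_value == pytest.approx(0.25)
        assert not res.significant

    def test_symmetric_two_differences(self):
        res = wilcoxon_signed_rank([1, 0], [0, 1])
        assert res.p_value == pytest.approx(1.0)

    def test_all_zero_differences_flagged_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate
        assert res.p_value == 1.0

    @pytest.mark.parametrize("n", range(3, 11))
    def test_exact_p_matches_sign_enumeration(self, n, rng):
        for _ in range(5):
            d = rng.normal(size=n)
            while len(np.unique(np.abs(d))) < n or np.any(d == 0):
                d = rng.normal(size=n)
            res = wilcoxon_signed_rank(d, np.zeros(n))
            assert res.p_value == pytest.approx(exact_wilcoxon_oracle(d), abs=1e-12)

    def test_large_sample_uses_normal_approximation(self, rng):
        a = rng.normal(0.5, 1, size=40)
        b = rng.normal(0.0, 1, size=40)
        res = wilcoxon_signed_rank(a, b)
        assert 0 <= res.p_value <= 1


def make_decision_set(y, pred, classes, grades=None):
    return DecisionSet(
        classes=classes,
        y_true=np.asarray(y),
        y_pred=np.asarray(pred),
        policy=ThresholdPolicy(kind="argmax"),
        who_grades=None if grades is None else np.asarray(grades),
    )


class TestPooling:
    def test_all_correct_gives_identity_rows(self):
        ds = make_decision_set(["a", "b", "a"], ["a", "b", "a"], ("a", "b"))
        pooled = pool_trials([ds])
        assert np.allclose(pooled.rows(), np.eye(2))

    def test_rows_sum_to_one(self, rng):
        classes = ("a", "b", "c")
        sets = []
        for _ in range(4):
            y = rng.choice(classes, size=30)
            pred = rng.choice(classes, size=30)
            sets.append(make_decision_set(y, pred, classes))
        rows = pool_trials(sets).rows()
        assert np.allclose(rows.sum(axis=1), 1.0, atol=1e-9)

    def test_pooling_is_order_invariant(self, rng):
        classes = ("a", "b")
        sets = [
            make_decision_set(
                rng.choice(classes, size=20), rng.choice(classes, size=20), classes
            )
            for _ in range(5)
        ]
        a = pool_trials(sets).counts
        b = pool_trials(sets[::-1]).counts
        assert np.array_equal(a, b)

    def test_per_grade_sensitivity_within_highrisk(self):
        classes = ("high_risk", "low_risk")
        ds = make_decision_set(
            ["high_risk", "high_risk", "high_risk", "low_risk"],
            ["high_risk", "low_risk", "high_risk", "low_risk"],
            classes,
            grades=["cancer", "cancer", "severe", "healthy"],
        )
        pooled = pool_trials([ds])
        assert pooled.grade_sensitivity["cancer"] == pytest.approx(0.5)
        assert pooled.grade_sensitivity["severe"] == pytest.approx(1.0)
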