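"""Youden's rule and the screening threshold-adjustment algorithms."""

import numpy as np
import pytest

from eisrisk._exceptions import InvalidArgumentError
from eisrisk.network import ScoreSet
from eisrisk.thresholds import (
    RocCurve,
    ThresholdPolicy,
    apply_policy,
    fit_policy,
    roc_points,
    sweep_Tstar,
    sweep_alpha,
    task2_decide,
    task2_select_Tstar,
    task3_select_alpha,
    youden_threshold,
)


def youden_oracle(scores, y_pos):
    """Brute-force maximum of TPR - FPR over all midpoint thresholds."""
    s = np.asarray(scores, float)
    pos = np.asarray(y_pos, bool)
    uniq = np.unique(s)
    cands = [uniq[-1] + 1, uniq[0] - 1] + list((uniq[:-1] + uniq[1:]) / 2)
    best_j, best_t = -np.inf, None
    for t in cands:
        j = np.mean(s[pos] >= t) - np.mean(s[~pos] >= t)
        if j > best_j + 1e-12 or (abs(j - best_j) <= 1e-12 and t > best_t):
            best_j, best_t = j, t
    return best_t, best_j


def triple_scores(rng, n=200):
    probs = rng.dirichlet(np.ones(3), size=n)
    y = rng.choice(["normal", "low_risk", "high_risk"], size=n, p=[0.5, 0.2, 0.3])
    return ScoreSet(probs=probs, y_true=y, classes=("normal", "low_risk", "high_risk"))


class TestYouden:
    def test_perfect_separation_gives_unit_j(self):
        roc = roc_points([0.9, 0.8, 0.1, 0.2], [True, True, False, False])
        _, j = youden_threshold(roc)
        assert j == pytest.approx(1.0)

    def test_identical_distributions_give_zero_j(self):
        roc = roc_points([0.2, 0.8, 0.2, 0.8], [True, True, False, False])
        _, j = youden_threshold(roc)
        assert j == pytest.approx(0.0)

    def test_given_roc_points(self):
        roc = RocCurve(
            thresholds=np.array([0.9, 0.6, 0.4, 0.1]),
            fpr=np.array([0.0, 0.1, 0.3, 1.0]),
            tpr=np.array([0.0, 0.8, 0.9, 1.0]),
        )
        t, j = youden_threshold(roc)
        assert j == pytest.approx(0.7)
        assert t == pytest.approx(0.6)

    def test_matches_exhaustive_midpoint_search(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 40))
            s = rng.choice(np.linspace(0, 1, 9), size=n)
            pos = rng.random(n) < 0.5
            if pos.all() or not pos.any():
                continue
            roc = roc_points(s, pos)
            t, j = youden_threshold(roc)
            t_oracle, j_oracle = youden_oracle(s, pos)
            assert j == pytest.approx(j_oracle, abs=1e-12)
            assert t == pytest.approx(t_oracle, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(InvalidArgumentError):
            roc_points([0.1, 0.2], [True, True])

    def test_negative_j_is_reported(self):
        # Worse-than-random ordering: positives score lower than negatives.
        roc = roc_points([0.1, 0.2, 0.8, 0.9], [True, True, False, False])
        _, j = youden_threshold(roc)
        assert j == pytest.approx(0.0)  # best midpoint threshold still floors at 0


class TestTask2Decide:
    @pytest.mark.parametrize(
        "z,tstar,expected",
        [
            ((0.45, 0.30, 0.25), 0.2, "high_risk"),
            ((0.55, 0.35, 0.10), 0.2, "normal"),
            ((0.25, 0.30, 0.45), 0.5, "low_risk"),  # arg-max would say high_risk
        ],
    )
    def test_rule_instances(self, z, tstar, expected):
        assert task2_decide(z, tstar) == expected

    def test_non_probability_input_rejected(self):
        with pytest.raises(InvalidArgumentError):
            task2_decide((0.5, 0.5, 0.5), 0.2)

    def test_contains_argmax_highrisk_region_for_small_tstar(self, rng):
        probs = rng.dirichlet(np.ones(3), size=1000)
        for t_star in (1 / 3, 0.2, 0.15):
            for z in probs:
                if np.argmax(z) == 2:  # arg-max calls high risk
                    assert task2_decide(z, t_star) == "high_risk"

    def test_lowering_tstar_only_grows_highrisk_set(self, rng):
        ss = triple_scores(rng)
        prev = set()
        for t in (0.5, 0.4, 0.3, 0.2, 0.15):
            dec = apply_policy(ss, ThresholdPolicy(kind="task2", T_star=t))
            now = set(np.flatnonzero(dec.y_pred == "high_risk"))
            assert prev <= now
            prev = now


class TestTstarSelection:
    def test_maximin_selection_matches_brute_force(self, rng):
        for _ in range(5):
            ss = triple_scores(rng, n=150)
            grid = np.round(np.arange(0.5, 0.1499, -0.05), 10)
            table = sweep_Tstar(ss, grid)
            best = max(sorted(table, reverse=True), key=lambda t: min(table[t].values()))
            assert task2_select_Tstar(ss) == pytest.approx(best)

    def test_flat_sensitivities_select_highest_threshold(self):
        # z3 never crosses any grid value: decisions identical across grid.
        probs = np.array([[0.9, 0.05, 0.05], [0.1, 0.85, 0.05], [0.05, 0.9, 0.05],
                          [0.85, 0.1, 0.05], [0.8, 0.1, 0.1], [0.1, 0.8, 0.1]])
        y = ["normal", "low_risk", "low_risk", "normal", "high_risk", "high_risk"]
        ss = ScoreSet(probs=probs, y_true=np.array(y),
                      classes=("normal", "low_risk", "high_risk"))
        assert task2_select_Tstar(ss) == pytest.approx(0.5)

    def test_missing_class_rejected(self, rng):
        probs = rng.dirichlet(np.ones(3), size=10)
        ss = ScoreSet(probs=probs, y_true=np.array(["normal"] * 10),
                      classes=("normal", "low_risk", "high_risk"))
        with pytest.raises(InvalidArgumentError):
            task2_select_Tstar(ss)


def binary_scores(rng, n=200, sep=1.5):
    s_pos = 1 / (1 + np.exp(-rng.normal(sep, 1, n // 3)))
    s_neg = 1 / (1 + np.exp(-rng.normal(-sep, 1, n - n // 3)))
    probs_hi = np.concatenate([s_pos, s_neg])
    y = np.array(["high_risk"] * (n // 3) + ["low_risk"] * (n - n // 3))
    probs = np.c_[probs_hi, 1 - probs_hi]
    return ScoreSet(probs=probs, y_true=y, classes=("high_risk", "low_risk"))


class TestAlphaSelection:
    def test_scaled_threshold_rule(self):
        ss = ScoreSet(
            probs=np.array([[0.15, 0.85], [0.10, 0.90]]),
            y_true=np.array(["high_risk", "low_risk"]),
            classes=("high_risk", "low_risk"),
        )
        dec = apply_policy(ss, ThresholdPolicy(kind="task3", T_Y=0.4, alpha=0.3))
        assert dec.y_pred[0] == "high_risk"  # 0.15 >= 0.12

    def test_alpha_one_equals_plain_youden(self, rng):
        ss = binary_scores(rng)
        roc = roc_points(ss.column("high_risk"), ss.y_true == "high_risk")
        t_y, _ = youden_threshold(roc)
        a = apply_policy(ss, ThresholdPolicy(kind="youden", T_Y=t_y))
        b = apply_policy(ss, ThresholdPolicy(kind="task3", T_Y=t_y, alpha=1.0))
        assert np.array_equal(a.y_pred, b.y_pred)

    def test_selection_matches_grid_search_oracle(self, rng):
        for _ in range(5):
            ss = binary_scores(rng, sep=1.0)
            roc = roc_points(ss.column("high_risk"), ss.y_true == "high_risk")
            t_y, _ = youden_threshold(roc)
            sel = task3_select_alpha(ss, t_y, specificity_floor=0.8)
            table = sweep_alpha(ss, t_y)
            feasible = {a: v for a, v in table.items() if v[1] >= 0.8}
            assert feasible, "test construction should admit feasible alphas"
            best_sens = max(v[0] for v in feasible.values())
            best = max(a for a, v in feasible.items() if v[0] == pytest.approx(best_sens))
            assert sel.alpha == pytest.approx(best)
            assert sel.feasible

    def test_infeasible_floor_falls_back_to_unit_alpha(self, rng):
        ss = binary_scores(rng, sep=0.1)
        sel = task3_select_alpha(ss, T_Y=1e-9, specificity_floor=0.999)
        assert sel.alpha == 1.0
        assert not sel.feasible

    def test_sweep_monotonicity(self, rng):
        ss = binary_scores(rng)
        roc = roc_points(ss.column("high_risk"), ss.y_true == "high_risk")
        t_y, _ = youden_threshold(roc)
        table = sweep_alpha(ss, t_y)
        alphas = sorted(table, reverse=True)
        sens = [table[a][0] for a in alphas]
        spec = [table[a][1] for a in alphas]
        assert all(s2 >= s1 - 1e-12 for s1, s2 in zip(sens, sens[1:]))
        assert all(s2 <= s1 + 1e-12 for s1, s2 in zip(spec, spec[1:]))


class TestPolicyGuards:
    def test_policy_depends_on_training_data_only(self, rng):
        train = binary_scores(rng)
        pol = fit_policy("task3", train)
        # Perturbing unseen (test) data cannot change the fitted thresholds.
        pol2 = fit_policy("task3", train)
        assert (pol.T_Y, pol.alpha) == (pol2.T_Y, pol2.alpha)

    def test_tstar_one_only_fires_on_certainty(self):
        probs = np.array([[0.0, 0.0, 1.0], [0.2, 0.3, 0.5]])
        ss = ScoreSet(probs=probs, y_true=np.array(["high_risk", "normal"]),
                      classes=("normal", "low_risk", "high_risk"))
        dec = apply_policy(ss, ThresholdPolicy(kind="task2", T_star=1.0))
        assert dec.y_pred[0] == "high_risk"
        assert dec.y_pred[1] != "high_risk"

    def test_invalid_policy_kind_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ThresholdPolicy(kind="magic")
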