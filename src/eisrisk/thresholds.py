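"""Decision thresholds tuned for screening sensitivity.

Classifier scores only become diagnoses once a threshold is chosen.  The
default operating point for a binary problem is Youden's rule: maximise
J = sensitivity + specificity - 1 over the training ROC.  Cancer screening,
however, prizes sensitivity, so two adjustment algorithms sit on top:

* Three-class rule (normal / low-risk / high-risk): call **high-risk**
  whenever the high-risk probability z3 >= T*; otherwise fall back to
  comparing z1 (normal) against z2 (low-risk).  T* is chosen on training
  scores by sweeping 0.5 down to 0.15 for the most balanced per-class
  sensitivities.  For any T* <= 1/3 the rule's high-risk region contains
  the arg-max rule's, so high-risk sensitivity can only improve.

* Binary composite rule: call high-risk whenever the score >= alpha * T_Y,
  sweeping alpha from 1 down to 0.1 and keeping the most sensitive setting
  whose training specificity stays above a floor.

All thresholds are functions of training data alone and are then applied
unchanged to test data.  Score ties resolve as ">= threshold -> positive"
throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._exceptions import InvalidArgumentError
from .network import ScoreSet

__all__ = [
    "RocCurve",
    "roc_points",
    "youden_threshold",
    "task2_decide",
    "task2_select_Tstar",
    "task3_select_alpha",
    "ThresholdPolicy",
    "DecisionSet",
    "apply_policy",
    "fit_policy",
    "sweep_Tstar",
    "sweep_alpha",
]

POSITIVE_CLASS = "high_risk"


@dataclass(frozen=True)
class RocCurve:
    """Candidate thresholds with their (FPR, TPR) operating points.

    Thresholds are the midpoints between consecutive sorted unique scores,
    plus one above the maximum (operating point (0,0)) and one below the
    minimum ((1,1)); a case is called positive when score >= threshold.
    Thresholds are stored in decreasing order, so FPR and TPR are
    non-decreasing along the arrays.
    """

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    positive: str = POSITIVE_CLASS


def roc_points(scores, y_is_positive) -> RocCurve:
    """Build the ROC operating points of a score vector."""
    s = np.asarray(scores, dtype=float)
    pos = np.asarray(y_is_positive, dtype=bool)
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("ROC needs both classes present")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0 if uniq.size > 1 else np.empty(0)
    cands = np.concatenate([[uniq[-1] + 1.0], mids[::-1], [uniq[0] - 1.0]])
    preds = s[None, :] >= cands[:, None]  # (T, n)
    tpr = (preds & pos[None, :]).sum(axis=1) / n_pos
    fpr = (preds & ~pos[None, :]).sum(axis=1) / n_neg
    return RocCurve(thresholds=cands, fpr=fpr, tpr=tpr)


def youden_threshold(roc: RocCurve) -> tuple[float, float]:
    """Return (T_Y, J): the threshold maximising J = TPR - FPR and that J.

    Ties break toward the higher (more specific) threshold.  J may be
    negative for a worse-than-random score ordering and is reported as-is.
    """
    j = roc.tpr - roc.fpr
    # Thresholds descend; among J-ties (to float tolerance) take the first,
    # i.e. highest, threshold.
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
    return float(roc.thresholds[best]), float(j[best])


def _triple(scores) -> tuple[float, float, float]:
    z = np.asarray(scores, dtype=float)
    if z.shape != (3,) or np.any(z < -1e-9) or abs(z.sum() - 1.0) > 1e-6:
        raise InvalidArgumentError("scores must be a probability triple")
    return float(z[0]), float(z[1]), float(z[2])


def task2_decide(scores, T_star: float) -> str:
    """Three-class screening decision on a (z_normal, z_low, z_high) triple.

    high_risk iff z3 >= T*; else normal iff z1 >= z2, else low_risk.
    """
    z1, z2, z3 = _triple(scores)
    if not (0 < T_star <= 1):
        raise InvalidArgumentError("T_star must lie in (0, 1]")
    if z3 >= T_star:
        return "high_risk"
    return "normal" if z1 >= z2 else "low_risk"


def _task2_decide_batch(z1, z2, z3, T_star) -> np.ndarray:
    out = np.where(z3 >= T_star, "high_risk", np.where(z1 >= z2, "normal", "low_risk"))
    return out


def _require_classes(score_set: ScoreSet, needed) -> None:
    present = set(score_set.y_true.tolist())
    missing = [c for c in needed if c not in present]
    if missing:
        raise InvalidArgumentError(f"classes missing from scores: {missing}")


def _task2_columns(score_set: ScoreSet) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    for c in ("normal", "low_risk", "high_risk"):
        if c not in score_set.classes:
            raise InvalidArgumentError(f"three-class rule needs class {c!r}")
    return (
        score_set.column("normal"),
        score_set.column("low_risk"),
        score_set.column("high_risk"),
    )


def sweep_Tstar(score_set: ScoreSet, grid=None) -> dict[float, dict[str, float]]:
    """Per-class sensitivity at each candidate T* (the sweep-curve table)."""
    grid = _default_tstar_grid() if grid is None else np.asarray(grid, float)
    z1, z2, z3 = _task2_columns(score_set)
    y = score_set.y_true
    table: dict[float, dict[str, float]] = {}
    for t in grid:
        pred = _task2_decide_batch(z1, z2, z3, t)
        table[float(t)] = {
            c: float(np.mean(pred[y == c] == c)) if (y == c).any() else np.nan
            for c in ("normal", "low_risk", "high_risk")
        }
    return table


def _default_tstar_grid() -> np.ndarray:
    return np.round(np.arange(0.5, 0.1499, -0.05), 10)


def task2_select_Tstar(score_set: ScoreSet, grid=None) -> float:
    """Choose T* on training scores: maximin per-class sensitivity.

    Sweeps T* from 0.5 down to 0.15 (step 0.05 by default) and returns the
    value maximising the minimum per-class sensitivity — the operational
    reading of "balanced performance over classes".  Ties break toward the
    higher T*.
    """
    _require_classes(score_set, ("normal", "low_risk", "high_risk"))
    table = sweep_Tstar(score_set, grid=grid)
    best_t, best_min = None, -np.inf
    for t in sorted(table, reverse=True):  # descending: first max wins ties
        lo = min(table[t].values())
        if lo > best_min + 1e-12:
            best_t, best_min = t, lo
    return float(best_t)


@dataclass(frozen=True)
class AlphaSelection:
    alpha: float
    feasible: bool


def sweep_alpha(
    score_set: ScoreSet, T_Y: float, alpha_grid=None
) -> dict[float, tuple[float, float]]:
    """(sensitivity, specificity) at each candidate alpha for rule score >= alpha*T_Y."""
    grid = (
        np.round(np.arange(1.0, 0.0999, -0.1), 10)
        if alpha_grid is None
        else np.asarray(alpha_grid, float)
    )
    s = score_set.column(POSITIVE_CLASS)
    pos = score_set.y_true == POSITIVE_CLASS
    if not pos.any() or pos.all():
        raise InvalidArgumentError("binary scores need both classes present")
    table = {}
    for a in grid:
        pred = s >= a * T_Y
        table[float(a)] = (
            float(np.mean(pred[pos])),
            float(np.mean(~pred[~pos])),
        )
    return table


def task3_select_alpha(
    score_set: ScoreSet,
    T_Y: float,
    alpha_grid=None,
    specificity_floor: float = 0.9,
) -> AlphaSelection:
    """Choose the Youden-scaling ratio alpha on training scores.

    Maximises training sensitivity subject to training specificity >=
    ``specificity_floor``; ties break toward the larger alpha (closer to
    the unscaled Youden point).  If no grid value meets the floor the
    selection falls back to alpha = 1.0 flagged infeasible.
    """
    table = sweep_alpha(score_set, T_Y, alpha_grid=alpha_grid)
    best_a, best_sens = None, -np.inf
    for a in sorted(table, reverse=True):
        sens, spec = table[a]
        if spec >= specificity_floor and sens > best_sens + 1e-12:
            best_a, best_sens = a, sens
    if best_a is None:
        return AlphaSelection(alpha=1.0, feasible=False)
    return AlphaSelection(alpha=float(best_a), feasible=True)


@dataclass(frozen=True)
class ThresholdPolicy:
    """A fully determined decision rule (thresholds fixed on training data)."""

    kind: str  # one of: argmax, youden, task2, task3
    T_star: float | None = None
    T_Y: float | None = None
    alpha: float | None = None
    feasible: bool = True

    def __post_init__(self) -> None:
        if self.kind not in ("argmax", "youden", "task2", "task3"):
            raise InvalidArgumentError(f"unknown policy kind {self.kind!r}")
        if self.kind == "task2" and self.T_star is None:
            raise InvalidArgumentError("task2 policy needs T_star")
        if self.kind == "youden" and self.T_Y is None:
            raise InvalidArgumentError("youden policy needs T_Y")
        if self.kind == "task3" and (self.T_Y is None or self.alpha is None):
            raise InvalidArgumentError("task3 policy needs T_Y and alpha")


@dataclass
class DecisionSet:
    """Per-reading decisions under one policy, with achieved rates."""

    classes: tuple[str, ...]
    y_true: np.ndarray
    y_pred: np.ndarray
    policy: ThresholdPolicy
    who_grades: np.ndarray | None = None
    sensitivity_by_class: dict[str, float] = field(default_factory=dict)

    def y_index(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[c] for c in self.y_true])

    def pred_index(self) -> np.ndarray:
        lookup = {c: i for i, c in enumerate(self.classes)}
        return np.array([lookup[c] for c in self.y_pred])


def apply_policy(score_set: ScoreSet, policy: ThresholdPolicy) -> DecisionSet:
    """Turn scores into class decisions under a fixed policy."""
    classes = score_set.classes
    if policy.kind == "argmax":
        pred = np.array([classes[i] for i in np.argmax(score_set.probs, axis=1)])
    elif policy.kind in ("youden", "task3"):
        if POSITIVE_CLASS not in classes or len(classes) != 2:
            raise InvalidArgumentError("binary policies need two classes incl. high_risk")
        thr = policy.T_Y if policy.kind == "youden" else policy.alpha * policy.T_Y
        neg = [c for c in classes if c != POSITIVE_CLASS][0]
        pred = np.where(score_set.column(POSITIVE_CLASS) >= thr, POSITIVE_CLASS, neg)
    elif policy.kind == "task2":
        z1, z2, z3 = _task2_columns(score_set)
        pred = _task2_decide_batch(z1, z2, z3, policy.T_star)
    else:  # pragma: no cover - guarded by ThresholdPolicy
        raise InvalidArgumentError(policy.kind)
    y = score_set.y_true
    sens = {
        c: (float(np.mean(pred[y == c] == c)) if (y == c).any() else np.nan)
        for c in classes
    }
    return DecisionSet(
        classes=classes,
        y_true=y,
        y_pred=np.asarray(pred),
        policy=policy,
        who_grades=score_set.who_grades,
        sensitivity_by_class=sens,
    )


def fit_policy(
    kind: str,
    train_scores: ScoreSet,
    fixed_Tstar: float | None = None,
    fixed_alpha: float | None = None,
    specificity_floor: float = 0.9,
) -> ThresholdPolicy:
    """Determine a policy's thresholds from training scores only."""
    if kind == "argmax":
        return ThresholdPolicy(kind="argmax")
    if kind == "youden":
        roc = roc_points(
            train_scores.column(POSITIVE_CLASS),
            train_scores.y_true == POSITIVE_CLASS,
        )
        t_y, _ = youden_threshold(roc)
        return ThresholdPolicy(kind="youden", T_Y=t_y)
    if kind == "task2":
        t_star = (
            fixed_Tstar if fixed_Tstar is not None else task2_select_Tstar(train_scores)
        )
        return ThresholdPolicy(kind="task2", T_star=t_star)
    if kind == "task3":
        roc = roc_points(
            train_scores.column(POSITIVE_CLASS),
            train_scores.y_true == POSITIVE_CLASS,
        )
        t_y, _ = youden_threshold(roc)
        if fixed_alpha is not None:
            return ThresholdPolicy(kind="task3", T_Y=t_y, alpha=fixed_alpha)
        sel = task3_select_alpha(train_scores, t_y, specificity_floor=specificity_floor)
        return ThresholdPolicy(
            kind="task3", T_Y=t_y, alpha=sel.alpha, feasible=sel.feasible
        )
    raise InvalidArgumentError(f"unknown policy kind {kind!r}")
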