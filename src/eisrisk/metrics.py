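"""Evaluation metrics: confusion-matrix rates, ROC/AUC, one-vs-rest
multi-class AUC, paired Wilcoxon comparison, and pooled-trial reporting.

Undefined rates (zero denominator) surface as ``math.nan`` — the explicit
"undefined" sentinel — rather than silently as 0, so pooled tables can
distinguish "no cases" from "all missed".
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score

from ._exceptions import InvalidArgumentError

__all__ = [
    "UNDEFINED",
    "BinaryConfusion",
    "accuracy",
    "sensitivity",
    "specificity",
    "roc_auc",
    "multiclass_auc",
    "wilcoxon_signed_rank",
    "WilcoxonResult",
    "pool_trials",
    "PooledDistribution",
]

#: Sentinel for metrics whose denominator is empty.
UNDEFINED = math.nan


@dataclass(frozen=True)
class BinaryConfusion:
    """Binary confusion counts with a designated positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidArgumentError("confusion counts must be non-negative")

    @classmethod
    def from_labels(cls, y_true, y_pred, positive) -> "BinaryConfusion":
        yt = np.asarray(y_true) == positive
        yp = np.asarray(y_pred) == positive
        return cls(
            tp=int(np.sum(yt & yp)),
            tn=int(np.sum(~yt & ~yp)),
            fp=int(np.sum(~yt & yp)),
            fn=int(np.sum(yt & ~yp)),
        )

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def accuracy(cm: BinaryConfusion) -> float:
    """(TP + TN) / (TP + FP + FN + TN)."""
    if cm.total == 0:
        raise InvalidArgumentError("empty confusion matrix")
    return (cm.tp + cm.tn) / cm.total


def sensitivity(cm: BinaryConfusion) -> float:
    """TP / (TP + FN); nan when there are no positive cases."""
    denom = cm.tp + cm.fn
    return cm.tp / denom if denom else UNDEFINED


def specificity(cm: BinaryConfusion) -> float:
    """TN / (FP + TN); nan when there are no negative cases."""
    denom = cm.tn + cm.fp
    return cm.tn / denom if denom else UNDEFINED


def roc_auc(pos_scores, neg_scores) -> float:
    """Area under the ROC curve from positive- and negative-class scores.

    Equals the tie-corrected pairwise probability
    P(score_pos > score_neg) + 0.5 * P(score_pos == score_neg).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise InvalidArgumentError("both score lists must be non-empty")
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(y, np.concatenate([pos, neg])))


def multiclass_auc(score_set, allow_missing: bool = False) -> float:
    """One-vs-rest multi-class AUC: the unweighted mean over classes of the
    AUC of that class's probability column against all other classes pooled.

    With two classes this reduces to the plain binary AUC.  A class absent
    from the truth labels raises unless ``allow_missing`` (then the mean is
    over the classes present — needed when a rare class cannot occupy every
    validation fold).
    """
    y = score_set.y_true
    aucs = []
    for i, cls in enumerate(score_set.classes):
        mask = y == cls
        if not mask.any() or mask.all():
            if allow_missing:
                continue
            raise InvalidArgumentError(f"class {cls!r} missing from score set")
        aucs.append(roc_auc(score_set.probs[mask, i], score_set.probs[~mask, i]))
    if not aucs:
        raise InvalidArgumentError("no class with both positives and negatives")
    return float(np.mean(aucs))


@dataclass(frozen=True)
class WilcoxonResult:
    statistic: float
    p_value: float
    significant: bool
    degenerate: bool = False


def wilcoxon_signed_rank(paired_a, paired_b, alpha: float = 0.05) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (Wilcoxon's original prescription); the
    p-value is exact (full enumeration) for n <= 25 non-zero differences
    and a normal approximation with continuity correction beyond that.
    All-zero differences return p = 1.0 flagged as degenerate.
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape:
        raise InvalidArgumentError("paired samples must have equal length")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, significant=False, degenerate=True)
    if d.size < 3:
        # Too few non-zero pairs for any meaningful significance; exact
        # enumeration still applies.
        method = "exact"
    else:
        method = "exact" if d.size <= 25 else "approx"
    res = stats.wilcoxon(
        d,
        zero_method="wilcox",
        alternative="two-sided",
        correction=True,
        method=method,
    )
    return WilcoxonResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        significant=bool(res.pvalue < alpha),
    )


@dataclass
class PooledDistribution:
    """Per-true-class distribution over predicted classes, pooled over trials."""

    classes: tuple[str, ...]
    counts: np.ndarray  # (M, M) true x predicted
    grade_sensitivity: dict[str, float]  # per-WHO-grade recall within high-risk
    n_trials: int

    def rows(self) -> np.ndarray:
        """Row-normalised distribution; rows with no cases are nan."""
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, self.counts / totals, np.nan)

    def per_class_sensitivity(self) -> dict[str, float]:
        rows = self.rows()
        return {
            c: (float(rows[i, i]) if not math.isnan(rows[i, i]) else UNDEFINED)
            for i, c in enumerate(self.classes)
        }


def pool_trials(decision_sets) -> PooledDistribution:
    """Pool per-trial test decisions into class-wise distributions.

    Also reports per-WHO-grade sensitivity within the high-risk class (how
    often cancer / severe / moderate cases were called high-risk), when
    grade annotations are available.  Pooling is order-invariant.
    """
    decision_sets = list(decision_sets)
    if not decision_sets:
        raise InvalidArgumentError("need at least one trial")
    classes = decision_sets[0].classes
    M = len(classes)
    counts = np.zeros((M, M))
    grade_tot: dict[str, int] = {}
    grade_hit: dict[str, int] = {}
    for ds in decision_sets:
        if tuple(ds.classes) != tuple(classes):
            raise InvalidArgumentError("inconsistent class sets across trials")
        ti = ds.y_index()
        pi = ds.pred_index()
        for t, p in zip(ti, pi):
            counts[t, p] += 1
        if ds.who_grades is not None and "high_risk" in classes:
            hi = classes.index("high_risk")
            for g, t, p in zip(ds.who_grades, ti, pi):
                if t == hi:
                    grade_tot[g] = grade_tot.get(g, 0) + 1
                    grade_hit[g] = grade_hit.get(g, 0) + int(p == hi)
    grade_sens = {
        g: grade_hit[g] / grade_tot[g] for g in sorted(grade_tot) if grade_tot[g] > 0
    }
    return PooledDistribution(
        classes=tuple(classes),
        counts=counts,
        grade_sensitivity=grade_sens,
        n_trials=len(decision_sets),
    )
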