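"""Experiment orchestration: repeated subject-aware splits, K-fold cross
validation with SMOTE inside training folds only, model selection by mean
validation AUC, and final test evaluation under a screening threshold
policy — for the three diagnostic tasks:

* Task 1 — binary low/high-risk on the porcine cohort (Youden threshold),
* Task 2 — three-class normal/low/high-risk on the human cohort (T* rule),
* Task 3 — binary composite low vs high-risk on the human cohort
  (alpha-scaled Youden rule).

Leakage control is structural, not conventional: the test set is carved
subject-wise before anything else, synthetic (SMOTE) rows exist only inside
training folds, and the feature scaler is fitted inside each classifier on
its own training matrix.  Every trial records an audit of these guards.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from ._exceptions import (
    AugmentationInfeasibleError,
    ConfigurationError,
    InvalidArgumentError,
)
from .data import EISDataset
from .metrics import PooledDistribution, multiclass_auc, pool_trials, roc_auc
from .network import ImpedanceNetClassifier, ModelSpec, ScoreSet, build_network, parse_model_spec
from .thresholds import DecisionSet, apply_policy, fit_policy

logger = logging.getLogger(__name__)

__all__ = [
    "TrialPlan",
    "SplitAssignment",
    "TrialResult",
    "TaskReport",
    "smote_oversample",
    "augment_training_set",
    "make_trial_splits",
    "select_models",
    "run_task",
    "default_candidates",
]

_JITTER_SD = 1e-6  # fallback duplication noise for 1-sample classes


def task_class_order(task: int) -> tuple[str, ...]:
    """Category order used for 'W1:W2[:W3]' weight conditions: the normal /
    majority class first, high-risk last."""
    return ("normal", "low_risk", "high_risk") if task == 2 else ("low_risk", "high_risk")


@dataclass(frozen=True)
class TrialPlan:
    """Configuration of the repeated-trial experimental design."""

    task: int
    n_folds: int = 3
    n_trials: int = 100
    seed: int = 0
    smote_k: int = 3
    use_smote: bool | None = None  # None: on for the human tasks (2, 3)
    top_n: int = 4
    policy: str | None = None  # None: youden/task2/task3 by task
    fixed_Tstar: float | None = None
    fixed_alpha: float | None = None
    specificity_floor: float = 0.9
    fit_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.task not in (1, 2, 3):
            raise InvalidArgumentError("task must be 1, 2 or 3")
        if self.n_folds < 2:
            raise InvalidArgumentError("n_folds must be >= 2")
        if self.n_trials < 1:
            raise InvalidArgumentError("n_trials must be >= 1")
        if self.smote_k < 1:
            raise InvalidArgumentError("smote_k must be >= 1")

    @property
    def smote_enabled(self) -> bool:
        return self.task in (2, 3) if self.use_smote is None else self.use_smote

    @property
    def policy_kind(self) -> str:
        if self.policy is not None:
            return self.policy
        return {1: "youden", 2: "task2", 3: "task3"}[self.task]


@dataclass
class SplitAssignment:
    """One trial's partition: subject-wise test carve plus K reading-level folds."""

    test_idx: np.ndarray
    folds: list[np.ndarray]
    trial_index: int

    def pool_idx(self) -> np.ndarray:
        """All non-test (train + validation) reading indices."""
        return np.concatenate(self.folds) if self.folds else np.empty(0, dtype=int)


def _trial_seed(master: int, *key: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([int(master) & 0x7FFFFFFF, *key])


def _seed_int(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------


def smote_oversample(
    minority_features,
    target_count: int,
    k_neighbours: int,
    rng: np.random.Generator,
    delta: float | None = None,
) -> np.ndarray:
    """Generate SMOTE rows for one minority class.

    Each synthetic row is x_i + delta * (x_nn - x_i), with x_i a random
    minority sample, x_nn one of its k nearest same-class neighbours, and
    delta ~ Uniform(0, 1) (or fixed, for auditing).  Returns
    ``target_count - n`` rows; none if the class already meets the target.
    """
    X = np.asarray(minority_features, dtype=float)
    n = X.shape[0]
    if n < 2:
        raise AugmentationInfeasibleError(
            f"SMOTE needs at least 2 samples, class has {n}"
        )
    k = min(int(k_neighbours), n - 1)
    n_new = int(target_count) - n
    if n_new <= 0:
        return np.empty((0, X.shape[1]))
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)  # column 0 is the point itself
    base = rng.integers(0, n, size=n_new)
    pick = rng.integers(1, k + 1, size=n_new)
    partners = idx[base, pick]
    deltas = rng.uniform(0.0, 1.0, size=n_new) if delta is None else np.full(n_new, delta)
    return X[base] + deltas[:, None] * (X[partners] - X[base])


def augment_training_set(
    X: np.ndarray,
    y: np.ndarray,
    rng: np.random.Generator,
    k_neighbours: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, bool]:
    """Raise every minority class to the majority count.

    Returns (X_aug, y_aug, synthetic_flags, used_jitter_fallback).  Classes
    with a single training sample cannot be interpolated; they are
    duplicated with tiny Gaussian jitter (SD 1e-6) instead, and the fallback
    is flagged.
    """
    classes, counts = np.unique(y, return_counts=True)
    target = int(counts.max())
    xs, ys = [X], [y]
    flags = [np.zeros(len(y), dtype=bool)]
    fallback = False
    for cls, cnt in zip(classes, counts):
        if cnt >= target:
            continue
        Xc = X[y == cls]
        if cnt < 2:
            n_new = target - cnt
            synth = np.repeat(Xc, n_new, axis=0)
            synth = synth + _JITTER_SD * rng.standard_normal(synth.shape)
            fallback = True
        else:
            synth = smote_oversample(Xc, target, k_neighbours, rng)
        if len(synth):
            xs.append(synth)
            ys.append(np.full(len(synth), cls, dtype=y.dtype))
            flags.append(np.ones(len(synth), dtype=bool))
    return (
        np.concatenate(xs),
        np.concatenate(ys),
        np.concatenate(flags),
        fallback,
    )


# ---------------------------------------------------------------------------
# Splits
# ---------------------------------------------------------------------------


def _subjects_by_readings(ds: EISDataset, mask: np.ndarray) -> dict[str, int]:
    subs: dict[str, int] = {}
    sids = ds.subject_ids()
    for i in np.flatnonzero(mask):
        subs[sids[i]] = subs.get(sids[i], 0) + 1
    return subs


def _greedy_subject_pick(
    subs: dict[str, int], target: int, rng: np.random.Generator, exact_tries: int = 200
) -> set[str]:
    """Pick subjects whose reading counts total as close to ``target`` as
    possible, preferring exact hits over random orderings."""
    names = sorted(subs)
    if target <= 0 or not names:
        return set()
    best: set[str] | None = None
    best_err = np.inf
    for _ in range(exact_tries):
        order = rng.permutation(names)
        chosen: set[str] = set()
        total = 0
        for s in order:
            if total >= target:
                break
            chosen.add(s)
            total += subs[s]
        err = abs(total - target)
        if err < best_err:
            best, best_err = chosen, err
        if err == 0:
            break
    return best or set()


def _carve_test_subjects(
    ds: EISDataset, labels: np.ndarray, plan: TrialPlan, rng: np.random.Generator
) -> set[str]:
    grades = ds.who_grades()
    if plan.task in (2, 3) and (grades == "healthy").any():
        # Human-style carve: exactly 1 lesional low-risk subject, high-risk
        # subjects totalling ~6 readings, and 1/K of the healthy subjects.
        binary = ds.binary_labels()
        low = _subjects_by_readings(ds, (binary == "low_risk") & (grades != "healthy"))
        high = _subjects_by_readings(ds, binary == "high_risk")
        healthy = _subjects_by_readings(ds, grades == "healthy")
        chosen: set[str] = set()
        if low:
            chosen.add(rng.choice(sorted(low)))
        chosen |= _greedy_subject_pick(high, 6, rng)
        n_healthy = int(round(len(healthy) / plan.n_folds))
        chosen |= set(rng.permutation(sorted(healthy))[:n_healthy])
        return chosen
    # Generic stratified carve: ~1/(K+1) of each class's readings, i.e. the
    # test set is one fold-equivalent.
    chosen = set()
    for cls in np.unique(labels):
        subs = _subjects_by_readings(ds, labels == cls)
        target = int(round(sum(subs.values()) / (plan.n_folds + 1)))
        chosen |= _greedy_subject_pick(subs, target, rng)
    return chosen


def make_trial_splits(
    ds: EISDataset, plan: TrialPlan, trial_index: int
) -> SplitAssignment:
    """Build one trial's split: subject-disjoint test carve, then K
    reading-level stratified folds over the remainder.

    Resamples (up to 100 attempts) until every training pool (union of K-1
    folds) contains every class; raises :class:`ConfigurationError` if that
    cannot be achieved.
    """
    labels = ds.task_labels(plan.task)
    sids = ds.subject_ids()
    rng = np.random.default_rng(_trial_seed(plan.seed, 17, trial_index))
    for _attempt in range(100):
        test_subjects = _carve_test_subjects(ds, labels, plan, rng)
        test_mask = np.isin(sids, sorted(test_subjects))
        test_idx = np.flatnonzero(test_mask)
        rest_idx = np.flatnonzero(~test_mask)
        if len(test_idx) == 0 or len(rest_idx) == 0:
            continue
        # Round-robin deal per class spreads rare classes across folds.
        folds: list[list[int]] = [[] for _ in range(plan.n_folds)]
        cursor = int(rng.integers(plan.n_folds))
        for cls in np.unique(labels[rest_idx]):
            cls_idx = rest_idx[labels[rest_idx] == cls]
            for i in rng.permutation(cls_idx):
                folds[cursor % plan.n_folds].append(int(i))
                cursor += 1
        fold_arrays = [np.array(sorted(f), dtype=int) for f in folds]
        all_classes = set(np.unique(labels))
        ok = set(np.unique(labels[test_idx])) == all_classes
        for k in range(plan.n_folds):
            pool = np.concatenate([fold_arrays[j] for j in range(plan.n_folds) if j != k])
            if set(np.unique(labels[pool])) != all_classes:
                ok = False
        if ok:
            return SplitAssignment(
                test_idx=test_idx, folds=fold_arrays, trial_index=trial_index
            )
    raise ConfigurationError(
        f"could not build a split with every class in every training pool "
        f"(trial {trial_index})"
    )


# ---------------------------------------------------------------------------
# Model selection and the full task loop
# ---------------------------------------------------------------------------


def default_candidates(
    n_classes: int,
    weights_grid=((1.0,), (0.1,)),
    lambda_grid=(0.01, 0.1),
    names=None,
) -> list[ModelSpec]:
    """The study's candidate grid: 8 architectures x weight/lambda conditions.

    ``weights_grid`` entries give the weight of the first category (the
    normal / majority class); the remaining classes get weight 1.  Weight
    tuples follow the task category order (normal or composite low-risk
    first, high-risk last), matching the 'W1:W2[:W3]' condition notation.
    """
    from .network import MODEL_GRID

    specs = []
    for name in names or MODEL_GRID:
        for w0 in weights_grid:
            w = tuple(list(w0) + [1.0] * (n_classes - len(w0)))
            for lam in lambda_grid:
                specs.append(
                    parse_model_spec(name, class_weights=w, l2_lambda=lam, n_classes=n_classes)
                )
    return specs


def _candidate_key(spec: ModelSpec) -> str:
    return f"{spec.name} {spec.condition}"


def _weights_by_class(spec: ModelSpec, task: int) -> dict[str, float] | None:
    """Map a spec's category-ordered weight tuple onto class names, so the
    classifier (which sorts classes alphabetically) applies them correctly."""
    if spec.class_weights is None:
        return None
    order = task_class_order(task)
    if len(order) != len(spec.class_weights):
        raise InvalidArgumentError("weight tuple length does not match the task")
    return dict(zip(order, spec.class_weights))


def select_models(
    validation_grid: dict[str, float],
    n: int = 4,
    param_counts: dict[str, int] | None = None,
) -> list[str]:
    """Rank candidates by mean validation AUC; return the top ``n`` keys.

    Ties break by lower parameter count, then lexicographic key order.
    """
    if not validation_grid:
        raise InvalidArgumentError("empty validation grid")
    param_counts = param_counts or {}

    def sort_key(k: str):
        return (-validation_grid[k], param_counts.get(k, 0), k)

    ranked = sorted(validation_grid, key=sort_key)
    return ranked[: min(n, len(ranked))]


@dataclass
class TrialResult:
    """One trial's validation grid, selections, thresholds and test outcomes."""

    trial_index: int
    validation_auc: dict[str, float]
    selected: list[str]
    test_scores: dict[str, ScoreSet]
    decisions: dict[str, DecisionSet]
    test_auc: dict[str, float]
    test_acc: dict[str, float]
    policies: dict[str, dict]
    smote_fallback: bool
    leakage_audit: dict


@dataclass
class TaskReport:
    """Pooled outcome of a multi-trial task run."""

    plan: TrialPlan
    trials: list[TrialResult]
    validation_grid: dict[str, float]
    selected: list[str]
    pooled_auc: dict[str, float]
    pooled_distribution: dict[str, PooledDistribution]
    mean_test_auc: dict[str, float]
    sd_test_auc: dict[str, float]
    mean_test_acc: dict[str, float]

    def summary_dict(self) -> dict:
        """JSON-serialisable deterministic summary."""
        out = {
            "task": self.plan.task,
            "n_trials": self.plan.n_trials,
            "n_folds": self.plan.n_folds,
            "seed": self.plan.seed,
            "policy": self.plan.policy_kind,
            "selected": list(self.selected),
            "validation_auc": {k: round(v, 10) for k, v in sorted(self.validation_grid.items())},
            "pooled_test_auc": {k: round(v, 10) for k, v in sorted(self.pooled_auc.items())},
            "mean_test_auc": {k: round(v, 10) for k, v in sorted(self.mean_test_auc.items())},
            "sd_test_auc": {k: round(v, 10) for k, v in sorted(self.sd_test_auc.items())},
            "mean_test_acc": {k: round(v, 10) for k, v in sorted(self.mean_test_acc.items())},
            "pooled_distribution": {
                k: {
                    "classes": list(d.classes),
                    "rows": np.nan_to_num(d.rows(), nan=-1.0).round(10).tolist(),
                    "grade_sensitivity": {
                        g: round(v, 10) for g, v in sorted(d.grade_sensitivity.items())
                    },
                }
                for k, d in sorted(self.pooled_distribution.items())
            },
        }
        return out


def _score_auc(scores: ScoreSet, task: int) -> float:
    if task == 2:
        return multiclass_auc(scores, allow_missing=True)
    pos = scores.column("high_risk")
    mask = scores.y_true == "high_risk"
    return roc_auc(pos[mask], pos[~mask])


def run_task(
    ds: EISDataset,
    plan: TrialPlan,
    candidates: list[ModelSpec] | None = None,
) -> TaskReport:
    """Run the full repeated-trial pipeline for one task.

    Per trial: carve the subject-disjoint test set; K-fold CV over the
    remainder (SMOTE inside each training fold for the human tasks) to
    score every candidate by validation AUC; select the top models on the
    *across-trial mean* validation AUC; retrain them on train+validation;
    determine the threshold policy on training scores; evaluate on the test
    set.  Results are pooled across trials.
    """
    labels_all = ds.task_labels(plan.task)
    n_classes = len(np.unique(labels_all))
    if candidates is None:
        candidates = default_candidates(n_classes)
    candidates = [
        spec
        if spec.n_classes == n_classes
        else parse_model_spec(
            spec.name,
            class_weights=spec.class_weights,
            l2_lambda=spec.l2_lambda,
            n_classes=n_classes,
        )
        for spec in candidates
    ]
    keys = [_candidate_key(s) for s in candidates]
    if len(set(keys)) != len(keys):
        raise InvalidArgumentError("duplicate candidate specs")
    param_counts = {
        k: build_network(s, random_state=0).n_parameters()
        for k, s in zip(keys, candidates)
    }

    X = ds.feature_matrix()
    sids = ds.subject_ids()
    grades = ds.who_grades()
    fit_params = dict(plan.fit_params)

    # Phase 1: validation grids across all trials.
    splits: list[SplitAssignment] = []
    val_grid_trials: list[dict[str, float]] = []
    fallback_any: list[bool] = []
    for t in range(plan.n_trials):
        split = make_trial_splits(ds, plan, t)
        splits.append(split)
        grid: dict[str, float] = {}
        fallback = False
        for ci, (key, spec) in enumerate(zip(keys, candidates)):
            fold_aucs = []
            for k in range(plan.n_folds):
                val_idx = split.folds[k]
                train_idx = np.concatenate(
                    [split.folds[j] for j in range(plan.n_folds) if j != k]
                )
                Xtr, ytr = X[train_idx], labels_all[train_idx]
                if plan.smote_enabled:
                    rng = np.random.default_rng(_trial_seed(plan.seed, 23, t, ci, k))
                    Xtr, ytr, _, fb = augment_training_set(
                        Xtr, ytr, rng, k_neighbours=plan.smote_k
                    )
                    fallback = fallback or fb
                clf = ImpedanceNetClassifier(
                    model_name=spec.name,
                    class_weights=_weights_by_class(spec, plan.task),
                    l2_lambda=spec.l2_lambda,
                    random_state=_seed_int(_trial_seed(plan.seed, 29, t, ci, k)),
                    **fit_params,
                )
                clf.fit(Xtr, ytr, X_val=X[val_idx], y_val=labels_all[val_idx])
                val_scores = clf.score_set(X[val_idx], labels_all[val_idx])
                fold_aucs.append(_score_auc(val_scores, plan.task))
            grid[key] = float(np.mean(fold_aucs))
        val_grid_trials.append(grid)
        fallback_any.append(fallback)
        logger.info("trial %d: validation grid computed", t)

    validation_grid = {
        k: float(np.mean([g[k] for g in val_grid_trials])) for k in keys
    }
    selected = select_models(
        validation_grid, n=min(plan.top_n, len(keys)), param_counts=param_counts
    )
    spec_by_key = dict(zip(keys, candidates))

    # Phase 2: retrain selected models per trial, thresholds, test metrics.
    trials: list[TrialResult] = []
    for t, split in enumerate(splits):
        pool_idx = split.pool_idx()
        test_idx = split.test_idx
        overlap = set(sids[pool_idx]) & set(sids[test_idx])
        audit = {
            "subject_overlap": len(overlap),
            "n_synthetic_eval": 0,
            "scaler_from_train_only": True,
        }
        test_scores: dict[str, ScoreSet] = {}
        decisions: dict[str, DecisionSet] = {}
        test_auc: dict[str, float] = {}
        test_acc: dict[str, float] = {}
        policies: dict[str, dict] = {}
        fallback = fallback_any[t]
        for ci, key in enumerate(selected):
            spec = spec_by_key[key]
            Xtr, ytr = X[pool_idx], labels_all[pool_idx]
            if plan.smote_enabled:
                rng = np.random.default_rng(_trial_seed(plan.seed, 31, t, ci))
                Xtr, ytr, synth_flags, fb = augment_training_set(
                    Xtr, ytr, rng, k_neighbours=plan.smote_k
                )
                fallback = fallback or fb
            clf = ImpedanceNetClassifier(
                model_name=spec.name,
                class_weights=_weights_by_class(spec, plan.task),
                l2_lambda=spec.l2_lambda,
                random_state=_seed_int(_trial_seed(plan.seed, 37, t, ci)),
                **fit_params,
            )
            clf.fit(Xtr, ytr)
            if clf.scaler_ is not None and not np.allclose(
                clf.scaler_.mean_, Xtr.mean(axis=0)
            ):
                audit["scaler_from_train_only"] = False
            # Thresholds come from the real (non-synthetic) training readings.
            train_scores = clf.score_set(
                X[pool_idx],
                labels_all[pool_idx],
                subject_ids=sids[pool_idx],
                who_grades=grades[pool_idx],
            )
            policy = fit_policy(
                plan.policy_kind,
                train_scores,
                fixed_Tstar=plan.fixed_Tstar,
                fixed_alpha=plan.fixed_alpha,
                specificity_floor=plan.specificity_floor,
            )
            scores = clf.score_set(
                X[test_idx],
                labels_all[test_idx],
                subject_ids=sids[test_idx],
                who_grades=grades[test_idx],
            )
            dec = apply_policy(scores, policy)
            test_scores[key] = scores
            decisions[key] = dec
            test_auc[key] = _score_auc(scores, plan.task)
            test_acc[key] = float(np.mean(dec.y_pred == dec.y_true))
            policies[key] = {
                "kind": policy.kind,
                "T_star": policy.T_star,
                "T_Y": policy.T_Y,
                "alpha": policy.alpha,
                "feasible": policy.feasible,
            }
            logger.info(
                "trial %d model %s: test AUC %.3f ACC %.3f (policy %s)",
                t, key, test_auc[key], test_acc[key], policy.kind,
            )
        trials.append(
            TrialResult(
                trial_index=t,
                validation_auc=val_grid_trials[t],
                selected=list(selected),
                test_scores=test_scores,
                decisions=decisions,
                test_auc=test_auc,
                test_acc=test_acc,
                policies=policies,
                smote_fallback=fallback,
                leakage_audit=audit,
            )
        )

    pooled_auc: dict[str, float] = {}
    pooled_dist: dict[str, PooledDistribution] = {}
    mean_auc: dict[str, float] = {}
    sd_auc: dict[str, float] = {}
    mean_acc: dict[str, float] = {}
    for key in selected:
        all_scores = np.concatenate([tr.test_scores[key].probs for tr in trials])
        all_true = np.concatenate([tr.test_scores[key].y_true for tr in trials])
        classes = trials[0].test_scores[key].classes
        pooled = ScoreSet(probs=all_scores, y_true=all_true, classes=classes)
        pooled_auc[key] = _score_auc(pooled, plan.task)
        pooled_dist[key] = pool_trials([tr.decisions[key] for tr in trials])
        aucs = [tr.test_auc[key] for tr in trials]
        mean_auc[key] = float(np.mean(aucs))
        sd_auc[key] = float(np.std(aucs, ddof=1)) if len(aucs) > 1 else 0.0
        mean_acc[key] = float(np.mean([tr.test_acc[key] for tr in trials]))

    return TaskReport(
        plan=plan,
        trials=trials,
        validation_grid=validation_grid,
        selected=list(selected),
        pooled_auc=pooled_auc,
        pooled_distribution=pooled_dist,
        mean_test_auc=mean_auc,
        sd_test_auc=sd_auc,
        mean_test_acc=mean_acc,
    )
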