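"""SMOTE-balanced random-forest classification under within-subject CV.

Each participant's trials are split into stratified k folds (k = 5); per
fold, SMOTE balances the training folds only, a 100-tree bagged forest
is fit, and the untouched, unbalanced test fold is scored with MCC, a
rank-based AUC on the forest's vote fractions, balanced accuracy and
Cohen's kappa.  The whole procedure is repeated (50 iterations by
default) with fresh fold splits, and a dimension's result is the
mean/max/min over iterations of the across-participant mean of fold
means.

Seeding: a master seed expands through ``numpy.random.SeedSequence``
keyed by (participant index, iteration, fold), so any sub-run is exactly
repeatable in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "CVConfig",
    "DimensionResult",
    "METRIC_NAMES",
    "stratified_folds",
    "smote_balance",
    "fit_forest",
    "ForestPredictor",
    "confusion_counts",
    "mcc",
    "balanced_accuracy",
    "kappa",
    "auc",
    "run_within_subject_cv",
    "run_repeated",
]

METRIC_NAMES = ("mcc", "auc", "ba", "kappa")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class MetricSet:
    """MCC/AUC/BA/kappa for one evaluation; NaN marks an undefined metric."""

    mcc: float
    auc: float
    ba: float
    kappa: float

    def as_array(self) -> np.ndarray:
        return np.array([self.mcc, self.auc, self.ba, self.kappa], dtype=float)


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 5
    n_trees: int = 100
    n_iterations: int = 50
    smote_k_neighbors: int = 5
    max_features: str | int | float = "sqrt"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class DimensionResult:
    """Aggregated classification result for one thought dimension."""

    #: iteration x metric frame of across-participant means
    iteration_values: pd.DataFrame
    #: metric x {mean, max, min} summary over iterations
    summary: pd.DataFrame
    #: participant x metric frame of per-participant grand means
    per_participant: pd.DataFrame
    n_participants: int


# ---------------------------------------------------------------------------
# metrics (authored from the confusion-matrix definitions)
# ---------------------------------------------------------------------------

def confusion_counts(y_true, y_pred, positive: int = 1) -> ConfusionCounts:
    yt = np.asarray(y_true) == positive
    yp = np.asarray(y_pred) == positive
    return ConfusionCounts(
        tp=int(np.sum(yt & yp)),
        tn=int(np.sum(~yt & ~yp)),
        fp=int(np.sum(~yt & yp)),
        fn=int(np.sum(yt & ~yp)),
    )


def mcc(counts: ConfusionCounts) -> float:
    """Matthews correlation coefficient; 0 when any marginal is empty."""
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    denom_sq = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom_sq == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom_sq))


def balanced_accuracy(counts: ConfusionCounts) -> float:
    """Mean of sensitivity and specificity; NaN if a true class is absent."""
    pos = counts.tp + counts.fn
    neg = counts.tn + counts.fp
    if pos == 0 or neg == 0:
        return float("nan")
    return float((counts.tp / pos + counts.tn / neg) / 2.0)


def kappa(counts: ConfusionCounts) -> float:
    """Cohen's kappa with marginal-product expected agreement."""
    n = counts.total
    if n == 0:
        return float("nan")
    p_o = (counts.tp + counts.tn) / n
    p_e = ((counts.tp + counts.fp) * (counts.tp + counts.fn)
           + (counts.tn + counts.fn) * (counts.tn + counts.fp)) / (n * n)
    if p_e == 1.0:
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def auc(y_true, scores, positive: int = 1) -> float:
    """Rank-based (Mann-Whitney) AUC with ties counted 1/2; NaN if one class absent."""
    yt = np.asarray(y_true) == positive
    s = np.asarray(scores, dtype=float)
    n_pos = int(yt.sum())
    n_neg = int((~yt).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    u = ranks[yt].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# folds, SMOTE, forest
# ---------------------------------------------------------------------------

def stratified_folds(labels, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Partition indices into k stratified folds (per-fold class counts +/- 1).

    Raises ValueError when either class has fewer than k members; such a
    participant should have been excluded upstream.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < k:
        raise ValueError(
            f"stratified {k}-fold split needs >= {k} members per class, got {dict(zip(classes.tolist(), counts.tolist()))}"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True,
                               random_state=int(rng.integers(2**31 - 1)))
    return [test_idx for _, test_idx in splitter.split(np.zeros((len(y), 1)), y)]


def smote_balance(
    X: np.ndarray,
    y: np.ndarray,
    k_neighbors: int = 5,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Oversample the minority class to parity by neighbor interpolation.

    Each synthetic point is ``x_i + u * (x_nn - x_i)`` with ``u ~ U[0, 1)``
    and ``x_nn`` one of the k nearest minority neighbors of a randomly
    chosen minority point.  ``k`` degrades to ``minority - 1``; a
    singleton minority is duplicated.  The inputs are never mutated.
    """
    if rng is None:
        rng = np.random.default_rng()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("SMOTE needs two classes in the training set")
    if classes.size > 2:
        raise ValueError("SMOTE implemented for binary labels only")
    minority = classes[np.argmin(counts)]
    n_needed = int(counts.max() - counts.min())
    if n_needed == 0:
        return X, y
    Xm = X[y == minority]
    if len(Xm) == 1:
        synthetic = np.repeat(Xm, n_needed, axis=0)
    else:
        k = min(k_neighbors, len(Xm) - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xm)
        neighbor_idx = nn.kneighbors(Xm, return_distance=False)[:, 1:]  # drop self
        base = rng.integers(0, len(Xm), size=n_needed)
        pick = rng.integers(0, k, size=n_needed)
        u = rng.random(n_needed)
        x_nn = Xm[neighbor_idx[base, pick]]
        synthetic = Xm[base] + u[:, None] * (x_nn - Xm[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


class ForestPredictor:
    """A fitted bagged forest exposing hard votes and a vote-fraction score."""

    def __init__(self, clf: RandomForestClassifier):
        self._clf = clf

    def score(self, X) -> np.ndarray:
        """Fraction of trees voting the positive (high) class, in [0, 1]."""
        X = np.asarray(X, dtype=float)
        votes = np.stack([
            self._clf.classes_[tree.predict(X).astype(int)] for tree in self._clf.estimators_
        ])
        return np.mean(votes == 1, axis=0)

    def predict(self, X) -> np.ndarray:
        """Majority vote of the trees (ties go to the positive class)."""
        return (self.score(X) >= 0.5).astype(int)


def fit_forest(X, y, n_trees: int = 100, seed: int = 0,
               max_features: str | int | float = "sqrt") -> ForestPredictor:
    """Fit a bagging random forest (bootstrap resampling + random split selection)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if len(X) == 0:
        raise ValueError("cannot fit a forest on an empty training set")
    clf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        bootstrap=True,
        random_state=int(seed) % (2**31 - 1),
    )
    clf.fit(X, y)
    return ForestPredictor(clf)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

def _evaluate_fold(predictor: ForestPredictor, X_test, y_test) -> MetricSet:
    if np.unique(y_test).size < 2:
        # degenerate test fold: all metrics recorded missing
        return MetricSet(float("nan"), float("nan"), float("nan"), float("nan"))
    y_pred = predictor.predict(X_test)
    scores = predictor.score(X_test)
    counts = confusion_counts(y_test, y_pred)
    return MetricSet(mcc(counts), auc(y_test, scores), balanced_accuracy(counts), kappa(counts))


def run_within_subject_cv(
    X,
    y,
    cfg: CVConfig = CVConfig(),
    seed_seq: np.random.SeedSequence | None = None,
    folds: Sequence[np.ndarray] | None = None,
) -> tuple[list[MetricSet], MetricSet]:
    """One stratified k-fold pass over a single participant's trials.

    Per fold: SMOTE on the training folds only, forest fit, evaluation on
    the untouched unbalanced test fold.  Returns per-fold metrics and the
    fold mean (NaN folds excluded from the mean).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if seed_seq is None:
        seed_seq = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(seed_seq)
    if folds is None:
        folds = stratified_folds(y, cfg.k_folds, rng)

    fold_metrics: list[MetricSet] = []
    for f, test_idx in enumerate(folds):
        mask = np.zeros(len(y), dtype=bool)
        mask[np.asarray(test_idx)] = True
        fold_seq = np.random.SeedSequence(entropy=seed_seq.entropy,
                                          spawn_key=seed_seq.spawn_key + (f,))
        fold_rng = np.random.default_rng(fold_seq)
        X_bal, y_bal = smote_balance(X[~mask], y[~mask], cfg.smote_k_neighbors, fold_rng)
        predictor = fit_forest(X_bal, y_bal, cfg.n_trees,
                               seed=int(fold_rng.integers(2**31 - 1)),
                               max_features=cfg.max_features)
        fold_metrics.append(_evaluate_fold(predictor, X[mask], y[mask]))

    stacked = np.stack([m.as_array() for m in fold_metrics])
    with np.errstate(invalid="ignore"):
        means = np.nanmean(stacked, axis=0)
    return fold_metrics, MetricSet(*means)


def _participant_seed_seq(master_seed: int, p_index: int, iteration: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=master_seed, spawn_key=(p_index, iteration))


def run_repeated(
    cohort: Mapping[str, tuple[np.ndarray, np.ndarray]],
    cfg: CVConfig = CVConfig(),
    feature_mask: Sequence[int] | None = None,
) -> DimensionResult:
    """Repeat within-subject CV ``n_iterations`` times over a cohort.

    ``cohort`` maps participant id -> (X, y).  Each iteration draws fresh
    fold splits (and fresh SMOTE draws) per participant; the iteration
    value is the across-participant mean of fold-mean metrics, and the
    result summarizes mean/max/min over iterations.  ``feature_mask``
    restricts the columns of X (feature-subset evaluation).
    """
    pids = sorted(cohort.keys())
    if not pids:
        raise ValueError("run_repeated needs at least one included participant")
    mask_idx = None if feature_mask is None else np.asarray(feature_mask, dtype=int)

    iter_rows = np.empty((cfg.n_iterations, len(METRIC_NAMES)))
    per_participant = np.zeros((len(pids), len(METRIC_NAMES)))
    for it in range(cfg.n_iterations):
        participant_means = np.empty((len(pids), len(METRIC_NAMES)))
        for p_idx, pid in enumerate(pids):
            X, y = cohort[pid]
            Xm = X if mask_idx is None else np.asarray(X)[:, mask_idx]
            _, fold_mean = run_within_subject_cv(
                Xm, y, cfg, seed_seq=_participant_seed_seq(cfg.seed, p_idx, it)
            )
            participant_means[p_idx] = fold_mean.as_array()
        with np.errstate(invalid="ignore"):
            iter_rows[it] = np.nanmean(participant_means, axis=0)
        per_participant += np.nan_to_num(participant_means) / cfg.n_iterations

    iteration_values = pd.DataFrame(iter_rows, columns=list(METRIC_NAMES))
    summary = pd.DataFrame(
        {
            "mean": iteration_values.mean(),
            "max": iteration_values.max(),
            "min": iteration_values.min(),
        }
    )
    return DimensionResult(
        iteration_values=iteration_values,
        summary=summary,
        per_participant=pd.DataFrame(per_participant, index=pids, columns=list(METRIC_NAMES)),
        n_participants=len(pids),
    )
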