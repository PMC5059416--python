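"""Iterative semi-supervised linear-SVM rescoring of PSMs.

The algorithm splits spectra into three cross-validation bins, seeds
each classifier with the single best signed feature, and then iterates:
score the training partition, take targets below the training q-value
threshold as positives and all decoys as negatives, and refit a linear
SVM with asymmetric misclassification costs.  Each PSM's final score
comes from the classifier whose test fold contained it.

For very large inputs a random *subset* of spectra can be used for
training: the normal three-fold procedure runs on the subset and every
PSM is then scored with the average of the three classifiers (after
per-classifier decoy standardization).  Target and decoy PSMs of one
spectrum always travel together during subset selection, which keeps the
competition structure of the training set intact.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from sklearn.svm import LinearSVC

from .pin import PsmTable
from .stats import target_decoy_qvalues

__all__ = [
    "TrainConfig",
    "ScoreVector",
    "CrossValidationModel",
    "subset_sample",
    "choose_initial_direction",
    "train_cross_validation",
    "score_all",
    "rescore",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training hyperparameters.

    ``c_pos``/``c_neg`` weight misclassified positives/negatives in the
    SVM loss; decoys outnumber confident targets early on, so the
    negative cost is larger by default.  ``subset_size`` switches on
    downsampled training when set and smaller than the input.
    """

    n_folds: int = 3
    q_train: float = 0.01
    iterations: int = 10
    c_pos: float = 10.0
    c_neg: float = 30.0
    subset_size: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")
        if not 0.0 < self.q_train < 1.0:
            raise ValueError("q_train must be in (0, 1)")
        if self.iterations < 0:
            raise ValueError("iterations must be non-negative")
        if self.c_pos <= 0 or self.c_neg <= 0:
            raise ValueError("misclassification costs must be positive")
        if self.subset_size is not None and self.subset_size < 1:
            raise ValueError("subset_size must be >= 1 when set")


@dataclass(frozen=True)
class ScoreVector:
    """A trained linear scoring function in raw feature space.

    ``decoy_mean``/``decoy_std`` are the decoy score statistics of the
    training partition, recorded so scores from different classifiers
    can be standardized onto a common scale.
    """

    weights: np.ndarray
    intercept: float
    decoy_mean: float
    decoy_std: float

    def raw_scores(self, features: np.ndarray) -> np.ndarray:
        if features.shape[1] != self.weights.size:
            raise ValueError("feature dimensionality does not match the score vector")
        return features @ self.weights + self.intercept

    def normalized_scores(self, features: np.ndarray) -> np.ndarray:
        return (self.raw_scores(features) - self.decoy_mean) / self.decoy_std


@dataclass
class CrossValidationModel:
    vectors: List[ScoreVector]
    fold_assignment: np.ndarray  # per-PSM test fold
    positive_history: List[List[int]]  # per fold, positives per iteration


def subset_sample(table: PsmTable, subset_size: int, seed: int) -> PsmTable:
    """Sample whole spectra until the PSM count first reaches ``subset_size``.

    Spectra (``spec_id`` equivalence classes) are drawn without
    replacement, so target/decoy PSMs of one spectrum are never
    separated.  Row order of the original table is preserved.  Asking
    for more PSMs than exist returns everything with a warning.
    """
    if subset_size < 1:
        raise ValueError("subset_size must be >= 1")
    if subset_size >= len(table):
        if subset_size > len(table):
            warnings.warn(
                "subset_size exceeds the number of PSMs; using the full set",
                stacklevel=2,
            )
        return table
    spectra, inverse = np.unique(table.spec_ids.astype(str), return_inverse=True)
    rows_of = [[] for _ in spectra]
    for row, s in enumerate(inverse):
        rows_of[s].append(row)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(spectra))
    keep_rows: List[int] = []
    for s in order:
        keep_rows.extend(rows_of[s])
        if len(keep_rows) >= subset_size:
            break
    return table.select(np.array(sorted(keep_rows), dtype=int))


def choose_initial_direction(
    features: np.ndarray, is_target: np.ndarray, q_train: float = 0.01
) -> Tuple[int, int]:
    """Pick the signed single feature that passes the most targets.

    Every feature is tried with both signs as the sole score; the
    (index, sign) maximizing the number of targets at ``q <= q_train``
    wins.  Ties break to the lowest feature index, then positive sign.
    """
    features = np.asarray(features, dtype=float)
    best_count = -1
    best = (0, 1)
    for j in range(features.shape[1]):
        for sign in (1, -1):
            q = target_decoy_qvalues(sign * features[:, j], is_target)
            count = int(((q <= q_train) & is_target).sum())
            if count > best_count:
                best_count = count
                best = (j, sign)
    return best


def _fold_assignment(table: PsmTable, n_folds: int, seed: int) -> np.ndarray:
    spectra, inverse = np.unique(table.spec_ids.astype(str), return_inverse=True)
    rng = np.random.default_rng([seed, 5])
    perm = rng.permutation(len(spectra))
    spectrum_fold = np.empty(len(spectra), dtype=int)
    spectrum_fold[perm] = np.arange(len(spectra)) % n_folds
    return spectrum_fold[inverse]


def train_cross_validation(table: PsmTable, config: TrainConfig) -> CrossValidationModel:
    """Train one linear SVM per cross-validation fold.

    Features are standardized internally; the returned score vectors act
    on raw features.  An iteration that finds zero positives keeps the
    previous direction and continues rather than aborting.
    """
    X = table.features
    y = table.is_target
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = (X - mu) / sd
    fold = _fold_assignment(table, config.n_folds, config.seed)

    vectors: List[ScoreVector] = []
    history: List[List[int]] = []
    for k in range(config.n_folds):
        train_mask = fold != k
        Xtr, ytr = Xs[train_mask], y[train_mask]
        if not ytr.any() or ytr.all():
            raise ValueError(f"fold {k}: training partition lacks targets or decoys")
        j, sign = choose_initial_direction(Xtr, ytr, config.q_train)
        w = np.zeros(X.shape[1])
        w[j] = sign
        b = 0.0
        counts: List[int] = []
        for _ in range(config.iterations):
            scores = Xtr @ w + b
            q = target_decoy_qvalues(scores, ytr)
            positives = ytr & (q <= config.q_train)
            counts.append(int(positives.sum()))
            if not positives.any():
                continue  # keep the previous direction for this iteration
            rows = positives | ~ytr
            y_fit = np.where(positives[rows], 1, -1)
            weights = np.where(y_fit == 1, config.c_pos, config.c_neg)
            clf = LinearSVC(C=1.0, dual=False, tol=1e-4, max_iter=20000)
            clf.fit(Xtr[rows], y_fit, sample_weight=weights)
            w = clf.coef_.ravel().copy()
            b = float(clf.intercept_[0])
        # back to raw feature space
        w_raw = w / sd
        b_raw = b - float((w * mu / sd).sum())
        train_scores = X[train_mask] @ w_raw + b_raw
        decoy_scores = train_scores[~ytr]
        d_mean = float(decoy_scores.mean()) if decoy_scores.size else 0.0
        d_std = float(decoy_scores.std()) if decoy_scores.size > 1 else 1.0
        if d_std == 0.0:
            d_std = 1.0
        vectors.append(ScoreVector(weights=w_raw, intercept=b_raw, decoy_mean=d_mean, decoy_std=d_std))
        history.append(counts)
    return CrossValidationModel(vectors=vectors, fold_assignment=fold, positive_history=history)


def score_all(
    table: PsmTable,
    vectors: List[ScoreVector],
    mode: str = "cross_validation",
    fold_assignment: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Score every PSM with the trained classifiers.

    ``cross_validation`` mode uses, for each PSM, the classifier whose
    test fold contained it; ``subset_average`` averages the
    decoy-standardized scores of all classifiers (used after subset
    training, where every PSM — trained on or not — gets the mean
    score).
    """
    if mode == "cross_validation":
        if fold_assignment is None:
            raise ValueError("cross_validation mode requires a fold assignment")
        per_fold = np.column_stack([v.normalized_scores(table.features) for v in vectors])
        return per_fold[np.arange(len(table)), np.asarray(fold_assignment, dtype=int)]
    if mode == "subset_average":
        per_vec = np.column_stack([v.normalized_scores(table.features) for v in vectors])
        return per_vec.mean(axis=1)
    raise ValueError(f"unknown scoring mode {mode!r}")


def rescore(table: PsmTable, config: TrainConfig = TrainConfig()) -> Tuple[np.ndarray, CrossValidationModel]:
    """Full rescoring: optional subset training, then scoring of all PSMs.

    Deterministic given the data and ``config.seed``.
    """
    if config.subset_size is not None and config.subset_size < len(table):
        subset = subset_sample(table, config.subset_size, config.seed)
        model = train_cross_validation(subset, config)
        scores = score_all(table, model.vectors, mode="subset_average")
    else:
        if config.subset_size is not None and config.subset_size > len(table):
            warnings.warn("subset_size exceeds the number of PSMs; training on the full set")
        model = train_cross_validation(table, config)
        scores = score_all(
            table, model.vectors, mode="cross_validation", fold_assignment=model.fold_assignment
        )
    return scores, model
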