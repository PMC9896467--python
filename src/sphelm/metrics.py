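"""Ranking metrics, stratified cross-validation and the CV fitness.

AUC is computed by the rank statistic (Mann-Whitney), so tied scores
contribute 1/2.  AUPR is average precision — the mean, over positives
in rank order, of the precision at each positive's rank — with ties
resolved pessimistically (negatives ranked ahead of positives at equal
score), which avoids the over-optimism of linear PR interpolation.

The cross-validated fitness couples these metrics to the ELM: a flat
parameter vector is decoded into hidden-layer weights and biases, the
output weights are solved per training fold by pseudoinverse, and the
fitness is the mean over folds of (AUC_i + AUPR_i) / 2 — a bounded
score in [0, 1] whose literal fold-sum (k times the mean) is exposed as
``fitness_sum``.  The fold split is seeded independently of the
optimizer so that the objective is stationary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .elm import ELMModel, decode_params

__all__ = [
    "compute_auc",
    "compute_aupr",
    "make_folds",
    "cross_validate",
    "fitness",
    "CVResult",
]


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(int).ravel()
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    return labels


def compute_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve via the rank statistic; ties count 1/2."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = rankdata(scores)
    pos_rank_sum = ranks[labels == 1].sum()
    return float((pos_rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def compute_aupr(labels: np.ndarray, scores: np.ndarray) -> float:
    """Average precision with pessimistic (negatives-first) tie ordering."""
    labels = _check_binary(labels)
    scores = np.asarray(scores, dtype=float).ravel()
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined: no positive samples")
    # Primary key: score descending.  Within ties, negatives first
    # (labels ascending), the worst case for precision.
    order = np.lexsort((labels, -scores))
    sorted_labels = labels[order]
    cum_pos = np.cumsum(sorted_labels)
    precision = cum_pos / np.arange(1, len(labels) + 1)
    return float(precision[sorted_labels == 1].sum() / n_pos)


def make_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Stratified k-fold assignment, reproducible from ``seed``.

    Within each class, shuffled indices are split into k chunks whose
    sizes differ by at most one.  If the rarer class has fewer than k
    members the split degrades (with a warning) to a plain random
    partition.
    """
    labels = _check_binary(labels)
    n = len(labels)
    if n < k:
        raise ValueError(f"cannot make {k} folds from {n} samples")
    rng = np.random.default_rng(seed)
    folds = np.empty(n, dtype=int)
    class_counts = [int((labels == c).sum()) for c in (0, 1)]
    if min(c for c in class_counts if c > 0) < k:
        warnings.warn("fewer samples than folds in a class; non-stratified split")
        perm = rng.permutation(n)
        for fold_id, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = fold_id
        return folds
    for c in (0, 1):
        idx = np.nonzero(labels == c)[0]
        perm = rng.permutation(idx)
        for fold_id, chunk in enumerate(np.array_split(perm, k)):
            folds[chunk] = fold_id
    return folds


@dataclass
class CVResult:
    """Per-fold ranking metrics and the aggregate fitness."""

    fold_auc: np.ndarray
    fold_aupr: np.ndarray
    folds: np.ndarray
    seed: int

    @property
    def auc(self) -> float:
        return float(np.mean(self.fold_auc))

    @property
    def aupr(self) -> float:
        return float(np.mean(self.fold_aupr))

    @property
    def fitness(self) -> float:
        """Mean over folds of (AUC_i + AUPR_i) / 2, in [0, 1]."""
        return float(np.mean((self.fold_auc + self.fold_aupr) / 2.0))

    @property
    def fitness_sum(self) -> float:
        """Literal fold-sum form: k times the mean fitness."""
        return self.fitness * len(self.fold_auc)

    def to_dict(self) -> dict:
        return {
            "fold_auc": self.fold_auc.tolist(),
            "fold_aupr": self.fold_aupr.tolist(),
            "auc": self.auc,
            "aupr": self.aupr,
            "fitness": self.fitness,
            "fitness_sum": self.fitness_sum,
            "seed": self.seed,
        }


def cross_validate(
    input_weights: np.ndarray,
    biases: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    activation: str = "sigmoid",
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """k-fold CV of an ELM with a fixed hidden layer.

    Per fold, the output weights are solved on the training split and
    the held-out split is scored; AUC and AUPR are computed on the raw
    scores.
    """
    y = _check_binary(y)
    folds = make_folds(y, k=k, seed=seed)
    fold_auc = np.empty(k)
    fold_aupr = np.empty(k)
    for fold_id in range(k):
        test = folds == fold_id
        model = ELMModel(input_weights, biases, activation).fit(X[~test], y[~test])
        scores = model.predict(X[test])
        fold_auc[fold_id] = compute_auc(y[test], scores)
        fold_aupr[fold_id] = compute_aupr(y[test], scores)
    return CVResult(fold_auc, fold_aupr, folds, seed)


def fitness(
    parameter_vector: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    hidden_nodes: int,
    activation: str = "sigmoid",
    k: int = 10,
    fold_seed: int = 0,
) -> float:
    """CV fitness of a flat ELM parameter vector (to be maximized).

    The vector of length ``L * (d + 1)`` decodes to input weights (first
    L*d entries, row-major) then biases.  Returns the mean over folds of
    (AUC_i + AUPR_i) / 2.
    """
    W, b = decode_params(parameter_vector, hidden_nodes, X.shape[1])
    return cross_validate(W, b, X, y, activation=activation, k=k, seed=fold_seed).fitness
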