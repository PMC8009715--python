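"""ReliefF attribute weighting and top-n feature selection.

ReliefF scores each feature by how well it separates an instance from its
nearest neighbors of other classes (misses) relative to its nearest
neighbors of the same class (hits).  For each visited instance T the weight
of attribute A is decreased by the average normalized difference to the k
nearest hits and increased by the prior-weighted average difference to the
k nearest misses of every other class:

    W[A] <- W[A] - sum_hits diff(A, T, H) / (m k)
                 + sum_{C != class(T)} P(C)/(1 - P(class(T)))
                   * sum_misses diff(A, T, M_C) / (m k)

diff is the attribute difference normalized by the attribute's range over
the dataset (0 when the range is 0), so weights live in [-1, 1] and are
invariant to per-feature rescaling.  Neighbor distance is the Manhattan sum
of per-attribute diff values.  By default every instance is visited once in
index order (m = n), which makes the weights fully deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("mammotex")


@dataclass(frozen=True)
class ReliefFConfig:
    k: int = 3                 # nearest hits/misses per class
    m: int | str = "all"       # instances to visit; "all" = full index-order sweep
    n_select: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.m != "all" and (not isinstance(self.m, int) or self.m < 1):
            raise ValueError('m must be a positive integer or "all"')


@dataclass(frozen=True)
class FeatureWeights:
    """Per-feature relevance weights and the induced descending ranking."""

    W: np.ndarray
    ranking: np.ndarray  # feature indices by descending W, ties to lower index

    def __post_init__(self):
        object.__setattr__(self, "W", np.asarray(self.W, dtype=float))
        object.__setattr__(self, "ranking", np.asarray(self.ranking, dtype=int))


def diff(a: int, i1: np.ndarray, i2: np.ndarray, ranges: np.ndarray) -> float:
    """Range-normalized attribute difference |I1[A] - I2[A]| / range[A]."""
    if ranges[a] == 0:
        return 0.0
    return abs(i1[a] - i2[a]) / ranges[a]


def _diff_matrix(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Range-scaled features and per-feature ranges (zero-range safe)."""
    ranges = X.max(axis=0) - X.min(axis=0)
    safe = np.where(ranges == 0, 1.0, ranges)
    return X / safe, ranges


def relieff_weights(
    X: np.ndarray, y: np.ndarray, config: ReliefFConfig = ReliefFConfig()
) -> FeatureWeights:
    """ReliefF weights W in [-1, 1]^p with a deterministic ranking.

    Classes with fewer than k+1 members have their neighbor count truncated
    (with a log notice); the update divides by the neighbor count actually
    used so truncation does not shrink the scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    labels, counts = np.unique(y, return_counts=True)
    if len(labels) < 2:
        raise ValueError("ReliefF needs at least two classes")
    if (counts < config.k + 1).any():
        small = [int(l) for l, c in zip(labels, counts) if c < config.k + 1]
        logger.warning("classes %s have < k+1 members; k truncated for them", small)
    priors = {int(l): c / n for l, c in zip(labels, counts)}

    Z, _ranges = _diff_matrix(X)  # per-attribute diff = |Z_i - Z_j| per column
    D = cdist(Z, Z, metric="cityblock")

    if config.m == "all":
        visit = np.arange(n)
    else:
        rng = np.random.default_rng(config.seed)
        visit = rng.choice(n, size=min(config.m, n), replace=True)
    m = len(visit)

    class_idx = {int(l): np.flatnonzero(y == l) for l in labels}
    W = np.zeros(p)
    for t in visit:
        cls = int(y[t])
        # nearest hits
        hits_pool = class_idx[cls]
        order = hits_pool[np.argsort(D[t, hits_pool], kind="stable")]
        order = order[order != t]
        hits = order[: config.k]
        if len(hits) > 0:
            hit_diffs = np.abs(Z[hits] - Z[t]).sum(axis=0) / len(hits)
            W -= hit_diffs / m
        # nearest misses per other class, prior-weighted
        for other in labels:
            other = int(other)
            if other == cls:
                continue
            pool = class_idx[other]
            order = pool[np.argsort(D[t, pool], kind="stable")]
            misses = order[: config.k]
            miss_diffs = np.abs(Z[misses] - Z[t]).sum(axis=0) / len(misses)
            W += (priors[other] / (1.0 - priors[cls])) * miss_diffs / m
    ranking = np.argsort(-W, kind="stable")
    return FeatureWeights(W, ranking)


def select_top(weights: FeatureWeights, n_select: int) -> np.ndarray:
    """Indices of the n_select highest-weighted features (stable tie rule)."""
    if n_select > len(weights.W):
        raise ValueError("n_select exceeds the number of features")
    return weights.ranking[:n_select].copy()


def _stratified_folds(
    y: np.ndarray, n_folds: int, seed: int
) -> list[np.ndarray]:
    """Per-class shuffled round-robin fold assignment."""
    rng = np.random.default_rng(seed)
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.array(sorted(f)) for f in folds]


def weight_curve(
    X: np.ndarray,
    y: np.ndarray,
    weights: FeatureWeights,
    classifier_factory,
    ns: list[int],
    n_folds: int = 5,
    seed: int = 0,
) -> list[tuple[int, float]]:
    """Cross-validated accuracy using the top-n ranked features, per n.

    ``classifier_factory()`` must return an object with fit(X, y) and
    predict(X).  Returns [(n, accuracy), ...] for plotting the cumulative
    accuracy-vs-feature-count curve.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if list(ns) != sorted(ns):
        raise ValueError("ns must be ascending")
    folds = _stratified_folds(y, n_folds, seed)
    results = []
    for n in ns:
        cols = select_top(weights, n)
        correct = 0
        for f in range(n_folds):
            test_idx = folds[f]
            train_idx = np.concatenate([folds[g] for g in range(n_folds) if g != f])
            clf = classifier_factory()
            clf.fit(X[np.ix_(train_idx, cols)], y[train_idx])
            pred = clf.predict(X[np.ix_(test_idx, cols)])
            correct += int((pred == y[test_idx]).sum())
        results.append((n, correct / len(y)))
    return results
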