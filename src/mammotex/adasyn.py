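"""Adaptive synthetic (ADASYN) oversampling for multiclass imbalance.

Every minority class is grown toward the majority-class count.  Each
minority sample i receives a difficulty weight r_i = (fraction of its K
nearest neighbors, over the whole dataset, that belong to a different
class); the class budget G = round((m_l - m_s) * beta) is allocated across
samples proportionally to the normalized weights, so harder-to-learn
boundary samples spawn more synthetics.  A synthetic is a convex
combination s = x_i + lambda * (x_zi - x_i) of the seed and one of its K
nearest same-class neighbors, lambda ~ Uniform(0, 1).

Neighbor searches use Euclidean distance on features standardized to zero
mean and unit variance (computed from the input table); synthesis happens
in the original feature space.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

logger = logging.getLogger("mammotex")


@dataclass
class LabeledDataset:
    """Feature matrix with integer class labels (and optional bookkeeping)."""

    X: np.ndarray
    y: np.ndarray
    feature_names: tuple[str, ...] | None = None
    synthetic: np.ndarray | None = None  # bool mask, True for generated rows

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != len(self.X):
            raise ValueError("X and y length mismatch")
        if len(self.X) < 1:
            raise ValueError("dataset must contain at least one sample")
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.y), dtype=bool)

    @property
    def n_samples(self) -> int:
        return len(self.y)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    @property
    def class_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.y, return_counts=True)
        return {int(l): int(c) for l, c in zip(labels, counts)}


@dataclass(frozen=True)
class AdasynConfig:
    beta: float = 1.0        # balance level: fraction of the gap to close
    k: int = 5               # neighbor count for difficulty weights/synthesis
    d_threshold: float = 1.0  # oversample classes with imbalance ratio below this
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.beta <= 1):
            raise ValueError("beta must be in (0, 1]")
        if self.k < 1:
            raise ValueError("K must be >= 1")


def imbalance_ratio(m_s: int, m_l: int) -> float:
    """Minority-to-majority count ratio d = m_s / m_l, in (0, 1]."""
    if m_l < 1:
        raise ValueError("majority count must be >= 1")
    if not (1 <= m_s <= m_l):
        raise ValueError("need m_l >= m_s >= 1")
    return m_s / m_l


def n_to_generate(m_l: int, m_s: int, beta: float) -> int:
    """Synthetic-sample budget G = round((m_l - m_s) * beta)."""
    return int(round((m_l - m_s) * beta))


def _standardize(X: np.ndarray) -> np.ndarray:
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    return (X - mu) / sd


def _knn_indices(D_row: np.ndarray, exclude: int, k: int) -> np.ndarray:
    """Indices of the k nearest points by a distance row, excluding one."""
    order = np.argsort(D_row, kind="stable")
    order = order[order != exclude]
    return order[:k]


def density_ratios(
    X: np.ndarray, y: np.ndarray, minority_label: int, K: int
) -> np.ndarray:
    """Normalized difficulty weights r_hat for each minority sample.

    r_i = (number of the sample's K Euclidean nearest neighbors in the whole
    dataset with a different label) / K, normalized to sum 1.  If every r_i
    is 0 (the class is nowhere near a boundary) the weights fall back to
    uniform.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = len(y)
    if K > n - 1:
        raise ValueError(f"K={K} exceeds available neighbors ({n - 1})")
    minority_idx = np.flatnonzero(y == minority_label)
    if len(minority_idx) == 0:
        raise ValueError(f"no samples with label {minority_label}")
    Z = _standardize(X)
    D = cdist(Z[minority_idx], Z)
    r = np.empty(len(minority_idx))
    for row, i in enumerate(minority_idx):
        nn = _knn_indices(D[row], i, K)
        r[row] = np.mean(y[nn] != minority_label)
    total = r.sum()
    if total == 0:
        return np.full(len(r), 1.0 / len(r))
    return r / total


def allocate_counts(r_hat: np.ndarray, G: int) -> np.ndarray:
    """Integer per-sample budgets via largest-remainder rounding of r_hat*G.

    Sums to G exactly; remainder ties break toward the lower index.
    """
    r_hat = np.asarray(r_hat, dtype=float)
    raw = r_hat * G
    base = np.floor(raw).astype(int)
    remainder = int(round(G - base.sum()))
    if remainder > 0:
        frac = raw - base
        # sort by (-fraction, index): stable argsort on -frac keeps low index first
        order = np.argsort(-frac, kind="stable")
        base[order[:remainder]] += 1
    return base


def synthesize(
    X: np.ndarray,
    y: np.ndarray,
    minority_label: int,
    g: np.ndarray,
    K: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Generate sum(g) synthetic samples for one minority class.

    Each synthetic is s = x_i + lambda * (x_zi - x_i) with x_zi drawn
    uniformly from the seed's K nearest same-class neighbors and
    lambda ~ Uniform(0, 1).  A singleton class duplicates its seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    minority_idx = np.flatnonzero(y == minority_label)
    g = np.asarray(g, dtype=int)
    if len(g) != len(minority_idx):
        raise ValueError("g must have one entry per minority sample")
    out = []
    if len(minority_idx) == 1:
        logger.warning(
            "class %s has a single sample; synthetics are duplicates of it",
            minority_label,
        )
        seed_x = X[minority_idx[0]]
        for _ in range(int(g.sum())):
            rng.uniform()  # keep the lambda stream aligned
            out.append(seed_x.copy())
        return np.array(out) if out else np.empty((0, X.shape[1]))

    Zm = _standardize(X)[minority_idx]
    Dm = cdist(Zm, Zm)
    k_eff = min(K, len(minority_idx) - 1)
    for row, i in enumerate(minority_idx):
        if g[row] == 0:
            continue
        nn_rows = _knn_indices(Dm[row], row, k_eff)
        neighbors = X[minority_idx[nn_rows]]
        for _ in range(int(g[row])):
            z = neighbors[rng.integers(len(neighbors))]
            lam = rng.uniform()
            out.append(X[i] + lam * (z - X[i]))
    return np.array(out) if out else np.empty((0, X.shape[1]))


def oversample(dataset: LabeledDataset, config: AdasynConfig = AdasynConfig()) -> LabeledDataset:
    """Balance every minority class toward the majority count.

    The majority class (ties: lowest label) is untouched; each class whose
    imbalance ratio is below ``d_threshold`` receives its G synthetics.
    Original rows appear unchanged, in their input order, before the
    generated block; deterministic given ``config.seed``.
    """
    counts = dataset.class_counts
    if len(counts) < 2:
        raise ValueError("oversampling needs at least two classes")
    m_l = max(counts.values())
    majority = min(l for l, c in counts.items() if c == m_l)
    new_X = [dataset.X]
    new_y = [dataset.y]
    for label in sorted(counts):
        if label == majority:
            continue
        m_s = counts[label]
        d = imbalance_ratio(m_s, m_l)
        if d >= config.d_threshold:
            continue
        G = n_to_generate(m_l, m_s, config.beta)
        if G == 0:
            continue
        r_hat = density_ratios(dataset.X, dataset.y, label, config.k)
        g = allocate_counts(r_hat, G)
        rng = np.random.default_rng([config.seed, int(label)])
        block = synthesize(dataset.X, dataset.y, label, g, config.k, rng)
        logger.info("class %s: d=%.4f, generated %d synthetics", label, d, len(block))
        new_X.append(block)
        new_y.append(np.full(len(block), label, dtype=dataset.y.dtype))
    X = np.vstack(new_X)
    y = np.concatenate(new_y)
    synthetic = np.zeros(len(y), dtype=bool)
    synthetic[dataset.n_samples :] = True
    return LabeledDataset(X, y, dataset.feature_names, synthetic)
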