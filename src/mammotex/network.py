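"""Four-layer feedforward classifier trained by Levenberg-Marquardt.

The default architecture is input -> 40 -> 20 -> 10 -> 8 (softmax): three
tanh hidden layers and an 8-way softmax output, one unit per BI-RADS
category.  Training minimizes the sum-squared error of the residuals
e = target - output over one-hot targets, which gives the residual
structure Levenberg-Marquardt requires; the damped Gauss-Newton step
solves

    (J^T J + mu I) dw = J^T e,        J = d e / d w,

and the parameters move w <- w - dw.  Accepted steps (those that lower the
SSE) shrink the damping mu; rejected steps grow it, so the method
interpolates between Gauss-Newton (mu -> 0) and small gradient-descent
steps (mu -> inf).  Multinomial cross-entropy is computed per epoch as a
monitoring metric only.

J is never materialized for the full training set: J^T J and J^T e are
accumulated over sample chunks, backpropagating one output unit at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError

from .adasyn import LabeledDataset

logger = logging.getLogger("mammotex")


@dataclass(frozen=True)
class NetworkSpec:
    n_inputs: int
    hidden: tuple[int, ...] = (40, 20, 10)
    n_outputs: int = 8
    seed: int = 0
    layer1_linear: bool = False  # literal reading of a linear first layer

    def __post_init__(self):
        if self.n_inputs < 1 or self.n_outputs < 1 or any(h < 1 for h in self.hidden):
            raise ValueError("all layer sizes must be >= 1")

    @property
    def layer_sizes(self) -> tuple[int, ...]:
        return (self.n_inputs, *self.hidden, self.n_outputs)


@dataclass(frozen=True)
class TrainConfig:
    mu0: float = 1e-3
    mu_inc: float = 10.0
    mu_dec: float = 0.1
    mu_max: float = 1e10
    max_epochs: int = 1000
    val_patience: int = 6
    grad_tol: float = 1e-7
    split: tuple[float, float, float] = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.mu0 <= 0 or not (self.mu_inc > 1 > self.mu_dec > 0):
            raise ValueError("need mu0 > 0 and mu_inc > 1 > mu_dec > 0")


@dataclass
class TrainedNetwork:
    spec: NetworkSpec
    weights: list[np.ndarray]  # W_l of shape (S_l, S_{l-1})
    biases: list[np.ndarray]
    class_labels: np.ndarray | None = None
    history: list[dict] = field(default_factory=list)
    split_indices: dict[str, np.ndarray] | None = None

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))


# ---------------------------------------------------------------------------
# Initialization and forward pass
# ---------------------------------------------------------------------------


def init(spec: NetworkSpec) -> TrainedNetwork:
    """Seeded Nguyen-Widrow-style init: uniform weights with rows rescaled
    to magnitude 0.7 * S^(1/R); biases start at 0."""
    rng = np.random.default_rng(spec.seed)
    sizes = spec.layer_sizes
    weights, biases = [], []
    for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
        w = rng.uniform(-1.0, 1.0, size=(fan_out, fan_in))
        norms = np.linalg.norm(w, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        beta = 0.7 * fan_out ** (1.0 / fan_in)
        weights.append(beta * w / norms)
        biases.append(np.zeros(fan_out))
    return TrainedNetwork(spec, weights, biases)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def _forward_cache(net: TrainedNetwork, X: np.ndarray) -> list[np.ndarray]:
    """Activations per layer, input first, softmax output last."""
    a = np.asarray(X, dtype=float)
    if a.ndim == 1:
        a = a[None, :]
    if a.shape[1] != net.spec.n_inputs:
        raise ValueError(
            f"expected {net.spec.n_inputs} input features, got {a.shape[1]}"
        )
    acts = [a]
    n_layers = len(net.weights)
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        z = acts[-1] @ w.T + b
        if l == n_layers - 1:
            a = _softmax(z)
        elif l == 0 and net.spec.layer1_linear:
            a = z
        else:
            a = np.tanh(z)
        acts.append(a)
    return acts


def forward(net: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    """Class probability matrix; each row sums to 1."""
    return _forward_cache(net, X)[-1]


def predict(net: TrainedNetwork, X: np.ndarray) -> np.ndarray:
    """Predicted labels: argmax probability, ties to the lowest class index."""
    probs = forward(net, X)
    idx = probs.argmax(axis=1)
    if net.class_labels is not None:
        return np.asarray(net.class_labels)[idx]
    return idx + 1


# ---------------------------------------------------------------------------
# Parameter vector helpers
# ---------------------------------------------------------------------------


def get_params(net: TrainedNetwork) -> np.ndarray:
    return np.concatenate(
        [np.concatenate([w.ravel(), b]) for w, b in zip(net.weights, net.biases)]
    )


def set_params(net: TrainedNetwork, theta: np.ndarray) -> None:
    pos = 0
    for l, (w, b) in enumerate(zip(net.weights, net.biases)):
        net.weights[l] = theta[pos : pos + w.size].reshape(w.shape).copy()
        pos += w.size
        net.biases[l] = theta[pos : pos + b.size].copy()
        pos += b.size


# ---------------------------------------------------------------------------
# Jacobian and LM step
# ---------------------------------------------------------------------------


def _activation_derivative(net: TrainedNetwork, layer: int, a: np.ndarray) -> np.ndarray:
    """d act / d z expressed through the activation value a (hidden layers)."""
    if layer == 0 and net.spec.layer1_linear:
        return np.ones_like(a)
    return 1.0 - a**2


def _backprop_rows(
    net: TrainedNetwork, acts: list[np.ndarray], out_unit: int
) -> np.ndarray:
    """Jacobian rows de_{s,o}/dw for one output unit o, all samples.

    The residual is e = t - a_L, so the seed gradient at the softmax input is
    de_{s,o}/dz_j = -a_o (delta_oj - a_j).
    """
    A = acts[-1]
    n = A.shape[0]
    n_layers = len(net.weights)
    seed = A * A[:, out_unit : out_unit + 1]  # a_o * a_j
    seed[:, out_unit] -= A[:, out_unit]  # minus a_o * delta_oj
    G = seed  # de/dz at the output layer
    pieces: list[np.ndarray] = [None] * n_layers  # type: ignore[list-item]
    for l in range(n_layers - 1, -1, -1):
        a_prev = acts[l]
        jw = (G[:, :, None] * a_prev[:, None, :]).reshape(n, -1)
        pieces[l] = np.concatenate([jw, G], axis=1)
        if l > 0:
            G = (G @ net.weights[l]) * _activation_derivative(net, l - 1, acts[l])
    return np.concatenate(pieces, axis=1)


def jacobian(
    net: TrainedNetwork, X: np.ndarray, targets: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Dense residual Jacobian J = de/dw and residual vector e = t - output.

    Rows are ordered output-unit-major: row o * n_samples + s holds sample
    s, output o.  Shape contract: (n_samples * n_outputs, n_params).
    """
    X = np.asarray(X, dtype=float)
    T = np.asarray(targets, dtype=float)
    acts = _forward_cache(net, X)
    A = acts[-1]
    e = (T - A).T.ravel()  # output-major to match the row order below
    rows = [_backprop_rows(net, acts, o) for o in range(net.spec.n_outputs)]
    return np.concatenate(rows, axis=0), e


def _normal_equations(
    net: TrainedNetwork, X: np.ndarray, T: np.ndarray, chunk: int = 256
) -> tuple[np.ndarray, np.ndarray, float]:
    """Accumulated J^T J, J^T e and SSE without materializing J."""
    n_par = net.n_params
    JtJ = np.zeros((n_par, n_par))
    Jte = np.zeros(n_par)
    sse = 0.0
    for start in range(0, len(X), chunk):
        xs = X[start : start + chunk]
        ts = T[start : start + chunk]
        acts = _forward_cache(net, xs)
        res = ts - acts[-1]
        sse += float((res**2).sum())
        for o in range(net.spec.n_outputs):
            Jo = _backprop_rows(net, acts, o)
            JtJ += Jo.T @ Jo
            Jte += Jo.T @ res[:, o]
    return JtJ, Jte, sse


def lm_step(J: np.ndarray, e: np.ndarray, mu: float) -> np.ndarray:
    """Solve the damped normal equations (J^T J + mu I) dw = J^T e."""
    return _solve_normal(J.T @ J, J.T @ e, mu)


def _solve_normal(JtJ: np.ndarray, Jte: np.ndarray, mu: float) -> np.ndarray:
    A = JtJ + mu * np.eye(len(Jte))
    c, low = cho_factor(A)
    return cho_solve((c, low), Jte)


# ---------------------------------------------------------------------------
# Splitting and training
# ---------------------------------------------------------------------------


def stratified_split(
    y: np.ndarray, fractions: tuple[float, float, float], seed: int
) -> dict[str, np.ndarray]:
    """Seeded stratified train/val/test indices, proportions within +-1/class."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y)
    parts: dict[str, list[int]] = {"train": [], "val": [], "test": []}
    f_train, f_val, _ = fractions
    for label in np.unique(y):
        idx = np.flatnonzero(y == label)
        rng.shuffle(idx)
        n = len(idx)
        n_train = int(round(n * f_train))
        n_val = int(round(n * f_val))
        n_train = min(n_train, n)
        n_val = min(n_val, n - n_train)
        parts["train"] += idx[:n_train].tolist()
        parts["val"] += idx[n_train : n_train + n_val].tolist()
        parts["test"] += idx[n_train + n_val :].tolist()
    return {k: np.array(sorted(v), dtype=int) for k, v in parts.items()}


def one_hot(y: np.ndarray, class_labels: np.ndarray) -> np.ndarray:
    pos = {int(l): i for i, l in enumerate(class_labels)}
    T = np.zeros((len(y), len(class_labels)))
    for row, label in enumerate(y):
        T[row, pos[int(label)]] = 1.0
    return T


def _mse(net: TrainedNetwork, X: np.ndarray, T: np.ndarray) -> float:
    res = T - forward(net, X)
    return float((res**2).mean())


def _cross_entropy(net: TrainedNetwork, X: np.ndarray, T: np.ndarray) -> float:
    p = np.clip(forward(net, X), 1e-12, 1.0)
    return float(-(T * np.log(p)).sum() / len(X))


def train(
    net: TrainedNetwork,
    dataset: LabeledDataset,
    config: TrainConfig = TrainConfig(),
) -> TrainedNetwork:
    """Classic Levenberg-Marquardt training loop with validation stopping.

    Per epoch: accumulate the normal equations at the current parameters,
    propose dw at the current damping mu, accept the step iff the training
    SSE decreases (then mu *= mu_dec), otherwise reject and mu *= mu_inc and
    retry within the epoch.  Stops on max_epochs, mu overflow, gradient norm
    below grad_tol, or val_patience consecutive validation-error increases;
    the parameters of the best validation epoch are restored at the end.
    """
    split = stratified_split(dataset.y, config.split, config.seed)
    class_labels = np.unique(dataset.y)
    if len(class_labels) != net.spec.n_outputs:
        raise ValueError(
            f"network has {net.spec.n_outputs} outputs but data has "
            f"{len(class_labels)} classes"
        )
    for name in ("train", "val"):
        if len(split[name]) == 0:
            raise ValueError(f"{name} split is empty")
    missing = set(class_labels.tolist()) - set(dataset.y[split["train"]].tolist())
    if missing:
        raise ValueError(f"classes {sorted(missing)} absent from the training split")

    Xtr = dataset.X[split["train"]]
    Ttr = one_hot(dataset.y[split["train"]], class_labels)
    Xval = dataset.X[split["val"]]
    Tval = one_hot(dataset.y[split["val"]], class_labels)

    net.class_labels = class_labels
    net.split_indices = split
    net.history = []
    mu = config.mu0
    theta = get_params(net)
    best_val = np.inf
    best_theta = theta.copy()
    val_increases = 0
    prev_val = np.inf

    for epoch in range(config.max_epochs):
        JtJ, Jte, sse = _normal_equations(net, Xtr, Ttr)
        grad_norm = float(np.linalg.norm(Jte))
        if not np.isfinite(sse):
            raise FloatingPointError("non-finite training loss; aborting")
        if grad_norm < config.grad_tol:
            logger.info("epoch %d: gradient norm %.2e below tolerance", epoch, grad_norm)
            break
        accepted = False
        while mu <= config.mu_max:
            try:
                dw = _solve_normal(JtJ, Jte, mu)
            except (LinAlgError, np.linalg.LinAlgError):
                mu *= config.mu_inc
                continue
            set_params(net, theta - dw)
            res = Ttr - forward(net, Xtr)
            sse_try = float((res**2).sum())
            if np.isfinite(sse_try) and sse_try < sse:
                theta = theta - dw
                mu = max(mu * config.mu_dec, 1e-20)
                accepted = True
                sse = sse_try
                break
            mu *= config.mu_inc
        if not accepted:
            set_params(net, theta)
            logger.info("epoch %d: mu overflow at %.2e; stopping", epoch, mu)
            break

        val_mse = _mse(net, Xval, Tval)
        net.history.append(
            {
                "epoch": epoch,
                "sse": sse,
                "mse_train": sse / Ttr.size,
                "mse_val": val_mse,
                "cross_entropy_train": _cross_entropy(net, Xtr, Ttr),
                "mu": mu,
                "grad_norm": grad_norm,
            }
        )
        if val_mse < best_val:
            best_val = val_mse
            best_theta = theta.copy()
        if val_mse > prev_val:
            val_increases += 1
            if val_increases >= config.val_patience:
                logger.info("epoch %d: validation error rose %d times; stopping",
                            epoch, val_increases)
                break
        else:
            val_increases = 0
        prev_val = val_mse

    set_params(net, best_theta)
    return net
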