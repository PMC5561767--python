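"""Weighted extreme learning machine (WELM) for imbalanced binary classification.

An extreme learning machine is a single-hidden-layer network whose hidden
parameters (input weights, biases) are drawn at random and frozen; only the
output weights beta are learned, by regularized least squares with the
closed-form ridge solutions

    n <= L (right form):  beta = F^T (I/C + W F F^T)^{-1} W p
    n >  L (left form):   beta = (I/C + F^T W F)^{-1} F^T W p

where F is the n x L hidden-layer output matrix, p the +1/-1 target vector,
C the regularization constant and W a diagonal matrix of per-sample weights.
With W = I both reduce to the unweighted ELM solutions; the two forms are
algebraically identical and differ only in the size of the matrix inverted
(n x n vs L x L). Class-frequency weights (scheme ``W1``: w_i = 1/n_class;
scheme ``W2``: golden-ratio 0.618/n_majority on the majority class) push the
decision boundary away from the minority class, which matters when
self-interacting proteins are outnumbered roughly 8:1 by non-SIPs.

The kernelized form replaces the explicit random feature map with a kernel
matrix Omega_ij = K(x_i, x_j) and solves

    alpha = (I/C + W Omega)^{-1} W p,    score(x) = [K(x, x_i)]_i . alpha

which for a linear kernel on the hidden-layer features coincides with the
explicit solution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg

__all__ = [
    "ACTIVATIONS",
    "HiddenLayer",
    "WeightScheme",
    "WELMModel",
    "KernelWELMModel",
    "TrainingConfig",
    "activation_apply",
    "init_hidden_layer",
    "hidden_output",
    "compute_class_weights",
    "welm_train",
    "welm_score",
    "welm_predict",
    "kernel_welm_train",
    "kernel_welm_score",
    "kernel_welm_predict",
    "grid_search",
]

#: Golden-ratio majority-class weight factor of the W2 scheme.
GOLDEN_RATIO = 0.618

ACTIVATIONS = {
    "tribas": lambda z: np.maximum(0.0, 1.0 - np.abs(z)),
    "sigmoid": lambda z: 1.0 / (1.0 + np.exp(-z)),
    "sin": np.sin,
    "hardlim": lambda z: np.where(z >= 0, 1.0, 0.0),
    "radbas": lambda z: np.exp(-np.square(z)),
}


def activation_apply(name: str, z):
    """Apply a named hidden-node activation elementwise.

    ``tribas`` is the triangular basis function max(0, 1 - |z|).
    """
    try:
        fn = ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; supported: {sorted(ACTIVATIONS)}"
        ) from None
    return fn(np.asarray(z, dtype=float))


@dataclass
class HiddenLayer:
    """Random, frozen hidden layer: z_l(x) = activation(w_l . x + b_l)."""

    input_weights: np.ndarray  # L_hidden x d
    biases: np.ndarray  # L_hidden
    activation: str
    seed: int

    def __post_init__(self) -> None:
        self.input_weights = np.asarray(self.input_weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.input_weights.ndim != 2:
            raise ValueError("input_weights must be L_hidden x d")
        if self.biases.shape != (self.input_weights.shape[0],):
            raise ValueError("biases must have one entry per hidden node")
        if self.activation not in ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; "
                f"supported: {sorted(ACTIVATIONS)}"
            )

    @property
    def n_hidden(self) -> int:
        return self.input_weights.shape[0]

    @property
    def input_dim(self) -> int:
        return self.input_weights.shape[1]


def init_hidden_layer(
    d: int, n_hidden: int, activation: str = "tribas", seed: int = 0
) -> HiddenLayer:
    """Draw input weights uniform on [-1, 1] and biases uniform on [0, 1].

    The same seed always reproduces the identical layer.
    """
    if d < 1 or n_hidden < 1:
        raise ValueError("input dim and hidden-node count must be >= 1")
    if activation not in ACTIVATIONS:
        raise ValueError(
            f"unknown activation {activation!r}; supported: {sorted(ACTIVATIONS)}"
        )
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(n_hidden, d))
    b = rng.uniform(0.0, 1.0, size=n_hidden)
    return HiddenLayer(input_weights=W, biases=b, activation=activation, seed=seed)


def hidden_output(hidden: HiddenLayer, X: np.ndarray) -> np.ndarray:
    """Hidden-layer output matrix F: entry (i, l) = act(w_l . x_i + b_l)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != hidden.input_dim:
        raise ValueError(
            f"dimension mismatch: hidden layer expects {hidden.input_dim} "
            f"features, got {X.shape[1]}"
        )
    return activation_apply(hidden.activation, X @ hidden.input_weights.T + hidden.biases)


@dataclass
class WeightScheme:
    """Per-sample weights materializing the diagonal of W at fit time."""

    name: str  # none | W1 | W2
    per_sample_weights: np.ndarray

    def __post_init__(self) -> None:
        self.per_sample_weights = np.asarray(self.per_sample_weights, dtype=float)
        if np.any(self.per_sample_weights < 0):
            raise ValueError("sample weights must be non-negative")


def compute_class_weights(y: np.ndarray, scheme: str = "W1") -> WeightScheme:
    """Materialize per-sample weights for a +1/-1 label vector.

    ``none``: all 1. ``W1``: w_i = 1/n_{class(i)}. ``W2``: as W1 but the
    majority class is further scaled by the golden ratio 0.618, widening the
    margin pushed toward the majority side.
    """
    y = np.asarray(y)
    if scheme == "none":
        return WeightScheme(name="none", per_sample_weights=np.ones(len(y)))
    if scheme not in ("W1", "W2"):
        raise ValueError(f"unknown weighting scheme {scheme!r}; use none, W1 or W2")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == -1))
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"scheme {scheme} needs both classes present "
            f"(got {n_pos} positive, {n_neg} negative)"
        )
    counts = np.where(y == 1, n_pos, n_neg).astype(float)
    w = 1.0 / counts
    if scheme == "W2":
        majority = 1 if n_pos >= n_neg else -1
        w = np.where(y == majority, GOLDEN_RATIO / counts, 1.0 / counts)
    return WeightScheme(name=scheme, per_sample_weights=w)


@dataclass
class TrainingConfig:
    """WELM hyper-parameters. The defaults are the reference profile
    (tribas activation, 5000 hidden neurons, C = 100, class-frequency
    weighting)."""

    activation: str = "tribas"
    n_hidden: int = 5000
    C: float = 100.0
    scheme: str = "W1"
    seed: int = 0
    solver_form: str = "auto"  # auto | left | right

    def replace(self, **kw) -> "TrainingConfig":
        return replace(self, **kw)


@dataclass
class WELMModel:
    """Trained explicit-feature WELM: random hidden layer + output weights."""

    hidden: HiddenLayer
    beta: np.ndarray
    C: float
    scheme: WeightScheme
    solver_form: str

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        if self.beta.shape[0] != self.hidden.n_hidden:
            raise ValueError("beta length must equal the hidden-node count")
        if self.C <= 0:
            raise ValueError("C must be positive")


def _solve_beta(
    F: np.ndarray, y: np.ndarray, w: np.ndarray, C: float, form: str
) -> np.ndarray:
    """Closed-form ridge solution for the output weights.

    right: beta = F^T (I/C + W F F^T)^{-1} W y   (inverts n x n)
    left:  beta = (I/C + F^T W F)^{-1} F^T W y   (inverts L x L)
    """
    n, L = F.shape
    if form == "right":
        A = np.eye(n) / C + w[:, None] * (F @ F.T)
        return F.T @ np.linalg.solve(A, w * y)
    if form == "left":
        A = np.eye(L) / C + F.T @ (w[:, None] * F)
        return scipy.linalg.solve(A, F.T @ (w * y), assume_a="pos")
    raise ValueError(f"unknown solver form {form!r}")


def welm_train(X: np.ndarray, y: np.ndarray, cfg: TrainingConfig) -> WELMModel:
    """Fit a WELM: draw the hidden layer from cfg.seed, materialize the
    weighting scheme from the labels, and solve for beta in closed form.

    ``solver_form='auto'`` inverts the smaller Gram matrix (n x n when
    n <= n_hidden, else n_hidden x n_hidden); both forms give the same beta.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 training samples")
    bad = set(np.unique(y)) - {-1.0, 1.0}
    if bad:
        raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")
    if cfg.C <= 0:
        raise ValueError("C must be positive")
    scheme = compute_class_weights(y, cfg.scheme)
    hidden = init_hidden_layer(X.shape[1], cfg.n_hidden, cfg.activation, cfg.seed)
    F = hidden_output(hidden, X)
    form = cfg.solver_form
    if form == "auto":
        form = "right" if X.shape[0] <= cfg.n_hidden else "left"
    beta = _solve_beta(F, y, scheme.per_sample_weights, cfg.C, form)
    return WELMModel(hidden=hidden, beta=beta, C=cfg.C, scheme=scheme, solver_form=form)


def welm_score(model: WELMModel, X: np.ndarray) -> np.ndarray:
    """Real-valued decision scores F(X) . beta."""
    return hidden_output(model.hidden, X) @ model.beta


def welm_predict(model: WELMModel, X: np.ndarray) -> np.ndarray:
    """Hard +1/-1 labels; a score of exactly 0 predicts +1."""
    return _sign(welm_score(model, X))


def _sign(scores: np.ndarray) -> np.ndarray:
    return np.where(np.asarray(scores) >= 0, 1, -1)


# ---------------------------------------------------------------------------
# Kernel form
# ---------------------------------------------------------------------------

@dataclass
class KernelSpec:
    """Kernel specification: ``linear``, ``rbf`` (with gamma) or
    ``tribas_map`` (linear kernel on the random tribas feature map)."""

    name: str
    gamma: float | None = None
    n_hidden: int | None = None
    seed: int | None = None
    activation: str = "tribas"

    def __post_init__(self) -> None:
        if self.name not in ("linear", "rbf", "tribas_map"):
            raise ValueError(f"unknown kernel {self.name!r}")
        if self.name == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValueError("rbf kernel requires gamma > 0")
        if self.name == "tribas_map" and (not self.n_hidden or self.seed is None):
            raise ValueError("tribas_map kernel requires n_hidden and seed")


def _feature_map(spec: KernelSpec, d: int) -> HiddenLayer | None:
    if spec.name == "tribas_map":
        return init_hidden_layer(d, spec.n_hidden, spec.activation, spec.seed)
    return None


def _kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray,
                   hidden: HiddenLayer | None) -> np.ndarray:
    if spec.name == "linear":
        return A @ B.T
    if spec.name == "rbf":
        sq = (
            np.sum(A * A, axis=1)[:, None]
            + np.sum(B * B, axis=1)[None, :]
            - 2.0 * A @ B.T
        )
        return np.exp(-spec.gamma * np.maximum(sq, 0.0))
    # tribas_map: linear kernel in the random-feature space
    return hidden_output(hidden, A) @ hidden_output(hidden, B).T


@dataclass
class KernelWELMModel:
    """Kernelized WELM: stored training inputs plus solved coefficients."""

    train_X: np.ndarray
    kernel: KernelSpec
    alpha: np.ndarray
    C: float
    scheme: WeightScheme
    hidden: HiddenLayer | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.train_X = np.asarray(self.train_X, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.alpha.shape[0] != self.train_X.shape[0]:
            raise ValueError("alpha must have one coefficient per training sample")


def kernel_welm_train(
    X: np.ndarray,
    y: np.ndarray,
    kernel: KernelSpec,
    C: float = 100.0,
    scheme: str = "W1",
) -> KernelWELMModel:
    """Solve alpha = (I/C + W Omega)^{-1} W y with Omega the kernel Gram matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y disagree on the number of samples")
    if C <= 0:
        raise ValueError("C must be positive")
    ws = compute_class_weights(y, scheme)
    w = ws.per_sample_weights
    hidden = _feature_map(kernel, X.shape[1])
    omega = _kernel_matrix(kernel, X, X, hidden)
    n = X.shape[0]
    A = np.eye(n) / C + w[:, None] * omega
    try:
        alpha = np.linalg.solve(A, w * y)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"kernel system is numerically singular ({exc}); try a larger C"
        ) from exc
    return KernelWELMModel(
        train_X=X, kernel=kernel, alpha=alpha, C=C, scheme=ws, hidden=hidden
    )


def kernel_welm_score(model: KernelWELMModel, X: np.ndarray) -> np.ndarray:
    """Decision scores [K(x, x_i)]_i . alpha."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = _kernel_matrix(model.kernel, X, model.train_X, model.hidden)
    return K @ model.alpha


def kernel_welm_predict(model: KernelWELMModel, X: np.ndarray) -> np.ndarray:
    """Hard +1/-1 labels from the kernel scores (0 maps to +1)."""
    return _sign(kernel_welm_score(model, X))


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

def grid_search(
    X: np.ndarray,
    y: np.ndarray,
    grid: dict[str, list],
    folds: int = 5,
    metric: str = "Ac",
    seed: int = 0,
) -> tuple[TrainingConfig, list[dict]]:
    """Exhaustive hyper-parameter search by internal stratified CV.

    ``grid`` maps TrainingConfig field names (C, n_hidden, activation,
    scheme) to candidate lists. Every combination is scored by ``metric``
    averaged over ``folds`` stratified folds of the training data only;
    the argmax config is returned (ties break to the earliest grid point)
    together with the full score table.
    """
    from sklearn.model_selection import StratifiedKFold

    from sipwelm.evaluation import compute_metrics, confusion_counts

    if not grid:
        raise ValueError("empty grid")
    if metric not in ("Ac", "Sn", "Sp", "Pe", "MCC"):
        raise ValueError(
            f"unknown metric {metric!r}; use one of Ac, Sn, Sp, Pe, MCC"
        )
    if folds < 2:
        raise ValueError("folds must be >= 2")
    y = np.asarray(y)
    n_min = min(int(np.sum(y == 1)), int(np.sum(y == -1)))
    if folds > n_min:
        raise ValueError(
            f"fold count {folds} exceeds minority-class size {n_min}"
        )
    keys = list(grid)
    unknown = set(keys) - {"C", "n_hidden", "activation", "scheme"}
    if unknown:
        raise ValueError(f"unknown grid keys: {sorted(unknown)}")

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.asarray(X), y))

    table: list[dict] = []
    best_cfg, best_score = None, -np.inf
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = TrainingConfig(seed=seed, **dict(zip(keys, combo)))
        fold_scores = []
        for tr, te in splits:
            model = welm_train(np.asarray(X)[tr], y[tr], cfg)
            pred = welm_predict(model, np.asarray(X)[te])
            report = compute_metrics(confusion_counts(y[te], pred))
            fold_scores.append(getattr(report, metric))
        mean_score = float(np.mean(fold_scores))
        row = {k: v for k, v in zip(keys, combo)}
        row[metric] = mean_score
        table.append(row)
        if mean_score > best_score:  # strict: ties keep the earliest point
            best_cfg, best_score = cfg, mean_score
    return best_cfg, table
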