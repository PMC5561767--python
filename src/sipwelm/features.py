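"""Local Average Group (LAG) features and PCA reduction.

LAG maps a variable-length L x 20 PSSM to a fixed 400-dimensional vector by
splitting the positions into 20 contiguous groups of ~5% of the sequence
length each and averaging each of the 20 residue columns within each group.
Feature layout: index (g-1)*20 + j holds the mean of column j (in the PSSM's
column order) over group g, for g = 1..20.

For lengths divisible by 20 the within-group mean equals the (20/P)-scaled
group sum of the defining formula; for other lengths we use the contiguous
floor-boundary partition b_g = floor(g*L/20), whose per-group arithmetic mean
is the natural extension (group sizes differ by at most one).

PCA (centering, no variance scaling) reduces the 400-dim LAG space to a
configurable dimension, 300 by default, to suppress noise directions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA as _SKPCA

from sipwelm.pssm_io import PSSM

#: Number of groups the positions are split into (each ~5% of the length).
N_GROUPS = 20

#: Dimension of the raw LAG vector (20 groups x 20 residue columns).
LAG_DIM = 400

#: Default PCA output dimension.
DEFAULT_PCA_DIM = 300

#: Sequences shorter than this are accepted with a warning (the curated
#: datasets exclude proteins under 50 residues).
SHORT_SEQUENCE_WARN = 50


@dataclass(frozen=True)
class GroupPartition:
    """Partition of positions 0..L-1 into 20 contiguous groups.

    ``boundaries`` holds 21 non-decreasing integers b_0=0 .. b_20=L; group g
    (1-based) covers the half-open 0-based range [b_{g-1}, b_g).
    """

    length: int
    boundaries: tuple[int, ...]

    def group_positions(self, g: int) -> range:
        """0-based positions of 1-based group g."""
        return range(self.boundaries[g - 1], self.boundaries[g])

    def sizes(self) -> list[int]:
        return [self.boundaries[g] - self.boundaries[g - 1] for g in range(1, 21)]


@dataclass
class FeatureVector:
    """LAG (or PCA-reduced) representation of one protein."""

    protein_id: str
    values: np.ndarray
    stage: str = "lag"  # lag | pca

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.stage == "lag" and self.values.shape[0] != LAG_DIM:
            raise ValueError(
                f"lag-stage vector must have {LAG_DIM} entries, "
                f"got {self.values.shape[0]}"
            )


@dataclass
class FeatureMatrix:
    """Aligned ids / feature rows / optional {+1,-1} labels."""

    ids: list[str]
    X: np.ndarray
    y: np.ndarray | None = None
    stage: str = "lag"

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-dimensional")
        if len(self.ids) != self.X.shape[0]:
            raise ValueError(
                f"{len(self.ids)} ids but {self.X.shape[0]} feature rows"
            )
        if self.y is not None:
            self.y = np.asarray(self.y)
            if self.y.shape[0] != self.X.shape[0]:
                raise ValueError("labels do not align with feature rows")
            bad = set(np.unique(self.y)) - {-1, 1}
            if bad:
                raise ValueError(f"labels must be +1/-1, found {sorted(bad)}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    def subset(self, idx) -> "FeatureMatrix":
        idx = np.asarray(idx)
        return FeatureMatrix(
            ids=[self.ids[i] for i in idx],
            X=self.X[idx],
            y=None if self.y is None else self.y[idx],
            stage=self.stage,
        )

    @staticmethod
    def from_vectors(
        vectors: list[FeatureVector], labels: dict[str, int] | None = None
    ) -> "FeatureMatrix":
        ids = [v.protein_id for v in vectors]
        X = np.vstack([v.values for v in vectors])
        y = None
        if labels is not None:
            missing = [i for i in ids if i not in labels]
            if missing:
                raise KeyError(f"no label for ids: {missing}")
            y = np.array([labels[i] for i in ids])
        stage = vectors[0].stage if vectors else "lag"
        return FeatureMatrix(ids=ids, X=X, y=y, stage=stage)


@dataclass
class PCAModel:
    """Fitted principal-component model (mean + orthonormal components)."""

    mean: np.ndarray
    components: np.ndarray  # n_components x input_dim
    explained_variance: np.ndarray
    n_components: int = field(init=False)

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float)
        self.components = np.asarray(self.components, dtype=float)
        self.explained_variance = np.asarray(self.explained_variance, dtype=float)
        self.n_components = self.components.shape[0]

    @property
    def input_dim(self) -> int:
        return self.components.shape[1]


def make_partition(L: int) -> GroupPartition:
    """Floor-boundary partition of L positions into 20 contiguous groups."""
    if L < N_GROUPS:
        raise ValueError(
            f"sequence too short for {N_GROUPS} groups (L={L}, need >= {N_GROUPS})"
        )
    boundaries = tuple(g * L // N_GROUPS for g in range(N_GROUPS + 1))
    return GroupPartition(length=L, boundaries=boundaries)


def lag_transform(pssm: PSSM) -> FeatureVector:
    """400-dim LAG vector: per-group, per-column means of the PSSM.

    Columns follow ``pssm.column_order``; groups follow sequence order.
    """
    L = pssm.length
    if L < SHORT_SEQUENCE_WARN:
        warnings.warn(
            f"{pssm.protein_id}: length {L} is below {SHORT_SEQUENCE_WARN} "
            "residues; LAG groups are very small",
            stacklevel=2,
        )
    part = make_partition(L)
    out = np.empty(LAG_DIM, dtype=float)
    for g in range(1, N_GROUPS + 1):
        rows = pssm.scores[part.boundaries[g - 1]: part.boundaries[g]]
        out[(g - 1) * 20: g * 20] = rows.mean(axis=0)
    return FeatureVector(protein_id=pssm.protein_id, values=out, stage="lag")


def pca_fit(X: FeatureMatrix | np.ndarray, n_components: int = DEFAULT_PCA_DIM) -> PCAModel:
    """Fit PCA on feature rows.

    Components are ordered by explained variance (descending) and the sign of
    each is fixed so its largest-magnitude loading is positive, making the
    fit deterministic. ``n_components`` beyond the feasible rank is clamped
    with a warning.
    """
    A = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    n, d = A.shape
    if n < 2:
        raise ValueError("PCA requires at least 2 samples")
    feasible = min(d, n - 1)
    if n_components > feasible:
        warnings.warn(
            f"n_components={n_components} exceeds feasible rank {feasible}; "
            "clamping",
            stacklevel=2,
        )
        n_components = feasible
    if n_components < 1:
        raise ValueError("n_components must be positive")
    sk = _SKPCA(n_components=n_components, svd_solver="full")
    sk.fit(A)
    comps = sk.components_.copy()
    for row in comps:
        j = np.argmax(np.abs(row))
        if row[j] < 0:
            row *= -1.0
    return PCAModel(
        mean=sk.mean_, components=comps, explained_variance=sk.explained_variance_
    )


def pca_apply(model: PCAModel, X: FeatureMatrix | np.ndarray):
    """Project rows onto the fitted components: (x - mean) @ components.T.

    A :class:`FeatureMatrix` input returns a :class:`FeatureMatrix` with
    stage ``pca`` and ids/labels carried through; an array returns an array.
    """
    A = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    if A.ndim != 2 or A.shape[1] != model.input_dim:
        got = A.shape[1] if A.ndim == 2 else A.shape
        raise ValueError(
            f"dimension mismatch: model expects {model.input_dim} columns, got {got}"
        )
    Z = (A - model.mean) @ model.components.T
    if isinstance(X, FeatureMatrix):
        return FeatureMatrix(ids=list(X.ids), X=Z, y=X.y, stage="pca")
    return Z


def pca_inverse(model: PCAModel, Z: np.ndarray) -> np.ndarray:
    """Map projected rows back to the input space: z @ components + mean."""
    Z = np.asarray(Z, dtype=float)
    return Z @ model.components + model.mean


@dataclass
class MinMaxScaler:
    """Global affine map of the training value range onto [-1, 1].

    Random-projection activations such as tribas(z) = max(0, 1 - |z|)
    respond only in a narrow band around zero, so classifier inputs are
    rescaled to [-1, 1] (the usual ELM convention) before the hidden layer.
    A single min/max over the whole training matrix is used rather than
    per-feature ranges: after PCA the trailing components carry almost pure
    noise at tiny scale, and stretching each of them to [-1, 1]
    independently would amplify that noise to the same magnitude as the
    leading components. A degenerate (constant) matrix maps to -1.
    """

    lo: float
    hi: float

    def __post_init__(self) -> None:
        self.lo = float(self.lo)
        self.hi = float(self.hi)


def minmax_fit(X: FeatureMatrix | np.ndarray) -> MinMaxScaler:
    A = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    return MinMaxScaler(lo=float(A.min()), hi=float(A.max()))


def minmax_apply(scaler: MinMaxScaler, X: FeatureMatrix | np.ndarray):
    A = X.X if isinstance(X, FeatureMatrix) else np.asarray(X, dtype=float)
    span = scaler.hi - scaler.lo
    if span == 0:
        span = 1.0
    Z = 2.0 * (A - scaler.lo) / span - 1.0
    if isinstance(X, FeatureMatrix):
        return FeatureMatrix(ids=list(X.ids), X=Z, y=X.y, stage=X.stage)
    return Z
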