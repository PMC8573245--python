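"""Local-hyperplane nearest-neighbor classification (HKNN and its kernelized form).

For a query ``x`` and each class ``c``, the k nearest same-class training
points ``N_i^c`` define a local hyperplane through their centroid
``Nbar_c`` spanned by the difference vectors ``V_i^c = N_i^c - Nbar_c``:

    LH_c = { Nbar_c + sum_i alpha_i V_i^c }

The coefficients minimize the ridge-penalized squared distance

    ||x - Nbar_c - sum_i alpha_i V_i^c||^2 + lambda * ||alpha||^2,

whose normal equations are ``(V V^T + lambda I) alpha = V (x - Nbar_c)``
with ``V`` the k x d matrix of difference rows. The class decision uses
the *unpenalized* residual distance; the query is assigned to the class
whose local hyperplane is nearest.

The kernelized variant (KHKNN) maps the centered query ``xbar = x - Nbar_c``
and the difference vectors through a feature map phi and solves the same
system on the Gram matrix:

    alpha = (K(V, V) + lambda I)^{-1} K(V, xbar)
    dist^2 = K(xbar, xbar) - 2 alpha . K(V, xbar) + alpha . K(V, V) alpha

Centering happens in input space *before* the kernel map; this is part of
the model definition, not an implementation shortcut, and differs from
centering in feature space.

Neighbors are found by Euclidean distance in (optionally pre-standardized)
input space on both paths. Ties: equidistant neighbors by ascending
training-row index; equal class distances by ascending class id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .exceptions import ConfigError, DataError, InputError
from .kernels import KernelSpec, cross_kernel, gram_matrix, kernel_value

__all__ = [
    "FeatureTable",
    "NeighborSet",
    "HyperplaneSolution",
    "DistanceProfile",
    "find_class_neighbors",
    "solve_alpha_linear",
    "solve_alpha_kernel",
    "classify",
    "classify_batch",
]

logger = logging.getLogger(__name__)

_KINDS = ("binary", "continuous")


@dataclass
class FeatureTable:
    """An n x d feature matrix with per-column metadata and integer labels.

    ``feature_kinds`` marks each column ``"binary"`` (values in {0, 1}) or
    ``"continuous"``; standardization in the evaluation layer leaves binary
    columns untouched. Labels are class ids ``0..C-1``.
    """

    values: np.ndarray
    feature_names: list[str]
    feature_kinds: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise InputError(f"values must be 2-D, got shape {self.values.shape}")
        n, d = self.values.shape
        if n < 2 or d < 1:
            raise InputError(f"need n >= 2 samples and d >= 1 features, got {n} x {d}")
        if not np.all(np.isfinite(self.values)):
            raise InputError("values contain non-finite entries")
        if len(self.feature_names) != d or len(self.feature_kinds) != d:
            raise InputError("feature_names/feature_kinds length must match column count")
        for kind, name in zip(self.feature_kinds, self.feature_names):
            if kind not in _KINDS:
                raise InputError(f"unknown feature kind {kind!r} for column {name!r}")
        for j, (kind, name) in enumerate(zip(self.feature_kinds, self.feature_names)):
            if kind == "binary" and not np.isin(self.values[:, j], (0.0, 1.0)).all():
                raise InputError(f"binary column {name!r} contains values outside {{0, 1}}")
        if self.labels.shape != (n,):
            raise InputError("labels must be a length-n vector")
        if not np.issubdtype(self.labels.dtype, np.integer):
            as_int = self.labels.astype(int)
            if not np.array_equal(as_int, self.labels):
                raise InputError("labels must be integers")
            self.labels = as_int
        if self.labels.min() < 0:
            raise InputError("labels must be nonnegative class ids")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max()) + 1

    def require_all_classes(self) -> None:
        """Raise unless every class id in 0..C-1 is present."""
        present = np.unique(self.labels)
        expected = np.arange(self.n_classes)
        if not np.array_equal(present, expected):
            missing = sorted(set(expected) - set(present))
            raise DataError(f"class ids {missing} have no samples")


@dataclass
class NeighborSet:
    """The k nearest same-class neighbors of a query, centered.

    ``diffs`` rows are ``V_i^c = N_i^c - Nbar_c`` and sum to zero. ``k`` is
    the *effective* neighbor count, capped at the class size when the class
    has fewer members than requested.
    """

    class_id: int
    neighbors: np.ndarray
    centroid: np.ndarray
    diffs: np.ndarray
    k: int
    k_capped: bool = False


@dataclass
class HyperplaneSolution:
    """Ridge solution for one class's local hyperplane.

    ``decision_distance_sq`` is the unpenalized residual used by the class
    decision rule; ``objective_value`` additionally includes the ridge term
    ``lambda * ||alpha||^2``. ``singular`` flags a rank-deficient system at
    ``lambda = 0`` resolved by the minimum-norm solution.
    """

    alpha: np.ndarray
    lambda_reg: float
    decision_distance_sq: float
    objective_value: float
    singular: bool = False


@dataclass
class DistanceProfile:
    """Per-class squared hyperplane distances and the argmin class."""

    per_class_distance_sq: np.ndarray
    predicted_class: int
    effective_k: list[int] = field(default_factory=list)


def find_class_neighbors(query, table: FeatureTable, class_id: int, k: int) -> NeighborSet:
    """The k rows of ``class_id`` nearest to ``query`` by Euclidean distance.

    Equidistant candidates are taken in ascending training-row order. If the
    class has m < k members, all m are returned and ``k_capped`` is set.
    """
    q = np.asarray(query, dtype=float)
    if q.shape != (table.n_features,):
        raise InputError(
            f"query dimension {q.shape} does not match table dimension {table.n_features}"
        )
    if k < 1:
        raise InputError(f"k must be >= 1, got {k}")
    mask = table.labels == class_id
    if not mask.any():
        raise DataError(f"class {class_id} has no samples")
    rows = table.values[mask]
    m = rows.shape[0]
    diff = rows - q[None, :]
    d2 = np.einsum("ij,ij->i", diff, diff)
    # stable sort keeps ascending within-class (hence training-row) order on ties
    order = np.argsort(d2, kind="stable")
    eff_k = min(k, m)
    chosen = rows[order[:eff_k]]
    centroid = chosen.mean(axis=0)
    return NeighborSet(
        class_id=int(class_id),
        neighbors=chosen,
        centroid=centroid,
        diffs=chosen - centroid[None, :],
        k=eff_k,
        k_capped=eff_k < k,
    )


def _refined_spd_solve(A: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Cholesky solve with one iterative-refinement step if the residual is large."""
    c, low = scipy.linalg.cho_factor(A)
    x = scipy.linalg.cho_solve((c, low), rhs)
    r = rhs - A @ x
    if np.linalg.norm(r) > 1e-10 * max(1.0, np.linalg.norm(rhs)):
        x = x + scipy.linalg.cho_solve((c, low), r)
    return x


def solve_alpha_linear(nbrs: NeighborSet, query, lambda_reg: float) -> HyperplaneSolution:
    """Solve the linear-path normal equations ``(V V^T + lambda I) alpha = V xbar``."""
    q = np.asarray(query, dtype=float)
    if q.shape != (nbrs.neighbors.shape[1],):
        raise InputError("query dimension does not match neighbor dimension")
    if lambda_reg < 0:
        raise ConfigError(f"lambda_reg must be >= 0, got {lambda_reg}")
    V = nbrs.diffs
    xbar = q - nbrs.centroid
    A = V @ V.T + lambda_reg * np.eye(nbrs.k)
    rhs = V @ xbar
    singular = False
    if lambda_reg > 0:
        alpha = _refined_spd_solve(A, rhs)
    else:
        try:
            alpha = _refined_spd_solve(A, rhs)
        except np.linalg.LinAlgError:
            alpha = None
        except scipy.linalg.LinAlgError:
            alpha = None
        if alpha is None:
            alpha, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            singular = True
            logger.debug("singular neighbor system at lambda=0; minimum-norm solution used")
    resid = xbar - V.T @ alpha
    dist = float(resid @ resid)
    return HyperplaneSolution(
        alpha=alpha,
        lambda_reg=float(lambda_reg),
        decision_distance_sq=dist,
        objective_value=dist + lambda_reg * float(alpha @ alpha),
        singular=singular,
    )


def solve_alpha_kernel(
    nbrs: NeighborSet, query, kernel: KernelSpec, lambda_reg: float
) -> HyperplaneSolution:
    """Solve the kernelized system ``alpha = (K(V,V) + lambda I)^{-1} K(V, xbar)``.

    The centered query ``xbar = x - Nbar_c`` is formed in input space before
    any kernel evaluation. Requires ``lambda_reg > 0`` so the regularized
    Gram system is guaranteed nonsingular.
    """
    if lambda_reg <= 0:
        raise ConfigError(f"kernel path requires lambda_reg > 0, got {lambda_reg}")
    q = np.asarray(query, dtype=float)
    if q.shape != (nbrs.neighbors.shape[1],):
        raise InputError("query dimension does not match neighbor dimension")
    xbar = q - nbrs.centroid
    G = gram_matrix(nbrs.diffs, kernel)
    kappa = cross_kernel(nbrs.diffs, xbar, kernel)
    alpha = _refined_spd_solve(G + lambda_reg * np.eye(nbrs.k), kappa)
    kxx = kernel_value(xbar, xbar, kernel)
    dist = kxx - 2.0 * float(alpha @ kappa) + float(alpha @ (G @ alpha))
    if dist < 0.0:
        logger.debug("clamping negative kernel decision distance %.3e to 0", dist)
        dist = 0.0
    return HyperplaneSolution(
        alpha=alpha,
        lambda_reg=float(lambda_reg),
        decision_distance_sq=dist,
        objective_value=dist + lambda_reg * float(alpha @ alpha),
    )


def classify(
    query,
    table: FeatureTable,
    k: int,
    kernel: KernelSpec | None,
    lambda_reg: float,
) -> DistanceProfile:
    """Assign ``query`` to the class whose local hyperplane is nearest.

    ``kernel=None`` selects the linear (HKNN) path; a :class:`KernelSpec`
    selects the kernelized path. Exact distance ties go to the smallest
    class id.
    """
    table.require_all_classes()
    if table.n_classes < 2:
        raise DataError("classification requires at least 2 classes")
    C = table.n_classes
    dists = np.empty(C)
    eff_ks: list[int] = []
    for c in range(C):
        nbrs = find_class_neighbors(query, table, c, k)
        if kernel is None:
            sol = solve_alpha_linear(nbrs, query, lambda_reg)
        else:
            sol = solve_alpha_kernel(nbrs, query, kernel, lambda_reg)
        dists[c] = sol.decision_distance_sq
        eff_ks.append(nbrs.k)
    return DistanceProfile(
        per_class_distance_sq=dists,
        predicted_class=int(np.argmin(dists)),  # argmin ties -> smallest class id
        effective_k=eff_ks,
    )


def classify_batch(
    queries,
    table: FeatureTable,
    k: int,
    kernel: KernelSpec | None,
    lambda_reg: float,
) -> list[DistanceProfile]:
    """Elementwise :func:`classify` over the rows of ``queries``, order preserved."""
    Q = np.asarray(queries, dtype=float)
    if Q.size == 0:
        return []
    if Q.ndim == 1:
        Q = Q[None, :]
    return [classify(q, table, k, kernel, lambda_reg) for q in Q]
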