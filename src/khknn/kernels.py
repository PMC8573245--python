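"""Kernel functions and Gram-matrix construction.

Two kernel families are supported: the Gaussian radial basis function

    K(x_i, x_j) = exp(-gamma * ||x_i - x_j||^2)

with bandwidth ``gamma > 0``, and the plain linear kernel ``x_i . x_j``.
Squared distances are accumulated from explicit coordinate differences
(never via the ||a||^2 + ||b||^2 - 2 a.b expansion), so near-identical
vectors cannot produce a negative squared distance through cancellation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigError, InputError

__all__ = ["KernelSpec", "kernel_value", "gram_matrix", "cross_kernel"]

_FAMILIES = ("rbf", "linear")


@dataclass(frozen=True)
class KernelSpec:
    """A kernel family plus its hyperparameters.

    Parameters
    ----------
    family : {"rbf", "linear"}
        Kernel family. The RBF kernel is ``exp(-gamma * ||a - b||^2)``.
    gamma : float, optional
        RBF bandwidth; must be strictly positive. Ignored (and may be left
        ``None``) for the linear kernel. ``gamma = 0`` would make every
        kernel value 1 and the Gram matrix degenerate, so it is rejected.
    """

    family: str
    gamma: float | None = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ConfigError(
                f"unknown kernel family {self.family!r}; expected one of {_FAMILIES}"
            )
        if self.family == "rbf":
            if self.gamma is None or not np.isfinite(self.gamma) or self.gamma <= 0:
                raise ConfigError(
                    f"rbf kernel requires gamma > 0, got {self.gamma!r}"
                )


def _as_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or v.size < 1:
        raise InputError(f"{name} must be a 1-D vector of length >= 1, got shape {v.shape}")
    return v


def _as_matrix(vectors, name: str) -> np.ndarray:
    try:
        m = np.asarray(vectors, dtype=float)
    except ValueError as exc:  # ragged nested sequence
        raise InputError(f"{name} must be a rectangular list of equal-length vectors") from exc
    if m.ndim == 1:
        m = m[None, :]
    if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
        raise InputError(f"{name} must contain >= 1 vectors of dimension >= 1, got shape {m.shape}")
    return m


def kernel_value(xi, xj, spec: KernelSpec) -> float:
    """Evaluate ``K(xi, xj)`` for a single pair of vectors."""
    a = _as_vector(xi, "xi")
    b = _as_vector(xj, "xj")
    if a.shape != b.shape:
        raise InputError(f"dimension mismatch: {a.shape[0]} vs {b.shape[0]}")
    if spec.family == "linear":
        return float(a @ b)
    diff = a - b
    return float(np.exp(-spec.gamma * (diff @ diff)))


def gram_matrix(vectors, spec: KernelSpec) -> np.ndarray:
    """Pairwise kernel matrix of a set of vectors.

    Symmetric by construction; for the RBF kernel the diagonal is exactly 1
    and the matrix is positive semidefinite.
    """
    V = _as_matrix(vectors, "vectors")
    if spec.family == "linear":
        return V @ V.T
    diff = V[:, None, :] - V[None, :, :]
    sq = np.einsum("ijk,ijk->ij", diff, diff)
    return np.exp(-spec.gamma * sq)


def cross_kernel(vectors, query, spec: KernelSpec) -> np.ndarray:
    """Vector of kernel values between each row of ``vectors`` and ``query``."""
    V = _as_matrix(vectors, "vectors")
    q = _as_vector(query, "query")
    if V.shape[1] != q.shape[0]:
        raise InputError(
            f"query dimension {q.shape[0]} does not match vectors dimension {V.shape[1]}"
        )
    if spec.family == "linear":
        return V @ q
    diff = V - q[None, :]
    sq = np.einsum("ij,ij->i", diff, diff)
    return np.exp(-spec.gamma * sq)
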