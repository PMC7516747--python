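"""Shared mathematical primitives of the interaction-margin framework.

This module defines the quadratic-Manhattan measurement, the neighbor
probability container, hit/miss entropies, the sample-weight container and
the entropy-regularized margin cost that every learner in the package
minimizes.

Notation
--------
For a labeled sample ``z_n = (x_n, y_n)`` the *hit set* ``H_n`` holds the
indices of same-class samples (excluding ``n``) and the *miss set* ``M_n``
the indices of opposite-class samples.  ``alpha[n][k]`` is the probability
that hit ``H_n[k]`` is the nearest hit of ``n``; ``beta`` plays the same
role for misses.  The interaction weight matrix ``W`` is symmetric with unit
Frobenius norm; its diagonal carries main effects and its off-diagonal
entries pairwise feature interactions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import LabeledDataset

__all__ = [
    "InteractionWeightMatrix",
    "NeighborWeights",
    "SampleWeights",
    "quad_manhattan",
    "pairwise_quad_manhattan",
    "hit_miss_entropies",
    "cost",
]

_SYM_TOL = 1e-12
_NORM_TOL = 1e-10
_PSD_TOL = -1e-10


@dataclass
class InteractionWeightMatrix:
    """Symmetric unit-Frobenius A x A matrix of feature(-pair) weights."""

    W: np.ndarray
    pruned: bool = False

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2 or self.W.shape[0] != self.W.shape[1]:
            raise ValueError("W must be square")
        if np.max(np.abs(self.W - self.W.T)) >= _SYM_TOL:
            raise ValueError("W must be symmetric")
        nrm = np.linalg.norm(self.W)
        if abs(nrm - 1.0) > _NORM_TOL:
            raise ValueError(f"W must have unit Frobenius norm, got {nrm}")

    @property
    def n_features(self) -> int:
        return self.W.shape[0]

    def is_psd(self, tol: float = _PSD_TOL) -> bool:
        return float(np.linalg.eigvalsh(self.W)[0]) >= tol


@dataclass
class NeighborWeights:
    """Per-instance hit/miss probability distributions.

    ``alpha[n]`` is aligned with ``hit_sets[n]`` and sums to one; likewise
    ``beta[n]`` with ``miss_sets[n]``.  Stored dense per instance over the
    hit/miss index lists, never as full N x N matrices.
    """

    hit_sets: list[np.ndarray]
    miss_sets: list[np.ndarray]
    alpha: list[np.ndarray]
    beta: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.alpha)
        if not (len(self.beta) == len(self.hit_sets) == len(self.miss_sets) == n):
            raise ValueError("inconsistent per-instance list lengths")
        for i in range(n):
            for name, idx, p in (
                ("alpha", self.hit_sets[i], self.alpha[i]),
                ("beta", self.miss_sets[i], self.beta[i]),
            ):
                if len(idx) == 0:
                    raise ValueError(
                        f"instance {i} has an empty {'hit' if name == 'alpha' else 'miss'} set"
                    )
                if len(idx) != len(p):
                    raise ValueError("probability vector does not match index set")
                # zeros are tolerated: the softmin underflows to an exact
                # one-hot in the small-sigma limit
                if np.any(np.asarray(p) < 0):
                    raise ValueError(f"{name} entries must be nonnegative")
                if abs(float(np.sum(p)) - 1.0) > 1e-12:
                    raise ValueError(f"{name}[{i}] does not sum to one")

    @property
    def n_samples(self) -> int:
        return len(self.alpha)


@dataclass
class SampleWeights:
    """Nonnegative per-sample weights summing to one (boosting weights)."""

    D: np.ndarray

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if np.any(self.D < 0):
            raise ValueError("sample weights must be nonnegative")
        if abs(float(self.D.sum()) - 1.0) > 1e-12:
            raise ValueError("sample weights must sum to one")

    @classmethod
    def uniform(cls, n: int) -> "SampleWeights":
        return cls(np.full(n, 1.0 / n))


def neighbor_matrices(
    nw: NeighborWeights, n_samples: int
) -> tuple[np.ndarray, np.ndarray]:
    """Dense N x N views of ``alpha`` and ``beta`` (zeros off the sets).

    Convenience for vectorized accumulation; the per-instance lists remain
    the canonical storage.
    """
    A = np.zeros((n_samples, n_samples))
    B = np.zeros((n_samples, n_samples))
    for n in range(n_samples):
        A[n, nw.hit_sets[n]] = nw.alpha[n]
        B[n, nw.miss_sets[n]] = nw.beta[n]
    return A, B


def quad_manhattan(
    W: InteractionWeightMatrix | np.ndarray, xi: np.ndarray, xj: np.ndarray
) -> float:
    """Quadratic-Manhattan measurement ``|xi - xj|^T W |xi - xj|``.

    The element-wise absolute difference makes off-diagonal entries of ``W``
    act as coefficients of feature *pairs*, so ``W[a, b]`` directly measures
    the contribution of the interaction between features ``a`` and ``b``.
    Symmetric in its two vector arguments and zero when they coincide.
    """
    M = W.W if isinstance(W, InteractionWeightMatrix) else np.asarray(W, float)
    xi = np.asarray(xi, dtype=float)
    xj = np.asarray(xj, dtype=float)
    if xi.shape != xj.shape or xi.ndim != 1 or xi.shape[0] != M.shape[0]:
        raise ValueError("vector length must match the weight matrix dimension")
    d = np.abs(xi - xj)
    return float(d @ M @ d)


def pairwise_quad_manhattan(
    W: InteractionWeightMatrix | np.ndarray,
    X: np.ndarray,
    Y: np.ndarray | None = None,
) -> np.ndarray:
    """All-pairs quadratic-Manhattan measurements between rows of X and Y.

    Returns the matrix ``Q[i, j] = |X_i - Y_j|^T W |X_i - Y_j|``.  Used by
    every optimizer step; vectorized over pairs.
    """
    M = W.W if isinstance(W, InteractionWeightMatrix) else np.asarray(W, float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = X if Y is None else np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[1] != M.shape[0] or Y.shape[1] != M.shape[0]:
        raise ValueError("feature count must match the weight matrix dimension")
    D = np.abs(X[:, None, :] - Y[None, :, :])  # (nX, nY, A)
    offdiag = M - np.diag(np.diag(M))
    if not offdiag.any():
        # diagonal W: O(N^2 A) instead of O(N^2 A^2)
        return (D * D) @ np.diag(M)
    return np.einsum("ija,ab,ijb->ij", D, M, D, optimize=True)


def hit_miss_entropies(nw: NeighborWeights, n: int) -> tuple[float, float]:
    """Shannon entropies (natural log) of instance ``n``'s hit and miss
    distributions.

    High hit entropy means same-class neighbors are spread evenly around the
    instance (a stable margin); low miss entropy means the opposite-class
    mass is concentrated.  Both values lie in ``[0, log |set|]``.
    """
    return _entropy(nw.alpha[n]), _entropy(nw.beta[n])


def _entropy(p: np.ndarray) -> float:
    p = np.asarray(p, dtype=float)
    # entries are validated > 0, but pruned-to-tiny values can underflow
    return float(-np.sum(np.where(p > 0, p * np.log(np.maximum(p, 1e-300)), 0.0)))


def cost(
    data: LabeledDataset,
    W: InteractionWeightMatrix | np.ndarray,
    nw: NeighborWeights,
    sigma: float,
    D: SampleWeights | None = None,
) -> float:
    """Entropy-regularized margin cost.

    ``sum_n D_n [ sum_h alpha q(x_n, x_h) - sum_m beta q(x_n, x_m) ]
    + sigma * sum_n D_n [ E_miss(n) - E_hit(n) ]``

    Minimizing the first term maximizes the probabilistic margin (small hit
    distances, large miss distances); the second term trades a high hit
    entropy against a low miss entropy, stabilizing the margin.  ``D``
    defaults to uniform ``1/N``, which equals the unweighted cost up to a
    global ``1/N`` factor and so leaves every argmin unchanged.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    n_samples = data.n_samples
    if D is None:
        D = SampleWeights.uniform(n_samples)
    Q = pairwise_quad_manhattan(W, data.features)
    A, B = neighbor_matrices(nw, n_samples)
    margin = np.einsum("nj,nj->n", A - B, Q)
    ent = np.array(
        [_entropy(nw.beta[n]) - _entropy(nw.alpha[n]) for n in range(n_samples)]
    )
    return float(D.D @ (margin + sigma * ent))
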