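"""The original Relief feature-weighting algorithm and its closed form.

Relief scores each feature by contrasting, per sampled instance, the
coordinate-wise difference to the nearest same-class sample (nearest hit,
NH) against the difference to the nearest opposite-class sample (nearest
miss, NM).  Two faithful variants are provided:

* :func:`relief_iterative` — the classical online update with element-wise
  *squared* differences, as the procedure is usually printed;
* :func:`relief_direction` + :func:`relief_closed_form` — the convex
  reformulation with element-wise *absolute* differences, whose constrained
  minimizer is the truncated-and-normalized direction
  ``w = (-u)_+ / ||(-u)_+||_2``.

The two use different difference powers and are deliberately not reconciled;
the closed form is also the diagonal limit of the interaction-matrix update
in :mod:`immigrate.optimizer`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import LabeledDataset

__all__ = [
    "FeatureWeightVector",
    "nearest_hit_miss",
    "relief_direction",
    "relief_closed_form",
    "relief_iterative",
]


@dataclass
class FeatureWeightVector:
    """Per-feature relevance weights.

    The closed-form variant yields nonnegative unit-L2 weights; the
    iterative variant's entries are unconstrained in sign.
    """

    w: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ValueError("weights must be a vector")


def nearest_hit_miss(data: LabeledDataset, n: int) -> tuple[int, int]:
    """Indices of the Euclidean nearest hit and nearest miss of sample ``n``.

    Ties are broken toward the lowest index.
    """
    X = data.features
    hits = data.hit_indices(n)
    misses = data.miss_indices(n)
    if hits.size == 0:
        raise ValueError(f"sample {n} has no hit (singleton class)")
    if misses.size == 0:
        raise ValueError(f"sample {n} has no miss")
    d_hit = np.linalg.norm(X[hits] - X[n], axis=1)
    d_miss = np.linalg.norm(X[misses] - X[n], axis=1)
    # argmin returns the first minimum; hits/misses are sorted ascending
    return int(hits[np.argmin(d_hit)]), int(misses[np.argmin(d_miss)])


def relief_direction(
    data: LabeledDataset, sample_indices: np.ndarray | list[int] | None = None
) -> np.ndarray:
    """Accumulated direction ``u = sum_n |x_n - NH(x_n)| - |x_n - NM(x_n)|``.

    A negative component marks a feature along which hits sit closer than
    misses, i.e. a feature that favors separation.
    """
    if sample_indices is None:
        sample_indices = np.arange(data.n_samples)
    X = data.features
    u = np.zeros(data.n_features)
    for n in np.asarray(sample_indices, dtype=int):
        h, m = nearest_hit_miss(data, n)
        u += np.abs(X[n] - X[h]) - np.abs(X[n] - X[m])
    return u


def relief_closed_form(u: np.ndarray) -> FeatureWeightVector:
    """Minimizer of the Relief cost over the nonnegative unit sphere.

    Truncates the negative components of ``-u`` to zero and L2-normalizes.
    Raises when no component of ``u`` is negative — no feature favors
    separation and the constrained problem has no informative minimizer.
    """
    u = np.asarray(u, dtype=float)
    pos = np.maximum(-u, 0.0)
    nrm = np.linalg.norm(pos)
    if nrm == 0.0:
        raise ValueError("no feature favors separation: all components of -u truncate to zero")
    return FeatureWeightVector(pos / nrm)


def relief_iterative(
    data: LabeledDataset, M: int, seed: int = 0
) -> FeatureWeightVector:
    """Classical online Relief with squared coordinate differences.

    Runs ``w <- w - (x_i - NH)^2 / M + (x_i - NM)^2 / M`` over ``M``
    sampled instances.  When ``M == N`` every instance is visited exactly
    once (sampling without replacement); otherwise instances are drawn
    uniformly with replacement.  Fully seeded.
    """
    if M > data.n_samples:
        raise ValueError("M cannot exceed the number of samples")
    rng = np.random.default_rng(seed)
    w = np.zeros(data.n_features)
    if M == 0:
        return FeatureWeightVector(w)
    if M == data.n_samples:
        order = rng.permutation(data.n_samples)
    else:
        order = rng.integers(0, data.n_samples, size=M)
    X = data.features
    for n in order:
        h, m = nearest_hit_miss(data, int(n))
        w = w - (X[n] - X[h]) ** 2 / M + (X[n] - X[m]) ** 2 / M
    return FeatureWeightVector(w)
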