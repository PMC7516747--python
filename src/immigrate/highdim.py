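"""Two-stage fitting for high-dimensional data.

Modelling every feature pair costs O(A^2) weights, which is wasteful when
most features are irrelevant (e.g. gene-expression tables).  The two-stage
procedure first runs a *diagonal-restricted* variant of the interaction
optimizer — main effects only, no interactions — to obtain a nonnegative
per-feature weight vector, screens out features whose weight falls at or
below a threshold (default ``2/A``), and then fits the full interaction
model on the surviving features, initializing the weight matrix from the
screened diagonal weights.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InteractionWeightMatrix, cost
from .data import LabeledDataset
from .optimizer import (
    DegenerateSpectrumError,
    ImmigrateModel,
    accumulate_sigma_diagonal,
    fit_immigrate,
    update_neighbor_weights,
)
from .preprocess import Scaler
from .relief import FeatureWeightVector

__all__ = [
    "ScreeningResult",
    "fit_diagonal_variant",
    "prescreen_features",
    "fit_im4e_immigrate",
]


@dataclass
class ScreeningResult:
    """Outcome of diagonal-weight feature screening."""

    weights: FeatureWeightVector
    kept: np.ndarray  # indices with weight strictly above threshold
    threshold: float

    @property
    def discarded(self) -> np.ndarray:
        a = self.weights.w.shape[0]
        mask = np.ones(a, dtype=bool)
        mask[self.kept] = False
        return np.flatnonzero(mask)


def fit_diagonal_variant(
    data: LabeledDataset,
    sigma: float = 1.0,
    max_iter: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
    standardize: bool = True,
    scaler: Scaler | None = None,
) -> FeatureWeightVector:
    """Margin optimizer restricted to a diagonal weight matrix.

    Alternates the usual softmin probability update (with distances taken
    under the current diagonal ``W``) with the diagonal closed form
    ``w = (-mu)_+ / ||(-mu)_+||_2`` applied to the diagonal of the scatter
    matrix.  Returns nonnegative per-feature weights with unit L2 norm —
    main effects only, used for screening and initialization.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    data.require_neighbors()
    a = data.n_features
    if standardize:
        scaler = Scaler.fit(data.features, warn=False)
        X = scaler.transform(data.features)
    else:
        X = data.features
    std_data = LabeledDataset(X, data.labels, feature_names=list(data.feature_names))

    rng = np.random.default_rng(seed)
    w = rng.random(a) + 1e-3
    w /= np.linalg.norm(w)

    prev_cost = None
    for t in range(1, max_iter + 1):
        W = InteractionWeightMatrix(np.diag(w / np.linalg.norm(w)))
        nw = update_neighbor_weights(std_data, W, sigma)
        mu = accumulate_sigma_diagonal(std_data, nw)
        pos = np.maximum(-mu, 0.0)
        nrm = np.linalg.norm(pos)
        if nrm == 0.0:
            if t == 1:
                raise DegenerateSpectrumError(
                    "all diagonal scatter entries nonnegative; no descent direction"
                )
            break
        w = pos / nrm
        c = cost(std_data, np.diag(w), nw, sigma)
        if prev_cost is not None and abs(c - prev_cost) < tol:
            break
        prev_cost = c
    return FeatureWeightVector(w)


def prescreen_features(
    weights: FeatureWeightVector, threshold: float | None = None
) -> ScreeningResult:
    """Keep features whose screening weight is strictly above ``threshold``.

    ``threshold`` defaults to ``2/A`` with ``A`` the original feature
    count.  Discarded indices remain available on the result so a caller
    can add features back.
    """
    w = weights.w
    if threshold is None:
        threshold = 2.0 / w.shape[0]
    kept = np.flatnonzero(w > threshold)
    if kept.size == 0:
        raise ValueError(
            f"no feature weight exceeds the screening threshold {threshold}; "
            "lower the threshold"
        )
    return ScreeningResult(weights=weights, kept=kept, threshold=threshold)


def fit_im4e_immigrate(
    data: LabeledDataset,
    sigma: float = 1.0,
    max_iter: int = 10,
    tol: float = 1e-4,
    prune: bool = False,
    seed: int = 0,
    screen_threshold: float | None = None,
) -> ImmigrateModel:
    """Screened two-stage fit: diagonal screening, then full interactions.

    Stage 1 learns diagonal weights on all features and screens at
    ``screen_threshold`` (default ``2/A``).  Stage 2 fits the full
    interaction model on the kept features only, starting from the
    (renormalized) diagonal of the kept screening weights.  The returned
    model records the kept indices so full-width queries are projected
    correctly at prediction time.
    """
    scaler = Scaler.fit(data.features, warn=False)
    X = scaler.transform(data.features)
    std = LabeledDataset(X, data.labels, feature_names=list(data.feature_names))

    w = fit_diagonal_variant(
        std, sigma=sigma, max_iter=max_iter, tol=tol, seed=seed, standardize=False
    )
    screen = prescreen_features(w, screen_threshold)
    kept = screen.kept

    restricted = std.restrict_features(kept)
    diag0 = np.diag(w.w[kept])
    nrm = np.linalg.norm(diag0)
    if nrm == 0.0:  # unreachable given strict screening, kept defensively
        diag0 = np.eye(kept.size)
        nrm = np.linalg.norm(diag0)
    W0 = InteractionWeightMatrix(diag0 / nrm)

    model = fit_immigrate(
        restricted,
        sigma=sigma,
        max_iter=max_iter,
        tol=tol,
        prune=prune,
        seed=seed,
        W0=W0,
        standardize=False,
    )
    model.scaler = scaler
    model.kept_features = kept
    model.feature_names = list(data.feature_names)
    return model
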