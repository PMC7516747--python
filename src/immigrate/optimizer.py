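"""The interaction-margin optimizer: alternating closed-form updates.

The learner minimizes the entropy-regularized margin cost of
:func:`immigrate.core.cost` over the neighbor probabilities and a symmetric
unit-Frobenius interaction weight matrix ``W`` by alternating two exact
steps:

Step 1 (``W`` fixed)
    The stationary neighbor probabilities are softmin weights of the
    quadratic-Manhattan distances, ``alpha_{n,h} ∝ exp(-q(x_n, x_h)/sigma)``
    and analogously for ``beta`` over the miss set.  The cost is a local
    minimum in ``alpha`` and a local maximum in ``beta`` there (a saddle in
    the joint probability space).

Step 2 (probabilities fixed)
    The margin term becomes ``tr(W Sigma)`` for the accumulated
    hit-minus-miss scatter ``Sigma``; its minimizer over PSD unit-Frobenius
    matrices is spectral: keep the eigenvectors of the negative eigenvalues
    ``mu_i`` with coefficients ``eta_i = (-mu_i)_+ / ||(-mu)_+||_2``, giving
    ``W = sum_i eta_i psi_i psi_i^T`` and the optimum ``tr(W Sigma) =
    -||(-mu)_+||_2``.  When ``Sigma`` is diagonal this reduces exactly to
    the closed-form Relief weighting applied to the eigenvalue vector.

Iteration stops when the cost change falls below ``tol`` or after
``max_iter`` rounds; in practice a handful of rounds suffice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    InteractionWeightMatrix,
    NeighborWeights,
    SampleWeights,
    cost,
    neighbor_matrices,
    pairwise_quad_manhattan,
)
from .data import LabeledDataset
from .preprocess import Scaler

__all__ = [
    "SigmaSpectrum",
    "ImmigrateModel",
    "DegenerateSpectrumError",
    "update_neighbor_weights",
    "accumulate_sigma",
    "accumulate_sigma_diagonal",
    "solve_weight_matrix",
    "random_weight_matrix",
    "prune_weight_matrix",
    "fit_immigrate",
    "predict",
    "predict_batch",
    "tune_hyperparameters",
    "SIGMA_GRID",
]

#: sigma schedule used for tuning: halved from 4 while strictly above 0.2
SIGMA_GRID: tuple[float, ...] = (4.0, 2.0, 1.0, 0.5, 0.25)


class DegenerateSpectrumError(RuntimeError):
    """No negative eigenvalue: the margin term admits no descent direction."""


@dataclass
class SigmaSpectrum:
    """Hit-minus-miss scatter matrix with its eigendecomposition attached."""

    Sigma: np.ndarray
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray  # orthonormal columns, Sigma @ v[:, i] = mu_i v[:, i]


@dataclass
class ImmigrateModel:
    """Fitted interaction-margin classifier.

    The prediction rule needs the training instances, so the model stores
    the standardized training table together with the scaler that produced
    it.  ``kept_features`` maps model columns back to original feature
    indices when the model was fitted after feature screening.
    """

    W: InteractionWeightMatrix
    sigma: float
    training_features: np.ndarray  # standardized, restricted to kept_features
    training_labels: np.ndarray
    scaler: Scaler  # full-width scaler
    class_order: list
    n_iterations: int = 0
    cost_trace: list[float] = field(default_factory=list)
    pruned: bool = False
    degenerate_stop: bool = False
    kept_features: np.ndarray | None = None
    feature_names: list[str] | None = None

    @property
    def class_counts(self) -> dict:
        vals, cnt = np.unique(self.training_labels, return_counts=True)
        return dict(zip(vals.tolist(), cnt.tolist()))

    # -- serialization (JSON keeps the deliverable text-only) ---------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "W": self.W.W.tolist(),
            "sigma": self.sigma,
            "pruned": self.pruned,
            "degenerate_stop": self.degenerate_stop,
            "n_iterations": self.n_iterations,
            "cost_trace": list(map(float, self.cost_trace)),
            "scaler_mean": self.scaler.mean.tolist(),
            "scaler_scale": self.scaler.scale.tolist(),
            "class_order": [_jsonable(c) for c in self.class_order],
            "training_features": self.training_features.tolist(),
            "training_labels": [_jsonable(y) for y in self.training_labels],
            "kept_features": None
            if self.kept_features is None
            else [int(i) for i in self.kept_features],
            "feature_names": self.feature_names,
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ImmigrateModel":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            W=InteractionWeightMatrix(np.array(d["W"]), pruned=d["pruned"]),
            sigma=d["sigma"],
            training_features=np.array(d["training_features"], dtype=float),
            training_labels=np.array(d["training_labels"]),
            scaler=Scaler(
                mean=np.array(d["scaler_mean"], dtype=float),
                scale=np.array(d["scaler_scale"], dtype=float),
            ),
            class_order=d["class_order"],
            n_iterations=d["n_iterations"],
            cost_trace=d["cost_trace"],
            pruned=d["pruned"],
            degenerate_stop=d["degenerate_stop"],
            kept_features=None
            if d["kept_features"] is None
            else np.array(d["kept_features"], dtype=int),
            feature_names=d.get("feature_names"),
        )


def _jsonable(v):
    return v.item() if isinstance(v, np.generic) else v


def _softmax_neg(q: np.ndarray, sigma: float) -> np.ndarray:
    """Softmin weights exp(-q/sigma) normalized, max-shifted against overflow."""
    z = -np.asarray(q, dtype=float) / sigma
    z -= z.max()
    e = np.exp(z)
    return e / e.sum()


def update_neighbor_weights(
    data: LabeledDataset,
    W: InteractionWeightMatrix | np.ndarray,
    sigma: float,
) -> NeighborWeights:
    """Step-1 closed form: softmin hit/miss probabilities under ``q``.

    ``alpha_{n,h} = exp(-q(x_n,x_h)/sigma) / sum_{h'} exp(-q(x_n,x_h')/sigma)``
    and the analogue for ``beta`` over the miss set.  Exponentials are
    max-shifted, so no overflow occurs even for tiny ``sigma``.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    data.require_neighbors()
    Q = pairwise_quad_manhattan(W, data.features)
    y = data.labels
    same = y[:, None] == y[None, :]
    np.fill_diagonal(same, False)
    diff = ~(y[:, None] == y[None, :])

    def _masked_softmax(mask: np.ndarray) -> np.ndarray:
        Z = np.where(mask, -Q / sigma, -np.inf)
        Z -= Z.max(axis=1, keepdims=True)
        E = np.exp(Z)
        return E / E.sum(axis=1, keepdims=True)

    Af = _masked_softmax(same)
    Bf = _masked_softmax(diff)
    hit_sets, miss_sets, alpha, beta = [], [], [], []
    for n in range(data.n_samples):
        hs = np.flatnonzero(same[n])
        ms = np.flatnonzero(diff[n])
        hit_sets.append(hs)
        miss_sets.append(ms)
        alpha.append(Af[n, hs])
        beta.append(Bf[n, ms])
    return NeighborWeights(hit_sets, miss_sets, alpha, beta)


def accumulate_sigma(
    data: LabeledDataset,
    nw: NeighborWeights,
    D: SampleWeights | None = None,
) -> SigmaSpectrum:
    """Weighted hit-minus-miss scatter ``Sigma`` with eigendecomposition.

    ``Sigma = sum_n D_n (Sigma_{n,H} - Sigma_{n,M})`` where
    ``Sigma_{n,H} = sum_h alpha_{n,h} |x_n-x_h||x_n-x_h|^T`` and the miss
    part is analogous.  Uniform ``D`` reproduces the unweighted scatter up
    to a harmless ``1/N`` scale.
    """
    X = data.features
    n_samples, a = X.shape
    if D is None:
        D = SampleWeights.uniform(n_samples)
    Af, Bf = neighbor_matrices(nw, n_samples)
    R = D.D[:, None] * (Af - Bf)
    Dabs = np.abs(X[:, None, :] - X[None, :, :])
    S = np.einsum("nj,nja,njb->ab", R, Dabs, Dabs, optimize=True)
    if not np.all(np.isfinite(S)):
        raise FloatingPointError("non-finite scatter accumulation")
    S = (S + S.T) / 2.0
    mu, psi = np.linalg.eigh(S)
    return SigmaSpectrum(Sigma=S, eigenvalues=mu, eigenvectors=psi)


def accumulate_sigma_diagonal(
    data: LabeledDataset,
    nw: NeighborWeights,
    D: SampleWeights | None = None,
) -> np.ndarray:
    """Diagonal of the weighted hit-minus-miss scatter, in O(N^2 A).

    Equals ``np.diag(accumulate_sigma(...).Sigma)``; used by the
    diagonal-restricted variant where the full A x A scatter is never
    needed.
    """
    X = data.features
    n_samples = X.shape[0]
    if D is None:
        D = SampleWeights.uniform(n_samples)
    Af, Bf = neighbor_matrices(nw, n_samples)
    R = D.D[:, None] * (Af - Bf)
    sq = (X[:, None, :] - X[None, :, :]) ** 2
    diag = np.einsum("nj,nja->a", R, sq, optimize=True)
    if not np.all(np.isfinite(diag)):
        raise FloatingPointError("non-finite scatter accumulation")
    return diag


def solve_weight_matrix(spec: SigmaSpectrum) -> InteractionWeightMatrix:
    """Step-2 closed form: spectral minimizer of ``tr(W Sigma)``.

    Keeps the eigenvectors with negative eigenvalues, weighting them by
    ``eta_i = (-mu_i)_+ / ||(-mu)_+||_2``, so that ``W = sum eta_i psi_i
    psi_i^T`` is symmetric PSD with unit Frobenius norm and attains the
    minimum trace ``-||(-mu)_+||_2``.
    """
    eta = np.maximum(-spec.eigenvalues, 0.0)
    nrm = np.linalg.norm(eta)
    if nrm == 0.0:
        raise DegenerateSpectrumError(
            "all eigenvalues of Sigma are nonnegative; no descent direction"
        )
    eta /= nrm
    psi = spec.eigenvectors
    W = (psi * eta) @ psi.T
    W = (W + W.T) / 2.0
    W /= np.linalg.norm(W)  # guard rounding; analytically already 1
    return InteractionWeightMatrix(W)


def random_weight_matrix(a: int, rng: np.random.Generator) -> InteractionWeightMatrix:
    """Random symmetric PSD matrix with unit Frobenius norm (seeded start)."""
    B = rng.standard_normal((a, a))
    S = (B + B.T) / 2.0
    mu, psi = np.linalg.eigh(S)
    mu = np.maximum(mu, 0.0)
    if mu.max() == 0.0:  # essentially impossible, but keep the contract
        return InteractionWeightMatrix(np.eye(a) / np.sqrt(a))
    W = (psi * mu) @ psi.T
    W = (W + W.T) / 2.0
    return InteractionWeightMatrix(W / np.linalg.norm(W))


def prune_weight_matrix(
    W: InteractionWeightMatrix, threshold: float | None = None
) -> InteractionWeightMatrix:
    """Zero entries with ``|w| < threshold`` and renormalize.

    ``threshold`` defaults to ``1/A``.  Pruning is symmetric by
    construction; the survivor matrix is rescaled to unit Frobenius norm.
    """
    a = W.n_features
    if threshold is None:
        threshold = 1.0 / a
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    M = np.where(np.abs(W.W) < threshold, 0.0, W.W)
    nrm = np.linalg.norm(M)
    if nrm == 0.0:
        raise ValueError("pruning removed every entry; lower the threshold")
    return InteractionWeightMatrix(M / nrm, pruned=True)


def fit_immigrate(
    data: LabeledDataset,
    sigma: float = 1.0,
    max_iter: int = 10,
    tol: float = 1e-4,
    prune: bool = False,
    prune_threshold: float | None = None,
    D: SampleWeights | None = None,
    seed: int = 0,
    W0: InteractionWeightMatrix | None = None,
    standardize: bool = True,
    scaler: Scaler | None = None,
) -> ImmigrateModel:
    """Fit the interaction-margin classifier by alternating optimization.

    Parameters
    ----------
    data
        Training set; both classes need at least two members.
    sigma
        Temperature of the neighbor softmin and weight of the entropy
        trade-off.  Larger values spread probability mass over more
        neighbors.
    max_iter, tol
        Stop when the cost change drops below ``tol`` or after ``max_iter``
        alternating rounds.
    prune
        Apply weight pruning (threshold ``prune_threshold`` or ``1/A``) to
        the final matrix.
    D
        Optional sample weights (boosting); defaults to uniform.
    seed
        Seeds the random initial ``W``; ignored when ``W0`` is given.
    W0
        Optional initial weight matrix (used by the screened two-stage fit).
    standardize
        Fit a z-scoring scaler on ``data`` and train on the standardized
        features (the default).  Pass ``False`` with an explicit ``scaler``
        when the caller standardized already.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be at least 1")
    data.require_neighbors()

    if standardize:
        scaler = Scaler.fit(data.features, warn=False)
        X = scaler.transform(data.features)
    else:
        if scaler is None:
            scaler = Scaler(
                mean=np.zeros(data.n_features), scale=np.ones(data.n_features)
            )
        X = data.features
    std_data = LabeledDataset(
        X, data.labels, feature_names=list(data.feature_names)
    )

    rng = np.random.default_rng(seed)
    W = W0 if W0 is not None else random_weight_matrix(data.n_features, rng)

    trace: list[float] = []
    degenerate = False
    n_done = 0
    nw = None
    for t in range(1, max_iter + 1):
        nw = update_neighbor_weights(std_data, W, sigma)
        spec = accumulate_sigma(std_data, nw, D)
        try:
            W = solve_weight_matrix(spec)
        except DegenerateSpectrumError:
            if t == 1:
                raise
            degenerate = True
            break
        n_done = t
        trace.append(cost(std_data, W, nw, sigma, D))
        if t >= 2 and abs(trace[-1] - trace[-2]) < tol:
            break

    pruned = False
    if prune:
        W = prune_weight_matrix(W, prune_threshold)
        pruned = True

    counts = {c: int(np.sum(data.labels == c)) for c in data.classes}
    class_order = sorted(counts, key=lambda c: (-counts[c], list(data.classes).index(c)))
    return ImmigrateModel(
        W=W,
        sigma=sigma,
        training_features=X,
        training_labels=data.labels.copy(),
        scaler=scaler,
        class_order=list(class_order),
        n_iterations=n_done,
        cost_trace=trace,
        pruned=pruned,
        degenerate_stop=degenerate,
        feature_names=list(data.feature_names),
    )


def _class_scores(model: ImmigrateModel, Xq: np.ndarray) -> dict:
    """Per-class margin scores for standardized, restricted query rows."""
    scores = {}
    for c in model.class_order:
        idx = np.flatnonzero(model.training_labels == c)
        Q = pairwise_quad_manhattan(model.W, Xq, model.training_features[idx])
        z = -Q / model.sigma
        z -= z.max(axis=1, keepdims=True)
        E = np.exp(z)
        A = E / E.sum(axis=1, keepdims=True)
        scores[c] = np.einsum("qn,qn->q", A, Q)
    return scores


def _prepare_queries(model: ImmigrateModel, X_new: np.ndarray) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    full_width = model.scaler.mean.shape[0]
    if X_new.shape[1] == full_width:
        Xq = model.scaler.transform(X_new)
        if model.kept_features is not None:
            Xq = Xq[:, model.kept_features]
    elif (
        model.kept_features is not None
        and X_new.shape[1] == len(model.kept_features)
    ):
        # already restricted: standardize with the kept columns' statistics
        sub = Scaler(
            mean=model.scaler.mean[model.kept_features],
            scale=model.scaler.scale[model.kept_features],
        )
        Xq = sub.transform(X_new)
    else:
        raise ValueError(
            f"query width {X_new.shape[1]} matches neither the original "
            f"({full_width}) nor the restricted feature count"
        )
    return Xq


def predict_batch(model: ImmigrateModel, X_new: np.ndarray) -> np.ndarray:
    """Predicted labels for each row of ``X_new`` (raw, unstandardized)."""
    Xq = _prepare_queries(model, X_new)
    scores = _class_scores(model, Xq)
    c0, c1 = model.class_order[0], model.class_order[1]
    s0, s1 = scores[c0], scores[c1]
    # class_order starts with the larger class, which also wins exact ties
    out = np.where(s1 < s0, c1, c0)
    return np.asarray(out)


def predict(model: ImmigrateModel, x_new: np.ndarray):
    """Classify one instance; returns ``(label, per-class scores)``.

    The score of class ``c`` is the softmin-weighted mean quadratic-
    Manhattan distance from the query to the training members of ``c``; the
    smaller score wins (the class that maximizes the query's margin).  Exact
    ties go to the larger training class, then to the first label in
    ``class_order``.
    """
    x_new = np.asarray(x_new, dtype=float)
    if x_new.ndim != 1:
        raise ValueError("predict takes a single feature vector; see predict_batch")
    Xq = _prepare_queries(model, x_new)
    scores = _class_scores(model, Xq)
    flat = {c: float(s[0]) for c, s in scores.items()}
    c0, c1 = model.class_order[0], model.class_order[1]
    label = c1 if flat[c1] < flat[c0] else c0
    return label, flat


def tune_hyperparameters(
    data: LabeledDataset,
    folds: int = 5,
    seed: int = 0,
    sigmas: tuple[float, ...] = SIGMA_GRID,
    max_iter: int = 10,
    tol: float = 1e-4,
) -> tuple[float, bool]:
    """Pick ``(sigma, prune)`` by internal stratified k-fold accuracy.

    The grid crosses the halving schedule ``sigmas`` with pruning on/off.
    Ties in mean accuracy resolve toward the larger ``sigma``, then toward
    pruning off.  A fold whose training part loses a class triggers a
    re-split with a fresh sub-seed (at most 5 attempts).
    """
    from sklearn.model_selection import StratifiedKFold

    X, y = data.features, data.labels
    splits = None
    for attempt in range(5):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + attempt)
        cand = list(skf.split(X, y))
        ok = all(
            np.unique(y[tr]).size == 2
            and min(np.sum(y[tr] == c) for c in np.unique(y[tr])) >= 2
            for tr, _ in cand
        )
        if ok:
            splits = cand
            break
    if splits is None:
        raise ValueError("could not build stratified folds with both classes present")

    results = []
    for s in sigmas:
        for pr in (False, True):
            accs = []
            for k, (tr, te) in enumerate(splits):
                sub = LabeledDataset(X[tr], y[tr], feature_names=list(data.feature_names))
                try:
                    m = fit_immigrate(
                        sub, sigma=s, max_iter=max_iter, tol=tol,
                        prune=pr, seed=seed * 1000 + k,
                    )
                except (DegenerateSpectrumError, ValueError):
                    accs.append(0.0)
                    continue
                pred = predict_batch(m, X[te])
                accs.append(float(np.mean(pred == y[te])))
            results.append((float(np.mean(accs)), s, pr))
    # argmax accuracy; ties -> larger sigma, then prune off
    results.sort(key=lambda r: (-r[0], -r[1], r[2]))
    _, best_sigma, best_prune = results[0]
    return best_sigma, best_prune
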