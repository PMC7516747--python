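"""Boosted interaction-margin ensembles (AdaBoost with annealed sigma).

Each boosting round fits a sample-weighted interaction-margin base learner:
the round's sample weights ``D_t`` multiply both the margin and the entropy
terms of the cost, which leaves the per-instance softmin probability updates
unchanged and enters the weight-matrix update only through the weighted
scatter accumulation.  The softmin temperature ``sigma`` is annealed
geometrically from ``sigma_max`` to ``sigma_min`` over the schedule, so
early learners see smooth global structure and later ones focus locally.

Standard AdaBoost bookkeeping applies: a round with weighted training error
``eps_t >= 1/2`` (no better than chance) or ``eps_t == 0`` (no gradient for
reweighting) is discarded and retried with a fresh initialization; stored
rounds receive the vote ``alpha_t = 0.5 log((1 - eps_t)/eps_t)`` and the
misclassified samples are up-weighted by ``exp(alpha_t)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import SampleWeights
from .data import LabeledDataset
from .optimizer import (
    DegenerateSpectrumError,
    ImmigrateModel,
    _jsonable,
    fit_immigrate,
    predict_batch,
)

__all__ = ["BoostedEnsemble", "sigma_schedule", "fit_bim", "predict_bim"]


@dataclass
class BoostedEnsemble:
    """Sequence of fitted base learners with their AdaBoost votes."""

    learners: list[ImmigrateModel] = field(default_factory=list)
    votes: list[float] = field(default_factory=list)
    sigma_schedule_params: tuple[float, float, int] = (4.0, 0.2, 100)
    class_order: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.learners) != len(self.votes):
            raise ValueError("one vote per learner required")
        if any(v <= 0 for v in self.votes):
            raise ValueError("votes must be positive")

    def __len__(self) -> int:
        return len(self.learners)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "votes": list(map(float, self.votes)),
            "sigma_schedule_params": list(self.sigma_schedule_params),
            "class_order": [_jsonable(c) for c in self.class_order],
            "learners": [json.loads(m.to_json()) for m in self.learners],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BoostedEnsemble":
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        d = json.loads(text)
        return cls(
            learners=[ImmigrateModel.from_json(json.dumps(m)) for m in d["learners"]],
            votes=d["votes"],
            sigma_schedule_params=tuple(d["sigma_schedule_params"]),
            class_order=d["class_order"],
        )


def sigma_schedule(t: int, T: int, sigma_max: float, sigma_min: float) -> float:
    """Geometric annealing: ``sigma_t = max(sigma_min, sigma_max r^(t-1))``
    with ratio ``r = (sigma_min/sigma_max)^(1/T)``.

    Round 1 uses ``sigma_max``; round ``T + 1`` reaches ``sigma_min``
    exactly, after which the schedule stays flat.
    """
    if T <= 0:
        raise ValueError("T must be positive")
    if not (sigma_max >= sigma_min > 0):
        raise ValueError("need sigma_max >= sigma_min > 0")
    if t < 1:
        raise ValueError("iteration index starts at 1")
    if sigma_max == sigma_min:
        return sigma_max
    r = (sigma_min / sigma_max) ** (1.0 / T)
    return max(sigma_min, sigma_max * r ** (t - 1))


def fit_bim(
    data: LabeledDataset,
    T: int = 100,
    sigma_max: float = 4.0,
    sigma_min: float = 0.2,
    base_max_iter: int = 10,
    tol: float = 1e-4,
    seed: int = 0,
) -> BoostedEnsemble:
    """AdaBoost over sample-weighted interaction-margin base learners.

    Sample weights start uniform; each stored round fits a base learner at
    the scheduled ``sigma_t``, measures its weighted training error, and
    up-weights misclassified samples.  Discarded rounds (``eps_t >= 1/2``
    or ``eps_t == 0``) redraw the base initialization seed without
    advancing the sigma schedule; total attempts are capped at ``2T`` so
    the fit always terminates.  If no round is storable but a perfect
    learner (``eps_t == 0``) was seen, that learner alone is returned with
    vote 1.
    """
    data.require_neighbors()
    n = data.n_samples
    rng = np.random.default_rng(seed)
    D = np.full(n, 1.0 / n)
    learners: list[ImmigrateModel] = []
    votes: list[float] = []
    perfect: ImmigrateModel | None = None

    t_sched = 1  # schedule index advances only on stored rounds
    attempts = 0
    while len(learners) < T and attempts < 2 * T:
        attempts += 1
        sig = sigma_schedule(t_sched, T, sigma_max, sigma_min)
        sub_seed = int(rng.integers(0, 2**31 - 1))
        try:
            h = fit_immigrate(
                data,
                sigma=sig,
                max_iter=base_max_iter,
                tol=tol,
                D=SampleWeights(D),
                seed=sub_seed,
            )
        except DegenerateSpectrumError:
            continue
        pred = predict_batch(h, data.features)
        wrong = pred != data.labels
        eps = float(np.sum(D[wrong]))
        if eps == 0.0:
            perfect = h
            continue
        if eps >= 0.5:
            continue
        alpha = 0.5 * np.log((1.0 - eps) / eps)
        learners.append(h)
        votes.append(float(alpha))
        D = D * np.exp(alpha * wrong.astype(float))
        D /= D.sum()
        t_sched += 1

    if not learners:
        if perfect is not None:
            warnings.warn(
                "every base learner fit the training data perfectly; "
                "returning a single-learner ensemble",
                stacklevel=2,
            )
            learners, votes = [perfect], [1.0]
        else:
            raise RuntimeError(
                "boosting produced no usable base learner within the attempt cap"
            )

    counts = {c: int(np.sum(data.labels == c)) for c in data.classes}
    class_order = sorted(
        counts, key=lambda c: (-counts[c], list(data.classes).index(c))
    )
    return BoostedEnsemble(
        learners=learners,
        votes=votes,
        sigma_schedule_params=(sigma_max, sigma_min, T),
        class_order=list(class_order),
    )


def predict_bim(ensemble: BoostedEnsemble, x_new: np.ndarray):
    """Vote-weighted ensemble prediction.

    Returns a single label for a vector, or an array of labels for a
    matrix of queries.  Ties in total vote go to the larger training class.
    """
    if len(ensemble) == 0:
        raise ValueError("empty ensemble")
    X = np.atleast_2d(np.asarray(x_new, dtype=float))
    single = np.asarray(x_new).ndim == 1
    c0, c1 = ensemble.class_order[0], ensemble.class_order[1]
    tally0 = np.zeros(X.shape[0])
    tally1 = np.zeros(X.shape[0])
    for h, v in zip(ensemble.learners, ensemble.votes):
        pred = predict_batch(h, X)
        tally0 += v * (pred == c0)
        tally1 += v * (pred == c1)
    out = np.where(tally1 > tally0, c1, c0)  # ties favor the larger class c0
    return out[0] if single else np.asarray(out)
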