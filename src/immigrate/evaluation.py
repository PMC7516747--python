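"""Evaluation protocol: repeated stratified CV and win/tie/loss testing.

Two classifiers are compared on a dataset by running the *same* repeated
stratified 10-fold cross-validation (ten repetitions, i.e. 100 paired
trials), then applying a two-stage paired Student's t-test at significance
level 0.05: if the two-sided test cannot reject equal mean accuracy the
comparison is a *tie*; otherwise a one-sided test in the direction of the
observed mean difference decides *win* or *loss*.  Pairing requires that
both classifiers see identical fold assignments, which the harness enforces
by deriving folds from the shared seed and the labels only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .boosting import fit_bim, predict_bim
from .data import LabeledDataset
from .highdim import fit_im4e_immigrate
from .optimizer import fit_immigrate, predict_batch, tune_hyperparameters
from .preprocess import Scaler

__all__ = [
    "CVReport",
    "WTLResult",
    "standardize",
    "make_learner",
    "repeated_kfold_cv",
    "paired_wtl_test",
]


@dataclass
class CVReport:
    """Per-trial accuracies of a repeated stratified k-fold run."""

    accuracies: np.ndarray
    folds: int
    repetitions: int
    seed: int

    def __post_init__(self) -> None:
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if self.accuracies.shape != (self.folds * self.repetitions,):
            raise ValueError("need one accuracy per fold x repetition")
        if np.any((self.accuracies < 0) | (self.accuracies > 1)):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def mean_accuracy(self) -> float:
        return float(self.accuracies.mean())


@dataclass
class WTLResult:
    """Outcome of the two-stage paired comparison of A vs B."""

    outcome: str  # "win" | "tie" | "loss"
    two_sided_p: float
    one_sided_p: float | None = None
    mean_difference: float = 0.0


def standardize(
    train: LabeledDataset, apply_to: LabeledDataset
) -> LabeledDataset:
    """Z-score ``apply_to`` with per-feature statistics fitted on ``train``."""
    sc = Scaler.fit(train.features)
    return LabeledDataset(
        sc.transform(apply_to.features),
        apply_to.labels,
        sample_ids=apply_to.sample_ids,
        feature_names=list(apply_to.feature_names),
    )


def make_learner(spec: dict) -> Callable:
    """Build a fit-and-predict closure from a learner configuration.

    ``spec["method"]`` selects among ``immigrate`` (optionally with
    ``tune: true`` for nested sigma/pruning selection), ``bim``,
    ``im4e_immigrate`` and ``relief_1nn`` (Relief weighting followed by a
    weighted 1-nearest-neighbor vote, the classical usage).  Remaining keys
    are forwarded to the fitting function.  The closure signature is
    ``learner(train_dataset, X_test, seed) -> predicted labels``; every
    learner standardizes internally on its training fold.
    """
    spec = dict(spec)
    method = spec.pop("method", "immigrate")
    tune = bool(spec.pop("tune", False))

    if method == "immigrate":

        def learner(train: LabeledDataset, X_test: np.ndarray, seed: int):
            kw = dict(spec)
            if tune:
                sig, pr = tune_hyperparameters(train, seed=seed)
                kw["sigma"], kw["prune"] = sig, pr
            model = fit_immigrate(train, seed=seed, **kw)
            return predict_batch(model, X_test)

    elif method == "bim":

        def learner(train: LabeledDataset, X_test: np.ndarray, seed: int):
            ens = fit_bim(train, seed=seed, **spec)
            return predict_bim(ens, X_test)

    elif method == "im4e_immigrate":

        def learner(train: LabeledDataset, X_test: np.ndarray, seed: int):
            model = fit_im4e_immigrate(train, seed=seed, **spec)
            return predict_batch(model, X_test)

    elif method == "relief_1nn":
        from .relief import relief_closed_form, relief_direction

        def learner(train: LabeledDataset, X_test: np.ndarray, seed: int):
            sc = Scaler.fit(train.features, warn=False)
            Xtr = sc.transform(train.features)
            std = LabeledDataset(Xtr, train.labels)
            w = relief_closed_form(relief_direction(std)).w
            Xte = sc.transform(np.atleast_2d(X_test))
            d = np.abs(Xte[:, None, :] - Xtr[None, :, :]) @ w
            return train.labels[np.argmin(d, axis=1)]

    else:
        raise ValueError(f"unknown learner method {method!r}")

    return learner


def repeated_kfold_cv(
    data: LabeledDataset,
    learner_spec: dict | Callable,
    folds: int = 10,
    repetitions: int = 10,
    seed: int = 0,
) -> CVReport:
    """Repeated stratified k-fold accuracy of a configured learner.

    Fold membership depends only on the seed, the labels and N — never on
    feature values — so two learners evaluated with the same seed see
    identical train/test splits and their per-trial accuracies are paired.
    Standardization (and any nested tuning) happens inside each training
    fold.
    """
    learner = learner_spec if callable(learner_spec) else make_learner(learner_spec)
    X, y = data.features, data.labels
    accs = []
    for rep in range(repetitions):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        for k, (tr, te) in enumerate(skf.split(np.zeros_like(y, dtype=float)[:, None], y)):
            if np.unique(y[tr]).size < 2:
                raise ValueError("training fold lost a class; reduce fold count")
            train = LabeledDataset(X[tr], y[tr], feature_names=list(data.feature_names))
            pred = learner(train, X[te], seed * 10_000 + rep * 100 + k)
            accs.append(float(np.mean(pred == y[te])))
    return CVReport(
        accuracies=np.asarray(accs), folds=folds, repetitions=repetitions, seed=seed
    )


def paired_wtl_test(a: CVReport, b: CVReport, alpha: float = 0.05) -> WTLResult:
    """Two-stage paired t-test: does A win, tie or lose against B?

    Stage 1 tests the two-sided null of equal means; ``p >= alpha`` is a
    tie.  Stage 2 tests one-sided in the direction of the observed mean
    difference; ``p < alpha`` makes it a win (A better) or loss.  Zero
    variance of the differences is handled by sign: all-zero differences
    tie, a constant nonzero difference decides by its sign.
    """
    if a.accuracies.shape != b.accuracies.shape:
        raise ValueError("reports must have the same number of trials")
    if (a.folds, a.repetitions, a.seed) != (b.folds, b.repetitions, b.seed):
        raise ValueError("reports are not paired (different fold structure or seed)")
    diff = a.accuracies - b.accuracies
    mean_diff = float(diff.mean())
    if np.allclose(diff.std(), 0.0):
        if mean_diff == 0.0:
            return WTLResult("tie", 1.0, None, 0.0)
        outcome = "win" if mean_diff > 0 else "loss"
        return WTLResult(outcome, 0.0, 0.0, mean_diff)
    t2 = stats.ttest_rel(a.accuracies, b.accuracies)
    if t2.pvalue >= alpha:
        return WTLResult("tie", float(t2.pvalue), None, mean_diff)
    direction = "greater" if mean_diff > 0 else "less"
    t1 = stats.ttest_rel(a.accuracies, b.accuracies, alternative=direction)
    if t1.pvalue < alpha:
        outcome = "win" if mean_diff > 0 else "loss"
    else:
        outcome = "tie"
    return WTLResult(outcome, float(t2.pvalue), float(t1.pvalue), mean_diff)
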