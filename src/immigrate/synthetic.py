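"""Two-Gaussian interaction benchmark with contamination.

The generator emulates a binary classification problem in which the two
class centroids differ along the direction ``x1 - x2`` while sharing a
positively correlated covariance, so the *interaction* between the two
features — not either feature alone — carries the class signal.  A
configurable fraction of each class is replaced by draws from a wide
"noise" Gaussian placed on the wrong side of the separating line, degrading
the detectability of the interaction as the fraction grows.

Defaults: 100 samples per class; class means (4, 2) and (6, 0) with shared
covariance [[1, 0.5], [0.5, 1]]; class-specific noise means (8, -2) and
(2, 4) with shared noise covariance [[8, 4], [4, 8]].  Optional independent
standard-normal nuisance features can be appended for screening studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data import LabeledDataset

__all__ = [
    "InteractionGaussianConfig",
    "generate_dataset",
    "noise_sweep",
    "bayes_reference_accuracy",
    "NOISE_FRACTIONS",
]

#: contamination sweep: 5% steps from 5% to 50%
NOISE_FRACTIONS: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))


def _check_cov(S: np.ndarray, name: str) -> np.ndarray:
    S = np.asarray(S, dtype=float)
    if S.shape != (2, 2) or np.max(np.abs(S - S.T)) > 1e-12:
        raise ValueError(f"{name} must be a symmetric 2x2 matrix")
    if np.linalg.eigvalsh(S)[0] < -1e-12:
        raise ValueError(f"{name} must be positive semidefinite")
    return S


@dataclass
class InteractionGaussianConfig:
    """Configuration of the contaminated two-Gaussian benchmark."""

    n_per_class: int = 100
    mean1: tuple[float, float] = (4.0, 2.0)
    mean2: tuple[float, float] = (6.0, 0.0)
    shared_cov: tuple = ((1.0, 0.5), (0.5, 1.0))
    noise_mean1: tuple[float, float] = (8.0, -2.0)
    noise_mean2: tuple[float, float] = (2.0, 4.0)
    noise_cov: tuple = ((8.0, 4.0), (4.0, 8.0))
    noise_fraction: float = 0.0
    extra_noise_features: int = 0
    seed: int = 0
    labels: tuple = (1, -1)

    def __post_init__(self) -> None:
        _check_cov(np.asarray(self.shared_cov), "shared_cov")
        _check_cov(np.asarray(self.noise_cov), "noise_cov")
        if not 0.0 <= self.noise_fraction <= 0.5:
            raise ValueError("noise_fraction must lie in [0, 0.5]")
        if self.extra_noise_features < 0:
            raise ValueError("extra_noise_features must be nonnegative")
        if self.n_per_class < 2:
            raise ValueError("need at least two samples per class")


def generate_dataset(cfg: InteractionGaussianConfig) -> LabeledDataset:
    """Draw one contaminated two-Gaussian dataset.

    Per class, ``round(noise_fraction * n_per_class)`` samples come from
    that class's noise Gaussian and *replace* clean draws, keeping the
    class sizes exactly balanced at ``n_per_class``.  Fully seeded.
    """
    rng = np.random.default_rng(cfg.seed)
    n_noise = int(round(cfg.noise_fraction * cfg.n_per_class))
    n_clean = cfg.n_per_class - n_noise
    blocks, labels = [], []
    for mean, nmean, lab in (
        (cfg.mean1, cfg.noise_mean1, cfg.labels[0]),
        (cfg.mean2, cfg.noise_mean2, cfg.labels[1]),
    ):
        clean = rng.multivariate_normal(mean, np.asarray(cfg.shared_cov), size=n_clean)
        rows = [clean]
        if n_noise:
            rows.append(
                rng.multivariate_normal(nmean, np.asarray(cfg.noise_cov), size=n_noise)
            )
        blocks.append(np.vstack(rows))
        labels.extend([lab] * cfg.n_per_class)
    X = np.vstack(blocks)
    names = ["f1", "f2"]
    if cfg.extra_noise_features:
        X = np.hstack(
            [X, rng.standard_normal((X.shape[0], cfg.extra_noise_features))]
        )
        names += [f"noise{i + 1}" for i in range(cfg.extra_noise_features)]
    return LabeledDataset(X, np.asarray(labels), feature_names=names)


def noise_sweep(base_cfg: InteractionGaussianConfig) -> list[LabeledDataset]:
    """Datasets at contamination 5%, 10%, ..., 50%.

    Element ``k`` uses seed ``base_seed * 1000 + k`` so it can be
    regenerated in isolation.
    """
    out = []
    for k, frac in enumerate(NOISE_FRACTIONS):
        cfg = InteractionGaussianConfig(
            n_per_class=base_cfg.n_per_class,
            mean1=base_cfg.mean1,
            mean2=base_cfg.mean2,
            shared_cov=base_cfg.shared_cov,
            noise_mean1=base_cfg.noise_mean1,
            noise_mean2=base_cfg.noise_mean2,
            noise_cov=base_cfg.noise_cov,
            noise_fraction=float(frac),
            extra_noise_features=base_cfg.extra_noise_features,
            seed=base_cfg.seed * 1000 + k,
            labels=base_cfg.labels,
        )
        out.append(generate_dataset(cfg))
    return out


def _mixture_logpdf(X: np.ndarray, mean, cov, nmean, ncov, rho: float) -> np.ndarray:
    clean = stats.multivariate_normal(mean, cov).pdf(X)
    if rho == 0.0:
        dens = clean
    else:
        noise = stats.multivariate_normal(nmean, ncov).pdf(X)
        dens = (1.0 - rho) * clean + rho * noise
    return np.log(np.maximum(dens, 1e-300))


def bayes_reference_accuracy(
    cfg: InteractionGaussianConfig, n_mc: int = 100_000, seed: int = 0
) -> tuple[float, float]:
    """Monte-Carlo accuracy of the exact likelihood-ratio classifier.

    Under the configured mixtures (equal class priors) the optimal rule
    assigns a point to the class with the larger mixture density.  Returns
    ``(accuracy, standard_error)``.  This ceiling is what any empirical
    classifier on this benchmark should be compared against.
    """
    if n_mc < 10_000:
        raise ValueError("use at least 1e4 Monte-Carlo draws")
    rng = np.random.default_rng(seed)
    rho = cfg.noise_fraction
    S, Sn = np.asarray(cfg.shared_cov), np.asarray(cfg.noise_cov)
    half = n_mc // 2
    correct = 0
    total = 0
    for mean, nmean, own_first in (
        (cfg.mean1, cfg.noise_mean1, True),
        (cfg.mean2, cfg.noise_mean2, False),
    ):
        n_noise = int(round(rho * half))
        X = np.vstack(
            [
                rng.multivariate_normal(mean, S, size=half - n_noise),
                rng.multivariate_normal(nmean, Sn, size=n_noise)
                if n_noise
                else np.empty((0, 2)),
            ]
        )
        lp1 = _mixture_logpdf(X, cfg.mean1, S, cfg.noise_mean1, Sn, rho)
        lp2 = _mixture_logpdf(X, cfg.mean2, S, cfg.noise_mean2, Sn, rho)
        pick_first = lp1 > lp2
        correct += int(np.sum(pick_first == own_first))
        total += X.shape[0]
    acc = correct / total
    se = float(np.sqrt(acc * (1.0 - acc) / total))
    return float(acc), se
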