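"""Feature standardization fitted on training data only."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["Scaler"]


@dataclass
class Scaler:
    """Per-feature z-scoring with train-set statistics.

    Zero-variance features are mapped to zero (with a warning at fit time)
    rather than dividing by zero.
    """

    mean: np.ndarray
    scale: np.ndarray  # population sd; 0 marks a constant column

    @classmethod
    def fit(cls, X: np.ndarray, warn: bool = True) -> "Scaler":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        if warn and np.any(scale == 0):
            cols = np.flatnonzero(scale == 0).tolist()
            warnings.warn(
                f"constant feature column(s) {cols}: standardized to zero",
                stacklevel=2,
            )
        return cls(mean=mean, scale=scale)

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        safe = np.where(self.scale > 0, self.scale, 1.0)
        out = (X - self.mean) / safe
        return np.where(self.scale > 0, out, 0.0)
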