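"""Labeled-dataset container and tabular I/O.

The algorithms in this package operate on a dense real feature matrix with a
binary class label per row.  :class:`LabeledDataset` is a thin validated
wrapper around a NumPy array plus a label vector; CSV/TSV round-tripping goes
through pandas.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["LabeledDataset", "read_table", "write_table"]


@dataclass
class LabeledDataset:
    """Feature matrix (N samples x A attributes) with binary labels.

    Parameters
    ----------
    features
        Real-valued matrix, one row per sample.  All entries must be finite.
    labels
        One class symbol per sample; exactly two distinct values must be
        present.
    sample_ids
        Optional per-row identifiers.
    feature_names
        Optional column names; defaults to ``f1..fA``.
    """

    features: np.ndarray
    labels: np.ndarray
    sample_ids: Sequence | None = None
    feature_names: Sequence[str] | None = None
    # filled in __post_init__
    classes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ValueError("features must be a 2-D matrix")
        n, a = self.features.shape
        if n < 2:
            raise ValueError("need at least two samples")
        if a < 1:
            raise ValueError("need at least one feature")
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per sample")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features contain non-finite values")
        classes = np.unique(self.labels)
        if classes.size != 2:
            raise ValueError(
                f"expected exactly two classes, found {classes.size}"
            )
        self.classes = classes
        if self.feature_names is None:
            self.feature_names = [f"f{i + 1}" for i in range(a)]
        elif len(self.feature_names) != a:
            raise ValueError("feature_names length must equal feature count")

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_indices(self, label) -> np.ndarray:
        """Row indices belonging to ``label``."""
        return np.flatnonzero(self.labels == label)

    def hit_indices(self, n: int) -> np.ndarray:
        """Same-class samples of row ``n``, excluding ``n`` itself."""
        idx = self.class_indices(self.labels[n])
        return idx[idx != n]

    def miss_indices(self, n: int) -> np.ndarray:
        """Opposite-class samples of row ``n``."""
        return np.flatnonzero(self.labels != self.labels[n])

    def require_neighbors(self) -> None:
        """Raise if any sample lacks a hit (a class with a single member)."""
        for c in self.classes:
            if self.class_indices(c).size < 2:
                raise ValueError(
                    f"class {c!r} has a single member: every sample needs at "
                    "least one same-class neighbor (nonempty hit set)"
                )

    def restrict_features(self, kept: np.ndarray) -> "LabeledDataset":
        """Dataset containing only the feature columns in ``kept``."""
        kept = np.asarray(kept, dtype=int)
        return LabeledDataset(
            self.features[:, kept],
            self.labels,
            sample_ids=self.sample_ids,
            feature_names=[self.feature_names[i] for i in kept],
        )

    def to_frame(self, label_col: str = "label") -> pd.DataFrame:
        df = pd.DataFrame(self.features, columns=list(self.feature_names))
        df[label_col] = self.labels
        return df


def read_table(path: str | Path, label_col: str = "label") -> LabeledDataset:
    """Read a CSV/TSV file (header required) into a :class:`LabeledDataset`.

    The delimiter is sniffed from the extension (``.tsv``/``.txt`` -> tab).
    Every column except ``label_col`` is parsed as a continuous feature.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    df = pd.read_csv(path, sep=sep)
    if label_col not in df.columns:
        raise ValueError(f"label column {label_col!r} not found in {path}")
    labels = df[label_col].to_numpy()
    feats = df.drop(columns=[label_col])
    return LabeledDataset(
        feats.to_numpy(dtype=float),
        labels,
        feature_names=list(feats.columns),
    )


def write_table(
    data: LabeledDataset, path: str | Path, label_col: str = "label"
) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".txt"} else ","
    data.to_frame(label_col).to_csv(path, sep=sep, index=False)
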