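"""Cohort-level feature redundancy reduction and per-fold supervised
feature ranking.

Redundancy reduction removes features whose absolute Pearson
correlation with an already-retained feature exceeds a threshold
(default 0.75), iterating in a deterministic priority order (descending
variance, ties broken by name).  Supervised ranking scores each feature
by its squared Pearson correlation with the binary lesion label
(squared point-biserial correlation, i.e. univariate regression R^2)
and keeps the top k on the training rows only.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureMatrix",
    "redundancy_reduction",
    "r_squared_ranking",
    "count_feature_occurrence",
]


@dataclass
class FeatureMatrix:
    """Lesion-by-feature matrix with binary risk labels and patient groups."""

    X: pd.DataFrame
    labels: np.ndarray
    groups: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if len(self.labels) != len(self.X):
            raise ValueError("labels length does not match rows")
        if not np.isin(self.labels, [0, 1]).all():
            raise ValueError("labels must be binary 0/1")
        if self.X.isna().any().any():
            raise ValueError("feature matrix contains missing values")
        if self.groups is None:
            raise ValueError("every row needs a patient group")
        self.groups = np.asarray(self.groups)
        if len(self.groups) != len(self.X):
            raise ValueError("groups length does not match rows")


def _as_frame(matrix) -> pd.DataFrame:
    return matrix.X if isinstance(matrix, FeatureMatrix) else pd.DataFrame(matrix)


def redundancy_reduction(matrix, threshold: float = 0.75) -> list[str]:
    """Greedy correlation-based redundancy elimination.

    Features are visited in descending variance order (ties by name);
    a feature is retained iff its absolute Pearson correlation with
    every already-retained feature is <= ``threshold``.  Zero-variance
    features are dropped first with a warning.  Returns retained names
    in priority order.
    """
    df = _as_frame(matrix)
    if df.shape[1] < 2 or df.shape[0] < 3:
        raise ValueError("need at least 2 features and 3 rows")
    variances = df.var(ddof=0)
    dead = variances[variances <= 0].index.tolist()
    if dead:
        warnings.warn(f"dropping {len(dead)} zero-variance features")
        df = df.drop(columns=dead)
        variances = variances.drop(dead)
    order = sorted(df.columns, key=lambda c: (-variances[c], c))
    corr = df[order].corr().abs().to_numpy()
    retained_idx: list[int] = []
    for i in range(len(order)):
        if all(corr[i, j] <= threshold for j in retained_idx):
            retained_idx.append(i)
    return [order[i] for i in retained_idx]


def _label_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of one feature against the binary
    label; 0 for a constant feature."""
    sx = x.std()
    sy = y.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
    return float(r * r)


def r_squared_ranking(train, labels=None, k: int = 5) -> list[str]:
    """Top-k feature names by squared correlation with the binary label,
    computed on training rows only; ties broken by name."""
    if isinstance(train, FeatureMatrix):
        df, y = train.X, train.labels
    else:
        df, y = train, np.asarray(labels)
    if k > df.shape[1]:
        raise ValueError(f"k={k} exceeds available features ({df.shape[1]})")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    y = y.astype(float)
    scores = {c: _label_r2(df[c].to_numpy(dtype=float), y) for c in df.columns}
    ranked = sorted(df.columns, key=lambda c: (-scores[c], c))
    return ranked[:k]


def count_feature_occurrence(selections: Iterable[Sequence[str]]) -> Counter:
    """Multiset counts of selected feature names across MC folds."""
    selections = list(selections)
    if not selections:
        raise ValueError("need at least one fold of selections")
    counts: Counter = Counter()
    for sel in selections:
        counts.update(sel)
    return counts
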