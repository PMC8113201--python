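"""Patient-grouped Monte Carlo cross-validation and the nine-member
mixed random-forest ensemble.

The fold scheme assigns a fixed number of patients (default 5) to the
validation role, uniformly without replacement over distinct subsets,
so no lesion of a validation patient ever reaches training.  The
classifier is a mixed ensemble of nine random forests with differing
hyperparameters; the hard label is the majority vote (>= 5 of 9
members) and the certainty score is by default the fraction of
positive member votes (a probability-averaging mode is available).
Class imbalance in the patient models is corrected on training data
only by SMOTE (convex interpolation between a minority sample and one
of its k nearest minority neighbours).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors

__all__ = [
    "MCFoldScheme",
    "EnsembleConfig",
    "EnsemblePrediction",
    "MixedEnsemble",
    "generate_mc_folds",
    "smote_oversample",
    "train_mixed_ensemble",
    "predict_ensemble",
    "permute_labels",
]


@dataclass
class MCFoldScheme:
    """Unique train/validation patient partitions for MC cross-validation."""

    folds: list[tuple[tuple[str, ...], tuple[str, ...]]]
    n_validation: int
    seed: int

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def validate(self) -> None:
        seen = set()
        for train, val in self.folds:
            if len(val) != self.n_validation:
                raise ValueError("validation set size mismatch")
            if set(train) & set(val):
                raise ValueError("train/validation overlap")
            key = frozenset(val)
            if key in seen:
                raise ValueError("duplicate validation subset")
            seen.add(key)

    def to_json(self, path: str | Path) -> None:
        payload = {"n_validation": self.n_validation, "seed": self.seed,
                   "folds": [[list(t), list(v)] for t, v in self.folds]}
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "MCFoldScheme":
        payload = json.loads(Path(path).read_text())
        folds = [(tuple(t), tuple(v)) for t, v in payload["folds"]]
        return cls(folds, payload["n_validation"], payload["seed"])


def generate_mc_folds(patient_ids, n_folds: int = 1000, n_validation: int = 5,
                      seed: int = 0) -> MCFoldScheme:
    """Sample `n_folds` distinct validation subsets of size `n_validation`
    uniformly without replacement; the remaining patients train."""
    ids = sorted(str(p) for p in set(patient_ids))
    n = len(ids)
    if n <= n_validation:
        raise ValueError("need more patients than validation slots")
    bound = comb(n, n_validation)
    if n_folds > bound:
        raise ValueError(
            f"cannot draw {n_folds} distinct validation subsets: "
            f"C({n},{n_validation}) = {bound}")
    rng = np.random.default_rng(seed)
    folds, seen = [], set()
    while len(folds) < n_folds:
        val = tuple(sorted(rng.choice(n, size=n_validation, replace=False)))
        if val in seen:
            continue
        seen.add(val)
        val_ids = tuple(ids[i] for i in val)
        train_ids = tuple(p for p in ids if p not in set(val_ids))
        folds.append((train_ids, val_ids))
    return MCFoldScheme(folds, n_validation, seed)


def smote_oversample(features: np.ndarray, labels: np.ndarray,
                     k_neighbors: int = 5, rng: np.random.Generator | int | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling: balance the two classes by
    convex interpolation between minority samples and their k nearest
    minority neighbours (k capped at minority size - 1)."""
    rng = np.random.default_rng(rng)
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE needs exactly two classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    X_min = X[y == minority]
    n_min = len(X_min)
    if n_min < 2:
        raise ValueError("minority class of size 1: cannot interpolate")
    n_needed = int(counts.max() - counts.min())
    k = min(k_neighbors, n_min - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X_min)
    _, idx = nn.kneighbors(X_min)
    base = rng.integers(0, n_min, size=n_needed)
    pick = rng.integers(1, k + 1, size=n_needed)  # skip self at column 0
    neighbour = idx[base, pick]
    u = rng.random(size=(n_needed, 1))
    synthetic = X_min[base] + u * (X_min[neighbour] - X_min[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)])
    return X_out, y_out


def default_member_configs() -> list[dict]:
    """Nine mixed hyperparameter sets: trees x depth grid with varied
    feature-rate and leaf-size settings."""
    grid = []
    feats = ["sqrt", 1.0, "sqrt"]
    leafs = [1, 2, 1]
    for i, n_trees in enumerate((25, 50, 100)):
        for j, depth in enumerate((4, 8, None)):
            grid.append({
                "n_estimators": n_trees,
                "max_depth": depth,
                "max_features": feats[(i + j) % 3],
                "min_samples_leaf": leafs[(i + j) % 3],
            })
    return grid


@dataclass
class EnsembleConfig:
    """Configuration of the nine-member mixed random-forest ensemble."""

    member_configs: list[dict] = field(default_factory=default_member_configs)
    seed: int = 0
    score_mode: str = "vote"  # "vote": fraction of positive member votes

    def __post_init__(self) -> None:
        if len(self.member_configs) != 9:
            raise ValueError("the mixed ensemble has exactly 9 members")
        for cfg in self.member_configs:
            for key in ("n_estimators", "min_samples_leaf"):
                if cfg.get(key, 1) <= 0:
                    raise ValueError(f"hyperparameter {key} must be positive")
            if cfg.get("max_depth") is not None and cfg["max_depth"] <= 0:
                raise ValueError("max_depth must be positive or None")
        if self.score_mode not in ("vote", "proba"):
            raise ValueError("score_mode must be 'vote' or 'proba'")


@dataclass
class EnsemblePrediction:
    label: int
    score: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.score <= 1.0):
            raise ValueError("score must lie in [0, 1]")


@dataclass
class MixedEnsemble:
    members: list[RandomForestClassifier]
    n_features: int
    score_mode: str


def _member_seed(config_seed: int, member_idx: int) -> int:
    ss = np.random.SeedSequence([config_seed, member_idx])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def train_mixed_ensemble(features: np.ndarray, labels: np.ndarray,
                         config: EnsembleConfig) -> MixedEnsemble:
    """Fit the nine independently seeded forests; deterministic given
    the config seed."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    members = []
    for m, cfg in enumerate(config.member_configs):
        clf = RandomForestClassifier(random_state=_member_seed(config.seed, m), **cfg)
        members.append(clf.fit(X, y))
    return MixedEnsemble(members, X.shape[1], config.score_mode)


def predict_ensemble(model: MixedEnsemble, rows: np.ndarray) -> list[EnsemblePrediction]:
    """Majority-vote label (>= 5 of 9 members) and mean certainty score
    per row."""
    X = np.asarray(rows, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.n_features:
        raise ValueError(f"feature count mismatch: got {X.shape[1]}, "
                         f"trained on {model.n_features}")
    votes = np.stack([m.predict(X) for m in model.members])  # (9, n)
    vote_frac = votes.mean(axis=0)
    labels = (votes.sum(axis=0) >= 5).astype(int)
    if model.score_mode == "proba":
        probas = np.stack([m.predict_proba(X)[:, list(m.classes_).index(1)]
                           for m in model.members])
        scores = probas.mean(axis=0)
    else:
        scores = vote_frac
    return [EnsemblePrediction(int(l), float(s)) for l, s in zip(labels, scores)]


def permute_labels(labels: np.ndarray, rng: np.random.Generator | int | None = None) -> np.ndarray:
    """Uniformly random permutation of the label vector (class counts
    preserved) — the sham-data control."""
    labels = np.asarray(labels)
    if labels.size < 2:
        raise ValueError("need at least 2 labels to permute")
    rng = np.random.default_rng(rng)
    return labels[rng.permutation(labels.size)]
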