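"""Pooled confusion-matrix analytics and ROC/AUC over Monte Carlo
validation predictions.

Metrics are computed by default on the concatenation of all
fold-validation predictions (a case appearing in many folds counts once
per appearance); per-fold averaging is available behind a flag.  AUC is
the Mann–Whitney probability with ties counted 1/2, identical to the
trapezoidal area under the empirical ROC curve.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "EvaluationReport",
    "confusion_analytics",
    "roc_auc",
    "conventional_value_auc",
    "pool_mc_predictions",
    "evaluate_arm",
]

ARMS = ("M_LH", "M_BCR", "M_OPR", "SHAM_LH", "SHAM_BCR", "SHAM_OPR",
        "SUV_CONVENTIONAL", "STANDARD_CLINICAL")


@dataclass
class EvaluationReport:
    """Pooled confusion counts, derived metrics and AUC for one arm."""

    arm: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    ppv: float | None
    npv: float | None
    auc: float | None
    n_folds: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def confusion_analytics(predictions, truths) -> dict:
    """Confusion counts and sensitivity / specificity / accuracy /
    PPV / NPV; ratios with zero denominator are reported as missing."""
    pred = np.asarray(predictions).astype(int)
    truth = np.asarray(truths).astype(int)
    if pred.size == 0:
        raise ValueError("empty predictions")
    if pred.shape != truth.shape:
        raise ValueError("predictions and truths must have equal length")
    tp = int(((pred == 1) & (truth == 1)).sum())
    fp = int(((pred == 1) & (truth == 0)).sum())
    tn = int(((pred == 0) & (truth == 0)).sum())
    fn = int(((pred == 0) & (truth == 1)).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": _ratio(tp, tp + fn),
        "specificity": _ratio(tn, tn + fp),
        "accuracy": _ratio(tp + tn, tp + tn + fp + fn),
        "ppv": _ratio(tp, tp + fp),
        "npv": _ratio(tn, tn + fn),
    }


def roc_auc(scores, truths) -> float:
    """Mann–Whitney AUC with ties counted 1/2."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(truths).astype(int)
    if s.size != t.size or s.size == 0:
        raise ValueError("scores and truths must be equal-length and non-empty")
    n_pos = int((t == 1).sum())
    n_neg = int((t == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[t == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def conventional_value_auc(features: pd.DataFrame, truths) -> dict[str, float]:
    """Whole-dataset AUC of each conventional per-lesion value (SUV
    metrics, volume) against the binary lesion risk — no cross-validation,
    mirroring the direct measurement on all lesions."""
    truth = np.asarray(truths).astype(int)
    if len(features) == 0:
        raise ValueError("empty lesion set")
    return {col: roc_auc(features[col].to_numpy(dtype=float), truth)
            for col in features.columns}


def pool_mc_predictions(rows: pd.DataFrame, arm: str | None = None) -> pd.DataFrame:
    """Concatenate validation-role predictions across MC folds.

    Each appearance of a case counts.  If `arm` is given, rows are
    filtered to that arm; otherwise the rows must already be a single
    arm (mixed arms raise)."""
    if len(rows) == 0:
        raise ValueError("empty fold prediction list")
    if arm is not None:
        rows = rows[rows["arm"] == arm]
        if len(rows) == 0:
            raise ValueError(f"no predictions for arm {arm!r}")
    elif rows["arm"].nunique() > 1:
        raise ValueError("mixed arms: pass an explicit arm filter")
    return rows.reset_index(drop=True)


def evaluate_arm(rows: pd.DataFrame, arm: str, pooling: str = "pooled") -> EvaluationReport:
    """Build the evaluation report of one arm from per-fold prediction
    rows (columns: fold_id, truth, label, score)."""
    pooled = pool_mc_predictions(rows, arm)
    n_folds = int(pooled["fold_id"].nunique())
    if pooling == "pooled":
        conf = confusion_analytics(pooled["label"], pooled["truth"])
    elif pooling == "perfold":
        per = [confusion_analytics(g["label"], g["truth"])
               for _, g in pooled.groupby("fold_id")]
        conf = confusion_analytics(pooled["label"], pooled["truth"])
        for key in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            vals = [c[key] for c in per if c[key] is not None]
            conf[key] = float(np.mean(vals)) if vals else None
    else:
        raise ValueError("pooling must be 'pooled' or 'perfold'")
    truth = pooled["truth"].to_numpy()
    auc = (roc_auc(pooled["score"], truth)
           if 0 < truth.sum() < len(truth) else None)
    return EvaluationReport(arm=arm, auc=auc, n_folds=n_folds, **conf)
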