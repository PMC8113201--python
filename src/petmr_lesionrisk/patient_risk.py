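"""Reference-standard labelling and patient-level risk inputs.

Lesions are dichotomized by their whole-mount histopathology pattern:
Gleason pattern >= 4 is high risk; Gleason 3, PIN (low or high grade),
prostatitis and benign prostatic hyperplasia are low risk.  Biochemical
recurrence (BCR) is two consecutive follow-up PSA values strictly above
0.2 ng/ml; overall patient risk (OPR) is positive if BCR or nodal or
metastatic stage is positive.

The patient models consume a (PSA, enumerated clinical stage, CLH)
triplet, where CLH is the lesion-volume-weighted mean of per-lesion
model scores:

    CLH = sum_i  M_LH(i) * v_i / V,   V = sum_i v_i

A three-tier clinical-standard comparator (D'Amico-style maximum
filter over pre-binned PSA / biopsy Gleason / clinical T stage) is also
provided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import HIGH_RISK_PATTERNS, PathologyPattern

__all__ = [
    "PatientRecord",
    "CLHInput",
    "DEFAULT_STAGE_ENCODING",
    "dichotomize_lesion",
    "detect_bcr",
    "derive_opr",
    "compute_clh",
    "assemble_patient_features",
    "damico_standard_risk",
]

#: Ordinal encoding of clinical T stage, preserving clinical ordering.
DEFAULT_STAGE_ENCODING = {"T2": 1, "T2a": 2, "T2c": 3, "T3a": 4, "T3b": 5, "T4": 6}

BCR_PSA_THRESHOLD = 0.2  # ng/ml; "rose above" read as strictly greater


@dataclass
class PatientRecord:
    """Clinical metadata of one patient; ``None`` marks a missing label."""

    patient_id: str
    psa_ng_ml: float
    stage_t: str
    stage_n_positive: bool | None
    stage_m_positive: bool | None
    gleason_biopsy: int
    psa_followup: list[float] = field(default_factory=list)
    bcr: bool | None = None
    opr: bool | None = None

    def __post_init__(self) -> None:
        if self.psa_ng_ml < 0:
            raise ValueError("PSA must be >= 0")
        if any(v < 0 for v in self.psa_followup):
            raise ValueError("follow-up PSA values must be >= 0")


def dichotomize_lesion(pattern: PathologyPattern | str) -> int:
    """Binary lesion risk from histopathology pattern: 1 iff Gleason >= 4."""
    pattern = PathologyPattern(pattern)
    return int(pattern in HIGH_RISK_PATTERNS)


def detect_bcr(psa_followup) -> bool | None:
    """Biochemical recurrence: two consecutive follow-up PSA values
    strictly above 0.2 ng/ml.  Fewer than 2 measurements ⇒ missing."""
    series = list(psa_followup)
    if len(series) < 2:
        return None
    above = [v > BCR_PSA_THRESHOLD for v in series]
    return any(a and b for a, b in zip(above, above[1:]))


def derive_opr(bcr: bool | None, n_positive: bool | None, m_positive: bool | None) -> bool | None:
    """Overall patient risk: positive if any of BCR / N-stage / M-stage
    is positive; negative only when all three are known negative."""
    inputs = (bcr, n_positive, m_positive)
    if any(v is True for v in inputs):
        return True
    if all(v is False for v in inputs):
        return False
    return None


@dataclass
class CLHInput:
    """Per-patient inputs to the composite low-vs-high score."""

    lesion_scores: list[float]
    lesion_volumes_ml: list[float]

    def __post_init__(self) -> None:
        if len(self.lesion_scores) != len(self.lesion_volumes_ml):
            raise ValueError("scores and volumes must have equal length")
        if len(self.lesion_scores) < 1:
            raise ValueError("need at least one lesion")
        if any(not (0.0 <= s <= 1.0) for s in self.lesion_scores):
            raise ValueError("lesion scores must lie in [0, 1]")
        if any(v <= 0 for v in self.lesion_volumes_ml):
            raise ValueError("lesion volumes must be > 0")

    @property
    def k(self) -> int:
        return len(self.lesion_scores)

    @property
    def total_volume(self) -> float:
        return float(sum(self.lesion_volumes_ml))


def compute_clh(clh_input: CLHInput) -> float:
    """Volume-weighted composite of per-lesion model scores — a convex
    combination, hence bounded by the min/max lesion score."""
    v = clh_input.total_volume
    if v <= 0:
        raise ValueError("total lesion volume must be > 0")
    return float(sum(s * vol for s, vol in zip(clh_input.lesion_scores,
                                               clh_input.lesion_volumes_ml)) / v)


def assemble_patient_features(record: PatientRecord, clh: float,
                              stage_encoding: dict[str, float] | None = None) -> np.ndarray:
    """The (PSA, enumerated stage, CLH) triplet, with no re-binning."""
    encoding = DEFAULT_STAGE_ENCODING if stage_encoding is None else stage_encoding
    if record.stage_t not in encoding:
        raise KeyError(f"clinical stage {record.stage_t!r} not in stage encoding")
    if not (0.0 <= clh <= 1.0):
        raise ValueError("CLH must lie in [0, 1]")
    return np.array([record.psa_ng_ml, float(encoding[record.stage_t]), clh])


# ---------------------------------------------------------------------------
# clinical-standard comparator

_STAGE_ORDER = ["T1", "T1a", "T1b", "T1c", "T2", "T2a", "T2b", "T2c",
                "T3", "T3a", "T3b", "T4"]


def _stage_tier(stage_t: str) -> int:
    """0 low (<= T2a), 1 intermediate (T2b), 2 high (>= T2c)."""
    try:
        pos = _STAGE_ORDER.index(stage_t)
    except ValueError as err:
        raise KeyError(f"unknown clinical stage {stage_t!r}") from err
    if pos <= _STAGE_ORDER.index("T2a"):
        return 0
    if stage_t == "T2b":
        return 1
    return 2


def damico_standard_risk(psa: float, gleason_biopsy: int, stage_t: str,
                         intermediate_positive: bool = False) -> tuple[str, bool]:
    """Three-tier clinical-standard risk from independently binned PSA,
    biopsy Gleason and clinical T stage, combined by a maximum filter.

    Bins: PSA < 10 / 10–20 / > 20 ng/ml; Gleason <= 6 / 7 / >= 8;
    stage <= T2a / T2b / >= T2c.  The binary prediction is positive for
    the high category (or intermediate+high with
    ``intermediate_positive=True``).
    """
    psa_tier = 0 if psa < 10 else (1 if psa <= 20 else 2)
    gs_tier = 0 if gleason_biopsy <= 6 else (1 if gleason_biopsy == 7 else 2)
    tier = max(psa_tier, gs_tier, _stage_tier(stage_t))
    category = ("low", "intermediate", "high")[tier]
    positive = tier >= (1 if intermediate_positive else 2)
    return category, positive
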