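"""Synthetic PET/MRI prostate cohort generator.

Emulates the statistical structure the analysis assumes, so every
downstream stage is testable without patient data:

* ~52 patients with 1–4 lesions each (~120 lesions), lesion pathology
  patterns drawn so low and high risk are balanced;
* tri-modal co-registered volumes per patient (PSMA-PET in SUV-like
  units, ADC, T2w) plus a gluteus-surrogate reference region for
  PET/T2w normalization;
* lesions are smooth ellipsoidal uptake blobs; high-risk lesions have
  higher mean PET uptake and stronger spatially correlated texture
  noise, and lower/more dispersed ADC — lesion VOLUME is drawn
  independently of risk class;
* per-patient clinical records (PSA, enumerated T stage, N/M status,
  biopsy Gleason, post-operative PSA follow-up series) whose BCR label
  is consistent with the two-consecutive-values-above-0.2 ng/ml rule,
  with label burden linked to the patient's high-risk lesion volume
  fraction; a configurable fraction of BCR/OPR labels is missing
  completely at random.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grids import LesionVOI, Modality, PathologyPattern, VolumeGrid, save_mask, load_mask
from .patient_risk import PatientRecord, derive_opr, detect_bcr

__all__ = [
    "CohortConfig",
    "SyntheticPatient",
    "generate_cohort",
    "generate_lesion_volume",
    "generate_clinical_record",
    "write_cohort",
    "read_cohort",
]

CLINICAL_COLUMNS = ["patient_id", "psa", "stage_t", "stage_n", "stage_m",
                    "gleason_biopsy", "psa_series", "bcr", "opr"]

#: Pathology pattern mixtures within each risk class (ratios follow the
#: lesion-type composition of a surgical prostate cohort).
LOW_PATTERNS = ((PathologyPattern.BPH, 0.33), (PathologyPattern.PIN_LOW, 0.27),
                (PathologyPattern.GLEASON3, 0.28), (PathologyPattern.PIN_HIGH, 0.08),
                (PathologyPattern.PROSTATITIS, 0.04))
HIGH_PATTERNS = ((PathologyPattern.GLEASON4, 0.82), (PathologyPattern.GLEASON5, 0.18))

#: Clinical T stage cut points on the latent severity scale (marginals
#: follow a radical-prostatectomy cohort: mostly T2 / T3a / T3b).
STAGE_CUTPOINTS = (("T2", 0.38), ("T2a", 0.40), ("T2c", 0.44),
                   ("T3a", 0.65), ("T3b", 0.98), ("T4", 1.0))


@dataclass
class CohortConfig:
    """Study conditions of the synthetic cohort.

    ``pet_intensity_params`` holds the per-class (mean, sd) of the
    lesion PET amplitude above background (SUV-like units);
    ``heterogeneity_params`` the per-class amplitude of spatially
    correlated texture noise; ``adc_params`` the per-class (mean, iqr)
    of in-lesion ADC (1e-6 mm^2/s units).  ``bcr_model_coefficients``
    are weights of a clipped linear probability model on (lesion risk
    burden, centred log PSA, enumerated stage).
    """

    n_patients: int = 52
    lesions_per_patient: tuple[int, int] = (1, 4)
    volume_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_spacing_mm: tuple[float, float, float] = (2.0, 2.0, 3.0)
    low_high_balance: float = 0.5  # fraction of high-risk lesions
    pet_intensity_params: dict = field(default_factory=lambda: {
        "low": (4.0, 1.2), "high": (6.5, 1.8)})
    heterogeneity_params: dict = field(default_factory=lambda: {
        "low": 0.5, "high": 2.0})
    adc_params: dict = field(default_factory=lambda: {
        "low": (1200.0, 250.0), "high": (750.0, 450.0)})
    bcr_model_coefficients: dict = field(default_factory=lambda: {
        "intercept": 0.02, "burden": 0.35, "log_psa": 0.06, "stage": 0.03})
    n_stage_coefficients: tuple[float, float] = (0.02, 0.25)   # intercept, burden
    m_stage_coefficients: tuple[float, float] = (0.01, 0.12)
    missing_bcr_fraction: float = 0.31
    missing_opr_fraction: float = 0.04
    psa_followup_len: int = 8
    lesion_radius_range_mm: tuple[float, float] = (4.0, 9.0)
    pet_background: float = 1.0
    t2w_background: float = 100.0
    adc_background: float = 1450.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if not (0.0 < self.low_high_balance < 1.0):
            raise ValueError("low_high_balance must lie in (0, 1)")
        if any(n < 8 for n in self.volume_shape):
            raise ValueError("degenerate volume shape: need >= 8 voxels per axis")
        for cls, (mu, sd) in self.pet_intensity_params.items():
            if sd <= 0:
                raise ValueError(f"PET intensity sd for class {cls!r} must be > 0")
        for cls, (mu, iqr) in self.adc_params.items():
            if iqr <= 0:
                raise ValueError(f"ADC iqr for class {cls!r} must be > 0")


@dataclass
class SyntheticPatient:
    patient_id: str
    volumes: dict[Modality, VolumeGrid]
    reference_mask: np.ndarray
    lesions: list[LesionVOI]
    record: PatientRecord

    @property
    def burden(self) -> float:
        """High-risk lesion volume fraction (the CLH-like generative burden)."""
        vols = np.array([l.volume_ml for l in self.lesions])
        high = np.array([l.is_high_risk for l in self.lesions], dtype=float)
        return float((vols * high).sum() / vols.sum())


# ---------------------------------------------------------------------------
# volumes


def _smooth_noise(shape, rng, sigma_vox: float = 1.2) -> np.ndarray:
    """Unit-variance spatially correlated (Gaussian-smoothed) noise."""
    n = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma_vox)
    sd = n.std()
    return n / sd if sd > 0 else n


def _background_volumes(config: CohortConfig, rng) -> dict[Modality, np.ndarray]:
    shape = config.volume_shape
    return {
        Modality.PSMA_PET: np.clip(
            config.pet_background * (1.0 + 0.08 * _smooth_noise(shape, rng)), 0.01, None),
        Modality.ADC: config.adc_background + 50.0 * _smooth_noise(shape, rng),
        Modality.T2W: config.t2w_background * (1.0 + 0.05 * _smooth_noise(shape, rng)),
    }


def _reference_mask(config: CohortConfig) -> np.ndarray:
    """Gluteus-surrogate reference box in a fixed corner of the grid."""
    mask = np.zeros(config.volume_shape, dtype=bool)
    mask[1:5, 1:5, 1:5] = True
    return mask


def _ellipsoid_field(shape, spacing, center_mm, radii_mm) -> np.ndarray:
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(((gx - center_mm[0]) / radii_mm[0]) ** 2
                   + ((gy - center_mm[1]) / radii_mm[1]) ** 2
                   + ((gz - center_mm[2]) / radii_mm[2]) ** 2)


def _add_lesion(arrays: dict[Modality, np.ndarray], config: CohortConfig,
                risk_class: str, center_mm, radii_mm, rng) -> np.ndarray:
    """Paint one lesion into the modality arrays; returns its voxel mask.

    The lesion is a smooth ellipsoidal blob: intensity follows a
    Gaussian radial profile (so iso-contour delineation recovers the
    ellipsoid) plus class-specific spatially correlated texture noise.
    """
    shape = config.volume_shape
    spacing = config.voxel_spacing_mm
    e = _ellipsoid_field(shape, spacing, center_mm, radii_mm)
    profile = np.exp(-(e**2) / (2 * 0.79**2))  # ~0.45 of peak at the mask edge
    mask = e <= 1.0

    mu, sd = config.pet_intensity_params[risk_class]
    amp = max(0.5, rng.normal(mu, sd))
    noise = _smooth_noise(shape, rng)
    het = config.heterogeneity_params[risk_class]
    arrays[Modality.PSMA_PET] += profile * np.clip(amp + het * noise, 0.05, None)

    adc_mu, adc_iqr = config.adc_params[risk_class]
    adc_sd = adc_iqr / 1.349  # iqr of a normal = 1.349 sd
    adc_target = rng.normal(adc_mu, 60.0)
    arrays[Modality.ADC] += profile * ((adc_target - config.adc_background)
                                       + adc_sd * _smooth_noise(shape, rng))
    arrays[Modality.T2W] += profile * (20.0 + 5.0 * _smooth_noise(shape, rng))
    return mask


def _sample_geometry(config: CohortConfig, rng, occupied: np.ndarray | None = None):
    """Class-independent lesion centre and radii; keeps the blob inside
    the grid and clear of the reference region."""
    shape = config.volume_shape
    spacing = config.voxel_spacing_mm
    lo_r, hi_r = config.lesion_radius_range_mm
    for _ in range(200):
        radii = rng.uniform(lo_r, hi_r, size=3)
        center = np.array([
            rng.uniform(r + 2 * s, (n - 1) * s - r - 2 * s)
            for r, n, s in zip(radii, shape, spacing)])
        # reference box sits at the low corner; keep a wide berth
        if np.all(center < np.array([12 * s for s in spacing]) + radii):
            continue
        if occupied is not None:
            e = _ellipsoid_field(shape, spacing, center, radii * 1.2)
            if (occupied & (e <= 1.0)).any():
                continue
        return center, radii
    raise RuntimeError("could not place lesion: volume too crowded")


def generate_lesion_volume(risk_class: str, config: CohortConfig,
                           rng: np.random.Generator) -> tuple[dict[Modality, VolumeGrid], np.ndarray]:
    """A fresh tri-modal volume containing a single lesion of the given
    class, plus its voxel mask — the unit draw used by property checks."""
    if risk_class not in ("low", "high"):
        raise ValueError("risk_class must be 'low' or 'high'")
    arrays = _background_volumes(config, rng)
    center, radii = _sample_geometry(config, rng)
    mask = _add_lesion(arrays, config, risk_class, center, radii, rng)
    grids = {m: VolumeGrid(a, config.voxel_spacing_mm, (0, 0, 0), m)
             for m, a in arrays.items()}
    return grids, mask


# ---------------------------------------------------------------------------
# clinical records


def _weighted_choice(rng, options) -> PathologyPattern:
    patterns, weights = zip(*options)
    w = np.asarray(weights, dtype=float)
    return patterns[rng.choice(len(patterns), p=w / w.sum())]


def _stage_from_latent(latent: float) -> str:
    for stage, cut in STAGE_CUTPOINTS:
        if latent <= cut:
            return stage
    return STAGE_CUTPOINTS[-1][0]


def _followup_series(bcr: bool, config: CohortConfig, rng) -> list[float]:
    """Post-operative PSA series consistent with the BCR rule: recurrent
    patients show two consecutive values > 0.2 ng/ml, others never do."""
    n = config.psa_followup_len
    if bcr:
        onset = int(rng.integers(0, n - 1))
        series = list(rng.uniform(0.0, 0.15, size=onset))
        rise = 0.25 + np.cumsum(rng.uniform(0.05, 0.4, size=n - onset))
        series += list(rise)
    else:
        series = list(rng.uniform(0.0, 0.18, size=n))
        if rng.random() < 0.15:  # an isolated blip, not recurrence
            series[int(rng.integers(0, n))] = float(rng.uniform(0.21, 0.35))
    return [round(float(v), 3) for v in series]


def generate_clinical_record(burden: float, config: CohortConfig,
                             rng: np.random.Generator,
                             patient_id: str = "p000",
                             gleason_biopsy: int | None = None) -> PatientRecord:
    """Clinical record of one patient given their lesion risk burden.

    PSA is log-normal (median ~7.5 ng/ml) shifted by burden; stage is
    drawn from a burden-linked latent severity; the BCR label follows a
    clipped linear probability model and the follow-up series is
    constructed to reproduce it under :func:`detect_bcr`; N/M positivity
    has low, burden-linked prevalence.  BCR/OPR labels are masked
    missing completely at random at the configured rates.
    """
    if not (0.0 <= burden <= 1.0):
        raise ValueError("burden must lie in [0, 1]")
    c = config.bcr_model_coefficients
    psa = float(np.exp(rng.normal(np.log(7.5) + 0.5 * (burden - 0.5), 0.7)))
    latent = 0.55 * burden + 0.45 * rng.random()
    stage = _stage_from_latent(latent)
    stage_enum = {"T2": 1, "T2a": 2, "T2c": 3, "T3a": 4, "T3b": 5, "T4": 6}[stage]

    p_bcr = float(np.clip(c["intercept"] + c["burden"] * burden
                          + c["log_psa"] * (np.log(psa) - np.log(7.5))
                          + c["stage"] * (stage_enum - 1), 0.0, 1.0))
    bcr = bool(rng.random() < p_bcr)
    series = _followup_series(bcr, config, rng)

    n0, n1 = config.n_stage_coefficients
    m0, m1 = config.m_stage_coefficients
    n_pos = bool(rng.random() < np.clip(n0 + n1 * burden, 0.0, 1.0))
    m_pos = bool(rng.random() < np.clip(m0 + m1 * burden, 0.0, 1.0))
    opr = derive_opr(bcr, n_pos, m_pos)

    if gleason_biopsy is None:
        gleason_biopsy = int(np.clip(6 + round(2.5 * burden + rng.normal(0, 0.7)), 6, 10))

    record = PatientRecord(
        patient_id=patient_id, psa_ng_ml=round(psa, 2), stage_t=stage,
        stage_n_positive=n_pos, stage_m_positive=m_pos,
        gleason_biopsy=gleason_biopsy, psa_followup=series, bcr=bcr, opr=opr)
    assert detect_bcr(record.psa_followup) == record.bcr
    if rng.random() < config.missing_bcr_fraction:
        record.bcr = None
    if rng.random() < config.missing_opr_fraction:
        record.opr = None
    return record


# ---------------------------------------------------------------------------
# cohort


def generate_cohort(config: CohortConfig) -> list[SyntheticPatient]:
    """Generate the full synthetic cohort; deterministic given the seed."""
    root = np.random.SeedSequence(config.seed)
    patients: list[SyntheticPatient] = []
    lesion_counter = 0
    for p, child in enumerate(root.spawn(config.n_patients)):
        rng = np.random.default_rng(child)
        pid = f"p{p:03d}"
        arrays = _background_volumes(config, rng)
        ref_mask = _reference_mask(config)
        n_lesions = int(rng.integers(config.lesions_per_patient[0],
                                     config.lesions_per_patient[1] + 1))
        occupied = ref_mask.copy()
        lesions: list[LesionVOI] = []
        for _ in range(n_lesions):
            risk_class = "high" if rng.random() < config.low_high_balance else "low"
            pattern = _weighted_choice(
                rng, HIGH_PATTERNS if risk_class == "high" else LOW_PATTERNS)
            center, radii = _sample_geometry(config, rng, occupied)
            mask = _add_lesion(arrays, config, risk_class, center, radii, rng)
            occupied |= mask
            lesion_counter += 1
            lesions.append(LesionVOI.from_mask(
                f"l{lesion_counter:03d}", pid, mask, pattern, config.voxel_spacing_mm))
        volumes = {m: VolumeGrid(a, config.voxel_spacing_mm, (0, 0, 0), m)
                   for m, a in arrays.items()}
        patient = SyntheticPatient(pid, volumes, ref_mask, lesions, None)
        patient.record = generate_clinical_record(patient.burden, config, rng, pid)
        patients.append(patient)
    return patients


# ---------------------------------------------------------------------------
# on-disk cohort format


def _fmt_bool(v: bool | None) -> str:
    return "" if v is None else ("1" if v else "0")


def _parse_bool(s: str) -> bool | None:
    return None if s == "" else bool(int(s))


def write_cohort(patients: list[SyntheticPatient], out_dir: str | Path) -> None:
    """Write NIfTI volumes/masks and the clinical CSV table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for patient in patients:
        pdir = out / patient.patient_id
        pdir.mkdir(exist_ok=True)
        for modality, grid in patient.volumes.items():
            grid.to_nifti(pdir / f"{modality.value.lower()}.nii.gz")
        spacing = next(iter(patient.volumes.values())).spacing_mm
        labelmap = np.zeros(patient.reference_mask.shape, dtype=np.int16)
        for i, lesion in enumerate(patient.lesions, start=1):
            labelmap[lesion.mask] = i
        save_mask(labelmap, spacing, (0, 0, 0), pdir / "lesions.nii.gz")
        save_mask(patient.reference_mask, spacing, (0, 0, 0), pdir / "reference.nii.gz")
        with open(pdir / "patterns.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "lesion_id", "pattern"])
            for i, lesion in enumerate(patient.lesions, start=1):
                w.writerow([i, lesion.lesion_id, lesion.pathology_pattern.value])
        r = patient.record
        rows.append([r.patient_id, r.psa_ng_ml, r.stage_t,
                     _fmt_bool(r.stage_n_positive), _fmt_bool(r.stage_m_positive),
                     r.gleason_biopsy, ";".join(str(v) for v in r.psa_followup),
                     _fmt_bool(r.bcr), _fmt_bool(r.opr)])
    with open(out / "clinical.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(CLINICAL_COLUMNS)
        w.writerows(rows)


def read_cohort(in_dir: str | Path) -> list[SyntheticPatient]:
    """Re-load a cohort written by :func:`write_cohort`."""
    root = Path(in_dir)
    records = {}
    with open(root / "clinical.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            records[row["patient_id"]] = PatientRecord(
                patient_id=row["patient_id"], psa_ng_ml=float(row["psa"]),
                stage_t=row["stage_t"], stage_n_positive=_parse_bool(row["stage_n"]),
                stage_m_positive=_parse_bool(row["stage_m"]),
                gleason_biopsy=int(row["gleason_biopsy"]),
                psa_followup=[float(v) for v in row["psa_series"].split(";") if v],
                bcr=_parse_bool(row["bcr"]), opr=_parse_bool(row["opr"]))
    patients = []
    for pid in sorted(records):
        pdir = root / pid
        volumes = {m: VolumeGrid.from_nifti(pdir / f"{m.value.lower()}.nii.gz", m)
                   for m in Modality}
        labelmap = load_mask(pdir / "lesions.nii.gz")
        ref = load_mask(pdir / "reference.nii.gz").astype(bool)
        spacing = volumes[Modality.PSMA_PET].spacing_mm
        lesions = []
        with open(pdir / "patterns.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                lesions.append(LesionVOI.from_mask(
                    row["lesion_id"], pid, labelmap == int(row["label"]),
                    PathologyPattern(row["pattern"]), spacing))
        patients.append(SyntheticPatient(pid, volumes, ref, lesions, records[pid]))
    return patients
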