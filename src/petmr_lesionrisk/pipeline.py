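"""End-to-end orchestration: cohort → preprocessing → radiomics →
redundancy reduction → Monte Carlo folds → lesion / patient ensembles
(real and sham arms) → pooled evaluation reports.

A single master seed fans out into named substreams (cohort, fold
scheme, per-fold member seeds, sham permutations, SMOTE draws), so a
full run is deterministic end to end.  Per-fold patient models consume
CLH values computed from that fold's lesion model applied to every
patient's lesions, which keeps the patient-level no-leakage contract.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .ensemble import (EnsembleConfig, MCFoldScheme, generate_mc_folds,
                       permute_labels, predict_ensemble, smote_oversample,
                       train_mixed_ensemble)
from .evaluation import confusion_analytics, conventional_value_auc, evaluate_arm
from .feature_engineering import (count_feature_occurrence, r_squared_ranking,
                                  redundancy_reduction)
from .grids import LesionVOI, Modality, VolumeGrid
from .patient_risk import (DEFAULT_STAGE_ENCODING, CLHInput, PatientRecord,
                           assemble_patient_features, compute_clh,
                           damico_standard_risk, dichotomize_lesion)
from .preprocess import normalize_to_reference, resample_isotropic, resample_mask
from .radiomics import extract_lesion_features
from .registry import FeatureRegistry, build_default_registry
from .synthetic import CohortConfig, SyntheticPatient, generate_cohort, write_cohort

__all__ = [
    "RunConfig",
    "preprocess_patient",
    "extract_cohort_features",
    "run_mc_analysis",
    "run_full_pipeline",
]

log = logging.getLogger("petmr_lesionrisk")

META_COLUMNS = ["patient_id", "lesion_id", "volume_ml", "pathology_pattern", "label"]

ALL_ARMS = ("M_LH", "SHAM_LH", "M_BCR", "M_OPR", "SHAM_BCR", "SHAM_OPR")


def _sub_seed(master: int, tag: int) -> int:
    """Named deterministic substream seed (< 2^31)."""
    return int(np.random.SeedSequence([master, tag]).generate_state(1)[0] % (2**31 - 1))


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    target_spacing_mm: float = 2.0
    interp: str = "kriging"
    iso_fraction: float = 0.45
    registry_bins: int = 32
    reduction_threshold: float = 0.75
    selection_k: int = 5
    n_folds: int = 1000
    n_validation: int = 5
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    smote_k: int = 5
    stage_encoding: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_ENCODING))
    arms: tuple[str, ...] = ALL_ARMS
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = CohortConfig(**{k: tuple(v) if isinstance(v, list) else v
                                 for k, v in raw.pop("cohort", {}).items()})
        ens_raw = raw.pop("ensemble", {})
        ensemble = EnsembleConfig(**ens_raw) if ens_raw else EnsembleConfig()
        if "arms" in raw:
            raw["arms"] = tuple(raw["arms"])
        return cls(cohort=cohort, ensemble=ensemble, **raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["arms"] = list(self.arms)
        return d


# ---------------------------------------------------------------------------
# preprocessing + extraction


def preprocess_patient(patient: SyntheticPatient, target_spacing_mm: float = 2.0,
                       interp: str = "kriging"):
    """Resample all modalities to the isotropic grid, normalize PET/T2w
    to the reference background, and carry lesion masks over by
    nearest-neighbour resampling."""
    spacing = next(iter(patient.volumes.values())).spacing_mm
    ref = resample_mask(patient.reference_mask, spacing, target_spacing_mm)
    volumes = {}
    for modality, grid in patient.volumes.items():
        res = resample_isotropic(grid, target_spacing_mm, method=interp)
        volumes[modality] = normalize_to_reference(res, ref)
    lesions = []
    for lesion in patient.lesions:
        mask = resample_mask(lesion.mask, spacing, target_spacing_mm)
        if not mask.any():
            log.warning("lesion %s vanished under resampling; skipped", lesion.lesion_id)
            continue
        lesions.append(LesionVOI.from_mask(lesion.lesion_id, lesion.patient_id, mask,
                                           lesion.pathology_pattern,
                                           (target_spacing_mm,) * 3))
    return volumes, lesions, ref


def extract_cohort_features(patients: list[SyntheticPatient],
                            registry: FeatureRegistry | None = None,
                            target_spacing_mm: float = 2.0,
                            interp: str = "kriging") -> pd.DataFrame:
    """Lesion-by-feature table: metadata columns plus the 446 features."""
    registry = registry or build_default_registry()
    rows = []
    for patient in patients:
        volumes, lesions, _ = preprocess_patient(patient, target_spacing_mm, interp)
        for voi in lesions:
            fv = extract_lesion_features(volumes, voi, registry)
            row = {"patient_id": voi.patient_id, "lesion_id": voi.lesion_id,
                   "volume_ml": voi.volume_ml,
                   "pathology_pattern": voi.pathology_pattern.value,
                   "label": dichotomize_lesion(voi.pathology_pattern)}
            row.update(dict(zip(fv.names, fv.values)))
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Monte Carlo analysis


def _patient_table(records: dict[str, PatientRecord], clh: dict[str, float],
                   stage_encoding: dict, target: str) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(ids, X, y) of patients with a non-missing label for `target`."""
    ids, feats, labels = [], [], []
    for pid in sorted(records):
        rec = records[pid]
        label = getattr(rec, target)
        if label is None or pid not in clh:
            continue
        ids.append(pid)
        feats.append(assemble_patient_features(rec, clh[pid], stage_encoding))
        labels.append(int(label))
    return ids, np.asarray(feats), np.asarray(labels)


def run_mc_analysis(features: pd.DataFrame, records: dict[str, PatientRecord] | None,
                    scheme: MCFoldScheme, ensemble: EnsembleConfig,
                    arms=ALL_ARMS, selection_k: int = 5,
                    reduction_threshold: float = 0.75, smote_k: int = 5,
                    stage_encoding: dict | None = None, seed: int = 0) -> dict:
    """Run every requested arm across the shared MC fold scheme.

    Returns a dict with the pooled per-fold prediction rows, the
    redundancy-retained feature names, the per-fold top-k selections and
    the per-fold CLH table.
    """
    arms = tuple(arms)
    stage_encoding = stage_encoding or DEFAULT_STAGE_ENCODING
    feature_cols = [c for c in features.columns if c not in META_COLUMNS]
    retained = redundancy_reduction(features[feature_cols], reduction_threshold)
    X = features[retained]
    y = features["label"].to_numpy(dtype=int)
    groups = features["patient_id"].to_numpy()
    volumes = features["volume_ml"].to_numpy(dtype=float)

    patient_arms = [a for a in arms if a in ("M_BCR", "M_OPR", "SHAM_BCR", "SHAM_OPR")]
    if records is None and patient_arms:
        log.warning("no clinical records: skipping patient arms %s", patient_arms)
        patient_arms = []
    need_lesion_model = bool(patient_arms) or "M_LH" in arms

    predictions: list[dict] = []
    selections: list[list[str]] = []
    clh_rows: list[dict] = []

    for fold_id, (train_ids, val_ids) in enumerate(scheme.folds):
        train_set, val_set = set(train_ids), set(val_ids)
        tr = np.isin(groups, list(train_set))
        va = np.isin(groups, list(val_set))
        fold_seed = _sub_seed(seed, fold_id)
        fold_cfg = replace(ensemble, seed=fold_seed)

        sel = r_squared_ranking(X[tr], y[tr], k=selection_k)
        selections.append(sel)
        Xs = X[sel].to_numpy(dtype=float)

        clh: dict[str, float] = {}
        if need_lesion_model:
            model = train_mixed_ensemble(Xs[tr], y[tr], fold_cfg)
            preds_all = predict_ensemble(model, Xs)
            scores_all = np.array([p.score for p in preds_all])
            if "M_LH" in arms:
                for i in np.flatnonzero(va):
                    predictions.append({
                        "arm": "M_LH", "fold_id": fold_id, "patient_id": groups[i],
                        "lesion_id": features["lesion_id"].iat[i],
                        "truth": int(y[i]), "label": preds_all[i].label,
                        "score": preds_all[i].score})
            for pid in train_set | val_set:
                sel_rows = groups == pid
                if sel_rows.any():
                    clh[pid] = compute_clh(CLHInput(list(scores_all[sel_rows]),
                                                    list(volumes[sel_rows])))
            clh_rows += [{"fold_id": fold_id, "patient_id": pid, "clh": v}
                         for pid, v in sorted(clh.items())]

        if "SHAM_LH" in arms:
            rng = np.random.default_rng([seed, fold_id, 11])
            y_sham = permute_labels(y, rng)
            if len(np.unique(y_sham[tr])) > 1:
                sham_model = train_mixed_ensemble(Xs[tr], y_sham[tr], fold_cfg)
                for i, pred in zip(np.flatnonzero(va),
                                   predict_ensemble(sham_model, Xs[va])):
                    predictions.append({
                        "arm": "SHAM_LH", "fold_id": fold_id, "patient_id": groups[i],
                        "lesion_id": features["lesion_id"].iat[i],
                        "truth": int(y_sham[i]), "label": pred.label,
                        "score": pred.score})

        for arm in patient_arms:
            target = "bcr" if arm.endswith("BCR") else "opr"
            sham = arm.startswith("SHAM")
            ids, Xp, yp = _patient_table(records, clh, stage_encoding, target)
            if sham:
                rng = np.random.default_rng([seed, fold_id, 21 if target == "bcr" else 22])
                yp = permute_labels(yp, rng)
            in_train = np.array([i in train_set for i in ids])
            in_val = np.array([i in val_set for i in ids])
            if in_val.sum() == 0 or len(np.unique(yp[in_train])) < 2:
                continue
            rng_smote = np.random.default_rng(
                [seed, fold_id, 31 if target == "bcr" else 32, int(sham)])
            if min(np.bincount(yp[in_train])) >= 2:
                Xb, yb = smote_oversample(Xp[in_train], yp[in_train], smote_k, rng_smote)
            else:  # minority of one patient: SMOTE undefined, train as-is
                Xb, yb = Xp[in_train], yp[in_train]
            model = train_mixed_ensemble(Xb, yb, fold_cfg)
            for i, pred in zip(np.flatnonzero(in_val), predict_ensemble(model, Xp[in_val])):
                predictions.append({
                    "arm": arm, "fold_id": fold_id, "patient_id": ids[i],
                    "lesion_id": "", "truth": int(yp[i]), "label": pred.label,
                    "score": pred.score})

    return {
        "predictions": pd.DataFrame(predictions),
        "retained": retained,
        "selections": selections,
        "occurrence": count_feature_occurrence(selections) if selections else {},
        "clh": pd.DataFrame(clh_rows),
    }


# ---------------------------------------------------------------------------
# full pipeline


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_full_pipeline(config: RunConfig, out_dir: str | Path,
                      write_volumes: bool = False) -> dict:
    """Run synth → preprocess → extract → reduce → folds → train/evaluate
    and write all artifacts (feature CSV, retained-feature JSON, fold
    scheme, per-fold predictions, pooled reports, occurrence table,
    manifest) into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "synthetic cohort"
    try:
        cohort_cfg = replace(config.cohort, seed=_sub_seed(config.seed, 0))
        patients = generate_cohort(cohort_cfg)
        if write_volumes:
            write_cohort(patients, out / "cohort")
        records = {p.patient_id: p.record for p in patients}

        stage = "feature extraction"
        registry = build_default_registry(config.registry_bins)
        registry.to_json(out / "registry.json")
        features = extract_cohort_features(patients, registry,
                                           config.target_spacing_mm, config.interp)
        features.to_csv(out / "features.csv", index=False)

        stage = "fold generation"
        scheme = generate_mc_folds([p.patient_id for p in patients],
                                   config.n_folds, config.n_validation,
                                   _sub_seed(config.seed, 1))
        scheme.to_json(out / "folds.json")

        stage = "monte carlo analysis"
        result = run_mc_analysis(features, records, scheme, config.ensemble,
                                 config.arms, config.selection_k,
                                 config.reduction_threshold, config.smote_k,
                                 config.stage_encoding, _sub_seed(config.seed, 2))
        (out / "retained_features.json").write_text(json.dumps(result["retained"]))
        result["predictions"].to_csv(out / "predictions.csv", index=False)
        if len(result["clh"]):
            result["clh"].to_csv(out / "clh.csv", index=False)
        occ = pd.DataFrame(sorted(result["occurrence"].items(),
                                  key=lambda kv: (-kv[1], kv[0])),
                           columns=["feature", "count"])
        occ.to_csv(out / "feature_occurrence.csv", index=False)

        stage = "evaluation"
        reports = {}
        preds = result["predictions"]
        for arm in config.arms:
            if len(preds) and (preds["arm"] == arm).any():
                reports[arm] = evaluate_arm(preds, arm).to_dict()
        conv = conventional_value_auc(
            features[["suv_max", "suv_peak", "suv_tlg", "volume_ml"]],
            features["label"])
        reports["SUV_CONVENTIONAL"] = conv
        if records is not None:
            reports["STANDARD_CLINICAL"] = _standard_comparator(records)
        (out / "reports.json").write_text(json.dumps(reports, indent=1))

        manifest = {"config": config.to_dict(), "config_hash": _config_hash(config),
                    "seeds": {"master": config.seed,
                              "cohort": _sub_seed(config.seed, 0),
                              "folds": _sub_seed(config.seed, 1),
                              "analysis": _sub_seed(config.seed, 2)},
                    "n_patients": len(patients), "n_lesions": len(features)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True, default=str))
        return {"reports": reports, "features": features, "scheme": scheme, **result}
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage: {stage}") from err


def _standard_comparator(records: dict[str, PatientRecord]) -> dict:
    """Whole-dataset clinical-standard (D'Amico-style) confusion
    analytics against BCR and OPR, under both binarization mappings."""
    out = {}
    for target in ("bcr", "opr"):
        for inter_pos in (False, True):
            preds, truths = [], []
            for rec in records.values():
                truth = getattr(rec, target)
                if truth is None:
                    continue
                _, positive = damico_standard_risk(rec.psa_ng_ml, rec.gleason_biopsy,
                                                   rec.stage_t, inter_pos)
                preds.append(int(positive))
                truths.append(int(truth))
            key = f"{target}_{'intermediate_high' if inter_pos else 'high_only'}"
            out[key] = confusion_analytics(preds, truths) if preds else None
    return out
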