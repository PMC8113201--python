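"""Radiomics feature tests: brute-force oracle equivalence on
micro-volumes, invariances, SUV metrics and vector assembly."""

import numpy as np
import pytest

import _oracles as oracle
from petmr_lesionrisk.grids import LesionVOI, Modality, PathologyPattern, VolumeGrid
from petmr_lesionrisk.radiomics import (assemble_feature_vector, border_distance_map,
                                        compute_gldzm_features, compute_glcm_features,
                                        compute_intensity_stats, compute_modality_features,
                                        compute_morphology_features, compute_ngtdm_features,
                                        compute_suv_metrics, discretize_fbn,
                                        extract_lesion_features, glcm_features_from_matrix,
                                        glcm_matrix, gldzm_matrix, glrlm_matrix,
                                        glszm_matrix)
from petmr_lesionrisk.registry import build_default_registry


def _micro(seed, shape=(5, 5, 5), bins=4):
    """Random micro-volume, full mask, discretized both ways."""
    rng = np.random.default_rng(seed)
    values = rng.random(shape)
    mask = rng.random(shape) < 0.8
    mask.flat[0] = True  # never empty
    levels = discretize_fbn(values, mask, bins)
    levels_o = oracle.discretize(values, mask, bins)
    np.testing.assert_array_equal(levels, levels_o)
    return values, mask, levels


@pytest.mark.parametrize("seed", range(6))
def test_glcm_matrix_matches_pair_enumeration(seed):
    _, _, levels = _micro(seed)
    for dist in (1, 2):
        counts = glcm_matrix(levels, 4, dist)
        expect = oracle.glcm_counts(levels, 4, dist)
        np.testing.assert_allclose(counts, expect, atol=1e-9)
        p = counts / counts.sum()
        assert p.sum() == pytest.approx(1.0)


@pytest.mark.parametrize("seed", range(6))
def test_glrlm_matrix_matches_run_enumeration(seed):
    _, _, levels = _micro(seed)
    np.testing.assert_allclose(glrlm_matrix(levels, 4),
                               oracle.glrlm_counts(levels, 4), atol=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_glszm_matrix_matches_flood_fill(seed):
    _, _, levels = _micro(seed)
    np.testing.assert_allclose(glszm_matrix(levels, 4),
                               oracle.glszm_counts(levels, 4), atol=1e-9)


@pytest.mark.parametrize("seed", range(6))
def test_gldzm_matrix_matches_flood_fill(seed):
    _, mask, levels = _micro(seed)
    got = gldzm_matrix(levels, mask, 4)
    expect = oracle.gldzm_counts(levels, mask, 4)
    # implementations may allocate different max-distance widths
    w = max(got.shape[1], expect.shape[1])
    got = np.pad(got, ((0, 0), (0, w - got.shape[1])))
    expect = np.pad(expect, ((0, 0), (0, w - expect.shape[1])))
    np.testing.assert_allclose(got, expect, atol=1e-9)


def test_gldzm_crafted_two_level_pattern():
    """4x4x1 two-level pattern against exhaustive zone enumeration."""
    levels = np.array([[1, 1, 2, 2], [1, 1, 2, 2], [2, 2, 1, 1], [2, 2, 1, 1]],
                      dtype=int).reshape(4, 4, 1)
    mask = np.ones((4, 4, 1), dtype=bool)
    counts = gldzm_matrix(levels, mask, 2)
    # all zones touch the border: distances all 1; zones: two level-1 zones?
    expect = oracle.gldzm_counts(levels, mask, 2)
    np.testing.assert_allclose(counts[:, :expect.shape[1]], expect)


def test_gldzm_degenerate_single_voxel():
    values = np.zeros((3, 3, 3))
    mask = np.zeros((3, 3, 3), dtype=bool)
    mask[1, 1, 1] = True
    values[1, 1, 1] = 7.0
    feats = compute_gldzm_features(values, mask, bins=4)
    # one zone at level 1 (constant region), distance 1 ⇒ hgze = 1
    assert feats["hgze"] == pytest.approx(1.0)
    assert feats["z_perc"] == pytest.approx(1.0)


def test_gldzm_uniform_plane_single_zone():
    values = np.full((3, 3, 1), 2.5)
    mask = np.ones((3, 3, 1), dtype=bool)
    feats = compute_gldzm_features(values, mask, bins=4)
    assert feats["glnu"] == pytest.approx(1.0)  # single zone
    assert feats["hgze"] == pytest.approx(1.0)  # constant ⇒ level 1


@pytest.mark.parametrize("seed", range(6))
def test_ngtdm_tables_match_loops(seed):
    _, _, levels = _micro(seed)
    p_o, s_o, nvc_o = oracle.ngtdm_tables(levels, 4)
    feats = compute_ngtdm_features(levels.astype(float),
                                  levels > 0, bins=4)
    # recompute coarseness from the oracle tables
    denom = float((p_o * s_o).sum())
    expect_coarse = 1.0 / denom if denom > 0 else 1e6
    assert feats["coarseness"] == pytest.approx(expect_coarse, rel=1e-9)


def test_glcm_checkerboard_hand_enumeration():
    """2x2x1 checkerboard of levels {1,2}: every in-plane horizontal and
    vertical pair is (1,2); diagonals are (1,1) and (2,2)."""
    levels = np.array([[1, 2], [2, 1]], dtype=int).reshape(2, 2, 1)
    counts = glcm_matrix(levels, 2, 1)
    expect = oracle.glcm_counts(levels, 2, 1)
    np.testing.assert_allclose(counts, expect)
    # hand count: 4 ordered (1,2)+(2,1) pairs doubled by symmetry = 8 off-diag,
    # 2 diagonal pairs (1,1),(2,2) each twice = 4
    assert counts.sum() == 12
    assert counts[0, 1] == counts[1, 0] == 4
    assert counts[0, 0] == counts[1, 1] == 2
    feats = glcm_features_from_matrix(counts)
    p = counts / counts.sum()
    expect_entropy = -(p[p > 0] * np.log2(p[p > 0])).sum()
    assert feats["joint_entr"] == pytest.approx(expect_entropy)


def test_glcm_constant_region_degenerate():
    values = np.full((4, 4, 4), 2.0)
    mask = np.ones((4, 4, 4), dtype=bool)
    feats = compute_glcm_features(values, mask, bins=8)
    assert feats["joint_entr"] == pytest.approx(0.0)
    assert feats["info_corr_1"] == 0.0
    assert feats["corr"] == 0.0


def test_glcm_label_permutation_invariance():
    rng = np.random.default_rng(3)
    levels = rng.integers(1, 5, size=(4, 4, 4))
    counts = glcm_matrix(levels, 4, 1)
    perm = np.array([0, 3, 1, 4, 2])  # relabel 1..4 -> 3,1,4,2
    counts_p = glcm_matrix(perm[levels], 4, 1)
    f1 = glcm_features_from_matrix(counts)
    f2 = glcm_features_from_matrix(counts_p)
    assert f1["joint_entr"] == pytest.approx(f2["joint_entr"])


def test_intensity_stats_oracle():
    from scipy import stats as sps
    x = np.array([1.0, 2.0, 3.0, 4.0])
    f = compute_intensity_stats(x)
    assert f["mean"] == pytest.approx(2.5)
    assert f["var"] == pytest.approx(np.var(x))
    assert f["skew"] == pytest.approx(sps.skew(x))
    assert f["kurt"] == pytest.approx(sps.kurtosis(x))
    assert f["iqr"] == pytest.approx(np.percentile(x, 75) - np.percentile(x, 25))
    assert f["cov"] == pytest.approx(np.std(x) / 2.5)
    assert f["energy"] == pytest.approx(30.0)

    const = compute_intensity_stats(np.full(4, 2.0))
    assert const["cov"] == 0.0 and const["iqr"] == 0.0 and const["skew"] == 0.0


def test_intensity_stats_scale_invariance_of_cov(rng):
    x = rng.random(50) + 0.5
    f1 = compute_intensity_stats(x)
    f2 = compute_intensity_stats(7.3 * x)
    assert f1["cov"] == pytest.approx(f2["cov"])


def test_rotation_invariance_of_merged_features():
    """90-degree rotation leaves merged-direction GLCM and intensity
    stats unchanged."""
    rng = np.random.default_rng(8)
    values = rng.random((6, 6, 6))
    mask = rng.random((6, 6, 6)) < 0.7
    mask[0, 0, 0] = True
    rot_v = np.rot90(values, k=1, axes=(0, 1))
    rot_m = np.rot90(mask, k=1, axes=(0, 1))
    f1 = compute_glcm_features(values, mask, bins=6)
    f2 = compute_glcm_features(rot_v, rot_m, bins=6)
    for key in ("joint_entr", "contrast", "info_corr_1", "energy"):
        assert f1[key] == pytest.approx(f2[key], abs=1e-12)
    s1 = compute_intensity_stats(values[mask])
    s2 = compute_intensity_stats(rot_v[rot_m])
    assert s1["mean"] == pytest.approx(s2["mean"])
    assert s1["iqr"] == pytest.approx(s2["iqr"])


# ---------------------------------------------------------------------------
# SUV metrics


def _pet(values, spacing=(2.0, 2.0, 2.0)):
    return VolumeGrid(values, spacing, (0, 0, 0), Modality.PSMA_PET)


def test_suv_uniform_lesion():
    values = np.zeros((20, 20, 20))
    mask = np.zeros((20, 20, 20), dtype=bool)
    mask[5:15, 5:15, 5:15] = True
    values[mask] = 5.0
    # embed in uniform background of same value so the peak sphere sees 5.0
    values[:] = 5.0
    f = compute_suv_metrics(_pet(values), mask)
    vol_ml = mask.sum() * 0.008
    assert f["suv_max"] == f["suv_peak"] == f["suv_mean"] == pytest.approx(5.0)
    assert f["suv_tlg"] == pytest.approx(5.0 * vol_ml)


def test_suv_hot_voxel_peak_below_max():
    values = np.zeros((15, 15, 15))
    mask = np.zeros((15, 15, 15), dtype=bool)
    mask[5:10, 5:10, 5:10] = True
    values[7, 7, 7] = 10.0
    f = compute_suv_metrics(_pet(values), mask)
    assert f["suv_max"] == pytest.approx(10.0)
    assert f["suv_peak"] < f["suv_max"]


def test_suv_tlg_arithmetic(rng):
    values = rng.random((12, 12, 12)) * 4
    mask = rng.random((12, 12, 12)) < 0.3
    mask[6, 6, 6] = True
    f = compute_suv_metrics(_pet(values), mask)
    assert f["suv_tlg"] == pytest.approx(values[mask].mean() * mask.sum() * 0.008)


# ---------------------------------------------------------------------------
# morphology


def test_morphology_cube():
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask[2:6, 2:6, 2:6] = True  # 4x4x4 voxels at 2mm = 8mm cube
    f = compute_morphology_features(mask, (2.0, 2.0, 2.0))
    assert f["volume_ml"] == pytest.approx(64 * 0.008)
    assert f["surface_area_mm2"] == pytest.approx(6 * 8.0 * 8.0)
    assert f["elongation"] == pytest.approx(1.0)
    assert f["flatness"] == pytest.approx(1.0)
    # cube sphericity = (pi/6)^(1/3) ~ 0.806
    assert f["sphericity"] == pytest.approx((np.pi / 6) ** (1 / 3), rel=1e-6)


def test_border_distance_map_chebyshev():
    mask = np.ones((5, 5, 5), dtype=bool)
    d = border_distance_map(mask)
    assert d[0, 0, 0] == 1
    assert d[2, 2, 2] == 3  # centre of a 5-cube


# ---------------------------------------------------------------------------
# assembly


def test_feature_vector_length_446(small_cohort):
    registry = build_default_registry()
    patient = small_cohort[0]
    voi = patient.lesions[0]
    fv = extract_lesion_features(patient.volumes, voi, registry)
    assert len(fv) == 446
    assert np.all(np.isfinite(fv.values))
    assert fv.names[-4:] == ("suv_max", "suv_peak", "suv_mean", "suv_tlg")


def test_identical_lesions_identical_vectors(small_cohort):
    registry = build_default_registry()
    patient = small_cohort[0]
    voi = patient.lesions[0]
    a = extract_lesion_features(patient.volumes, voi, registry)
    b = extract_lesion_features(patient.volumes, voi, registry)
    np.testing.assert_array_equal(a.values, b.values)


def test_missing_registry_entry_raises():
    registry = build_default_registry()
    rng = np.random.default_rng(0)
    values = rng.random((6, 6, 6))
    mask = np.ones((6, 6, 6), dtype=bool)
    per_mod = {m: compute_modality_features(
        VolumeGrid(values, (2, 2, 2), (0, 0, 0), m), mask, 32) for m in Modality}
    morph = compute_morphology_features(mask, (2, 2, 2))
    suv = compute_suv_metrics(VolumeGrid(values, (2, 2, 2)), mask)
    fv = assemble_feature_vector(per_mod, morph, suv, registry, "l1")
    assert len(fv) == 446
    del per_mod[Modality.ADC]["stat_mean"]
    with pytest.raises(KeyError, match="adc_stat_mean"):
        assemble_feature_vector(per_mod, morph, suv, registry, "l1")
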