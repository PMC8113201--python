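"""Tests of isotropic resampling (kriging and trilinear), reference
normalization and iso-count VOI extraction."""

import numpy as np
import pytest

from petmr_lesionrisk.grids import Modality, VolumeGrid
from petmr_lesionrisk.preprocess import (isocount_voi, normalize_to_reference,
                                         resample_isotropic, resample_mask)


def _grid(values, spacing=(2.0, 2.0, 3.0), modality=Modality.PSMA_PET):
    return VolumeGrid(np.asarray(values, dtype=float), spacing, (0, 0, 0), modality)


@pytest.mark.parametrize("method", ["kriging", "trilinear"])
def test_constant_volume_reproduced(method):
    vol = _grid(np.full((10, 10, 10), 3.7))
    out = resample_isotropic(vol, 2.0, method=method)
    assert out.spacing_mm == (2.0, 2.0, 2.0)
    np.testing.assert_allclose(out.values, 3.7, rtol=1e-9)


@pytest.mark.parametrize("method", ["kriging", "trilinear"])
def test_identity_at_target_spacing(method):
    rng = np.random.default_rng(0)
    values = rng.random((8, 8, 8))
    vol = _grid(values, spacing=(2.0, 2.0, 2.0))
    out = resample_isotropic(vol, 2.0, method=method)
    assert out.shape == vol.shape
    np.testing.assert_allclose(out.values, values, atol=1e-9)


def test_linear_ramp_reproduced_with_linear_drift():
    """Kriging with the linear-compatible (first-order drift) system
    reproduces an affine field at off-lattice points to 1e-6."""
    shape = (9, 9, 9)
    gx, gy, gz = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    values = 2.0 + 0.5 * gx + 0.25 * gy - 0.1 * gz
    vol = _grid(values, spacing=(2.0, 2.0, 3.0))
    out = resample_isotropic(vol, 2.0, method="kriging", drift="linear")
    # direct evaluation of the same affine field on the output lattice
    ox, oy, oz = np.meshgrid(*[np.arange(n) for n in out.shape], indexing="ij")
    expect = 2.0 + 0.5 * (ox * 2.0 / 2.0) + 0.25 * (oy * 2.0 / 2.0) - 0.1 * np.minimum(oz * 2.0 / 3.0, shape[2] - 1)
    np.testing.assert_allclose(out.values, expect, rtol=1e-6, atol=1e-6)


def test_extent_covered():
    vol = _grid(np.zeros((10, 12, 14)), spacing=(1.7, 2.3, 3.1))
    out = resample_isotropic(vol, 2.0)
    for n_out, n_src, sp in zip(out.shape, vol.shape, vol.spacing_mm):
        assert (n_out - 1) * 2.0 >= (n_src - 1) * sp - 1e-9


def test_no_overshoot_default_variogram():
    """Default spherical-variogram resampling keeps values within 1% of
    the source dynamic range beyond the source min/max."""
    rng = np.random.default_rng(1)
    values = rng.random((10, 10, 10)) * 10.0
    vol = _grid(values, spacing=(2.0, 2.0, 3.0))
    out = resample_isotropic(vol, 2.0, method="kriging")
    dyn = values.max() - values.min()
    assert out.values.max() <= values.max() + 0.01 * dyn
    assert out.values.min() >= values.min() - 0.01 * dyn


def test_nonfinite_rejected():
    values = np.zeros((8, 8, 8))
    with pytest.raises(ValueError):
        vol = _grid(values)
        vol.values[0, 0, 0] = np.nan
        resample_isotropic(vol, 2.0)


def test_mask_resampling_preserves_support():
    mask = np.zeros((10, 10, 10), dtype=bool)
    mask[3:7, 3:7, 3:7] = True
    out = resample_mask(mask, (2.0, 2.0, 3.0), 2.0)
    assert out.dtype == bool
    assert out.any()


# ---------------------------------------------------------------------------
# normalization


def test_normalize_divides_by_reference_mean():
    values = np.ones((8, 8, 8)) * 4.0
    values[4, 4, 4] = 8.0
    ref = np.zeros((8, 8, 8), dtype=bool)
    ref[0:2, 0:2, 0:2] = True
    vol = _grid(values)
    out = normalize_to_reference(vol, ref)
    assert out.values[4, 4, 4] == pytest.approx(2.0)
    assert out.values[ref].mean() == pytest.approx(1.0)


def test_normalize_idempotent_and_adc_passthrough():
    rng = np.random.default_rng(2)
    values = rng.random((8, 8, 8)) + 0.5
    ref = np.zeros((8, 8, 8), dtype=bool)
    ref[:3, :3, :3] = True
    once = normalize_to_reference(_grid(values), ref)
    twice = normalize_to_reference(once, ref)
    np.testing.assert_allclose(once.values, twice.values)

    adc = _grid(values, modality=Modality.ADC)
    assert normalize_to_reference(adc, ref) is adc


def test_normalize_rejects_nonpositive_reference():
    values = np.zeros((8, 8, 8))
    ref = np.zeros((8, 8, 8), dtype=bool)
    ref[0, 0, 0] = True
    with pytest.raises(ValueError, match="reference"):
        normalize_to_reference(_grid(values), ref)


# ---------------------------------------------------------------------------
# iso-count VOI


def _gaussian_blob(shape=(21, 21, 21), center=(10, 10, 10), sigma=3.0, amp=10.0):
    gx, gy, gz = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    d2 = (gx - center[0]) ** 2 + (gy - center[1]) ** 2 + (gz - center[2]) ** 2
    return amp * np.exp(-d2 / (2 * sigma**2))


def test_isocount_half_maximum_region():
    """Against a brute-force threshold + connected-component oracle."""
    from scipy import ndimage
    values = _gaussian_blob()
    vol = _grid(values, spacing=(2.0, 2.0, 2.0))
    mask = isocount_voi(vol, (7, 8, 9), iso_fraction=0.5)
    # oracle: global threshold at half max, component containing the peak
    above = values >= 0.5 * values.max()
    labels, _ = ndimage.label(above, structure=np.ones((3, 3, 3)))
    expect = labels == labels[10, 10, 10]
    np.testing.assert_array_equal(mask, expect)


def test_isocount_monotone_in_fraction():
    values = _gaussian_blob() + 0.01
    vol = _grid(values)
    prev = None
    for frac in (0.2, 0.4, 0.6, 0.8, 0.95):
        mask = isocount_voi(vol, (10, 10, 10), frac)
        if prev is not None:
            assert (mask <= prev).all()  # set inclusion
        prev = mask
    assert prev.sum() >= 1  # high fraction shrinks towards the peak


def test_isocount_separated_blobs():
    values = _gaussian_blob(center=(5, 5, 5), sigma=1.5)
    values += _gaussian_blob(center=(15, 15, 15), sigma=1.5)
    vol = _grid(values + 1e-9)
    mask = isocount_voi(vol, (5, 6, 5), 0.5)
    assert mask[5, 5, 5]
    assert not mask[15, 15, 15]


def test_isocount_rejects_background_seed():
    values = np.zeros((9, 9, 9))
    values[4, 4, 4] = 5.0
    with pytest.raises(ValueError, match="background"):
        isocount_voi(_grid(values), (0, 0, 0), 0.5)
    with pytest.raises(ValueError):
        isocount_voi(_grid(values + 1.0), (4, 4, 4), 1.5)
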