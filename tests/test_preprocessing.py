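import numpy as np
import pytest

from ctvi_synth.errors import DegenerateCaseError, ParameterError
from ctvi_synth.image_io import CTVolumePair, ImageVolume
from ctvi_synth.preprocessing import (
    LungMask,
    apply_rigid_shift,
    assemble_case,
    compute_lung_mask,
    crop_or_pad,
    mask_ct,
    minmax_normalize,
    preprocess_case,
    resample_isotropic,
    standardize_activity,
    union_mask,
)


def hu(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(np.asarray(data, np.float32), spacing, units="HU")


# --- resampling -----------------------------------------------------------

def test_resample_identity_when_already_isotropic():
    vol = hu(np.random.default_rng(0).normal(size=(8, 8, 8)))
    out = resample_isotropic(vol, 1.0)
    np.testing.assert_allclose(out.data, vol.data, atol=1e-6)
    assert out.spacing == (1.0, 1.0, 1.0)


def test_resample_size_rule():
    vol = hu(np.zeros((4, 4, 4)), spacing=(2.0, 2.0, 2.0))
    out = resample_isotropic(vol, 1.0)
    assert out.shape == (8, 8, 8)


def test_resample_reproduces_linear_ramp():
    """Order-3 spline interpolation reproduces an affine field exactly."""
    nx = 16
    ramp = np.broadcast_to(np.arange(nx, dtype=np.float32), (8, 8, nx)).copy()
    vol = hu(ramp, spacing=(2.0, 2.0, 2.0))
    out = resample_isotropic(vol, 1.0)
    # analytic ramp on the fine grid (grid-aligned resampling): index i maps
    # to coarse coordinate (i + 0.5) / 2 - 0.5
    x_fine = (np.arange(out.shape[2]) + 0.5) / 2.0 - 0.5
    expected = np.clip(x_fine, 0, nx - 1)
    interior = slice(6, -6)  # away from the boundary-handling zone
    np.testing.assert_allclose(out.data[4, 4, interior], expected[interior],
                               rtol=1e-3, atol=2e-3)


def test_resample_rejects_bad_spacing():
    with pytest.raises(ParameterError):
        resample_isotropic(hu(np.zeros((4, 4, 4))), -1.0)


# --- rigid shift ----------------------------------------------------------

def test_shift_zero_is_identity():
    vol = hu(np.random.default_rng(1).normal(size=(6, 6, 6)))
    np.testing.assert_array_equal(apply_rigid_shift(vol, (0, 0, 0)).data, vol.data)


def test_shift_moves_impulse_by_integer_voxels():
    data = np.full((9, 9, 9), -1000.0, np.float32)
    data[4, 4, 4] = 500.0
    out = apply_rigid_shift(hu(data), (2.0, -1.0, 3.0))
    assert np.unravel_index(np.argmax(out.data), out.data.shape) == (6, 3, 7)


def test_shift_inverse_recovers_interior():
    # affine field: linear interpolation reproduces it exactly, so the
    # shift-then-unshift composition is the identity away from the borders
    zz, yy, xx = np.mgrid[:12, :12, :12].astype(np.float32)
    smooth = 0.3 * zz + 0.5 * yy - 0.2 * xx + 5.0
    vol = hu(smooth)
    back = apply_rigid_shift(apply_rigid_shift(vol, (1.5, -0.5, 2.0)),
                             (-1.5, 0.5, -2.0))
    inner = (slice(3, -3),) * 3
    np.testing.assert_allclose(back.data[inner], smooth[inner], atol=1e-3)


def test_shift_fills_background_by_units():
    act = ImageVolume(np.ones((4, 4, 4), np.float32), (1, 1, 1),
                      units="kBq_per_mL")
    out = apply_rigid_shift(act, (2.0, 0, 0))
    assert out.data[0].max() == 0.0  # activity background is 0
    ct = apply_rigid_shift(hu(np.zeros((4, 4, 4))), (2.0, 0, 0))
    assert ct.data[0].min() == -1000.0  # HU background is air


# --- lung masking ---------------------------------------------------------

def _two_ellipsoid_ct(shape=(24, 32, 32)):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    cz, cy = shape[0] / 2, shape[1] / 2
    lungs = np.zeros(shape, bool)
    for cx in (shape[2] * 0.3, shape[2] * 0.7):
        lungs |= (((zz - cz) / (shape[0] * 0.33)) ** 2
                  + ((yy - cy) / (shape[1] * 0.28)) ** 2
                  + ((xx - cx) / (shape[2] * 0.14)) ** 2) <= 1
    body = (((zz - cz) / (shape[0] * 0.48)) ** 2
            + ((yy - cy) / (shape[1] * 0.42)) ** 2
            + ((xx - shape[2] / 2) / (shape[2] * 0.45)) ** 2) <= 1
    ct = np.full(shape, -1000.0, np.float32)
    ct[body] = 0.0
    ct[lungs] = -800.0
    return hu(ct), lungs


def test_lung_mask_recovers_ellipsoid_phantom():
    ct, lungs = _two_ellipsoid_ct()
    mask = compute_lung_mask(ct, closing_radius_vox=0, min_component_vox=10)
    jac = (mask.data & lungs).sum() / (mask.data | lungs).sum()
    assert jac >= 0.99


def test_lung_mask_degenerate_uniform_body():
    with pytest.raises(DegenerateCaseError, match="caseX"):
        compute_lung_mask(hu(np.zeros((8, 8, 8))), case_id="caseX")


def test_lung_mask_small_pocket_excluded():
    ct, lungs = _two_ellipsoid_ct()
    # a ~20-voxel air pocket inside the body, outside the lungs
    ct.data[2:4, 26:29, 14:18] = -900.0
    pocket = np.zeros_like(lungs)
    pocket[2:4, 26:29, 14:18] = True
    assert not (pocket & lungs).any()
    mask = compute_lung_mask(ct, closing_radius_vox=0, min_component_vox=100)
    assert not (mask.data & pocket).any()


# --- union / masking ------------------------------------------------------

def test_union_counts_and_idempotence():
    a = np.zeros((4, 4, 4), bool)
    b = np.zeros((4, 4, 4), bool)
    a.ravel()[:10] = True
    b.ravel()[30:50] = True
    ma, mb = LungMask(a, "exhale"), LungMask(b, "inhale")
    u = union_mask(ma, mb)
    assert u.n_voxels == 30 and u.source == "union"
    assert union_mask(ma, ma).n_voxels == ma.n_voxels


def test_union_size_property_random_masks():
    rng = np.random.default_rng(3)
    for _ in range(100):
        a = rng.random((5, 5, 5)) > 0.5
        b = rng.random((5, 5, 5)) > 0.5
        u = union_mask(LungMask(a, "exhale"), LungMask(b, "inhale"))
        assert u.n_voxels >= max(a.sum(), b.sum())


def test_mask_ct_fill_and_interior_preservation():
    rng = np.random.default_rng(4)
    data = rng.normal(0, 100, (6, 6, 6)).astype(np.float32)
    mask = np.zeros((6, 6, 6), bool)
    mask[:, :, :3] = True
    out = mask_ct(hu(data), LungMask(mask, "exhale"), fill_hu=-1000)
    np.testing.assert_array_equal(out.data[mask], data[mask])
    assert (out.data[~mask] == -1000).all()
    full = mask_ct(hu(data), LungMask(np.ones((6, 6, 6), bool), "exhale"))
    np.testing.assert_array_equal(full.data, data)


# --- crop / pad -----------------------------------------------------------

def test_crop_identity_when_shape_matches():
    vol = hu(np.random.default_rng(5).normal(size=(10, 12, 12)))
    out = crop_or_pad(vol, (10, 12, 12))
    np.testing.assert_array_equal(out.data, vol.data)


def test_crop_centers_on_mask_centroid():
    data = np.full((30, 40, 40), -1000.0, np.float32)
    mask = np.zeros((30, 40, 40), bool)
    mask[20:24, 28:32, 6:10] = True  # off-centre blob, centroid (21.5, 29.5, 7.5)
    data[22, 30, 8] = 777.0
    out = crop_or_pad(hu(data), (16, 16, 16), mask=LungMask(mask, "union"))
    marker = np.unravel_index(np.argmax(out.data), out.data.shape)
    assert all(abs(m - 8) <= 1 for m in marker)


def test_pad_symmetric_with_fill():
    vol = hu(np.zeros((4, 4, 4)))
    out = crop_or_pad(vol, (8, 8, 8))
    assert out.shape == (8, 8, 8)
    assert (out.data[:2] == -1000).all() and (out.data[-2:] == -1000).all()
    assert (out.data[2:6, 2:6, 2:6] == 0).all()


# --- normalization / standardization --------------------------------------

def test_minmax_three_values():
    out = minmax_normalize(hu(np.array([[[0.0, 5.0, 10.0]]])))
    np.testing.assert_allclose(out.data, [[[0.0, 0.5, 1.0]]])


def test_minmax_constant_is_zero():
    out = minmax_normalize(hu(np.full((3, 3, 3), 42.0)))
    assert (out.data == 0).all()


def test_minmax_spans_unit_interval():
    rng = np.random.default_rng(6)
    out = minmax_normalize(hu(rng.normal(size=(5, 5, 5))))
    assert out.data.min() == 0.0 and out.data.max() == 1.0


def test_minmax_monotone():
    rng = np.random.default_rng(7)
    data = rng.normal(size=(4, 4, 4))
    out = minmax_normalize(hu(data))
    assert (np.argsort(out.data.ravel(), kind="stable")
            == np.argsort(data.ravel(), kind="stable")).all()


def test_standardize_activity_hotspot_oracle():
    """99 voxels at 1.0 plus one at 1000.0: clip threshold is mu + 4*sigma
    with population sigma, ~408.6."""
    vals = np.ones(100, np.float64)
    vals[-1] = 1000.0
    mu, sigma = vals.mean(), vals.std()
    assert mu == pytest.approx(10.99)
    assert mu + 4 * sigma == pytest.approx(408.6, abs=0.1)
    data = vals.reshape(1, 10, 10).astype(np.float32)
    pet = ImageVolume(data, (1, 1, 1), units="kBq_per_mL")
    lung = LungMask(np.ones_like(data, bool), "union")
    out = standardize_activity(pet, lung)
    expected = np.minimum(vals, mu + 4 * sigma)
    expected = (expected - expected.min()) / (expected.max() - expected.min())
    np.testing.assert_allclose(out.data.ravel(), expected, rtol=1e-5, atol=1e-7)
    # exactly the hot spot sits at the clip threshold (normalized max)
    assert (out.data == out.data.max()).sum() == 1


def test_standardize_constant_lung_unchanged():
    data = np.full((2, 4, 4), 5.0, np.float32)
    pet = ImageVolume(data, (1, 1, 1), units="kBq_per_mL")
    lung = LungMask(np.ones_like(data, bool), "union")
    out = standardize_activity(pet, lung)
    # sigma = 0 -> threshold = mean -> nothing strictly greater is clipped;
    # constant volume then normalizes to zeros
    assert (out.data == 0).all()


def test_standardize_never_increases_and_empty_mask_errors():
    rng = np.random.default_rng(8)
    data = (rng.gamma(2.0, 2.0, (4, 8, 8))).astype(np.float32)
    pet = ImageVolume(data, (1, 1, 1), units="kBq_per_mL")
    lung = LungMask(data > 1.0, "union")
    vals = data[lung.data]
    thr = vals.mean() + 4 * vals.std()
    clipped = np.minimum(data, thr)
    out = standardize_activity(pet, lung)
    # monotone rescale of the clipped values: order preserved, none increased
    assert (np.argsort(out.data.ravel(), kind="stable")
            == np.argsort(clipped.ravel(), kind="stable")).all()
    with pytest.raises(DegenerateCaseError):
        standardize_activity(pet, LungMask(np.zeros_like(data, bool), "union"))


# --- case assembly ---------------------------------------------------------

def test_assemble_case_channel_structure():
    rng = np.random.default_rng(9)
    ex = hu(rng.normal(-500, 300, (8, 8, 8)))
    inh = hu(rng.normal(-500, 300, (8, 8, 8)))
    vent = ImageVolume(rng.random((8, 8, 8)).astype(np.float32), (1, 1, 1),
                       units="normalized")
    mask = LungMask(rng.random((8, 8, 8)) > 0.4, "exhale")
    un = LungMask(mask.data | (rng.random((8, 8, 8)) > 0.6), "union")
    case = assemble_case(CTVolumePair(exhale=ex, inhale=inh), vent, mask, un,
                         "t1")
    np.testing.assert_allclose(case.channels[2],
                               (case.channels[0] + case.channels[1]) / 2,
                               atol=1e-6)
    assert case.channels.min() >= 0 and case.channels.max() <= 1
    assert case.label.min() >= 0 and case.label.max() <= 1


def test_assemble_identical_phases_identical_channels():
    rng = np.random.default_rng(10)
    data = rng.normal(-500, 300, (6, 6, 6)).astype(np.float32)
    ex, inh = hu(data.copy()), hu(data.copy())
    vent = ImageVolume(rng.random((6, 6, 6)).astype(np.float32), (1, 1, 1),
                       units="normalized")
    mask = LungMask(np.ones((6, 6, 6), bool), "exhale")
    case = assemble_case(CTVolumePair(exhale=ex, inhale=inh), vent, mask,
                         LungMask(mask.data, "union"), "t2")
    np.testing.assert_array_equal(case.channels[0], case.channels[1])
    np.testing.assert_array_equal(case.channels[0], case.channels[2])


def test_full_preprocess_deterministic(phantom_case):
    kwargs = dict(target_spacing_mm=4.0, crop_shape=(40, 64, 64),
                  closing_radius_vox=1)
    a = preprocess_case(phantom_case.pair, phantom_case.pet_like, "d1", **kwargs)
    b = preprocess_case(phantom_case.pair, phantom_case.pet_like, "d1", **kwargs)
    np.testing.assert_array_equal(a.channels, b.channels)
    np.testing.assert_array_equal(a.label, b.label)
    np.testing.assert_array_equal(a.exhale_mask.data, b.exhale_mask.data)
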