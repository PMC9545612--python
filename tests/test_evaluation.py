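import numpy as np
import pytest

from ctvi_synth.errors import DegenerateCaseError, ParameterError
from ctvi_synth.evaluation import (
    HFL,
    LFL,
    MFL,
    OUTSIDE,
    EvaluationReport,
    aggregate_reports,
    dice_coefficient,
    equal_volume_tertiles,
    evaluate_case,
    spearman_masked,
)
from ctvi_synth.preprocessing import LungMask


def _vol_mask(values):
    """1D values embedded in a (1,1,n) grid with a full mask."""
    arr = np.asarray(values, np.float64).reshape(1, 1, -1)
    return arr, LungMask(np.ones_like(arr, bool), "exhale")


# --- Spearman ----------------------------------------------------------------

def test_spearman_identity_and_reversal():
    rng = np.random.default_rng(0)
    a = rng.random((4, 5, 5))
    mask = LungMask(rng.random((4, 5, 5)) > 0.3, "exhale")
    assert spearman_masked(a, a, mask) == pytest.approx(1.0)
    assert spearman_masked(a, -a, mask) == pytest.approx(-1.0)


def test_spearman_rank_formula_example():
    a, mask = _vol_mask([1, 2, 3, 4])
    b, _ = _vol_mask([1, 3, 2, 4])
    assert spearman_masked(a, b, mask) == pytest.approx(0.8)


def test_spearman_constant_input_raises():
    a, mask = _vol_mask([1, 1, 1, 1])
    b, _ = _vol_mask([1, 2, 3, 4])
    with pytest.raises(DegenerateCaseError):
        spearman_masked(a, b, mask)


def test_spearman_only_uses_masked_voxels():
    a, mask = _vol_mask([1, 2, 3, 4])
    b, _ = _vol_mask([1, 3, 2, 4])
    mask.data[0, 0, 3] = False
    a2 = a.copy()
    a2[0, 0, 3] = -99  # outside mask: must not matter
    assert spearman_masked(a, b, mask) == pytest.approx(
        spearman_masked(a2, b, mask)
    )


# --- tertiles ----------------------------------------------------------------

def test_tertiles_nine_distinct_values():
    vol, mask = _vol_mask([1, 2, 3, 4, 5, 6, 7, 8, 9])
    seg = equal_volume_tertiles(vol, mask)
    labels = seg.labels.ravel()
    assert (labels[:3] == LFL).all()
    assert (labels[3:6] == MFL).all()
    assert (labels[6:] == HFL).all()
    assert seg.thresholds == (3.0, 6.0)


def test_tertiles_remainder_low_to_high():
    vol, mask = _vol_mask(list(range(10)))
    seg = equal_volume_tertiles(vol, mask)
    labels = seg.labels.ravel()
    sizes = [(labels == r).sum() for r in (LFL, MFL, HFL)]
    assert sizes == [4, 3, 3]


def test_tertiles_stable_tie_break():
    vol, mask = _vol_mask([0, 0, 0, 0, 0, 0, 1, 2, 3])
    seg = equal_volume_tertiles(vol, mask)
    labels = seg.labels.ravel()
    assert (labels[:3] == LFL).all()
    assert (labels[3:6] == MFL).all()
    assert (labels[6:] == HFL).all()


def test_tertiles_region_counts_and_mask_partition():
    rng = np.random.default_rng(1)
    vol = rng.random((6, 7, 8))
    mask = LungMask(rng.random((6, 7, 8)) > 0.4, "exhale")
    seg = equal_volume_tertiles(vol, mask)
    counts = [(seg.labels == r).sum() for r in (LFL, MFL, HFL)]
    assert max(counts) - min(counts) <= 2
    assert (seg.labels[~mask.data] == OUTSIDE).all()
    assert ((seg.labels >= 0) == mask.data).all()


def test_tertiles_too_few_voxels():
    vol, _ = _vol_mask([1, 2])
    mask = LungMask(np.ones((1, 1, 2), bool), "exhale")
    with pytest.raises(DegenerateCaseError):
        equal_volume_tertiles(vol, mask)


# --- Dice --------------------------------------------------------------------

def test_dice_basic_cases():
    a = np.zeros((3, 3, 3), bool)
    b = np.zeros((3, 3, 3), bool)
    a[0], b[0] = True, True
    assert dice_coefficient(a, b) == 1.0
    b[:] = False
    b[1] = True
    assert dice_coefficient(a, b) == 0.0
    assert dice_coefficient(np.zeros((2, 2, 2), bool),
                            np.zeros((2, 2, 2), bool)) == 1.0


def test_dice_set_count_example():
    # TP=2, FP=1, FN=1 -> 2*2/(2*2+1+1) = 2/3
    a = np.array([[[1, 1, 1, 0]]], bool)
    b = np.array([[[1, 1, 0, 1]]], bool)
    assert dice_coefficient(a, b) == pytest.approx(2 / 3)


def test_dice_symmetry_and_identity_property():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = rng.random((4, 4, 4)) > 0.5
        b = rng.random((4, 4, 4)) > 0.5
        assert dice_coefficient(a, b) == dice_coefficient(b, a)
        assert (dice_coefficient(a, b) == 1.0) == np.array_equal(a, b)


# --- evaluate_case -------------------------------------------------------------

def test_evaluate_identity_maximal():
    rng = np.random.default_rng(3)
    vol = rng.random((5, 6, 6))
    mask = LungMask(rng.random((5, 6, 6)) > 0.3, "exhale")
    rep = evaluate_case(vol, vol, mask, "self")
    assert rep.spearman == pytest.approx(1.0)
    assert rep.dsc_hfl == rep.dsc_mfl == rep.dsc_lfl == 1.0
    assert rep.dsc_avg == 1.0


def test_evaluate_monotone_transform_invariant():
    rng = np.random.default_rng(4)
    vol = rng.permutation(5 * 6 * 6).reshape(5, 6, 6).astype(float)  # tie-free
    mask = LungMask(rng.random((5, 6, 6)) > 0.3, "exhale")
    rep = evaluate_case(np.exp(vol / 100), vol, mask)
    assert rep.spearman == pytest.approx(1.0)
    assert rep.dsc_avg == 1.0


def test_evaluate_reversal():
    rng = np.random.default_rng(5)
    vol = rng.permutation(4 * 5 * 5).reshape(4, 5, 5).astype(float)
    mask = LungMask(np.ones((4, 5, 5), bool), "exhale")
    rep = evaluate_case(1.0 - vol / vol.max(), vol, mask)
    assert rep.spearman == pytest.approx(-1.0)
    assert rep.dsc_hfl == pytest.approx(0.0)
    assert rep.dsc_lfl == pytest.approx(0.0)


# --- aggregation ---------------------------------------------------------------

def _rep(cid, sp, h, m, l):
    return EvaluationReport(cid, sp, h, m, l)


def test_aggregate_single_and_pair():
    df = aggregate_reports([_rep("a", 0.5, 0.6, 0.4, 0.6)])
    assert df.loc[df.metric == "Spearman correlation", "mean"].item() == 0.5
    assert (df["sd"] == 0).all()
    df2 = aggregate_reports([_rep("a", 0.4, 0.5, 0.5, 0.5),
                             _rep("b", 0.6, 0.5, 0.5, 0.5)])
    assert df2.loc[df2.metric == "Spearman correlation", "mean"].item() == pytest.approx(0.5)


def test_aggregate_sample_sd_three_values():
    vals = [0.2, 0.5, 0.8]
    reports = [_rep(str(i), v, v, v, v) for i, v in enumerate(vals)]
    df = aggregate_reports(reports)
    expected_sd = np.std(vals, ddof=1)
    assert df.loc[df.metric == "DSC average", "sd"].item() == pytest.approx(expected_sd)
    with pytest.raises(ParameterError):
        aggregate_reports([])


def test_report_dsc_avg_is_exact_mean():
    rep = _rep("x", 0.1, 0.3, 0.4, 0.5)
    assert rep.dsc_avg == (0.3 + 0.4 + 0.5) / 3


# --- property tests -------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.lists(st.floats(0, 1, allow_nan=False, width=32), min_size=3,
                max_size=60))
def test_tertile_partition_properties(values):
    """For any masked value list: regions partition the mask, sizes differ
    pairwise by <= 1 beyond the remainder rule, and region values are
    ordered LFL <= MFL <= HFL at the boundaries."""
    vol, mask = _vol_mask(values)
    seg = equal_volume_tertiles(vol, mask)
    labels = seg.labels.ravel()
    n = len(values)
    counts = [(labels == r).sum() for r in (LFL, MFL, HFL)]
    assert sum(counts) == n
    assert max(counts) - min(counts) <= 1
    arr = np.asarray(values, float)
    assert seg.thresholds[0] <= seg.thresholds[1]
    # region values respect the thresholds
    assert arr[labels == LFL].max() <= seg.thresholds[0]
    assert arr[labels == HFL].min() >= seg.thresholds[1]


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.integers(0, 2**12 - 1), st.integers(0, 2**12 - 1))
def test_dice_bounds_and_symmetry(bits_a, bits_b):
    a = np.array([(bits_a >> i) & 1 for i in range(12)], bool).reshape(1, 3, 4)
    b = np.array([(bits_b >> i) & 1 for i in range(12)], bool).reshape(1, 3, 4)
    d = dice_coefficient(a, b)
    assert 0.0 <= d <= 1.0
    assert d == dice_coefficient(b, a)
    assert (d == 1.0) == np.array_equal(a, b)
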