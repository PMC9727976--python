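"""Confusion metrics, radial boundary distances, BLE and vertical CDR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.ndimage import binary_erosion

from fundusseg.metrics import (ConfusionCounts, ble, confusion_counts,
                               evaluate_masks, f1_score, precision_recall,
                               radial_boundary, rate_metrics, vertical_cdr)

from conftest import disc_mask

counts_strategy = st.tuples(st.integers(0, 500), st.integers(0, 500),
                            st.integers(0, 500), st.integers(0, 500))


# ---------------------------------------------------------------- confusion
def test_confusion_counts_toy_enumeration():
    gt = np.zeros((3, 3), dtype=np.uint8)
    gt[0, 0] = gt[0, 1] = gt[1, 0] = 2          # 3 cup pixels
    pred = np.zeros((3, 3), dtype=np.uint8)
    pred[0, 0] = pred[0, 1] = 2                  # hits 2 of them
    pred[2, 2] = 2                               # plus 1 background pixel
    c = confusion_counts(pred, gt, "OC")
    assert (c.TP, c.FP, c.FN, c.TN) == (2, 1, 1, 5)


def test_confusion_counts_all_cup_on_background():
    gt = np.zeros((2, 2), dtype=np.uint8)
    pred = np.full((2, 2), 2, dtype=np.uint8)
    c = confusion_counts(pred, gt, "OC")
    assert (c.TP, c.FP, c.TN, c.FN) == (0, 4, 0, 0)


def test_confusion_perfect_prediction_has_no_errors(synthetic_sample):
    _, mask, _ = synthetic_sample
    for structure in ("OD", "OC"):
        c = confusion_counts(mask, mask, structure)
        assert c.FP == 0 and c.FN == 0


def test_od_positive_class_includes_cup_pixels():
    gt = np.array([[0, 1], [2, 2]], dtype=np.uint8)
    pred = np.array([[0, 1], [1, 1]], dtype=np.uint8)
    c = confusion_counts(pred, gt, "OD")
    assert c.TP == 3 and c.FN == 0 and c.FP == 0


def test_confusion_input_validation():
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((2, 2)), np.zeros((3, 3)), "OD")
    with pytest.raises(ValueError):
        confusion_counts(np.full((2, 2), 7), np.zeros((2, 2)), "OD")
    with pytest.raises(ValueError):
        confusion_counts(np.zeros((2, 2)), np.zeros((2, 2)), "disc")


# ---------------------------------------------------------------- F1 / rates
@pytest.mark.parametrize("tp,fp,fn,expected", [
    (4, 0, 0, 1.0),
    (0, 3, 2, 0.0),
    (6, 2, 2, 0.75),
])
def test_f1_examples(tp, fp, fn, expected):
    c = ConfusionCounts(TP=tp, FP=fp, TN=0, FN=fn)
    assert f1_score(c) == pytest.approx(expected)
    if expected == 0.75:
        assert precision_recall(c) == (0.75, 0.75)


def test_rate_metrics_examples():
    assert rate_metrics(ConfusionCounts(TP=10, FP=0, TN=20, FN=0)) == \
        (1.0, 1.0, 1.0)
    assert rate_metrics(ConfusionCounts(TP=0, FP=20, TN=0, FN=10)) == \
        (0.0, 0.0, 0.0)
    spc, sen, acc = rate_metrics(ConfusionCounts(TP=8, FN=2, TN=15, FP=5))
    assert (spc, sen) == (0.75, 0.8)
    assert acc == pytest.approx(23 / 30)


def test_rate_metrics_degenerate_is_nan_not_zero():
    spc, sen, acc = rate_metrics(ConfusionCounts(TP=0, FP=0, TN=5, FN=0))
    assert np.isnan(sen) and spc == 1.0 and acc == 1.0


@given(counts_strategy)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_accuracy_decomposition_identity(counts):
    tp, fp, tn, fn = counts
    c = ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)
    if c.P == 0 or c.N == 0:
        return
    spc, sen, acc = rate_metrics(c)
    decomposed = spc * c.N / (c.P + c.N) + sen * c.P / (c.P + c.N)
    assert acc == pytest.approx(decomposed, abs=1e-12)


@given(counts_strategy)
@settings(max_examples=100, deadline=None, derandomize=True)
def test_f1_symmetric_in_fp_fn_and_bounded(counts):
    tp, fp, tn, fn = counts
    a = f1_score(ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn))
    b = f1_score(ConfusionCounts(TP=tp, FP=fn, TN=tn, FN=fp))
    assert a == pytest.approx(b)
    assert 0.0 <= a <= 1.0
    if tp > 0 and fp == 0 and fn == 0:
        assert a == 1.0
    if tp > 0 and (fp > 0 or fn > 0):
        assert a < 1.0


# ---------------------------------------------------------------- boundaries
def _fine_radial_oracle(mask, structure, center, n_dirs, step=0.005):
    """Independent ray-marching at a 100x finer step."""
    pos = np.isin(mask, (1, 2) if structure == "OD" else (2,))
    h, w = mask.shape
    cx, cy = center
    ts = np.arange(0.0, np.hypot(h, w) + step, step)
    out = np.zeros(n_dirs)
    for k in range(n_dirs):
        theta = 2 * np.pi * k / n_dirs
        xs = np.ceil(cx + ts * np.cos(theta) - 0.5).astype(int)
        ys = np.ceil(cy + ts * np.sin(theta) - 0.5).astype(int)
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        hit = np.zeros(ts.shape, bool)
        hit[ok] = pos[ys[ok], xs[ok]]
        if hit.any():
            out[k] = ts[np.nonzero(hit)[0][-1]]
    return out


def test_radial_boundary_filled_disc_radius_30():
    mask = disc_mask(101, (50, 50), disc_radius=30, cup_radius=0)
    rb = radial_boundary(mask, "OD", (50, 50), n_dirs=24)
    assert not rb.empty
    # the rasterised circle itself deviates up to ~1 px from the ideal
    # radius along oblique directions (pixel-centre inclusion)
    np.testing.assert_allclose(rb.distances, 30.0, atol=1.0)
    np.testing.assert_allclose(rb.distances.mean(), 30.0, atol=0.5)


def test_radial_boundary_empty_mask_flagged():
    rb = radial_boundary(np.zeros((20, 20), dtype=np.uint8), "OC", (10, 10))
    assert rb.empty and np.all(rb.distances == 0)


def test_radial_boundary_half_plane():
    mask = np.zeros((41, 41), dtype=np.uint8)
    mask[:, 20:] = 1
    rb = radial_boundary(mask, "OD", (20, 20), n_dirs=4)
    assert rb.distances[2] == 0.0            # theta = pi points left
    assert rb.distances[0] == pytest.approx(20.0, abs=0.5)  # to the border


def _random_star_blob(rng, size=64, base_radius=18.0, amplitude=4.0):
    """Random smooth star-shaped blob: r(theta) from low-order harmonics,
    so every ray from the centre crosses the boundary exactly once."""
    coeffs = rng.normal(size=4)
    cx, cy = size / 2 + rng.uniform(-3, 3), size / 2 + rng.uniform(-3, 3)
    yy, xx = np.mgrid[0:size, 0:size]
    theta = np.arctan2(yy - cy, xx - cx)
    r_bound = base_radius + amplitude * (
        coeffs[0] * np.sin(theta) + coeffs[1] * np.cos(theta) +
        0.5 * coeffs[2] * np.sin(2 * theta) +
        0.5 * coeffs[3] * np.cos(2 * theta)) / np.sum(np.abs(coeffs))
    mask = (np.hypot(xx - cx, yy - cy) <= r_bound).astype(np.uint8)
    return mask, (cx, cy)


def test_radial_boundary_agrees_with_fine_oracle(rng):
    for trial in range(10):
        mask, center = _random_star_blob(rng)
        got = radial_boundary(mask, "OD", center, n_dirs=24).distances
        want = _fine_radial_oracle(mask, "OD", center, 24)
        np.testing.assert_allclose(got, want, atol=0.5)


def test_ble_identical_masks_is_zero(rng):
    for _ in range(20):
        mask = (rng.random((32, 32)) < 0.3).astype(np.uint8)
        mask[16, 16] = 1
        assert ble(mask, mask, "OD", (16, 16)) == 0.0


def test_ble_concentric_discs_radius_difference():
    gt = disc_mask(121, (60, 60), disc_radius=50, cup_radius=0)
    pred = disc_mask(121, (60, 60), disc_radius=45, cup_radius=0)
    assert ble(pred, gt, "OD", (60, 60), n_dirs=24) == \
        pytest.approx(5.0, abs=0.5)


def test_ble_shifted_disc_matches_fine_oracle():
    gt = disc_mask(141, (70, 70), disc_radius=40, cup_radius=0)
    pred = np.zeros_like(gt)
    pred[:, 10:] = gt[:, :-10]  # shift +10 px along x
    center = (70, 70)
    got = ble(pred, gt, "OD", center, n_dirs=24)
    want = np.mean(np.abs(_fine_radial_oracle(gt, "OD", center, 24, 0.01) -
                          _fine_radial_oracle(pred, "OD", center, 24, 0.01)))
    assert got == pytest.approx(want, abs=0.5)


def test_ble_erosion_monotonicity():
    gt = disc_mask(121, (60, 60), disc_radius=45, cup_radius=0)
    previous = 0.0
    yy, xx = np.mgrid[-6:7, -6:7]
    for k in (2, 4, 6):
        ball = xx ** 2 + yy ** 2 <= k ** 2  # Euclidean (uniform) erosion
        eroded = binary_erosion(gt, structure=ball).astype(np.uint8)
        value = ble(eroded, gt, "OD", (60, 60))
        assert value == pytest.approx(k, abs=0.5)
        assert value > previous
        previous = value


def test_ble_rotation_invariance():
    gt = disc_mask(121, (60, 60), disc_radius=42, cup_radius=0)
    pred = disc_mask(121, (60, 60), disc_radius=38, cup_radius=0)
    base = ble(pred, gt, "OD", (60, 60), n_dirs=4)
    # rotating both masks by 90 degrees about the centre (exact for arrays)
    rotated = ble(np.rot90(pred).copy(), np.rot90(gt).copy(), "OD", (60, 60),
                  n_dirs=4)
    assert rotated == pytest.approx(base, abs=0.5)


def test_ble_printed_radicand_form():
    gt = disc_mask(121, (60, 60), disc_radius=50, cup_radius=0)
    pred = disc_mask(121, (60, 60), disc_radius=45, cup_radius=0)
    # prediction inside ground truth: radicand nonnegative, value defined
    v = ble(pred, gt, "OD", (60, 60), printed_radicand=True)
    assert v == pytest.approx(np.sqrt(50 ** 2 - 45 ** 2), rel=0.05)
    with pytest.raises(ValueError):
        ble(gt, pred, "OD", (60, 60), printed_radicand=True)


def test_ble_missing_structure_degenerates_with_warning():
    gt = disc_mask(61, (30, 30), disc_radius=20, cup_radius=0)
    empty = np.zeros_like(gt)
    with pytest.warns(UserWarning):
        v = ble(empty, gt, "OD", (30, 30))
    assert v == pytest.approx(20.0, abs=0.5)


# ---------------------------------------------------------------- CDR
def test_vertical_cdr_concentric_discs():
    mask = disc_mask(121, (60, 60), disc_radius=50, cup_radius=25)
    assert vertical_cdr(mask) == pytest.approx(51 / 101, abs=1e-9)


def test_vertical_cdr_degenerate_cases():
    full_cup = np.full((10, 10), 2, dtype=np.uint8)
    assert vertical_cdr(full_cup) == 1.0
    disc_only = disc_mask(61, (30, 30), disc_radius=20, cup_radius=0)
    assert vertical_cdr(disc_only) == 0.0
    with pytest.warns(UserWarning):
        assert np.isnan(vertical_cdr(np.zeros((5, 5), dtype=np.uint8)))


def test_evaluate_masks_report_is_complete(synthetic_sample):
    _, mask, center = synthetic_sample
    row = evaluate_masks(mask, mask, center=center)
    for structure in ("OD", "OC"):
        assert row[f"F1_{structure}"] == 1.0
        assert row[f"BLE_{structure}"] == 0.0
    assert row["CDR_pred"] == row["CDR_gt"]
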