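"""Segmentation metrics against brute-force oracles and boundary rules."""

import numpy as np
import pytest

from csvdseg.seg_metrics import (confusion_counts, precision, specificity,
                                 dice_from_counts, hd95, extract_lesions,
                                 per_lesion_sensitivity, bootstrap_ci,
                                 patient_metrics, ConfusionCounts)
from csvdseg.training import dice_loss
from oracles import confusion_oracle, hd95_oracle


def random_mask(rng, shape, p=0.15):
    m = rng.random(shape) < p
    return m


# ---------------------------------------------------------------------------
# confusion metrics
# ---------------------------------------------------------------------------

def test_confusion_trivial_cases():
    a = np.ones((10, 10), dtype=bool)
    b = np.zeros((10, 10), dtype=bool)
    c = confusion_counts(a, b)
    assert (c.tp, c.fp, c.fn, c.tn) == (0, 100, 0, 0)
    c2 = confusion_counts(a, a)
    assert c2.fp == c2.fn == 0 and c2.total == 100


def test_confusion_rejects_nonbinary():
    with pytest.raises(ValueError):
        confusion_counts(np.array([0.3, 0.7]), np.array([0, 1]))


def test_formula_examples():
    assert precision(ConfusionCounts(tp=3, tn=0, fp=1, fn=0)) == 0.75
    assert dice_from_counts(ConfusionCounts(tp=4, tn=0, fp=1, fn=1)) == 0.8
    assert specificity(ConfusionCounts(tp=0, tn=90, fp=10, fn=0)) == 0.9


def test_empty_mask_conventions():
    empty = ConfusionCounts(tp=0, tn=50, fp=0, fn=0)
    assert precision(empty) == specificity(empty) == dice_from_counts(empty) == 1.0
    one_empty = ConfusionCounts(tp=0, tn=40, fp=0, fn=10)
    assert dice_from_counts(one_empty) == 0.0


def test_confusion_matches_loop_oracle(rng):
    for _ in range(20):
        shape = tuple(rng.integers(3, 17, 3))
        p, t = random_mask(rng, shape), random_mask(rng, shape)
        c = confusion_counts(p, t)
        assert (c.tp, c.tn, c.fp, c.fn) == (confusion_oracle(p, t)[0],
                                            confusion_oracle(p, t)[1],
                                            confusion_oracle(p, t)[2],
                                            confusion_oracle(p, t)[3])


def test_dice_from_counts_equals_one_minus_dice_loss(rng):
    for _ in range(10):
        p = random_mask(rng, (8, 8, 4), 0.3)
        t = random_mask(rng, (8, 8, 4), 0.3)
        c = confusion_counts(p, t)
        assert abs(dice_from_counts(c)
                   - (1.0 - dice_loss(t.astype(float), p.astype(float),
                                      smooth=0.0))) < 1e-9


# ---------------------------------------------------------------------------
# HD95
# ---------------------------------------------------------------------------

def test_hd95_trivial_geometry():
    a = np.zeros((9, 9, 9), dtype=bool)
    a[4, 4, 2] = True
    b = np.zeros((9, 9, 9), dtype=bool)
    b[4, 4, 5] = True
    assert np.isclose(hd95(a, b, (1, 1, 1)), 3.0)
    assert hd95(a, a) == 0.0


def test_hd95_empty_mask_is_missing_not_zero():
    a = np.zeros((4, 4, 4), dtype=bool)
    b = np.ones((4, 4, 4), dtype=bool)
    assert np.isnan(hd95(a, b))
    assert np.isnan(hd95(b, a))


def test_hd95_matches_brute_force_oracle(rng):
    spacings = [(1, 1, 1), (1, 1, 2.5), (0.5, 0.9, 6)]
    for i in range(15):
        shape = tuple(rng.integers(4, 11, 3))
        a, b = random_mask(rng, shape, 0.25), random_mask(rng, shape, 0.25)
        if not (a.any() and b.any()):
            continue
        sp = np.array(spacings[i % 3], dtype=float)
        assert abs(hd95(a, b, sp) - hd95_oracle(a, b, sp)) < 1e-6
        # symmetry and upper bound by the exact Hausdorff distance
        assert np.isclose(hd95(a, b, sp), hd95(b, a, sp))
        assert hd95(a, b, sp) <= hd95(a, b, sp, method="scaled_max") / 0.95 + 1e-12


def test_hd95_scaled_max_variant():
    a = np.zeros((10, 1, 1), dtype=bool)
    a[0] = True
    b = np.zeros((10, 1, 1), dtype=bool)
    b[9] = True
    assert np.isclose(hd95(a, b, (1, 1, 1), method="scaled_max"), 9 * 0.95)


# ---------------------------------------------------------------------------
# lesion instances and lesion-wise sensitivity
# ---------------------------------------------------------------------------

def test_extract_lesions_components():
    m = np.zeros((12, 12, 6), dtype=bool)
    m[1:4, 1:4, 1:3] = True
    m[8:11, 8:11, 3:5] = True
    inst = extract_lesions(m, spacing=(1, 1, 2))
    assert len(inst) == 2
    assert sum(i.volume_mm3 for i in inst) == m.sum() * 2
    assert extract_lesions(np.zeros((4, 4), dtype=bool)) == []


def test_diagonal_voxels_single_component():
    m = np.zeros((3, 3, 3), dtype=bool)
    m[0, 0, 0] = m[1, 1, 1] = True        # touch only at a corner
    assert len(extract_lesions(m)) == 1
    m2 = np.zeros((3, 3), dtype=bool)
    m2[0, 0] = m2[1, 1] = True            # 8-connectivity in 2-D
    assert len(extract_lesions(m2)) == 1


def test_half_coverage_boundary_rule():
    truth = np.zeros((10, 10), dtype=bool)
    truth[0, :10] = True                  # one 10-voxel lesion
    inst = extract_lesions(truth)
    pred5 = np.zeros_like(truth)
    pred5[0, :5] = True
    assert per_lesion_sensitivity(pred5, inst)[0] == 1.0   # exactly 50% -> TP
    pred4 = np.zeros_like(truth)
    pred4[0, :4] = True
    assert per_lesion_sensitivity(pred4, inst)[0] == 0.0   # 40% -> FN


def test_per_lesion_sensitivity_counts_and_invariance(rng):
    truth = np.zeros((30, 10), dtype=bool)
    truth[0:1, 0:10] = True       # covered 100%
    truth[10:11, 0:10] = True     # covered 60%
    truth[20:21, 0:10] = True     # covered 10%
    pred = np.zeros_like(truth)
    pred[0, :] = True
    pred[10, :6] = True
    pred[20, :1] = True
    inst = extract_lesions(truth)
    sen, tp, fn = per_lesion_sensitivity(pred, inst)
    assert (tp, fn) == (2, 1) and np.isclose(sen, 2 / 3)
    order = rng.permutation(len(inst))
    sen2, _, _ = per_lesion_sensitivity(pred, [inst[i] for i in order])
    assert sen2 == sen
    assert np.isnan(per_lesion_sensitivity(pred, [])[0])


# ---------------------------------------------------------------------------
# bootstrap CI
# ---------------------------------------------------------------------------

def test_bootstrap_degenerate_and_coverage(rng):
    lo, hi = bootstrap_ci([0.7] * 10, n_boot=200, seed=0)
    assert lo == hi == 0.7
    x = rng.normal(0.5, 0.1, 200)
    lo, hi = bootstrap_ci(x, n_boot=2000, seed=0)
    assert lo <= x.mean() <= hi
    lo5, hi5 = bootstrap_ci(x[:5], n_boot=2000, seed=0)
    assert (hi5 - lo5) > (hi - lo)        # fewer patients, wider interval
    with pytest.warns(UserWarning):
        bootstrap_ci(x[:5], n_boot=50, seed=0)


def test_perfect_prediction_metrics():
    truth = np.zeros((12, 12, 8), dtype=bool)
    truth[3:6, 3:6, 2:5] = True
    row = patient_metrics(truth, truth, spacing=(1, 1, 1))
    assert row["precision"] == row["specificity"] == row["dice"] == 1.0
    assert row["hd95_mm"] == 0.0
    assert row["lesion_sen"] == 1.0
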