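"""Loss closed forms, LR schedule, early stopping, gradient flow, nested CV."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from csvdseg import training
from csvdseg.nn import Tensor
from csvdseg.io_preprocess import SliceSample, make_fold_plan
from csvdseg.mo_unet import NetworkConfig, build_mo_unet
from csvdseg.training import (TrainConfig, cross_entropy_loss, dice_loss,
                              total_loss, lr_at_step, train_one_iteration,
                              run_nested_cv)


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("y, p, expected", [
    ([1.0], [0.5], math.log(2)),
    ([1.0, 0.0], [0.9, 0.2], -(math.log(0.9) + math.log(0.8)) / 2),
])
def test_cross_entropy_closed_forms(y, p, expected):
    assert np.isclose(cross_entropy_loss(np.array(y), np.array(p)), expected,
                      atol=1e-12)


def test_cross_entropy_perfect_prediction_near_zero():
    y = np.array([1.0, 0.0, 1.0])
    assert cross_entropy_loss(y, y) < 1e-6


def test_cross_entropy_shape_mismatch():
    with pytest.raises(ValueError):
        cross_entropy_loss(np.zeros(3), np.zeros(4))


def test_dice_loss_identity_disjoint_and_half():
    x = np.zeros(10)
    x[:4] = 1
    assert dice_loss(x, x) < 0.2            # ~0 up to smoothing
    assert dice_loss(x, x, smooth=0.0) == 0.0
    y = np.zeros(10)
    y[4:8] = 1
    assert dice_loss(x, y, smooth=0.0) == 1.0
    half = np.where(x > 0, 0.5, 0.0)
    assert np.isclose(dice_loss(x, half, smooth=0.0), 1.0 / 3.0)


def test_total_loss_additivity_and_bounds(rng):
    y = (rng.random(50) > 0.6).astype(float)
    p = rng.uniform(0.05, 0.95, 50)
    ce, dc = cross_entropy_loss(y, p), dice_loss(y, p)
    tot = total_loss(y, p)
    assert abs(tot - (ce + dc)) < 1e-9
    assert tot >= max(ce, dc)
    assert total_loss(y, y) < 0.1            # perfect prediction ~ 0


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.booleans(), min_size=1, max_size=40).flatmap(
    lambda ys: st.tuples(
        st.just(np.array(ys, dtype=float)),
        st.lists(st.floats(0.001, 0.999), min_size=len(ys),
                 max_size=len(ys)).map(np.array))))
def test_loss_properties_hold_for_arbitrary_inputs(pair):
    """CE and Dice losses are non-negative and total decomposes exactly."""
    y, p = pair
    ce = cross_entropy_loss(y, p)
    dc = dice_loss(y, p)
    assert ce >= 0.0
    assert 0.0 <= dc <= 1.0
    assert abs(total_loss(y, p) - (ce + dc)) < 1e-9


def test_loss_decomposition_on_tensors(rng):
    y = Tensor((rng.random((2, 1, 8, 8)) > 0.7).astype(float))
    p = Tensor(rng.uniform(0.01, 0.99, (2, 1, 8, 8)))
    resid = total_loss(y, p).data - (cross_entropy_loss(y, p).data
                                     + dice_loss(y, p).data)
    assert abs(float(resid)) < 1e-9


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

def test_lr_schedule_closed_form():
    assert abs(lr_at_step(0) - 0.001) < 1e-12
    assert abs(lr_at_step(500) - 0.00095) < 1e-12
    assert abs(lr_at_step(1000) - 0.0009025) < 1e-12


def test_lr_monotone_nonincreasing():
    lrs = [lr_at_step(s) for s in range(0, 3000, 37)]
    assert all(b <= a for a, b in zip(lrs, lrs[1:]))


def test_lr_negative_step_rejected():
    with pytest.raises(ValueError):
        lr_at_step(-1)


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def _blob_samples(n, pid_prefix, rng, size=16):
    """FLAIR slices with a bright square blob labelled as WMH."""
    out = []
    for i in range(n):
        img = rng.normal(0.2, 0.02, (size, size))
        mask = np.zeros((size, size), dtype=bool)
        r, c = rng.integers(2, size - 6, 2)
        mask[r:r + 4, c:c + 4] = True
        img[mask] = 0.9
        out.append(SliceSample(f"{pid_prefix}{i % 5}", "FLAIR", i,
                               np.clip(img, 0, 1),
                               {"WMH": mask, "lacune": np.zeros_like(mask)}))
    return out


def small_cfg():
    return NetworkConfig(input_size=16, encoder_stage_widths=(4, 8))


def test_training_loss_decreases_and_lr_wiring(rng):
    train_s = _blob_samples(20, "TR", rng)
    val_s = _blob_samples(8, "VA", rng)
    model = build_mo_unet(small_cfg(), seed=0)
    cfg = TrainConfig(max_epochs=10, patience=10, seed=0)
    model, hist = train_one_iteration(model, train_s, val_s, cfg)
    assert hist.train_loss[-1] < hist.train_loss[0]
    # recorded LR matches the schedule at the cumulative step count
    steps_per_epoch = math.ceil(20 / cfg.batch_size)
    for e, lr in enumerate(hist.lr):
        assert np.isclose(lr, lr_at_step(steps_per_epoch * (e + 1), cfg))


def test_gradient_flows_into_shared_encoder(rng):
    model = build_mo_unet(small_cfg(), seed=0)
    before = [p.data.copy() for p in model.encoder.parameters()]
    train_s = _blob_samples(6, "TR", rng)
    cfg = TrainConfig(max_epochs=1, patience=1, seed=0)
    model, _ = train_one_iteration(model, train_s, _blob_samples(4, "VA", rng), cfg)
    after = [p.data for p in model.encoder.parameters()]
    assert any(not np.array_equal(a, b) for a, b in zip(before, after))


def test_patient_leakage_rejected(rng):
    model = build_mo_unet(small_cfg(), seed=0)
    s = _blob_samples(4, "X", rng)
    with pytest.raises(ValueError, match="leakage"):
        train_one_iteration(model, s, s, TrainConfig(max_epochs=1, patience=1))


def test_early_stopping_counter_semantics(monkeypatch, rng):
    """Improvement through epoch 3, strict worsening after -> stop at epoch 8."""
    metrics = iter([0.1, 0.2, 0.3, 0.29, 0.28, 0.27, 0.26, 0.25, 0.24, 0.23])
    monkeypatch.setattr(training, "evaluate_dice",
                        lambda model, samples, threshold=0.5: {"WMH": next(metrics)})
    model = build_mo_unet(small_cfg(), seed=0)
    cfg = TrainConfig(max_epochs=20, patience=5, seed=0)
    _, hist = train_one_iteration(model, _blob_samples(6, "TR", rng),
                                  _blob_samples(4, "VA", rng), cfg)
    assert hist.stopped_epoch == 8
    assert len(hist.train_loss) == 8


def test_nonfinite_loss_aborts_with_last_good_state(monkeypatch, rng):
    model = build_mo_unet(small_cfg(), seed=0)
    calls = {"n": 0}
    orig = training._batch_loss

    def exploding(model_, tag, batch, config):
        calls["n"] += 1
        loss = orig(model_, tag, batch, config)
        if calls["n"] > 4:
            loss.data = np.array(np.nan)
        return loss

    monkeypatch.setattr(training, "_batch_loss", exploding)
    cfg = TrainConfig(max_epochs=5, patience=5, seed=0)
    model, hist = train_one_iteration(model, _blob_samples(12, "TR", rng),
                                      _blob_samples(4, "VA", rng), cfg)
    assert hist.aborted


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def _fast_cv(monkeypatch, width_to_metric):
    """Bypass optimisation so CV bookkeeping can be tested exactly."""
    monkeypatch.setattr(training, "train_one_iteration",
                        lambda model, tr, va, cfg: (model, training.TrainHistory()))
    tested = []

    def fake_eval(model, samples, threshold=0.5):
        pids = {s.patient_id for s in samples}
        tested.append(pids)
        w = model.config.encoder_stage_widths[0]
        return {"WMH": width_to_metric[w]}

    monkeypatch.setattr(training, "evaluate_dice", fake_eval)
    return tested


def test_nested_cv_contract_and_dominant_point(monkeypatch, rng):
    pids = [f"P{i}" for i in range(10)]
    samples = {p: [SliceSample(p, "FLAIR", 0, np.zeros((16, 16)),
                               {"WMH": np.zeros((16, 16), dtype=bool),
                                "lacune": np.zeros((16, 16), dtype=bool)})]
               for p in pids}
    plan = make_fold_plan(pids, k=5, seed=1)
    _fast_cv(monkeypatch, {4: 0.3, 8: 0.9})
    grid = [{"encoder_stage_widths": (4, 8)}, {"encoder_stage_widths": (8, 16)}]
    res = run_nested_cv(samples, plan, grid,
                        network_config=small_cfg(), seed=0)
    assert len(res) == 5
    # each patient is tested exactly once across the 5 held-out evaluations
    tested = [p for r in res for f in [plan.iterations[r["fold"]]["test"]] for p in f]
    assert sorted(tested) == sorted(pids)
    # the point dominating validation Dice on every fold is always chosen
    assert all(r["chosen"] == grid[1] for r in res)


def test_nested_cv_degenerate_and_empty_grid(monkeypatch):
    pids = [f"P{i}" for i in range(5)]
    samples = {p: [SliceSample(p, "FLAIR", 0, np.zeros((16, 16)),
                               {"WMH": np.zeros((16, 16), dtype=bool),
                                "lacune": np.zeros((16, 16), dtype=bool)})]
               for p in pids}
    plan = make_fold_plan(pids, k=5, seed=0)
    with pytest.raises(ValueError):
        run_nested_cv(samples, plan, [], network_config=small_cfg())
    _fast_cv(monkeypatch, {4: 0.5})
    res = run_nested_cv(samples, plan, [{"encoder_stage_widths": (4, 8)}],
                        network_config=small_cfg())
    assert all(r["chosen"] == {"encoder_stage_widths": (4, 8)} for r in res)
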