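"""Losses, learning-rate schedule, optimisation loop and nested cross-validation.

The segmentation loss is the sum of pixelwise binary cross-entropy and soft
Dice loss, L = L_ce + L_dice.  Optimisation uses Adam with L2 weight decay
(lambda = 1e-4) and an exponentially decaying learning rate
lr(step) = lr_initial * rate^(step / step_decay) with a continuous exponent.
Training stops after ``max_epochs`` or when the validation metric (mean
validation Dice over the active markers) fails to improve for ``patience``
consecutive epochs; the best-validation checkpoint is returned.

Model selection uses patient-level nested cross-validation: for each of the
k outer folds the remaining patients are split 80:20 into train/validation,
hyperparameters are tuned on that inner split, and the winner is evaluated
once on the held-out fold.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import nn
from .nn import Tensor
from .mo_unet import NetworkConfig, MOUNet, build_mo_unet


@dataclasses.dataclass
class TrainConfig:
    lr_initial: float = 0.001
    decay_rate: float = 0.95
    decay_step: int = 500
    weight_decay: float = 0.0001
    batch_size: int = 6
    max_epochs: int = 100
    patience: int = 5
    norm_epsilon: float = 0.001
    norm_momentum: float = 0.99
    eps_clip: float = 1e-7
    dice_smooth: float = 1.0
    seed: int = 0

    def validate(self):
        for f in ("lr_initial", "decay_rate", "decay_step", "batch_size",
                  "max_epochs", "patience"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")


@dataclasses.dataclass
class TrainHistory:
    train_loss: list = dataclasses.field(default_factory=list)
    val_loss: list = dataclasses.field(default_factory=list)
    val_dice: list = dataclasses.field(default_factory=list)   # dicts per marker
    lr: list = dataclasses.field(default_factory=list)
    stopped_epoch: int | None = None
    aborted: bool = False


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def _pair(y, y_hat):
    y_t = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float64))
    p_t = y_hat if isinstance(y_hat, Tensor) else Tensor(np.asarray(y_hat, dtype=np.float64))
    if y_t.shape != p_t.shape:
        raise ValueError(f"shape mismatch {y_t.shape} vs {p_t.shape}")
    return y_t, p_t, isinstance(y_hat, Tensor)


def cross_entropy_loss(y, y_hat, eps_clip: float = 1e-7):
    """Mean pixelwise binary cross-entropy -[y log p + (1-y) log(1-p)].

    Predictions are clamped to [eps_clip, 1 - eps_clip] before the logs.
    """
    y_t, p_t, keep = _pair(y, y_hat)
    p_c = p_t.clip(eps_clip, 1.0 - eps_clip)
    loss = -(y_t * p_c.log() + (1.0 - y_t) * (1.0 - p_c).log()).mean()
    return loss if keep else float(loss.data)


def dice_loss(y, y_hat, smooth: float = 1.0):
    """Soft Dice loss 1 - (2 sum(x*y) + s) / (sum x + sum y + s)."""
    y_t, p_t, keep = _pair(y, y_hat)
    inter = (y_t * p_t).sum()
    denom = y_t.sum() + p_t.sum()
    loss = 1.0 - (2.0 * inter + smooth) / (denom + smooth)
    return loss if keep else float(loss.data)


def total_loss(y, y_hat, eps_clip: float = 1e-7, smooth: float = 1.0):
    """Combined segmentation loss L = L_ce + L_dice."""
    ce = cross_entropy_loss(y, y_hat, eps_clip)
    dc = dice_loss(y, y_hat, smooth)
    return ce + dc


# ---------------------------------------------------------------------------
# learning-rate schedule
# ---------------------------------------------------------------------------

def lr_at_step(step_global: int, config: TrainConfig | None = None) -> float:
    """lr_initial * rate^(step / step_decay), continuous exponent."""
    if config is None:
        config = TrainConfig()
    if step_global < 0:
        raise ValueError("step must be >= 0")
    return config.lr_initial * config.decay_rate ** (step_global / config.decay_step)


# ---------------------------------------------------------------------------
# batching helpers
# ---------------------------------------------------------------------------

def _make_batches(samples, batch_size, rng):
    """Single-sequence batches; order shuffled across the epoch."""
    by_seq = {}
    for s in samples:
        by_seq.setdefault(s.sequence_tag, []).append(s)
    batches = []
    for tag, group in sorted(by_seq.items()):
        idx = rng.permutation(len(group))
        for start in range(0, len(group), batch_size):
            batches.append((tag, [group[i] for i in idx[start:start + batch_size]]))
    order = rng.permutation(len(batches))
    return [batches[i] for i in order]


def _batch_arrays(batch, markers):
    x = np.stack([s.image for s in batch])[:, None]
    ys = {m: np.stack([s.labels[m].astype(np.float64) for s in batch])[:, None]
          for m in markers}
    return x, ys


def _batch_loss(model: MOUNet, tag, batch, config: TrainConfig):
    markers = model.config.routing[tag]
    x, ys = _batch_arrays(batch, markers)
    preds = model(Tensor(x), tag)
    loss = None
    for m in markers:
        lm = total_loss(Tensor(ys[m]), preds[m], config.eps_clip, config.dice_smooth)
        loss = lm if loss is None else loss + lm
    return loss


def evaluate_dice(model: MOUNet, samples, threshold: float = 0.5) -> dict:
    """Global per-marker Dice over a slice set (eval mode, binarised at 0.5)."""
    was_training = model.training
    model.eval()
    stats = {m: [0.0, 0.0] for m in model.config.decoder_markers}  # [2TP, |X|+|Y|]
    try:
        by_seq = {}
        for s in samples:
            by_seq.setdefault(s.sequence_tag, []).append(s)
        for tag, group in sorted(by_seq.items()):
            markers = model.config.routing[tag]
            for start in range(0, len(group), 12):
                batch = group[start:start + 12]
                x, ys = _batch_arrays(batch, markers)
                preds = model(Tensor(x), tag)
                for m in markers:
                    p = preds[m].data >= threshold
                    y = ys[m] > 0.5
                    stats[m][0] += 2.0 * np.sum(p & y)
                    stats[m][1] += float(p.sum() + y.sum())
    finally:
        model.train(was_training)
    out = {}
    for m, (num, den) in stats.items():
        if den > 0:
            out[m] = num / den
    return out


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train_one_iteration(model: MOUNet, train_samples, val_samples,
                        config: TrainConfig | None = None):
    """Optimise the model on one train/validation split.

    Returns (model restored to its best-validation checkpoint, TrainHistory).
    A non-finite loss aborts training and restores the last good checkpoint.
    """
    config = config or TrainConfig()
    config.validate()
    train_pats = {s.patient_id for s in train_samples}
    val_pats = {s.patient_id for s in val_samples}
    if train_pats & val_pats:
        raise ValueError(f"patient leakage between train and validation: "
                         f"{sorted(train_pats & val_pats)}")

    rng = np.random.default_rng(config.seed)
    opt = nn.Adam(model.parameters(), weight_decay=config.weight_decay)
    history = TrainHistory()
    best_metric, best_state, bad_epochs = -np.inf, None, 0
    step = 0
    model.train()

    for epoch in range(config.max_epochs):
        epoch_loss, n_slices = 0.0, 0
        try:
            for tag, batch in _make_batches(train_samples, config.batch_size, rng):
                loss = _batch_loss(model, tag, batch, config)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(f"non-finite loss at step {step}")
                model.zero_grad()
                loss.backward()
                opt.step(lr_at_step(step, config))
                step += 1
                epoch_loss += float(loss.data) * len(batch)
                n_slices += len(batch)
        except FloatingPointError:
            history.aborted = True
            break

        val_dice = evaluate_dice(model, val_samples)
        val_loss = _validation_loss(model, val_samples, config)
        metric = float(np.mean(list(val_dice.values()))) if val_dice else 0.0
        history.train_loss.append(epoch_loss / max(n_slices, 1))
        history.val_loss.append(val_loss)
        history.val_dice.append(val_dice)
        history.lr.append(lr_at_step(step, config))

        if metric > best_metric:
            best_metric = metric
            best_state = [a.copy() for a in model.state_arrays()]
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= config.patience:
                history.stopped_epoch = epoch + 1
                break

    if best_state is not None:
        model.load_state_arrays(best_state)
    model.eval()
    return model, history


def _validation_loss(model: MOUNet, samples, config: TrainConfig) -> float:
    was_training = model.training
    model.eval()
    total, n = 0.0, 0
    try:
        by_seq = {}
        for s in samples:
            by_seq.setdefault(s.sequence_tag, []).append(s)
        for tag, group in sorted(by_seq.items()):
            for start in range(0, len(group), config.batch_size):
                batch = group[start:start + config.batch_size]
                loss = _batch_loss(model, tag, batch, config)
                total += float(loss.data) * len(batch)
                n += len(batch)
    finally:
        model.train(was_training)
    return total / max(n, 1)


# ---------------------------------------------------------------------------
# nested cross-validation
# ---------------------------------------------------------------------------

def run_nested_cv(samples_by_patient: dict, fold_plan, hyper_grid,
                  train_config: TrainConfig | None = None,
                  network_config: NetworkConfig | None = None,
                  seed: int = 0):
    """Nested CV: tune on each inner split, evaluate once on the held-out fold.

    ``hyper_grid`` is a list of dicts of dataclass-field overrides (applied
    to the network or training config, whichever owns the field).  Selection
    criterion is mean validation Dice over active markers.  Returns a list of
    per-fold dicts with the chosen point, test Dice and the trained model.
    """
    train_config = train_config or TrainConfig()
    network_config = network_config or NetworkConfig()
    grid = list(hyper_grid)
    if not grid:
        raise ValueError("empty hyperparameter grid")

    def gather(pids):
        return [s for p in pids for s in samples_by_patient[p]]

    results = []
    for i, it in enumerate(fold_plan.iterations):
        train_s, val_s = gather(it["train"]), gather(it["validation"])
        best = None
        for j, point in enumerate(grid):
            ncfg = _override(network_config, point)
            tcfg = _override(train_config, point)
            tcfg = dataclasses.replace(tcfg, seed=seed + 1000 * i + j)
            model = build_mo_unet(ncfg, seed=seed + 1000 * i + j)
            model, hist = train_one_iteration(model, train_s, val_s, tcfg)
            val_dice = evaluate_dice(model, val_s)
            metric = float(np.mean(list(val_dice.values()))) if val_dice else 0.0
            if best is None or metric > best["val_metric"]:
                best = {"point": point, "val_metric": metric, "model": model,
                        "history": hist}
        test_dice = evaluate_dice(best["model"], gather(it["test"]))
        results.append({"fold": i, "chosen": best["point"],
                        "val_metric": best["val_metric"],
                        "test_dice": test_dice, "model": best["model"],
                        "history": best["history"]})
    return results


def _override(cfg, point: dict):
    fields = {f.name for f in dataclasses.fields(cfg)}
    own = {k: v for k, v in point.items() if k in fields}
    return dataclasses.replace(cfg, **own) if own else cfg
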