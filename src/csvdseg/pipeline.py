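"""End-to-end orchestration: phantom cohort -> slices -> model -> burden.

This glue module wires the pieces together for desk-scale experiments: it
renders a phantom cohort, cuts it into normalised slices, pretrains the
encoder, trains the multi-output network on patient-disjoint splits,
segments whole volumes slice-by-slice, and feeds the resulting masks through
the metrics and burden modules.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import io_preprocess, seg_metrics, burden_quant
from .phantom_sim import (PhantomSpec, MultiSeqVolume, SEQUENCES, MARKERS,
                          MARKER_SOURCE, generate_patient)
from .io_preprocess import extract_slices, make_fold_plan
from .mo_unet import NetworkConfig, build_mo_unet, pretrain_autoencoder, forward_route
from .training import TrainConfig, train_one_iteration, evaluate_dice


def phantom_slices(vol: MultiSeqVolume, masks: dict, config: NetworkConfig,
                   target_size: int | None = None) -> list:
    """All slice samples of one patient, labelled per the routing table."""
    samples = []
    for seq in SEQUENCES:
        if seq not in config.routing:
            continue
        samples.extend(extract_slices(vol, masks, seq, config.routing[seq],
                                      target_size=target_size))
    return samples


def cohort_slices(data_dir, config: NetworkConfig, target_size: int) -> dict:
    """Load a cohort written by ``generate_cohort`` into per-patient slices."""
    data_dir = Path(data_dir)
    manifest = pd.read_csv(data_dir / "manifest.csv")
    out = {}
    for pid in manifest["patient_id"]:
        masks = {}
        for marker in MARKERS:
            v = io_preprocess.read_volume(
                data_dir / f"{pid}_mask_{marker}.nii.gz", MARKER_SOURCE[marker])
            masks[marker] = v.volumes[MARKER_SOURCE[marker]] > 0.5
        volumes, spacing = {}, {}
        for seq in SEQUENCES:
            v = io_preprocess.read_volume(data_dir / f"{pid}_{seq}.nii.gz", seq)
            volumes[seq] = v.volumes[seq]
            spacing[seq] = v.spacing[seq]
        vol = MultiSeqVolume(patient_id=pid, volumes=volumes, spacing=spacing)
        out[pid] = phantom_slices(vol, masks, config, target_size=target_size)
    return out


def predict_masks(model, vol: MultiSeqVolume, threshold: float = 0.5,
                  batch_size: int = 12) -> dict:
    """Segment a whole patient: per-marker binary 3-D masks.

    Each sequence volume is cut into normalised slices and routed through
    the network; a marker's mask is taken from its source sequence.
    """
    probs = {}
    for seq, markers in model.config.routing.items():
        grid = vol.volumes[seq]
        n_z = grid.shape[2]
        stack = np.stack([io_preprocess.minmax_normalize(grid[:, :, z])
                          for z in range(n_z)])
        maps = {m: [] for m in markers}
        for start in range(0, n_z, batch_size):
            out = forward_route(model, stack[start:start + batch_size], seq)
            for m in markers:
                maps[m].append(out[m])
        for m in markers:
            probs.setdefault(m, {})[seq] = np.concatenate(maps[m], axis=0)
    masks = {}
    for m in model.config.decoder_markers:
        src = MARKER_SOURCE[m]
        if m in probs and src in probs[m]:
            masks[m] = np.moveaxis(probs[m][src], 0, 2) >= threshold
    return masks


# ---------------------------------------------------------------------------
# miniature experiment
# ---------------------------------------------------------------------------

def build_phantom_cohort(spec: PhantomSpec, n_patients: int,
                         burden_levels=None) -> list:
    """In-memory cohort: list of (patient_id, burden, volume, ground truth)."""
    if burden_levels is None:
        burden_levels = [i % 5 for i in range(n_patients)]
    child_seeds = np.random.SeedSequence(spec.seed).spawn(n_patients)
    cohort = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        rng = np.random.default_rng(child_seeds[i])
        vol, gt = generate_patient(spec, burden_levels[i], patient_id=pid, rng=rng)
        cohort.append((pid, burden_levels[i], vol, gt))
    return cohort


def run_miniature_experiment(seed: int = 0, n_patients: int = 30,
                             image_shape=(64, 64, 24),
                             widths=(8, 16, 32),
                             ae_epochs: int = 10, seg_epochs: int = 14,
                             max_train_slices: int = 500,
                             negative_fraction: float = 0.3,
                             threshold: float = 0.5) -> dict:
    """Desk-scale end-to-end run: phantoms -> pretraining -> MO-UNet -> burden.

    Splits the cohort at patient level (~60:20:20 train/validation/test),
    pretrains the encoder as an autoencoder on training-patient slices,
    trains the segmentation network on lesion-positive training slices with
    early stopping, then evaluates held-out segmentation quality and the
    full volume/Z-score burden pipeline on the whole cohort.
    """
    from . import nn
    prev_dtype = nn.DTYPE
    nn.set_default_dtype(np.float32)   # adequate for training, ~2x faster
    try:
        return _run_miniature(seed, n_patients, image_shape, widths, ae_epochs,
                              seg_epochs, max_train_slices, negative_fraction,
                              threshold)
    finally:
        nn.set_default_dtype(prev_dtype)


def _run_miniature(seed, n_patients, image_shape, widths, ae_epochs,
                   seg_epochs, max_train_slices, negative_fraction, threshold):
    seed = int(seed) % (2 ** 31)
    spec = PhantomSpec(image_shape=tuple(image_shape), seed=seed)
    config = NetworkConfig(input_size=image_shape[0],
                           encoder_stage_widths=tuple(widths))
    cohort = build_phantom_cohort(spec, n_patients)

    rng = np.random.default_rng(seed + 1)
    pids = [c[0] for c in cohort]
    order = [pids[i] for i in rng.permutation(len(pids))]
    n_test = max(1, round(0.2 * len(order)))
    n_val = max(1, round(0.2 * len(order)))
    test_p = set(order[:n_test])
    val_p = set(order[n_test:n_test + n_val])
    train_p = set(order[n_test + n_val:])

    by_patient = {pid: phantom_slices(vol, gt.masks, config)
                  for pid, _, vol, gt in cohort}

    # positives carry the learning signal; a fraction of lesion-free slices
    # teaches the background (pure-noise slices otherwise trigger false
    # positives at inference, where every slice is segmented)
    pos = [s for p in train_p for s in by_patient[p] if s.is_positive]
    neg = [s for p in train_p for s in by_patient[p] if not s.is_positive]
    if len(pos) > max_train_slices:
        keep = rng.permutation(len(pos))[:max_train_slices]
        pos = [pos[i] for i in sorted(keep)]
    n_neg = min(len(neg), int(round(negative_fraction * len(pos))))
    keep = rng.permutation(len(neg))[:n_neg]
    train_s = pos + [neg[i] for i in sorted(keep)]
    val_s = [s for p in val_p for s in by_patient[p]]
    test_s = [s for p in test_p for s in by_patient[p]]

    # encoder pretraining on unlabelled training-patient slices (pooled sequences)
    ae_images = [s.image for p in sorted(train_p) for s in by_patient[p]]
    ae_images = [ae_images[i] for i in rng.permutation(len(ae_images))[:120]]
    encoder, ae_losses = pretrain_autoencoder(ae_images, config,
                                              epochs=ae_epochs, seed=seed + 2)

    model = build_mo_unet(config, pretrained_encoder=encoder, seed=seed + 3)
    tcfg = TrainConfig(max_epochs=seg_epochs, seed=seed + 4)
    model, history = train_one_iteration(model, train_s, val_s, tcfg)

    heldout_dice = evaluate_dice(model, test_s, threshold=threshold)

    # whole-cohort volume quantification
    pred_vols, true_vols, burdens = {}, {}, {}
    for pid, burden, vol, gt in cohort:
        pred = predict_masks(model, vol, threshold=threshold)
        pred_vols[pid] = {
            m: burden_quant.marker_volume(pred[m], vol.spacing[MARKER_SOURCE[m]])
            for m in MARKERS}
        true_vols[pid] = {
            m: burden_quant.marker_volume(gt.masks[m], vol.spacing[MARKER_SOURCE[m]])
            for m in MARKERS}
        burdens[pid] = burden
    pred_df = pd.DataFrame(pred_vols).T.sort_index()[list(MARKERS)]
    true_df = pd.DataFrame(true_vols).T.sort_index()[list(MARKERS)]
    z = burden_quant.zscore_burden(pred_df)
    burden_series = pd.Series(burdens).sort_index()
    z_by_burden = z["z_sum"].groupby(burden_series).mean()

    pearson = {m: burden_quant.pearson_r(true_df[m], pred_df[m])
               for m in MARKERS}

    return {
        "spec": spec, "config": config, "model": model,
        "history": history, "ae_losses": ae_losses,
        "splits": {"train": sorted(train_p), "validation": sorted(val_p),
                   "test": sorted(test_p)},
        "heldout_dice": heldout_dice,
        "pred_volumes": pred_df, "true_volumes": true_df,
        "zscores": z, "burden_levels": burden_series,
        "z_sum_by_burden": z_by_burden, "pearson_r": pearson,
    }
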