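# csvdseg

Multi-output U-Net segmentation and quantitative burden scoring of cerebral
small vessel disease (CSVD) markers on multisequence brain MRI — white
matter hyperintensities (WMH, FLAIR), cerebral microbleeds (CMB, SWI),
lacunes (FLAIR/T1) and enlarged perivascular spaces (EPVS, T1) — together
with a synthetic phantom generator so the whole system can be trained and
tested on a CPU workstation without patient data.

It is aimed at neuroimaging researchers who want a single trainable pipeline
from raw volumes to per-patient quantitative burden, and at methods
developers who need a fully inspectable reference implementation of the
multi-task architecture and its evaluation stack.

## The model

A single U-shaped network with **one shared encoder and four marker-specific
decoders**.  The encoder stacks MBConv blocks (depthwise-separable + 1×1
pointwise convolutions, Swish activations, squeeze-excitation, residual
connections) and can be pretrained as the encoder half of a reconstruction
autoencoder on unlabelled slices.  A selection unit routes the encoded
features by input sequence — FLAIR → {WMH, lacune}, SWI → {CMB},
T1 → {EPVS, lacune} — into decoders that upsample with transposed
convolutions, merge encoder skips at each scale, and apply concurrent
spatial-and-channel squeeze & excitation (scSE) attention before a sigmoid
probability head.  Training minimises

    L = L_ce + L_Dice

per routed marker, with Adam (L2 weight decay λ = 1e-4, batch size 6) and
learning rate `lr(step) = 0.001 · 0.95^(step/500)`, early stopping on mean
validation Dice (patience 5), inside patient-level nested 5-fold
cross-validation.  Evaluation reports Pre, Sp, Dice, HD95 (95th percentile
of pooled directed surface distances, in mm), lesion-wise sensitivity
(≥ 50% coverage rule) with bootstrap CIs, and the burden module turns masks
into volumes, clinical visual-score bins, a 4-point total burden score and a
summed per-marker Z score.  The network runs on a small, fully tested numpy
autodiff backend — no GPU or deep-learning framework required.

See `docs/methods.md` for the complete model, parameter and phantom
description.

## Worked example

```python
import numpy as np
from csvdseg import PhantomSpec, NetworkConfig, build_mo_unet
from csvdseg.pipeline import build_phantom_cohort, phantom_slices, predict_masks
from csvdseg.training import TrainConfig, train_one_iteration
from csvdseg.seg_metrics import patient_metrics

cohort = build_phantom_cohort(PhantomSpec(seed=1), n_patients=10)
cfg = NetworkConfig()                      # 64x64 input, widths (8, 16, 32)
samples = {pid: phantom_slices(vol, gt.masks, cfg) for pid, _, vol, gt in cohort}
train = [s for pid in list(samples)[:8] for s in samples[pid] if s.is_positive]
val = [s for pid in list(samples)[8:] for s in samples[pid]]

model = build_mo_unet(cfg, seed=0)
model, hist = train_one_iteration(model, train, val,
                                  TrainConfig(max_epochs=5, seed=0))
pid, _, vol, gt = cohort[-1]
pred = predict_masks(model, vol)
print(patient_metrics(pred["WMH"], gt.masks["WMH"], spacing=(1, 1, 2),
                      marker="WMH"))
```

A fuller run of the same pipeline (30 phantoms, autoencoder pretraining,
early-stopped training, whole-cohort burden quantification) is wrapped in
`csvdseg.pipeline.run_miniature_experiment(seed=1)`; on one CPU it finishes
in a few minutes and prints held-out Dice per marker, e.g.

    heldout dice  {'WMH': 0.768, 'CMB': 0.964, 'lacune': 0.741, 'EPVS': 0.881}
    volume pearson {'WMH': 0.988, 'CMB': 0.997, 'lacune': 0.931, 'EPVS': 0.992}

meaning: on held-out phantom patients the network overlaps the true lesion
masks at Dice 0.74–0.96 depending on marker, and the per-patient predicted
lesion volumes correlate with the true volumes at r ≥ 0.93, so the
downstream Z-score burden ranking is trustworthy at phantom contrast.

There is also a thin CLI:

```
csvd simulate --out cohort/ --n 10 --seed 1
csvd preprocess --in cohort/ --out slices/ --size 64 --augment
csvd train --data cohort/ --out run/ --epochs 10 --seed 1
csvd evaluate --pred pred_masks/ --truth cohort/ --out metrics.csv
csvd burden --pred pred_masks/ --truth cohort/ --out burden.csv
```

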