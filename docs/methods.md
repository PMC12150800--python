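# Methods

## Problem

Cerebral small vessel disease (CSVD) manifests on brain MRI as four
co-occurring lesion classes, each best seen on a different sequence:

| Marker | Appearance | Source sequence |
|---|---|---|
| WMH (white matter hyperintensity) | confluent bright regions | FLAIR |
| CMB (cerebral microbleed) | small round dark foci | SWI |
| Lacune | 3–15 mm CSF-like cavity, bright FLAIR rim | FLAIR (also visible on T1) |
| EPVS (enlarged perivascular space) | thin CSF-signal tube, ≤ 3 mm diameter | T1 |

`csvdseg` segments all four markers simultaneously with a single
multi-output U-shaped network, and turns the masks into quantitative
per-patient burden measures (volumes, visual-score bins, a 4-point total
burden score, and a summed Z-score global burden).

## Network

One shared encoder of stacked MBConv blocks (1×1 expansion → depthwise 3×3,
optionally strided → channel squeeze-excitation → 1×1 projection; Swish
activations; batch normalisation; residual connection when shapes match)
produces a bottleneck plus one skip feature map per scale.  A *selection
unit* — hard routing keyed on the batch's sequence tag, not a learned gate —
passes the encoded features to the decoders relevant for that sequence:

    FLAIR → {WMH, lacune}     SWI → {CMB}     T1 → {EPVS, lacune}

Each of the four marker decoders upsamples with transposed convolutions
(kernel = stride = 2), concatenates the encoder skip at each scale, applies
a 3×3 convolution and a concurrent spatial-and-channel squeeze & excitation
(scSE) block with additive fusion of the two recalibrated maps (reduction
ratio 2), and ends in a 1-channel sigmoid probability map at input
resolution.  Markers not routed from a sequence are absent from the output,
not zero-filled.

The encoder can be pretrained as the encoder half of a plain reconstruction
autoencoder (transposed-convolution decoder, MSE loss) on unlabelled slices
pooled across sequences; its parameters (including normalisation statistics)
are then transferred into the segmentation model.  A contrastive pretraining
term is not implemented; the training entry point accepts any encoder with
matching widths, so one can be supplied externally.

### Numpy backend

The network runs on a small reverse-mode autodiff engine written for this
package (`csvdseg.nn`): grouped/depthwise 2-D convolution (with a fast 1×1
path), non-overlapping transposed convolution, fused batch normalisation and
Swish, reductions, concatenation, and Adam with L2 weight decay.  Every
primitive's gradient is validated against central finite differences in the
test suite.  Tensors default to float64 (exact gradient checks); the
training pipeline switches to float32, which roughly halves memory traffic
and does not change results beyond round-off.  Transposed convolutions are
restricted to kernel = stride (non-overlapping windows), which is all the
decoders use and avoids checkerboard overlap entirely.

## Training

Loss per decoder head: `L = L_ce + L_dice`, the sum of mean pixelwise binary
cross-entropy (predictions clamped to `[1e-7, 1 − 1e-7]` before the logs)
and soft Dice loss with smoothing constant 1.0.  For a batch, losses are
summed over the markers routed from the batch's sequence.

Optimiser: Adam (standard moment coefficients) with L2 weight decay
λ = 1e-4, batch size 6, and the exponentially decaying learning rate

    lr(step) = 0.001 · 0.95^(step / 500)

with a continuous (not staircase) exponent.  The "epsilon = 0.001,
momentum = 0.99" hyperparameters are the batch-normalisation epsilon and
running-average retention, which is where those values are natural; Adam has
no single "momentum" and its epsilon convention differs.  Training runs at
most 100 epochs and stops early when the validation metric — mean validation
Dice over the active markers, computed from globally pooled TP/FP/FN at
threshold 0.5 — fails to improve for 5 consecutive epochs; the
best-validation checkpoint is kept.  A non-finite loss aborts the epoch loop
and restores the last good checkpoint.

Model selection uses patient-level nested cross-validation: 5 outer folds
(105 patients → 21 per fold); in each iteration the remaining 84 patients
are split 80:20 (validation = round(0.2·84) = 17) for hyperparameter tuning,
and the winning point is evaluated once on the held-out fold.  Slices of one
patient never straddle splits.

## Preprocessing

Volumes are cut along the slice axis; each slice is resized (bilinear for
images, nearest-neighbour for masks, which therefore stay binary) and
min-max normalised to [0, 1] *per slice* — chosen over per-volume because
the network consumes 2-D slices; a constant slice maps to all-zeros.
Positive slices (any labelled voxel) can be expanded 11-fold by a fixed
inventory: original, vertical and horizontal flips, ±30° rotations, ±20%
displacements along each in-plane axis, and 0.8×/1.2× centred scalings.  The
11× factor and the three transform categories are fixed; the exact
inventory (2 flips + 2 rotations + 4 displacements + 2 scales) is this
package's concrete realisation of them.  Rotations and scalings pad with
zeros; masks are re-binarised after interpolation.

NIfTI is read with nibabel; DICOM series with pydicom, sorting slices by
position and refusing series whose inter-slice gaps are inconsistent (a
missing slice is an error, never a silent gap-fill).

## Phantom generator

No patient data ship with the package; a synthetic phantom generator stands
in for them.  It emulates only what the pipeline consumes, deliberately
nothing more:

- **Geometry.** A fixed ellipsoid (semi-axes 0.45 of the grid) is the
  "brain"; a small central ellipsoid is a CSF "ventricle" surrogate; an
  interior box (central 40% per axis) designates the "basal ganglia" for
  EPVS counting.  Default desk-scale grid 64×64×24 voxels (320×320 matrices
  are supported through the same configuration); per-sequence voxel spacing
  defaults mirror a clinical protocol: T1 1×1×1 mm, FLAIR 1×1×2 mm,
  SWI 1×1×1.6 mm.
- **Intensity model.** Piecewise-constant tissue classes plus additive
  Gaussian noise (σ = 0.03 of the dynamic range).  No bias field, no
  partial-volume model, no registration error, no k-space artefacts.
- **Lesions.** WMH: ellipsoidal blobs, 5–30 mm, seeded near the ventricle
  surface, painted hyperintense on FLAIR only.  CMB: 2–10 mm spheres,
  hypointense on SWI only.  Lacunes: 3–15 mm spheres, CSF-dark on T1 and
  FLAIR with a 1-voxel bright FLAIR rim.  EPVS: tubes 1–3 mm in diameter and
  3–20 mm long with random orientation, CSF-dark on T1 only.  Sizes follow
  the STRIVE-style conventions for these markers; they are generator
  parameters, not claims about any cohort.
- **Counts.** Drawn Poisson(rate · (1 + burden_level)) with burden_level
  ordinal 0–4 and default rates WMH 2, CMB 2, lacune 1, EPVS 4 — stated
  explicitly so Monte-Carlo tests have a null distribution.  Ground-truth
  instances and counts are recomputed from the final mask by 26-connected
  component labelling, so merged lesions are counted as one, exactly as an
  evaluator would.

Passing tests on phantoms therefore demonstrate that the architecture,
losses, optimisation, metrics and burden pipeline work end to end at this
contrast and noise level; they do not demonstrate clinical-grade accuracy on
real anatomy, scanner artefacts, or subtle lesions.

## Evaluation metrics

Voxelwise: Pre = TP/(TP+FP), Sp = TN/(FP+TN), Dice = 2TP/(FP+2TP+FN),
computed per patient volume (not per slice) after thresholding at 0.5.
Empty-mask conventions: both masks empty → Dice/Pre/Sp = 1; exactly one
empty → Dice = 0 and HD95 reported as missing (NaN), never 0 — this keeps
spurious zeros from dominating patient averages.

HD95 is the 95th percentile of the pooled directed surface distances (border
voxels = mask minus its face-connected erosion, distances in physical mm),
which makes it symmetric; a `scaled_max` variant (0.95 × the larger directed
Hausdorff distance) is available behind a flag for comparability with that
formulation.  Lesion-wise sensitivity uses 26-connectivity (3-D) /
8-connectivity (2-D) components and counts a reference lesion as detected
when the prediction covers ≥ 50% of its voxels (boundary inclusive); WMH is
excluded from lesion-wise sensitivity, as is usual for confluent lesions.
Confidence intervals are percentile bootstrap over patients (default 2000
resamples, seeded).

## Burden quantification

Marker volume = foreground voxels × voxel volume of the marker's source
sequence.  Visual bins: CMB 0 / 1–10 / >10; lacune 0 / 1–4 / >4;
basal-ganglia EPVS 0 / 1–10 / 11–20 / 21–40 / >40; WMH grade from the summed
deep + periventricular Fazekas scale (0–2 → 0, 3–4 → 1, 5–6 → 2).  The
4-point total burden score awards one point each for ≥ 1 lacune, ≥ 1 CMB,
EPVS bin ≥ 2, and severe WMH; the WMH criterion is configurable (an explicit
deep/periventricular reading can override the default grade-2 rule, since
the phantom has no true Fazekas reading).  Z-score burden standardises each
marker's volume against the cohort (population SD) and sums the four
z-values; a zero-SD marker contributes 0 with a warning.  EPVS are counted
in the basal-ganglia box for binning, while whole-brain EPVS volume is also
reported.

Agreement statistics: Pearson r, Bland–Altman mean difference with
mean ± 1.96·SD limits, one-way ANOVA across visual-score groups, and
pairwise least-significant-difference tests on the pooled within-group
variance — deliberately without multiplicity correction, as LSD specifies.

## Desk-scale experiment sizes

The miniature end-to-end experiment (`csvdseg.pipeline.run_miniature_experiment`,
also behind `scripts/acceptance.py`) uses 30 phantoms at 64×64×24, encoder
widths (8, 16, 32), a ~60:20:20 patient split, autoencoder pretraining for
10 epochs on 120 pooled slices, and segmentation training on up to 500
lesion-positive slices plus 30% as many lesion-free slices for at most 14
epochs with early stopping (patience 5).  The lesion-free fraction exists
because inference segments every slice of a volume: a network trained only
on positives produces false positives on pure-noise slices.  The 11×
augmentation policy is not applied here — positive-only sampling already
balances classes at phantom contrast — but is exercised by its own tests.
These sizes are the package's defaults for a CPU-only workstation; the
architecture scales to 320×320 inputs and deeper width schedules through
`NetworkConfig`.

## Known limitations

- The phantom's contrast is far cleaner than clinical MRI; reported phantom
  metrics are upper bounds on what identical code would achieve on real data.
- The backend is CPU numpy; it is adequate for desk-scale grids, not for
  full-resolution clinical training runs.
- The selection unit is hard routing on metadata; no learned cross-decoder
  feature mixing is attempted when a sequence maps to several markers.
- Transposed convolutions require kernel = stride; arbitrary overlap is not
  supported.
- DICOM writing is out of scope (reading only), as are skull stripping,
  registration and bias-field correction.
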