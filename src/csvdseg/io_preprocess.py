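"""Volume reading, slicing, normalisation, positive augmentation and CV plan.

The training pipeline consumes 2-D slices: each volume is cut along its last
axis, every slice is resized and min-max normalised to [0, 1], and slices
containing any labelled lesion voxel ("positives") can be expanded by a fixed
11-fold augmentation policy (flips, +-30 deg rotations, +-20% displacements
along each in-plane axis, 0.8x / 1.2x scalings).  Patient-level 5-fold
splitting with an inner 80:20 train/validation split prevents any slice-level
leakage between splits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import nibabel as nib
import pydicom
from skimage import transform as sktf

from .phantom_sim import MultiSeqVolume, SEQUENCES


@dataclasses.dataclass
class SliceSample:
    patient_id: str
    sequence_tag: str
    slice_index: int
    image: np.ndarray                  # 2-D, values in [0, 1]
    labels: dict                       # marker tag -> binary 2-D array
    is_positive: bool = False

    def __post_init__(self):
        self.is_positive = any(m.any() for m in self.labels.values())


@dataclasses.dataclass
class AugmentationPolicy:
    flips: tuple = ("vertical", "horizontal")
    rotation_degrees: float = 30.0
    max_displacement_fraction: float = 0.20
    scale_range: tuple = (0.8, 1.2)
    expansion_factor: int = 11


@dataclasses.dataclass
class FoldPlan:
    k: int
    folds: list                        # k disjoint patient-id lists
    iterations: list                   # dicts with keys test / train / validation
    seed: int


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def read_volume(path, sequence_tag: str) -> MultiSeqVolume:
    """Read a NIfTI file or a DICOM series directory into a volume fragment.

    Fails loudly on missing/zero spacing and on inconsistent DICOM slice
    spacing (a missing slice is an error, never a silent gap-fill).
    """
    if sequence_tag not in SEQUENCES:
        raise ValueError(f"unknown sequence tag {sequence_tag!r}")
    path = Path(path)
    if path.is_dir():
        grid, spacing = _read_dicom_series(path)
        pid = path.name
    else:
        img = nib.load(str(path))
        grid = np.asarray(img.dataobj, dtype=np.float64)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        pid = path.name.split(".")[0]
    if len(spacing) != 3 or any(not np.isfinite(s) or s <= 0 for s in spacing):
        raise ValueError(f"missing or invalid voxel spacing {spacing} in {path}")
    if not np.isfinite(grid).all():
        raise ValueError(f"non-finite voxel values in {path}")
    return MultiSeqVolume(patient_id=pid, volumes={sequence_tag: grid},
                          spacing={sequence_tag: spacing})


def _read_dicom_series(dirpath: Path):
    files = sorted(p for p in dirpath.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise ValueError(f"no DICOM files in {dirpath}")
    slices = [pydicom.dcmread(str(f)) for f in files]
    try:
        slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))
        zs = np.array([float(d.ImagePositionPatient[2]) for d in slices])
    except AttributeError as e:
        raise ValueError(f"DICOM series in {dirpath} lacks position info: {e}")
    px = slices[0].PixelSpacing
    if len(slices) > 1:
        dz = np.diff(zs)
        if dz.min() <= 0:
            raise ValueError("duplicate or unsorted DICOM slice positions")
        if (dz.max() - dz.min()) > 1e-3 * dz.mean():
            raise ValueError(
                f"inconsistent DICOM slice spacing (range {dz.min():.4g}-{dz.max():.4g} mm); "
                "a slice may be missing")
        slice_gap = float(dz.mean())
    else:
        slice_gap = float(getattr(slices[0], "SliceThickness", 0.0))
    grid = np.stack([d.pixel_array.astype(np.float64) for d in slices], axis=-1)
    return grid, (float(px[0]), float(px[1]), slice_gap)


# ---------------------------------------------------------------------------
# normalisation / resizing
# ---------------------------------------------------------------------------

def minmax_normalize(image: np.ndarray) -> np.ndarray:
    """Map to [0, 1] by (x - min) / (max - min); a constant image maps to 0."""
    lo, hi = float(image.min()), float(image.max())
    if hi <= lo:
        return np.zeros_like(image, dtype=np.float64)
    return (image.astype(np.float64) - lo) / (hi - lo)


def normalize_resize(image: np.ndarray, target_size: int, labels: dict | None = None):
    """Resize to ``target_size`` squared (bilinear) and min-max normalise.

    Label masks, when given, are resized with nearest-neighbour interpolation
    so they stay binary.  Returns the image, or (image, labels).
    """
    shape = (int(target_size), int(target_size))
    if image.shape != shape:
        image = sktf.resize(image.astype(np.float64), shape, order=1,
                            preserve_range=True, anti_aliasing=False)
    image = minmax_normalize(image)
    if labels is None:
        return image
    out_labels = {}
    for k, m in labels.items():
        if m.shape != shape:
            m = sktf.resize(m.astype(np.float64), shape, order=0,
                            preserve_range=True, anti_aliasing=False)
        out_labels[k] = m > 0.5
    return image, out_labels


def extract_slices(volume: MultiSeqVolume, masks: dict, sequence_tag: str,
                   markers, target_size: int | None = None) -> list:
    """Cut a volume into per-slice samples labelled with the given markers."""
    grid = volume.volumes[sequence_tag]
    samples = []
    for z in range(grid.shape[2]):
        img = grid[:, :, z]
        labels = {m: masks[m][:, :, z].astype(bool) for m in markers}
        if target_size is not None:
            img, labels = normalize_resize(img, target_size, labels)
        else:
            img = minmax_normalize(img)
        samples.append(SliceSample(volume.patient_id, sequence_tag, z, img, labels))
    return samples


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def _warp(img: np.ndarray, tform, order: int) -> np.ndarray:
    return sktf.warp(img.astype(np.float64), tform.inverse, order=order,
                     preserve_range=True, cval=0.0)


def _centered(shape, scale=1.0, rotation_deg=0.0):
    h, w = shape
    center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])
    return (sktf.AffineTransform(translation=-center)
            + sktf.AffineTransform(scale=scale, rotation=np.deg2rad(rotation_deg))
            + sktf.AffineTransform(translation=center))


def _transform_inventory(shape, policy: AugmentationPolicy):
    h, w = shape
    f = policy.max_displacement_fraction
    rot = policy.rotation_degrees
    s_lo, s_hi = policy.scale_range
    geo = [_centered(shape, rotation_deg=+rot), _centered(shape, rotation_deg=-rot),
           sktf.AffineTransform(translation=(+f * w, 0)),
           sktf.AffineTransform(translation=(-f * w, 0)),
           sktf.AffineTransform(translation=(0, +f * h)),
           sktf.AffineTransform(translation=(0, -f * h)),
           _centered(shape, scale=s_lo), _centered(shape, scale=s_hi)]
    return geo


def augment_positives(sample: SliceSample,
                      policy: AugmentationPolicy | None = None) -> list:
    """Expand one positive slice into exactly ``expansion_factor`` samples.

    Inventory: original, vertical flip, horizontal flip, +-30 deg rotations,
    +-20% x/y displacements, 0.8x and 1.2x centred scalings — 11 samples in
    total.  The identical transform is applied to the image and every label
    mask; masks are re-binarised after interpolation.
    """
    if policy is None:
        policy = AugmentationPolicy()
    if not sample.is_positive:
        raise ValueError("augmentation is applied to positive samples only")

    def make(img, labels):
        return SliceSample(sample.patient_id, sample.sequence_tag,
                           sample.slice_index, img,
                           {k: v.astype(bool) for k, v in labels.items()})

    out = [make(sample.image.copy(), {k: v.copy() for k, v in sample.labels.items()})]
    if "vertical" in policy.flips:
        out.append(make(sample.image[::-1, :].copy(),
                        {k: v[::-1, :].copy() for k, v in sample.labels.items()}))
    if "horizontal" in policy.flips:
        out.append(make(sample.image[:, ::-1].copy(),
                        {k: v[:, ::-1].copy() for k, v in sample.labels.items()}))
    for tform in _transform_inventory(sample.image.shape, policy):
        img = _warp(sample.image, tform, order=1)
        labels = {k: _warp(v.astype(float), tform, order=0) > 0.5
                  for k, v in sample.labels.items()}
        out.append(make(img, labels))
    assert len(out) == policy.expansion_factor
    return out


# ---------------------------------------------------------------------------
# cross-validation plan
# ---------------------------------------------------------------------------

def make_fold_plan(patient_ids, k: int = 5, seed: int = 0,
                   stratify_by: dict | None = None) -> FoldPlan:
    """Patient-level k-fold plan with an inner 80:20 train/validation split.

    Folds are as equal as possible (105 patients -> five folds of 21).  When
    ``stratify_by`` maps patient id to an ordinal (e.g. burden level), ids
    are dealt round-robin in stratum order so folds are stratum-balanced.
    """
    ids = list(patient_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate patient ids")
    if len(ids) < k:
        raise ValueError(f"need at least {k} patients, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    if stratify_by is not None:
        order.sort(key=lambda p: stratify_by[p])   # stable: random within stratum
    folds = [order[i::k] for i in range(k)]

    iterations = []
    for i in range(k):
        test = list(folds[i])
        remaining = [p for j, f in enumerate(folds) if j != i for p in f]
        remaining = [remaining[j] for j in rng.permutation(len(remaining))]
        n_val = int(round(0.2 * len(remaining)))
        iterations.append({"test": test, "validation": remaining[:n_val],
                           "train": remaining[n_val:]})
    return FoldPlan(k=k, folds=folds, iterations=iterations, seed=seed)


# ---------------------------------------------------------------------------
# intermediate array container (.npy + JSON sidecar)
# ---------------------------------------------------------------------------

def save_array(path, array: np.ndarray, meta: dict):
    """Write an array as .npy with a JSON sidecar (shape, spacing, tags...)."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), array)
    meta = dict(meta, shape=list(array.shape), dtype=str(array.dtype))
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_array(path):
    path = Path(path)
    array = np.load(path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    return array, meta
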