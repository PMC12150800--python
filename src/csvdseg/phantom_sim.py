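"""Synthetic multisequence brain-MRI phantoms with four lesion classes.

The generator emulates the kind of data the segmentation pipeline consumes:
co-registered T1 / FLAIR / SWI volumes of one "patient", containing white
matter hyperintensities (WMH), cerebral microbleeds (CMBs), lacunes and
enlarged perivascular spaces (EPVSs), each rendered with its characteristic
sequence-specific contrast, together with exact voxel-level ground truth.

The intensity model is deliberately simple — piecewise-constant tissue
classes (background, brain, a central CSF "ventricle" surrogate) plus
additive Gaussian noise.  Lesion counts are drawn Poisson(rate x
(1 + burden_level)) so that cohort-level burden trends have a declared null
distribution that tests can check against.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import nibabel as nib
from scipy import ndimage

SEQUENCES = ("T1", "FLAIR", "SWI")
MARKERS = ("WMH", "CMB", "lacune", "EPVS")

#: the sequence on which each marker is delineated (and whose grid its mask
#: is aligned to)
MARKER_SOURCE = {"WMH": "FLAIR", "CMB": "SWI", "lacune": "FLAIR", "EPVS": "T1"}

# piecewise-constant tissue intensities per sequence, on a [0, 1] scale
_TISSUE = {
    "T1": {"background": 0.02, "brain": 0.60, "csf": 0.15},
    "FLAIR": {"background": 0.02, "brain": 0.55, "csf": 0.10},
    "SWI": {"background": 0.02, "brain": 0.60, "csf": 0.45},
}
# lesion intensities, keyed (marker, sequence) — a marker only alters the
# sequences listed here
_LESION_INTENSITY = {
    ("WMH", "FLAIR"): 0.95,
    ("CMB", "SWI"): 0.08,
    ("lacune", "T1"): 0.15,
    ("lacune", "FLAIR"): 0.12,
    ("EPVS", "T1"): 0.15,
}
_LACUNE_RIM_FLAIR = 0.90  # 1-voxel bright FLAIR rim around lacunes


@dataclasses.dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    Lesion rates are expected counts at burden level 0; the draw is
    Poisson(rate * (1 + burden_level)).  Size ranges are lesion diameters in
    mm (for EPVS the range is the tube length; diameter is capped at 3 mm).
    """

    image_shape: tuple = (64, 64, 24)
    spacing_per_sequence: dict = dataclasses.field(default_factory=lambda: {
        "T1": (1.0, 1.0, 1.0), "FLAIR": (1.0, 1.0, 2.0), "SWI": (1.0, 1.0, 1.6)})
    lesion_rates: dict = dataclasses.field(default_factory=lambda: {
        "WMH": 2.0, "CMB": 2.0, "lacune": 1.0, "EPVS": 4.0})
    lesion_size_ranges: dict = dataclasses.field(default_factory=lambda: {
        "WMH": (5.0, 30.0), "CMB": (2.0, 10.0), "lacune": (3.0, 15.0),
        "EPVS": (3.0, 20.0)})
    noise_sigma: float = 0.03
    seed: int = 0

    def validate(self):
        shape = tuple(int(s) for s in self.image_shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise ValueError(f"image_shape must be 3 positive ints, got {self.image_shape}")
        for seq in SEQUENCES:
            if any(s <= 0 for s in self.spacing_per_sequence[seq]):
                raise ValueError(f"non-positive spacing for {seq}")
        for m in MARKERS:
            if self.lesion_rates[m] < 0:
                raise ValueError(f"negative lesion rate for {m}")
            lo, hi = self.lesion_size_ranges[m]
            if lo > hi:
                raise ValueError(f"size range not ordered for {m}")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


@dataclasses.dataclass
class MultiSeqVolume:
    patient_id: str
    volumes: dict          # sequence tag -> 3-D float array
    spacing: dict          # sequence tag -> (sx, sy, sz) mm


@dataclasses.dataclass
class LesionGroundTruth:
    masks: dict            # marker tag -> binary 3-D array (source-sequence grid)
    instances: dict        # marker tag -> list of dicts (voxels, centroid, volume_mm3)
    counts: dict           # marker tag -> int, = n connected components
    epvs_bg_count: int     # EPVS instances whose centroid lies in the BG box


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def brain_mask(shape) -> np.ndarray:
    """Fixed ellipsoid standing in for the brain, inscribed in the volume."""
    grids = np.indices(shape).astype(float)
    c = (np.asarray(shape) - 1) / 2.0
    semi = 0.45 * np.asarray(shape)
    d2 = sum(((grids[i] - c[i]) / semi[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def ventricle_mask(shape) -> np.ndarray:
    """Small central ellipsoid of CSF intensity (ventricle surrogate)."""
    grids = np.indices(shape).astype(float)
    c = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * np.array([0.10, 0.18, 0.28])
    semi = np.maximum(semi, 1.0)
    d2 = sum(((grids[i] - c[i]) / semi[i]) ** 2 for i in range(3))
    return d2 <= 1.0


def basal_ganglia_box(shape):
    """Interior box designating the basal-ganglia region: slices per axis."""
    return tuple(slice(int(0.30 * s), int(np.ceil(0.70 * s))) for s in shape)


def _in_bg_box(centroid, shape) -> bool:
    box = basal_ganglia_box(shape)
    return all(b.start <= c < b.stop for c, b in zip(centroid, box))


def _mm_coords(shape, spacing):
    """Voxel-centre coordinates in mm, relative to the volume centre."""
    grids = np.indices(shape).astype(float)
    c = (np.asarray(shape) - 1) / 2.0
    return [(grids[i] - c[i]) * spacing[i] for i in range(3)]


def _ellipsoid(shape, spacing, center_vox, semi_mm):
    grids = np.indices(shape).astype(float)
    d2 = sum((((grids[i] - center_vox[i]) * spacing[i]) / semi_mm[i]) ** 2
             for i in range(3))
    return d2 <= 1.0


def _sphere(shape, spacing, center_vox, radius_mm):
    return _ellipsoid(shape, spacing, center_vox, (radius_mm,) * 3)


def _cylinder(shape, spacing, center_vox, axis, half_len_mm, radius_mm):
    grids = np.indices(shape).astype(float)
    rel = [(grids[i] - center_vox[i]) * spacing[i] for i in range(3)]
    t = sum(rel[i] * axis[i] for i in range(3))
    perp2 = sum((rel[i] - t * axis[i]) ** 2 for i in range(3))
    return (np.abs(t) <= half_len_mm) & (perp2 <= radius_mm ** 2)


# ---------------------------------------------------------------------------
# patient generation
# ---------------------------------------------------------------------------

def _sample_center(rng, brain, near=None):
    """Random voxel inside the brain; optionally near a given region."""
    idx = np.argwhere(near if near is not None else brain)
    return idx[rng.integers(len(idx))].astype(float)


def generate_patient(spec: PhantomSpec, burden_level: int,
                     patient_id: str = "P000",
                     rng: np.random.Generator | None = None):
    """Render one synthetic patient: three sequence volumes + ground truth.

    ``burden_level`` (ordinal 0-4) monotonically scales the expected lesion
    counts: counts ~ Poisson(rate * (1 + burden_level)).
    """
    spec.validate()
    if not (0 <= int(burden_level) <= 4):
        raise ValueError(f"burden_level must be in 0..4, got {burden_level}")
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    shape = tuple(int(s) for s in spec.image_shape)
    brain = brain_mask(shape)
    vent = ventricle_mask(shape) & brain

    # background tissue per sequence
    grids = {}
    for seq in SEQUENCES:
        t = _TISSUE[seq]
        g = np.full(shape, t["background"], dtype=np.float64)
        g[brain] = t["brain"]
        g[vent] = t["csf"]
        grids[seq] = g

    masks = {m: np.zeros(shape, dtype=bool) for m in MARKERS}
    scale = 1.0 + int(burden_level)

    # region WMH lesions gather near the ventricle surface
    vent_shell = ndimage.binary_dilation(vent, iterations=3) & brain

    for marker in MARKERS:
        n_lesions = rng.poisson(spec.lesion_rates[marker] * scale)
        spacing = spec.spacing_per_sequence[MARKER_SOURCE[marker]]
        lo, hi = spec.lesion_size_ranges[marker]
        for _ in range(n_lesions):
            if marker == "WMH":
                center = _sample_center(rng, brain, near=vent_shell)
                d = rng.uniform(lo, hi)
                semi = (d / 2.0) * rng.uniform(0.5, 1.0, size=3)
                lesion = _ellipsoid(shape, spacing, center, semi)
            elif marker in ("CMB", "lacune"):
                center = _sample_center(rng, brain)
                d = rng.uniform(lo, hi)
                lesion = _sphere(shape, spacing, center, d / 2.0)
            else:  # EPVS: thin tube, diameter <= 3 mm
                center = _sample_center(rng, brain)
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                length = rng.uniform(lo, hi)
                radius = rng.uniform(0.5, 1.5)   # diameter 1-3 mm
                lesion = _cylinder(shape, spacing, center, axis, length / 2.0, radius)
            lesion &= brain
            if not lesion.any():
                continue
            masks[marker] |= lesion

    # paint lesions into their source sequences only
    for (marker, seq), value in _LESION_INTENSITY.items():
        grids[seq][masks[marker]] = value
    if masks["lacune"].any():
        rim = ndimage.binary_dilation(masks["lacune"]) & ~masks["lacune"] & brain
        grids["FLAIR"][rim & ~masks["WMH"]] = _LACUNE_RIM_FLAIR

    for seq in SEQUENCES:
        grids[seq] += rng.normal(0.0, spec.noise_sigma, size=shape)

    # ground-truth instances from connected components (26-connectivity)
    structure = np.ones((3, 3, 3), dtype=bool)
    instances, counts = {}, {}
    for marker in MARKERS:
        spacing = spec.spacing_per_sequence[MARKER_SOURCE[marker]]
        voxvol = float(np.prod(spacing))
        lab, n = ndimage.label(masks[marker], structure=structure)
        inst = []
        for i in range(1, n + 1):
            vox = np.argwhere(lab == i)
            inst.append({
                "voxels": vox,
                "centroid": vox.mean(axis=0),
                "volume_mm3": len(vox) * voxvol,
            })
        instances[marker] = inst
        counts[marker] = n

    epvs_bg = sum(1 for inst in instances["EPVS"]
                  if _in_bg_box(inst["centroid"], shape))

    vol = MultiSeqVolume(patient_id=patient_id, volumes=grids,
                         spacing=dict(spec.spacing_per_sequence))
    gt = LesionGroundTruth(masks=masks, instances=instances, counts=counts,
                           epvs_bg_count=epvs_bg)
    return vol, gt


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _nifti(grid, spacing):
    affine = np.diag(list(spacing) + [1.0])
    return nib.Nifti1Image(np.asarray(grid, dtype=np.float32), affine)


def generate_cohort(spec: PhantomSpec, n_patients: int, out_dir,
                    force: bool = False, burden_levels=None) -> pd.DataFrame:
    """Write a cohort of phantoms to ``out_dir`` and return the manifest.

    Per patient: one NIfTI per sequence and one per marker mask.  Burden
    levels cycle 0..4 unless given explicitly.  Patient seeds are spawned
    deterministically from ``spec.seed``.
    """
    spec.validate()
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    out_dir = Path(out_dir)
    if out_dir.exists() and any(out_dir.iterdir()) and not force:
        raise FileExistsError(f"{out_dir} exists and is not empty (use force=True)")
    out_dir.mkdir(parents=True, exist_ok=True)

    if burden_levels is None:
        burden_levels = [i % 5 for i in range(n_patients)]
    if len(burden_levels) != n_patients:
        raise ValueError("burden_levels length must equal n_patients")

    rows = []
    child_seeds = np.random.SeedSequence(spec.seed).spawn(n_patients)
    for i in range(n_patients):
        pid = f"P{i:03d}"
        rng = np.random.default_rng(child_seeds[i])
        vol, gt = generate_patient(spec, burden_levels[i], patient_id=pid, rng=rng)
        for seq in SEQUENCES:
            _nifti(vol.volumes[seq], vol.spacing[seq]).to_filename(
                out_dir / f"{pid}_{seq}.nii.gz")
        row = {"patient_id": pid, "burden_level": burden_levels[i],
               "epvs_bg_count": gt.epvs_bg_count}
        for marker in MARKERS:
            spacing = spec.spacing_per_sequence[MARKER_SOURCE[marker]]
            _nifti(gt.masks[marker].astype(np.uint8), spacing).to_filename(
                out_dir / f"{pid}_mask_{marker}.nii.gz")
            row[f"count_{marker}"] = gt.counts[marker]
            row[f"volume_{marker}"] = sum(x["volume_mm3"] for x in gt.instances[marker])
        rows.append(row)

    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest
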