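"""Segmentation evaluation: confusion metrics, HD95, lesion-wise sensitivity.

Voxelwise metrics follow the usual confusion-matrix definitions
(Pre = TP/(TP+FP), Sp = TN/(FP+TN), Dice = 2TP/(FP+2TP+FN)).  HD95 is the
95th percentile of the pooled directed surface distances between the two
masks, in physical mm.  Lesion-wise sensitivity counts a reference lesion as
detected when the prediction covers at least 50% of its voxels.  Confidence
intervals are percentile bootstrap over patients.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree


@dataclasses.dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclasses.dataclass
class LesionInstance:
    voxels: np.ndarray          # (n, ndim) integer indices
    size: int
    volume_mm3: float
    marker: str | None = None


def _check_binary(arr, name):
    a = np.asarray(arr)
    if a.dtype != bool:
        vals = np.unique(a)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError(f"{name} must be binary, found values {vals[:5]}")
        a = a.astype(bool)
    return a


# ---------------------------------------------------------------------------
# voxelwise confusion metrics
# ---------------------------------------------------------------------------

def confusion_counts(pred, truth) -> ConfusionCounts:
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    tp = int(np.sum(p & t))
    fp = int(np.sum(p & ~t))
    fn = int(np.sum(~p & t))
    tn = p.size - tp - fp - fn
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def precision(c: ConfusionCounts) -> float:
    """TP / (TP + FP); defined as 1 when nothing was predicted positive."""
    return c.tp / (c.tp + c.fp) if (c.tp + c.fp) > 0 else 1.0


def specificity(c: ConfusionCounts) -> float:
    """TN / (FP + TN); defined as 1 when there are no true negatives to miss."""
    return c.tn / (c.fp + c.tn) if (c.fp + c.tn) > 0 else 1.0


def dice_from_counts(c: ConfusionCounts) -> float:
    """2TP / (FP + 2TP + FN); 1 when both masks are empty."""
    denom = c.fp + 2 * c.tp + c.fn
    return 2 * c.tp / denom if denom > 0 else 1.0


# ---------------------------------------------------------------------------
# surface distances
# ---------------------------------------------------------------------------

def _surface_points(mask: np.ndarray, spacing) -> np.ndarray:
    """Physical coordinates of border voxels (mask minus its erosion)."""
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    border = mask & ~ndimage.binary_erosion(mask, structure=structure,
                                            border_value=0)
    return np.argwhere(border) * np.asarray(spacing, dtype=float)


def hd95(pred, truth, spacing=None, method: str = "percentile") -> float:
    """95th-percentile Hausdorff distance between two masks, in mm.

    Both directed surface-distance sets d(X->Y) and d(Y->X) are pooled and
    the 95th percentile taken, making the measure symmetric.  ``method=
    "scaled_max"`` instead returns max of the two directed Hausdorff
    distances scaled by 0.95 (a variant kept for comparability).  Returns
    NaN when either mask is empty (reported as missing, never 0).
    """
    p = _check_binary(pred, "pred")
    t = _check_binary(truth, "truth")
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch {p.shape} vs {t.shape}")
    if spacing is None:
        spacing = (1.0,) * p.ndim
    if not p.any() or not t.any():
        return float("nan")
    a = _surface_points(p, spacing)
    b = _surface_points(t, spacing)
    d_ab = cKDTree(b).query(a)[0]
    d_ba = cKDTree(a).query(b)[0]
    if method == "percentile":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), 95))
    if method == "scaled_max":
        return float(max(d_ab.max(), d_ba.max()) * 0.95)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# lesion instances
# ---------------------------------------------------------------------------

def extract_lesions(mask, spacing=None, marker: str | None = None) -> list:
    """Connected components under 26-connectivity (3-D) / 8-connectivity (2-D)."""
    m = _check_binary(mask, "mask")
    if spacing is None:
        spacing = (1.0,) * m.ndim
    voxvol = float(np.prod(spacing))
    structure = np.ones((3,) * m.ndim, dtype=bool)
    lab, n = ndimage.label(m, structure=structure)
    out = []
    for i in range(1, n + 1):
        vox = np.argwhere(lab == i)
        out.append(LesionInstance(voxels=vox, size=len(vox),
                                  volume_mm3=len(vox) * voxvol, marker=marker))
    return out


def per_lesion_sensitivity(pred, truth_instances):
    """Lesion-wise sensitivity with the >= 50% coverage rule.

    A reference lesion counts as detected (lesion TP) iff the prediction
    covers at least half of its voxels.  Returns (sen, n_tp, n_fn); sen is
    NaN when there are no reference lesions.
    """
    p = _check_binary(pred, "pred")
    n_tp = n_fn = 0
    for inst in truth_instances:
        idx = tuple(inst.voxels.T)
        coverage = p[idx].sum() / inst.size
        if coverage >= 0.5:
            n_tp += 1
        else:
            n_fn += 1
    sen = n_tp / (n_tp + n_fn) if (n_tp + n_fn) > 0 else float("nan")
    return sen, n_tp, n_fn


# ---------------------------------------------------------------------------
# confidence intervals and cohort reports
# ---------------------------------------------------------------------------

def bootstrap_ci(values, n_boot: int = 2000, level: float = 0.95,
                 seed: int = 0):
    """Percentile bootstrap CI of the mean over patients."""
    vals = np.asarray([v for v in values if np.isfinite(v)], dtype=float)
    if len(vals) < 2:
        raise ValueError("need at least 2 finite per-patient values")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; CI will be unstable")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(vals), size=(n_boot, len(vals)))
    means = vals[idx].mean(axis=1)
    alpha = (1.0 - level) / 2.0
    return (float(np.quantile(means, alpha)), float(np.quantile(means, 1 - alpha)))


#: markers excluded from lesion-wise sensitivity (confluent-lesion practice)
SEN_EXCLUDED = ("WMH",)


def patient_metrics(pred, truth, spacing=None, marker: str | None = None,
                    threshold: float = 0.5) -> dict:
    """All voxel- and lesion-level metrics for one patient volume pair."""
    p = np.asarray(pred)
    if p.dtype != bool and not np.isin(np.unique(p), (0, 1)).all():
        p = p >= threshold
    c = confusion_counts(p, truth)
    row = {
        "precision": precision(c),
        "specificity": specificity(c),
        "dice": dice_from_counts(c),
        "hd95_mm": hd95(np.asarray(p, dtype=bool), truth, spacing),
    }
    if marker is None or marker not in SEN_EXCLUDED:
        sen, n_tp, n_fn = per_lesion_sensitivity(
            np.asarray(p, dtype=bool),
            extract_lesions(truth, spacing, marker))
        row.update(lesion_sen=sen, lesion_tp=n_tp, lesion_fn=n_fn)
    else:
        row.update(lesion_sen=float("nan"), lesion_tp=0, lesion_fn=0)
    return row


def cohort_report(per_patient_rows, n_boot: int = 2000, seed: int = 0) -> dict:
    """Mean and 95% bootstrap CI per metric over a cohort of patients."""
    report = {}
    keys = ("precision", "specificity", "dice", "hd95_mm", "lesion_sen")
    for k in keys:
        vals = np.asarray([r[k] for r in per_patient_rows], dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) == 0:
            report[k] = {"mean": float("nan"), "ci": (float("nan"), float("nan"))}
            continue
        entry = {"mean": float(finite.mean())}
        entry["ci"] = (bootstrap_ci(finite, n_boot=n_boot, seed=seed)
                       if len(finite) >= 2 else (float(finite[0]), float(finite[0])))
        report[k] = entry
    return report
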