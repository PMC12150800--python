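"""Independent brute-force oracles shared by the metric test modules."""

import numpy as np


def confusion_oracle(pred, truth):
    """Per-voxel python loop, independent of any vectorised path."""
    tp = tn = fp = fn = 0
    for p, t in zip(pred.ravel(), truth.ravel()):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return tp, tn, fp, fn


def surface_oracle(mask):
    """Border voxels: any face-neighbour outside the mask (or the grid)."""
    pts = []
    for idx in np.argwhere(mask):
        border = False
        for ax in range(mask.ndim):
            for d in (-1, 1):
                nb = idx.copy()
                nb[ax] += d
                if (nb < 0).any() or (nb >= np.array(mask.shape)).any() \
                        or not mask[tuple(nb)]:
                    border = True
                    break
            if border:
                break
        if border:
            pts.append(idx)
    return np.array(pts, dtype=float)


def hd95_oracle(a, b, spacing):
    """Exhaustive all-pairs Euclidean distances, pooled 95th percentile."""
    sa = surface_oracle(a) * spacing
    sb = surface_oracle(b) * spacing
    d2 = ((sa[:, None, :] - sb[None, :, :]) ** 2).sum(-1)
    d_ab = np.sqrt(d2.min(axis=1))
    d_ba = np.sqrt(d2.min(axis=0))
    return np.percentile(np.concatenate([d_ab, d_ba]), 95)
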