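"""Gray-level run-length matrix features.

Maximal runs of equal level are collected along each of the 13 unique 3-D
directions; out-of-mask voxels interrupt runs.  Features are computed per
direction and averaged over directions containing at least one run.
"""

from __future__ import annotations

import numpy as np

from ._offsets import UNIQUE_OFFSETS
from .discretize import DiscretizedROI

__all__ = ["glrlm_matrices", "glrlm_features"]


def _line_starts(shape, d):
    """Voxels whose predecessor along ``d`` falls outside the array."""
    idx = np.indices(shape).reshape(3, -1).T
    prev = idx - np.asarray(d)
    outside = (
        (prev < 0) | (prev >= np.asarray(shape))
    ).any(axis=1)
    return idx[outside]


def glrlm_matrices(disc: DiscretizedROI) -> list[np.ndarray]:
    """One (Ng, max_run_length) count matrix per direction."""
    shape = disc.levels.shape
    max_len = int(np.ceil(np.sqrt(sum(s**2 for s in shape)))) + 1
    lev = disc.levels  # 0 outside mask
    mats = []
    for d in UNIQUE_OFFSETS:
        mat = np.zeros((disc.ng, max_len))
        for start in _line_starts(shape, d):
            v = start.copy()
            run_level = 0
            run_len = 0
            while (v >= 0).all() and (v < shape).all():
                level = lev[tuple(v)]
                if level == run_level and level != 0:
                    run_len += 1
                else:
                    if run_level != 0:
                        mat[run_level - 1, run_len - 1] += 1
                    run_level = level
                    run_len = 1 if level != 0 else 0
                v += d
            if run_level != 0:
                mat[run_level - 1, run_len - 1] += 1
        mats.append(mat)
    return mats


def _features_one(mat: np.ndarray) -> dict[str, float]:
    nr = mat.sum()
    ng, nl = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nl + 1)[None, :]
    row = mat.sum(axis=1)  # per gray level
    col = mat.sum(axis=0)  # per run length
    return {
        "GLRLM.GLN": float((row**2).sum() / nr),
        "GLRLM.RLN": float((col**2).sum() / nr),
        "GLRLM.HGLRE": float((mat * i**2).sum() / nr),
        "GLRLM.SRHGLE": float((mat * i**2 / j**2).sum() / nr),
        "GLRLM.LRHGLE": float((mat * i**2 * j**2).sum() / nr),
    }


def glrlm_features(disc: DiscretizedROI) -> dict[str, float]:
    """Direction-averaged GLN, RLN, HGLRE, SRHGLE, LRHGLE."""
    per_dir = [
        _features_one(mat) for mat in glrlm_matrices(disc) if mat.sum() > 0
    ]
    if not per_dir:
        raise ValueError("no runs in any direction (empty ROI?)")
    keys = per_dir[0].keys()
    return {k: float(np.mean([f[k] for f in per_dir])) for k in keys}
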