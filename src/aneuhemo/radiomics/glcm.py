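"""Gray-level co-occurrence matrix features.

Pairs are counted for the 13 unique offsets at Chebyshev distance
``distance``, each matrix symmetrized and normalized, features computed per
offset and averaged over offsets that contain at least one pair.
"""

from __future__ import annotations

import numpy as np

from ._offsets import UNIQUE_OFFSETS, shifted_views
from .discretize import DiscretizedROI

__all__ = ["glcm_matrices", "glcm_features"]


def glcm_matrices(disc: DiscretizedROI, distance: int = 1) -> np.ndarray:
    """(13, Ng, Ng) symmetrized (unnormalized) co-occurrence counts."""
    ng = disc.ng
    lev = disc.levels
    mask = disc.mask
    out = np.zeros((len(UNIQUE_OFFSETS), ng, ng))
    for k, off in enumerate(UNIQUE_OFFSETS):
        off_d = tuple(distance * o for o in off)
        ctr, nbr = shifted_views(lev, off_d)
        valid = mask[ctr] & mask[nbr]
        i = lev[ctr][valid] - 1
        j = lev[nbr][valid] - 1
        mat = np.zeros((ng, ng))
        np.add.at(mat, (i, j), 1.0)
        out[k] = mat + mat.T
    return out


def _features_one(p: np.ndarray) -> dict[str, float]:
    ng = p.shape[0]
    i = np.arange(1, ng + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    mu_x = float((ii * p).sum())
    mu_y = float((jj * p).sum())
    contrast = float(((ii - jj) ** 2 * p).sum())
    cs = float(((ii + jj - mu_x - mu_y) ** 3 * p).sum())
    cp = float(((ii + jj - mu_x - mu_y) ** 4 * p).sum())
    # distribution of |i - j|
    k = np.arange(ng)
    p_diff = np.zeros(ng)
    np.add.at(p_diff, np.abs(ii - jj).ravel(), p.ravel())
    da = float((k * p_diff).sum())
    dv = float(((k - da) ** 2 * p_diff).sum())
    return {
        "Contrast": contrast,
        "CS": cs,
        "CP": cp,
        "GLCM.DA": da,
        "GLCM.DV": dv,
    }


def glcm_features(disc: DiscretizedROI, distance: int = 1) -> dict[str, float]:
    """Offset-averaged Contrast, Cluster Shade/Prominence, Difference
    Average/Variance.  A ROI with no co-occurring pairs (e.g. one voxel)
    yields zeros and is flagged via the ``degenerate`` key."""
    mats = glcm_matrices(disc, distance)
    per_offset = []
    for mat in mats:
        total = mat.sum()
        if total == 0:
            continue
        per_offset.append(_features_one(mat / total))
    if not per_offset:
        out = {"Contrast": 0.0, "CS": 0.0, "CP": 0.0, "GLCM.DA": 0.0, "GLCM.DV": 0.0}
        out["degenerate"] = True
        return out
    keys = per_offset[0].keys()
    out = {k: float(np.mean([f[k] for f in per_offset])) for k in keys}
    out["degenerate"] = False
    return out
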