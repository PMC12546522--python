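"""Gray-level dependence matrix features.

A voxel's dependence is 1 plus the number of its in-mask 26-neighbors whose
level differs by at most ``alpha``.
"""

from __future__ import annotations

import numpy as np

from ._offsets import ALL_OFFSETS, shifted_views
from .discretize import DiscretizedROI

__all__ = ["gldm_matrix", "gldm_features"]


def gldm_matrix(disc: DiscretizedROI, alpha: int = 0) -> np.ndarray:
    """(Ng, 27) voxel-count matrix indexed by (level, dependence)."""
    lev = disc.levels
    mask = disc.mask
    dep = np.zeros(lev.shape, dtype=np.int64)
    for off in ALL_OFFSETS:
        ctr, nbr = shifted_views(lev, off)
        ok = mask[ctr] & mask[nbr] & (np.abs(lev[ctr] - lev[nbr]) <= alpha)
        dep[ctr] += ok
    mat = np.zeros((disc.ng, 27))
    i = lev[mask] - 1
    j = dep[mask]  # dependence - 1 (dependence = 1 + count)
    np.add.at(mat, (i, j), 1.0)
    return mat


def gldm_features(disc: DiscretizedROI, alpha: int = 0) -> dict[str, float]:
    """DN, DNN, GLN, HGLE, SDHGLE."""
    mat = gldm_matrix(disc, alpha=alpha)
    nz = mat.sum()  # equals the ROI voxel count
    ng, nd = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nd + 1)[None, :]
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    dn = float((col**2).sum() / nz)
    return {
        "GLDM.DN": dn,
        "GLDM.DNN": dn / nz,
        "GLDM.GLN": float((row**2).sum() / nz),
        "GLDM.HGLE": float((mat * i**2).sum() / nz),
        "GLDM.SDHGLE": float((mat * i**2 / j**2).sum() / nz),
    }
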