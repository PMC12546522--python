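"""Gray-level size-zone matrix features.

A zone is a 26-connected component of equal-level in-mask voxels; the
matrix is orientation-free so no direction averaging is involved.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .discretize import DiscretizedROI

__all__ = ["glszm_matrix", "glszm_features"]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def glszm_matrix(disc: DiscretizedROI) -> np.ndarray:
    """(Ng, max_zone_size) zone count matrix."""
    n = disc.n_voxels
    mat = np.zeros((disc.ng, n))
    for level in np.unique(disc.level_values()):
        binary = (disc.levels == level) & disc.mask
        labeled, n_zones = ndimage.label(binary, structure=_STRUCT26)
        if n_zones == 0:
            continue
        sizes = np.bincount(labeled.ravel())[1:]
        for s in sizes:
            mat[level - 1, s - 1] += 1
    return mat


def glszm_features(disc: DiscretizedROI) -> dict[str, float]:
    """SZN, GLN, GLV, HGLZE, SAHGLE."""
    mat = glszm_matrix(disc)
    nz = mat.sum()
    ng, nmax = mat.shape
    i = np.arange(1, ng + 1)[:, None]
    j = np.arange(1, nmax + 1)[None, :]
    row = mat.sum(axis=1)
    col = mat.sum(axis=0)
    p = mat / nz
    mu = float((p * i).sum())
    return {
        "GLSZM.SZN": float((col**2).sum() / nz),
        "GLSZM.GLN": float((row**2).sum() / nz),
        "GLSZM.GLV": float((p * (i - mu) ** 2).sum()),
        "GLSZM.HGLZE": float((mat * i**2).sum() / nz),
        "GLSZM.SAHGLE": float((mat * i**2 / j**2).sum() / nz),
    }
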