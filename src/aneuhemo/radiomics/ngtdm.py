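"""Neighborhood gray-tone difference matrix features.

For each level i over voxels with at least one in-mask 26-neighbor:
n_i voxels, p_i = n_i / Nvp, and s_i the summed absolute difference between
i and the mean level of each voxel's in-mask neighborhood.

Sentinels for degenerate denominators (constant ROI) follow common
reference conventions: Coarseness -> 1e6, Strength -> 0.
"""

from __future__ import annotations

import numpy as np

from ._offsets import ALL_OFFSETS, shifted_views
from .discretize import DiscretizedROI

__all__ = ["ngtdm_table", "ngtdm_features"]

COARSENESS_SENTINEL = 1.0e6


def ngtdm_table(disc: DiscretizedROI) -> tuple[np.ndarray, np.ndarray, int]:
    """(n_i, s_i) arrays over levels 1..Ng plus the valid-voxel count Nvp."""
    lev = disc.levels
    mask = disc.mask
    nbr_sum = np.zeros(lev.shape, dtype=float)
    nbr_cnt = np.zeros(lev.shape, dtype=np.int64)
    for off in ALL_OFFSETS:
        ctr, nbr = shifted_views(lev, off)
        ok = mask[nbr]
        nbr_sum[ctr] += np.where(ok, lev[nbr], 0)
        nbr_cnt[ctr] += ok
    valid = mask & (nbr_cnt > 0)
    nvp = int(valid.sum())
    n = np.zeros(disc.ng)
    s = np.zeros(disc.ng)
    if nvp:
        levels = lev[valid]
        mean_nbr = nbr_sum[valid] / nbr_cnt[valid]
        diffs = np.abs(levels - mean_nbr)
        np.add.at(n, levels - 1, 1.0)
        np.add.at(s, levels - 1, diffs)
    return n, s, nvp


def ngtdm_features(disc: DiscretizedROI) -> dict[str, float]:
    """Coarseness, Complexity, Strength."""
    n, s, nvp = ngtdm_table(disc)
    if nvp == 0:
        raise ValueError("no voxel has an in-mask neighbor")
    p = n / nvp
    i = np.arange(1, disc.ng + 1, dtype=float)
    present = p > 0

    denom = float((p * s).sum())
    coarseness = COARSENESS_SENTINEL if denom == 0 else 1.0 / denom

    ip = i[present]
    pp = p[present]
    sp = s[present]
    di = np.abs(ip[:, None] - ip[None, :])
    psum = pp[:, None] + pp[None, :]
    complexity = float(
        (di * (pp[:, None] * sp[:, None] + pp[None, :] * sp[None, :]) / psum).sum()
    ) / nvp

    s_total = float(s.sum())
    strength = (
        0.0 if s_total == 0 else float((psum * di**2).sum()) / s_total
    )
    return {
        "NGTDM.Coarseness": coarseness,
        "NGTDM.Complexity": complexity,
        "NGTDM.Strength": strength,
    }
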