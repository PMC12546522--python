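"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately written with plain Python loops and explicit
formula transcriptions, sharing no code path with the package
implementations it checks.
"""

from __future__ import annotations

import itertools

import numpy as np

OFFSETS_13 = [
    o
    for o in itertools.product((-1, 0, 1), repeat=3)
    if o != (0, 0, 0) and o > (0, 0, 0)
]
OFFSETS_26 = [o for o in itertools.product((-1, 0, 1), repeat=3) if o != (0, 0, 0)]


def _in_bounds(v, shape):
    return all(0 <= v[a] < shape[a] for a in range(3))


# ---------------------------------------------------------------- GLCM


def glcm_oracle(levels, mask, ng, distance=1):
    """Offset-averaged GLCM features by explicit pair enumeration."""
    shape = levels.shape
    voxels = [tuple(v) for v in np.argwhere(mask)]
    feats_per_offset = []
    for off in OFFSETS_13:
        off = tuple(distance * o for o in off)
        mat = [[0.0] * ng for _ in range(ng)]
        for v in voxels:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _in_bounds(w, shape) and mask[w]:
                i = levels[v] - 1
                j = levels[w] - 1
                mat[i][j] += 1
                mat[j][i] += 1
        total = sum(sum(row) for row in mat)
        if total == 0:
            continue
        p = [[mat[i][j] / total for j in range(ng)] for i in range(ng)]
        mu_x = sum((i + 1) * p[i][j] for i in range(ng) for j in range(ng))
        mu_y = sum((j + 1) * p[i][j] for i in range(ng) for j in range(ng))
        contrast = sum(
            (i - j) ** 2 * p[i][j] for i in range(ng) for j in range(ng)
        )
        cs = sum(
            (i + j + 2 - mu_x - mu_y) ** 3 * p[i][j]
            for i in range(ng)
            for j in range(ng)
        )
        cp = sum(
            (i + j + 2 - mu_x - mu_y) ** 4 * p[i][j]
            for i in range(ng)
            for j in range(ng)
        )
        pdiff = [0.0] * ng
        for i in range(ng):
            for j in range(ng):
                pdiff[abs(i - j)] += p[i][j]
        da = sum(k * pdiff[k] for k in range(ng))
        dv = sum((k - da) ** 2 * pdiff[k] for k in range(ng))
        feats_per_offset.append(
            {"Contrast": contrast, "CS": cs, "CP": cp, "GLCM.DA": da, "GLCM.DV": dv}
        )
    keys = feats_per_offset[0].keys()
    return {
        k: sum(f[k] for f in feats_per_offset) / len(feats_per_offset) for k in keys
    }


# ---------------------------------------------------------------- GLRLM


def glrlm_oracle(levels, mask, ng):
    """Direction-averaged run-length features by explicit run walking."""
    shape = levels.shape
    feats_per_dir = []
    for d in OFFSETS_13:
        runs = []  # (level, length)
        for v in itertools.product(*(range(s) for s in shape)):
            if not mask[v]:
                continue
            prev = (v[0] - d[0], v[1] - d[1], v[2] - d[2])
            # run starts here if the previous voxel can't extend it
            if _in_bounds(prev, shape) and mask[prev] and levels[prev] == levels[v]:
                continue
            length = 0
            w = v
            while _in_bounds(w, shape) and mask[w] and levels[w] == levels[v]:
                length += 1
                w = (w[0] + d[0], w[1] + d[1], w[2] + d[2])
            runs.append((levels[v], length))
        if not runs:
            continue
        nr = len(runs)
        gln = 0.0
        for i in range(1, ng + 1):
            gln += sum(1 for lv, _ in runs if lv == i) ** 2
        rln = 0.0
        for j in set(length for _, length in runs):
            rln += sum(1 for _, length in runs if length == j) ** 2
        hglre = sum(lv**2 for lv, _ in runs)
        srhgle = sum(lv**2 / length**2 for lv, length in runs)
        lrhgle = sum(lv**2 * length**2 for lv, length in runs)
        feats_per_dir.append(
            {
                "GLRLM.GLN": gln / nr,
                "GLRLM.RLN": rln / nr,
                "GLRLM.HGLRE": hglre / nr,
                "GLRLM.SRHGLE": srhgle / nr,
                "GLRLM.LRHGLE": lrhgle / nr,
            }
        )
    keys = feats_per_dir[0].keys()
    return {k: sum(f[k] for f in feats_per_dir) / len(feats_per_dir) for k in keys}


# ---------------------------------------------------------------- GLSZM


def _zones(levels, mask):
    """All 26-connected equal-level zones as (level, size) via BFS flood fill."""
    shape = levels.shape
    seen = set()
    zones = []
    for v in itertools.product(*(range(s) for s in shape)):
        if not mask[v] or v in seen:
            continue
        level = levels[v]
        stack = [v]
        seen.add(v)
        size = 0
        while stack:
            u = stack.pop()
            size += 1
            for off in OFFSETS_26:
                w = (u[0] + off[0], u[1] + off[1], u[2] + off[2])
                if (
                    _in_bounds(w, shape)
                    and w not in seen
                    and mask[w]
                    and levels[w] == level
                ):
                    seen.add(w)
                    stack.append(w)
        zones.append((level, size))
    return zones


def glszm_oracle(levels, mask, ng):
    zones = _zones(levels, mask)
    nz = len(zones)
    gln = sum(
        sum(1 for lv, _ in zones if lv == i) ** 2 for i in range(1, ng + 1)
    )
    szn = sum(
        sum(1 for _, sz in zones if sz == j) ** 2
        for j in set(sz for _, sz in zones)
    )
    mu = sum(lv for lv, _ in zones) / nz
    glv = sum((lv - mu) ** 2 for lv, _ in zones) / nz
    hglze = sum(lv**2 for lv, _ in zones)
    sahgle = sum(lv**2 / sz**2 for lv, sz in zones)
    return {
        "GLSZM.SZN": szn / nz,
        "GLSZM.GLN": gln / nz,
        "GLSZM.GLV": glv,
        "GLSZM.HGLZE": hglze / nz,
        "GLSZM.SAHGLE": sahgle / nz,
    }


# ---------------------------------------------------------------- GLDM


def gldm_oracle(levels, mask, ng, alpha=0):
    shape = levels.shape
    entries = []  # (level, dependence)
    for v in itertools.product(*(range(s) for s in shape)):
        if not mask[v]:
            continue
        dep = 1
        for off in OFFSETS_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _in_bounds(w, shape) and mask[w] and abs(levels[v] - levels[w]) <= alpha:
                dep += 1
        entries.append((levels[v], dep))
    nz = len(entries)
    dn = sum(
        sum(1 for _, d in entries if d == j) ** 2
        for j in set(d for _, d in entries)
    )
    gln = sum(
        sum(1 for lv, _ in entries if lv == i) ** 2 for i in range(1, ng + 1)
    )
    hgle = sum(lv**2 for lv, _ in entries)
    sdhgle = sum(lv**2 / d**2 for lv, d in entries)
    return {
        "GLDM.DN": dn / nz,
        "GLDM.DNN": dn / nz**2,
        "GLDM.GLN": gln / nz,
        "GLDM.HGLE": hgle / nz,
        "GLDM.SDHGLE": sdhgle / nz,
    }


# ---------------------------------------------------------------- NGTDM


def ngtdm_oracle(levels, mask, ng):
    shape = levels.shape
    n = [0.0] * (ng + 1)
    s = [0.0] * (ng + 1)
    nvp = 0
    for v in itertools.product(*(range(s_) for s_ in shape)):
        if not mask[v]:
            continue
        nbrs = []
        for off in OFFSETS_26:
            w = (v[0] + off[0], v[1] + off[1], v[2] + off[2])
            if _in_bounds(w, shape) and mask[w]:
                nbrs.append(levels[w])
        if not nbrs:
            continue
        nvp += 1
        i = levels[v]
        n[i] += 1
        s[i] += abs(i - sum(nbrs) / len(nbrs))
    p = [ni / nvp for ni in n]
    denom = sum(p[i] * s[i] for i in range(1, ng + 1))
    coarseness = 1e6 if denom == 0 else 1.0 / denom
    complexity = 0.0
    for i in range(1, ng + 1):
        for j in range(1, ng + 1):
            if p[i] > 0 and p[j] > 0:
                complexity += (
                    abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                )
    complexity /= nvp
    s_total = sum(s[1:])
    strength = 0.0
    if s_total > 0:
        for i in range(1, ng + 1):
            for j in range(1, ng + 1):
                if p[i] > 0 and p[j] > 0:
                    strength += (p[i] + p[j]) * (i - j) ** 2
        strength /= s_total
    return {
        "NGTDM.Coarseness": coarseness,
        "NGTDM.Complexity": complexity,
        "NGTDM.Strength": strength,
    }


# ---------------------------------------------------------------- vortex


def q_oracle(points, tets, velocity):
    """Per-cell Q by per-cell explicit matrix inversion (slow, independent)."""
    out = np.zeros(len(tets))
    for c, tet in enumerate(tets):
        x0, x1, x2, x3 = (points[i] for i in tet)
        u0, u1, u2, u3 = (velocity[i] for i in tet)
        X = np.column_stack([x1 - x0, x2 - x0, x3 - x0])
        U = np.column_stack([u1 - u0, u2 - u0, u3 - u0])
        J = U @ np.linalg.inv(X)
        q = 0.0
        for a in range(3):
            for b in range(3):
                s_ab = 0.5 * (J[a, b] + J[b, a])
                w_ab = 0.5 * (J[a, b] - J[b, a])
                q += 0.5 * (w_ab**2 - s_ab**2)
        out[c] = q
    return out


# ---------------------------------------------------------------- spearman


def spearman_permutation_p(x, y):
    """Exact two-sided permutation p for Spearman rho (small n only)."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)

    def rho_of(r1, r2):
        return np.corrcoef(r1, r2)[0, 1]

    observed = abs(rho_of(rx, ry))
    count = total = 0
    for perm in itertools.permutations(ry):
        total += 1
        if abs(rho_of(rx, np.array(perm))) >= observed - 1e-12:
            count += 1
    return count / total
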