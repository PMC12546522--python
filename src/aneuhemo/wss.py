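"""Wall-shear-stress wall metrics: TAWSS, OSI, ECAP, RRT and sac summaries.

Definitions (per surface point, over one cardiac cycle of duration T with P
equally sampled phases; integrals discretized as phase means):

    TAWSS = (1/T) int |tau| dt
    OSI   = 1/2 * (1 - || int tau dt || / int |tau| dt)
    ECAP  = OSI / TAWSS
    RRT   = 1 / ((1 - 2 OSI) * TAWSS)

OSI is clamped to [0, 0.5]; points where the shear magnitude integrates to
zero get OSI = 0 and are flagged.  ECAP and RRT are non-finite (and
flagged) wherever their denominators fall below ``eps``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fields import TimeSeriesVectorField
from .meshes import SurfaceMesh

__all__ = [
    "WallMetricField",
    "time_average_wss",
    "oscillatory_shear_index",
    "ecap",
    "relative_residence_time",
    "compute_wall_metrics",
    "summarize_wall_metrics",
]

EPS = 1e-12


def _phase_integrals(
    f: TimeSeriesVectorField, rule: str
) -> tuple[np.ndarray, np.ndarray]:
    """Cycle means of the vector and of its magnitude, per point.

    ``rectangle``: plain phase mean — exact for equal sampling of a periodic
    signal.  ``trapezoid``: periodic trapezoid weights for non-uniform
    ``phase_times``.
    """
    mags = f.magnitudes()
    if rule == "rectangle":
        return f.values.mean(axis=0), mags.mean(axis=0)
    if rule == "trapezoid":
        t = f.phase_times
        T = f.cycle_duration
        # periodic trapezoid: each sample weighted by half the span between
        # its cyclic neighbours
        prev = np.roll(t, 1)
        prev[0] -= T
        nxt = np.roll(t, -1)
        nxt[-1] += T
        w = (nxt - prev) / 2.0 / T
        vec = np.einsum("p,pnk->nk", w, f.values)
        mag = np.einsum("p,pn->n", w, mags)
        return vec, mag
    raise ValueError(f"unknown integration rule {rule!r}")


def time_average_wss(field: TimeSeriesVectorField, rule: str = "rectangle") -> np.ndarray:
    """TAWSS per point: cycle mean of the WSS vector magnitude (Pa)."""
    if not isinstance(field.mesh, SurfaceMesh):
        raise TypeError("WSS metrics require a surface field")
    field.check_finite()
    _, mean_mag = _phase_integrals(field, rule)
    return mean_mag


def oscillatory_shear_index(
    field: TimeSeriesVectorField, rule: str = "rectangle"
) -> tuple[np.ndarray, np.ndarray]:
    """OSI per point plus a flag for zero-shear points (OSI set to 0 there)."""
    if not isinstance(field.mesh, SurfaceMesh):
        raise TypeError("WSS metrics require a surface field")
    field.check_finite()
    mean_vec, mean_mag = _phase_integrals(field, rule)
    zero = mean_mag <= EPS
    denom = np.where(zero, 1.0, mean_mag)
    osi = 0.5 * (1.0 - np.linalg.norm(mean_vec, axis=1) / denom)
    osi[zero] = 0.0
    np.clip(osi, 0.0, 0.5, out=osi)
    return osi, zero


def ecap(osi: np.ndarray, tawss: np.ndarray, eps: float = EPS) -> tuple[np.ndarray, np.ndarray]:
    """ECAP = OSI / TAWSS; non-finite + flagged where TAWSS < eps."""
    osi = np.asarray(osi, float)
    tawss = np.asarray(tawss, float)
    if osi.shape != tawss.shape:
        raise ValueError("shape mismatch between OSI and TAWSS")
    flagged = tawss < eps
    out = np.full_like(osi, np.nan)
    ok = ~flagged
    out[ok] = osi[ok] / tawss[ok]
    return out, flagged


def relative_residence_time(
    osi: np.ndarray, tawss: np.ndarray, eps: float = EPS
) -> tuple[np.ndarray, np.ndarray]:
    """RRT = 1 / ((1 - 2 OSI) * TAWSS); flagged where the denominator < eps."""
    osi = np.asarray(osi, float)
    tawss = np.asarray(tawss, float)
    if osi.shape != tawss.shape:
        raise ValueError("shape mismatch between OSI and TAWSS")
    denom = (1.0 - 2.0 * osi) * tawss
    flagged = denom < eps
    out = np.full_like(osi, np.nan)
    ok = ~flagged
    out[ok] = 1.0 / denom[ok]
    return out, flagged


@dataclass
class WallMetricField:
    """Per-point wall metrics plus flags and sac-level summaries."""

    mesh: SurfaceMesh
    tawss: np.ndarray
    osi: np.ndarray
    ecap: np.ndarray
    rrt: np.ndarray
    zero_shear_flag: np.ndarray
    ecap_flag: np.ndarray
    rrt_flag: np.ndarray
    summary: dict = field(default_factory=dict)


def compute_wall_metrics(
    field: TimeSeriesVectorField,
    weighting: str = "area",
    rule: str = "rectangle",
) -> WallMetricField:
    """Full per-point metric stack plus summaries (see summarize_wall_metrics)."""
    tawss = time_average_wss(field, rule)
    osi, zero = oscillatory_shear_index(field, rule)
    ecap_vals, ecap_flag = ecap(osi, tawss)
    rrt_vals, rrt_flag = relative_residence_time(osi, tawss)
    metrics = WallMetricField(
        mesh=field.mesh,
        tawss=tawss,
        osi=osi,
        ecap=ecap_vals,
        rrt=rrt_vals,
        zero_shear_flag=zero,
        ecap_flag=ecap_flag,
        rrt_flag=rrt_flag,
    )
    metrics.summary = summarize_wall_metrics(metrics, weighting=weighting)
    return metrics


def _weighted_mean(values: np.ndarray, weights: np.ndarray, keep: np.ndarray) -> float:
    w = weights[keep]
    if w.sum() <= 0:
        raise ValueError("all points flagged/zero-weight in summary")
    return float(np.sum(values[keep] * w) / w.sum())


def summarize_wall_metrics(metrics: WallMetricField, weighting: str = "area") -> dict:
    """Sac-level scalars: avg OSI/ECAP/RRT, mean/max TAWSS.

    ``weighting='area'`` uses lumped point areas; ``'uniform'`` weights every
    point equally.  Flagged points are excluded from the ECAP/RRT means and
    the exclusion counts are reported.
    """
    if weighting == "area":
        w = metrics.mesh.point_areas()
    elif weighting == "uniform":
        w = np.ones(metrics.mesh.n_points)
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if not np.any(w > 0):
        raise ValueError("mesh has no positive point areas")
    all_pts = np.ones(len(w), dtype=bool)
    return {
        "weighting": weighting,
        "avg_osi": _weighted_mean(metrics.osi, w, all_pts),
        "avg_ecap": _weighted_mean(metrics.ecap, w, ~metrics.ecap_flag),
        "avg_rrt": _weighted_mean(metrics.rrt, w, ~metrics.rrt_flag),
        "avg_tawss": _weighted_mean(metrics.tawss, w, all_pts),
        "max_tawss": float(metrics.tawss.max()),
        "n_ecap_excluded": int(metrics.ecap_flag.sum()),
        "n_rrt_excluded": int(metrics.rrt_flag.sum()),
        "n_zero_shear": int(metrics.zero_shear_flag.sum()),
    }
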