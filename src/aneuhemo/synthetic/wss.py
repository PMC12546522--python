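"""Pulsatile wall-shear-stress series with closed-form OSI/TAWSS targets.

Each region of the surface carries a fixed unit direction d and a positive
magnitude waveform m(t); a chosen fraction of the phases points along -d
instead of +d.  For constant m the planted OSI is exactly
(1 - |1 - 2 f|) / 2; in general the truth records the exact discrete value
computed from the planted signs and magnitudes.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from ..fields import TimeSeriesVectorField
from ..meshes import SurfaceMesh
from .truth import SyntheticTruth

__all__ = ["make_pulsatile_wss_series"]

MagnitudeSpec = "dict | float | np.ndarray | Callable[[np.ndarray], np.ndarray]"


def _magnitude_samples(spec, phase_times: np.ndarray, cycle: float) -> np.ndarray:
    """Evaluate a magnitude waveform spec at the phase times; must be > 0."""
    if callable(spec):
        m = np.asarray(spec(phase_times), dtype=float)
    elif isinstance(spec, dict):
        kind = spec.get("kind", "constant")
        if kind == "constant":
            m = np.full_like(phase_times, float(spec["value"]))
        elif kind == "pulsatile":
            base = float(spec["base"])
            amp = float(spec.get("amplitude", 0.0))
            m = base + amp * np.sin(2 * np.pi * phase_times / cycle)
        else:
            raise ValueError(f"unknown magnitude kind {kind!r}")
    elif np.isscalar(spec):
        m = np.full_like(phase_times, float(spec))
    else:
        m = np.asarray(spec, dtype=float)
        if m.shape != phase_times.shape:
            raise ValueError("magnitude array length must equal phase count")
    if (m <= 0).any():
        raise ValueError("magnitude waveform must be strictly positive")
    return m


def make_pulsatile_wss_series(
    mesh: SurfaceMesh,
    regions: np.ndarray | None = None,
    magnitude_profile=2.0,
    reversal_fraction=0.0,
    phases: int = 20,
    seed: int | None = None,
    cycle_duration: float = 1.0,
    directions: dict | None = None,
) -> tuple[TimeSeriesVectorField, SyntheticTruth]:
    """Generate a planted WSS series on ``mesh``.

    Parameters
    ----------
    regions : (n_points,) int labels or None for a single region 0.
    magnitude_profile : waveform spec, or mapping region label -> spec.
    reversal_fraction : float in [0, 0.5], or mapping region label -> float.
        The first round(f * P) phases point along -d.
    directions : optional mapping region label -> 3-vector; random unit
        directions drawn from ``seed`` otherwise.
    """
    if phases < 2:
        raise ValueError("need at least 2 phases")
    rng = np.random.default_rng(seed)
    n = mesh.n_points
    if regions is None:
        regions = np.zeros(n, dtype=np.int64)
    regions = np.asarray(regions, dtype=np.int64)
    if regions.shape != (n,):
        raise ValueError("regions must be one label per mesh point")
    labels = np.unique(regions)

    phase_times = np.arange(phases) * (cycle_duration / phases)

    def per_region(spec, label):
        if isinstance(spec, dict) and set(spec) >= set(labels.tolist()):
            return spec[label]
        return spec

    values = np.zeros((phases, n, 3))
    region_truth = {}
    osi_true = np.zeros(n)
    tawss_true = np.zeros(n)
    for label in labels:
        f = float(per_region(reversal_fraction, label))
        if not 0.0 <= f <= 0.5:
            raise ValueError("reversal_fraction must be in [0, 0.5]")
        m = _magnitude_samples(
            per_region(magnitude_profile, label), phase_times, cycle_duration
        )
        if directions is not None and label in directions:
            d = np.asarray(directions[label], dtype=float)
        else:
            d = rng.standard_normal(3)
        d = d / np.linalg.norm(d)

        k = int(round(f * phases))
        signs = np.ones(phases)
        signs[:k] = -1.0
        f_actual = k / phases

        sel = regions == label
        values[:, sel, :] = (signs * m)[:, None, None] * d[None, None, :]

        tawss = float(m.mean())
        osi = 0.5 * (1.0 - abs(float((signs * m).sum())) / float(m.sum()))
        region_truth[int(label)] = {
            "reversal_fraction": f_actual,
            "tawss": tawss,
            "osi": osi,
            "direction": d,
        }
        osi_true[sel] = osi
        tawss_true[sel] = tawss

    field = TimeSeriesVectorField(
        mesh, values, phase_times, cycle_duration=cycle_duration, units="Pa"
    )
    truth = SyntheticTruth(
        generator="make_pulsatile_wss_series",
        parameters={"phases": phases, "cycle_duration": cycle_duration},
        seed=seed,
        targets={
            "regions": region_truth,
            "osi": osi_true,
            "tawss": tawss_true,
        },
    )
    return field, truth
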