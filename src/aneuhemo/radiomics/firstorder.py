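"""First-order (histogram) features on raw ROI intensities."""

from __future__ import annotations

import numpy as np

__all__ = ["first_order"]


def first_order(
    values: np.ndarray, voxel_volume: float, shift: float = 0.0
) -> dict[str, float]:
    """Mean, Minimum, RMS, Energy, Total Energy of the in-mask intensities.

    ``shift`` is the optional intensity offset c added inside the squares
    (Energy = sum (x + c)^2); the default is 0.
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty ROI")
    xs = x + shift
    energy = float(np.sum(xs * xs))
    return {
        "Mean": float(x.mean()),
        "Minimum": float(x.min()),
        "RMS": float(np.sqrt(np.mean(xs * xs))),
        "Energy": energy,
        "Total Energy": voxel_volume * energy,
    }
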