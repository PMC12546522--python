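"""Gray-level discretization of a masked image region."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..fields import LabeledImageVolume

__all__ = ["DiscretizedROI", "discretize"]


@dataclass
class DiscretizedROI:
    """Integer gray levels 1..Ng on a masked 3-D grid.

    ``levels`` is a full-shape int array with 0 outside the mask.
    """

    levels: np.ndarray
    mask: np.ndarray
    ng: int
    spacing: tuple[float, float, float]
    roi_name: str
    policy: dict

    def __post_init__(self) -> None:
        inmask = self.levels[self.mask]
        if inmask.size == 0:
            raise ValueError("empty ROI")
        if inmask.min() < 1 or inmask.max() > self.ng:
            raise ValueError("levels out of [1, Ng]")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def level_values(self) -> np.ndarray:
        """In-mask levels as a flat array."""
        return self.levels[self.mask]


def discretize(
    image: LabeledImageVolume,
    roi: str,
    policy: str = "fixed_bin_count",
    n_bins: int = 32,
    bin_width: float | None = None,
) -> DiscretizedROI:
    """Map ROI intensities to integer levels.

    fixed_bin_count: level = min(Ng, 1 + floor(Ng * (x - min) / range));
    a constant ROI maps to a single level with effective Ng = 1.
    fixed_bin_width: level = 1 + floor((x - min) / w).
    """
    mask = image.mask(roi)
    x = image.voxels[mask]
    levels = np.zeros(image.voxels.shape, dtype=np.int64)
    if policy == "fixed_bin_count":
        if n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        rng = x.max() - x.min()
        if rng == 0:
            lev = np.ones(x.shape, dtype=np.int64)
            ng = 1
        else:
            lev = np.minimum(
                n_bins, 1 + np.floor(n_bins * (x - x.min()) / rng).astype(np.int64)
            )
            ng = n_bins
        meta = {"policy": policy, "n_bins": n_bins, "ng_effective": int(lev.max())}
    elif policy == "fixed_bin_width":
        if bin_width is None or bin_width <= 0:
            raise ValueError("bin_width must be positive")
        lev = 1 + np.floor((x - x.min()) / bin_width).astype(np.int64)
        ng = int(lev.max())
        meta = {"policy": policy, "bin_width": bin_width, "ng_effective": ng}
    else:
        raise ValueError(f"unknown discretization policy {policy!r}")
    levels[mask] = lev
    return DiscretizedROI(
        levels=levels,
        mask=mask,
        ng=ng,
        spacing=image.spacing,
        roi_name=roi,
        policy=meta,
    )
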