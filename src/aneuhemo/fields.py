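"""Time-resolved vector fields and labeled image volumes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .meshes import SurfaceMesh, VolumeMesh

__all__ = ["TimeSeriesVectorField", "LabeledImageVolume"]


@dataclass
class TimeSeriesVectorField:
    """Per-point 3-vectors over the phases of one cardiac cycle.

    Parameters
    ----------
    mesh : SurfaceMesh or VolumeMesh
        Fixed geometry shared by all phases.
    values : (P, N, 3) float array
        One 3-vector per mesh point per phase.  Units: Pa for wall shear
        stress, m/s for velocity.
    phase_times : (P,) float array, seconds
        Strictly increasing sample times, all inside [0, cycle_duration).
    cycle_duration : float, seconds
    units : str
    """

    mesh: SurfaceMesh | VolumeMesh
    values: np.ndarray
    phase_times: np.ndarray
    cycle_duration: float = 1.0
    units: str = "Pa"

    def __post_init__(self) -> None:
        self.values = np.ascontiguousarray(self.values, dtype=float)
        self.phase_times = np.ascontiguousarray(self.phase_times, dtype=float)
        if self.values.ndim != 3 or self.values.shape[2] != 3:
            raise ValueError("values must be (P, N, 3)")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 phases")
        if self.values.shape[1] != self.mesh.n_points:
            raise ValueError(
                f"field has {self.values.shape[1]} points, mesh has "
                f"{self.mesh.n_points}"
            )
        if self.phase_times.shape != (self.values.shape[0],):
            raise ValueError("phase_times length must equal phase count")
        if (np.diff(self.phase_times) <= 0).any():
            raise ValueError("phase_times must be strictly increasing")
        if self.phase_times[0] < 0 or self.phase_times[-1] >= self.cycle_duration:
            raise ValueError("phase_times must lie in [0, cycle_duration)")

    @property
    def n_phases(self) -> int:
        return self.values.shape[0]

    @property
    def n_points(self) -> int:
        return self.values.shape[1]

    def check_finite(self) -> None:
        bad = ~np.isfinite(self.values)
        if bad.any():
            p, n, _ = np.argwhere(bad)[0]
            raise ValueError(f"non-finite vector at phase {p}, point {n}")

    def magnitudes(self) -> np.ndarray:
        """(P, N) vector magnitudes."""
        return np.linalg.norm(self.values, axis=2)


@dataclass
class LabeledImageVolume:
    """3-D grayscale volume with named binary ROI masks.

    ``spacing`` is mm per axis; masks must match the voxel array shape.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    masks: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.ascontiguousarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be three positive values")
        for name, m in list(self.masks.items()):
            m = np.ascontiguousarray(m, dtype=bool)
            if m.shape != self.voxels.shape:
                raise ValueError(f"mask {name!r} shape mismatch")
            self.masks[name] = m

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def mask(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(
                f"ROI {name!r} not present; available: {sorted(self.masks)}"
            )
        m = self.masks[name]
        if not m.any():
            raise ValueError(f"ROI {name!r} is empty")
        return m
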