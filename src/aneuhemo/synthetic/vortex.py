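"""Synthetic swirling-flow velocity series built from Gaussian rotation blobs.

Each blob is a rigid rotation enveloped by a Gaussian, giving smooth,
compact-support-like swirling structures whose expected vortex-core
locations and counts are known by construction:

    u_k(x, t) = omega_k * (a_k x (x - c_k(t))) * exp(-|x - c_k(t)|^2 / (2 sigma_k^2))
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..fields import TimeSeriesVectorField
from ..meshes import VolumeMesh
from .truth import SyntheticTruth

__all__ = ["VortexBlob", "make_vortex_velocity_series"]


@dataclass
class VortexBlob:
    """One Gaussian-enveloped rigid-rotation structure.

    ``center`` may be a single 3-vector (static blob) or a (P, 3) path.
    """

    center: np.ndarray
    sigma: float
    omega: float = 1.0
    axis: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        ax = np.asarray(self.axis, dtype=float)
        self.axis = tuple(ax / np.linalg.norm(ax))

    def centers(self, phases: int) -> np.ndarray:
        if self.center.ndim == 1:
            return np.broadcast_to(self.center, (phases, 3)).copy()
        if self.center.shape != (phases, 3):
            raise ValueError("center path must be (phases, 3)")
        return self.center

    def velocity(self, points: np.ndarray, center: np.ndarray) -> np.ndarray:
        r = points - center
        env = np.exp(-np.einsum("ij,ij->i", r, r) / (2.0 * self.sigma**2))
        swirl = self.omega * np.cross(np.asarray(self.axis), r)
        return swirl * env[:, None]


def make_vortex_velocity_series(
    mesh: VolumeMesh,
    vortices: list[VortexBlob],
    phases: int = 20,
    cycle_duration: float = 1.0,
    background: np.ndarray | None = None,
    seed: int | None = None,
) -> tuple[TimeSeriesVectorField, SyntheticTruth]:
    """Superpose blob velocities on the mesh points for every phase.

    The truth records each blob's center path and sigma, the expected core
    count per phase, and flags phases where any two blob supports (3 sigma)
    intersect — the expected count is then ambiguous.
    """
    if phases < 2:
        raise ValueError("need at least 2 phases")
    if not vortices:
        raise ValueError("need at least one vortex blob")
    pts = mesh.points
    values = np.zeros((phases, mesh.n_points, 3))
    paths = [b.centers(phases) for b in vortices]
    for blob, path in zip(vortices, paths):
        for p in range(phases):
            values[p] += blob.velocity(pts, path[p])
    if background is not None:
        values += np.asarray(background, dtype=float)

    ambiguous = np.zeros(phases, dtype=bool)
    for p in range(phases):
        for i in range(len(vortices)):
            for j in range(i + 1, len(vortices)):
                d = np.linalg.norm(paths[i][p] - paths[j][p])
                if d < 3.0 * (vortices[i].sigma + vortices[j].sigma):
                    ambiguous[p] = True

    phase_times = np.arange(phases) * (cycle_duration / phases)
    field = TimeSeriesVectorField(
        mesh, values, phase_times, cycle_duration=cycle_duration, units="m/s"
    )
    truth = SyntheticTruth(
        generator="make_vortex_velocity_series",
        parameters={"phases": phases, "cycle_duration": cycle_duration},
        seed=seed,
        targets={
            "n_blobs": len(vortices),
            "center_paths": np.stack(paths),
            "sigmas": [b.sigma for b in vortices],
            "omegas": [b.omega for b in vortices],
            "expected_noc": np.full(phases, len(vortices), dtype=np.int64),
            "ambiguous_phase": ambiguous,
        },
    )
    return field, truth
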