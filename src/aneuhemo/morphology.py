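"""Aneurysm sac morphometrics from a triangulated surface.

Height is the maximum signed distance of sac vertices from the neck plane;
width is the maximum caliper extent of the vertices projected onto the
plane orthogonal to the inflow direction; aspect ratio = height / width and
size ratio = height / parent-vessel diameter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .meshes import SurfaceMesh, triangle_areas

__all__ = [
    "MorphologyMetrics",
    "surface_area",
    "enclosed_volume",
    "sac_metrics",
    "size_ratio",
    "compute_morphology",
]


def surface_area(mesh: SurfaceMesh) -> float:
    """Total triangle area, mm^2.  Degenerate triangles contribute 0 (warned)."""
    areas = triangle_areas(mesh.points, mesh.triangles)
    n_bad = int((areas <= 0).sum())
    if n_bad:
        warnings.warn(f"{n_bad} degenerate triangles contribute zero area")
    return float(areas.sum())


def enclosed_volume(mesh: SurfaceMesh) -> float:
    """Enclosed volume of a closed, consistently oriented surface, mm^3.

    Divergence-theorem sum of signed origin-tetrahedra; the result is
    origin-independent and returned as an absolute value, so either global
    orientation is accepted.
    """
    n_boundary = mesh.boundary_edge_count()
    if n_boundary:
        raise ValueError(f"surface is open: {n_boundary} boundary edges")
    if not mesh.is_consistently_oriented():
        raise ValueError("surface orientation is inconsistent")
    p = mesh.points[mesh.triangles]
    signed = np.einsum("ij,ij->i", np.cross(p[:, 0], p[:, 1]), p[:, 2]) / 6.0
    return float(abs(signed.sum()))


def _projected_diameter(points: np.ndarray, direction: np.ndarray) -> float:
    """Maximum pairwise distance after projecting out ``direction``."""
    d = direction / np.linalg.norm(direction)
    # orthonormal basis of the plane perpendicular to d
    helper = np.array([1.0, 0.0, 0.0])
    if abs(d @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(d, helper)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(d, e1)
    proj = np.stack([points @ e1, points @ e2], axis=1)
    try:
        hull_pts = proj[ConvexHull(proj).vertices]
    except QhullError:  # collinear projections
        hull_pts = proj
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    return float(np.sqrt((diff**2).sum(axis=2)).max())


def sac_metrics(
    sac: SurfaceMesh,
    neck_point: np.ndarray,
    neck_normal: np.ndarray,
    inflow_direction: np.ndarray,
    below_tolerance: float = 1e-6,
) -> tuple[float, float, float]:
    """(height, width, aspect_ratio) for a sac above the neck plane.

    The neck normal must point toward the dome.  Vertices more than
    ``below_tolerance`` times the height below the plane are rejected.
    """
    neck_point = np.asarray(neck_point, float)
    n = np.asarray(neck_normal, float)
    n = n / np.linalg.norm(n)
    signed = (sac.points - neck_point) @ n
    height = float(signed.max())
    if height <= 0:
        raise ValueError("all sac vertices lie on or below the neck plane")
    if signed.min() < -max(below_tolerance * height, 1e-9):
        raise ValueError(
            f"sac vertices extend {-signed.min():.3g} mm below the neck plane"
        )
    width = _projected_diameter(sac.points, np.asarray(inflow_direction, float))
    return height, width, height / width


def size_ratio(height: float, parent_diameter: float) -> float:
    """Sac height over parent-vessel diameter."""
    if parent_diameter <= 0:
        raise ValueError("parent diameter must be positive")
    return height / parent_diameter


@dataclass
class MorphologyMetrics:
    volume: float
    surface_area: float
    height: float
    width: float
    aspect_ratio: float
    parent_diameter: float
    size_ratio: float

    def as_dict(self) -> dict:
        return {
            "volume": self.volume,
            "surface_area": self.surface_area,
            "height": self.height,
            "width": self.width,
            "aspect_ratio": self.aspect_ratio,
            "parent_diameter": self.parent_diameter,
            "size_ratio": self.size_ratio,
        }


def compute_morphology(
    sac: SurfaceMesh,
    neck_point,
    neck_normal,
    inflow_direction,
    parent_diameter: float,
) -> MorphologyMetrics:
    """All six morphometrics for a closed sac surface."""
    height, width, ar = sac_metrics(sac, neck_point, neck_normal, inflow_direction)
    return MorphologyMetrics(
        volume=enclosed_volume(sac),
        surface_area=surface_area(sac),
        height=height,
        width=width,
        aspect_ratio=ar,
        parent_diameter=float(parent_diameter),
        size_ratio=size_ratio(height, parent_diameter),
    )
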