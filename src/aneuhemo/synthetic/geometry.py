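"""Analytic test geometries: icospheres and tetrahedralized balls."""

from __future__ import annotations

import math

import numpy as np
from scipy.spatial import Delaunay

from ..meshes import SurfaceMesh, VolumeMesh

__all__ = ["make_sphere_surface", "make_tet_ball", "icosahedron"]


def icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Unit icosahedron (12 vertices, 20 outward-oriented triangles)."""
    phi = (1.0 + math.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ],
        dtype=np.int64,
    )
    return verts, faces


def make_sphere_surface(radius: float, subdivisions: int = 3) -> SurfaceMesh:
    """Closed icosphere by repeated edge-midpoint subdivision.

    Area and enclosed volume converge to 4*pi*r^2 and 4/3*pi*r^3 as
    ``subdivisions`` grows (within 0.5% at subdivision 4).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    verts, faces = icosahedron()
    verts = [v for v in verts]
    midpoint_cache: dict[tuple[int, int], int] = {}

    def midpoint(i: int, j: int) -> int:
        key = (min(i, j), max(i, j))
        if key in midpoint_cache:
            return midpoint_cache[key]
        m = verts[i] + verts[j]
        m /= np.linalg.norm(m)
        verts.append(m)
        idx = len(verts) - 1
        midpoint_cache[key] = idx
        return idx

    for _ in range(subdivisions):
        new_faces = []
        for a, b, c in faces:
            ab = midpoint(a, b)
            bc = midpoint(b, c)
            ca = midpoint(c, a)
            new_faces += [[a, ab, ca], [b, bc, ab], [c, ca, bc], [ab, bc, ca]]
        faces = np.array(new_faces, dtype=np.int64)

    points = np.array(verts) * radius
    mesh = SurfaceMesh(points, faces)
    mesh.validate()
    return mesh


def make_tet_ball(radius: float, target_edge: float) -> VolumeMesh:
    """Tetrahedralize a ball of given radius.

    Interior points come from a cubic grid at ``target_edge`` spacing; the
    boundary is sampled with icosphere vertices at a comparable edge length,
    and the point cloud is Delaunay-tetrahedralized.  Total volume is within
    2% of 4/3*pi*r^3 once ``target_edge <= radius / 8``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if not 0 < target_edge < radius:
        raise ValueError("require 0 < target_edge < radius")

    h = target_edge
    n = int(math.floor(radius / h))
    axis = np.arange(-n, n + 1) * h
    gx, gy, gz = np.meshgrid(axis, axis, axis, indexing="ij")
    grid = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    # keep interior points clear of the surface shell
    inside = np.linalg.norm(grid, axis=1) <= radius - 0.5 * h
    interior = grid[inside]

    # icosphere edge length is ~1.05 r / 2^s; pick s so it matches target_edge
    subdiv = max(0, math.ceil(math.log2(max(1.05 * radius / h, 1.0))))
    shell = make_sphere_surface(radius, subdivisions=subdiv).points

    pts = np.vstack([interior, shell])
    tri = Delaunay(pts, qhull_options="QJ")
    mesh = VolumeMesh(tri.points, tri.simplices)

    # Joggled Delaunay can emit slivers of (numerically) zero volume.
    vols = mesh.cell_volumes()
    tol = 1e-12 * radius**3
    keep = vols > tol
    mesh = VolumeMesh(mesh.points, mesh.tets[keep])
    mesh.validate()
    return mesh
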