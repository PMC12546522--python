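"""Triangulated surface and tetrahedral volume meshes.

Geometry lives in millimetres throughout the package.  Both mesh types are
plain frozen containers over NumPy arrays plus the derived quantities the
downstream metrics need (lumped point areas, signed cell volumes, face
adjacency).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "SurfaceMesh",
    "VolumeMesh",
    "triangle_areas",
    "triangle_normals",
]


def triangle_areas(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Per-triangle areas from the cross-product formula."""
    p = points[triangles]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(cross, axis=1)


def triangle_normals(points: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Unit normals (right-hand rule); zero vector for degenerate triangles."""
    p = points[triangles]
    cross = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    norm = np.linalg.norm(cross, axis=1)
    out = np.zeros_like(cross)
    ok = norm > 0
    out[ok] = cross[ok] / norm[ok, None]
    return out


@dataclass
class SurfaceMesh:
    """Triangulated surface.

    Parameters
    ----------
    points : (N, 3) float array, mm
    triangles : (M, 3) int array of vertex indices
    """

    points: np.ndarray
    triangles: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValueError("triangles must be (M, 3)")
        if self.triangles.size and (
            self.triangles.min() < 0 or self.triangles.max() >= len(self.points)
        ):
            raise ValueError("triangle indices out of range")

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_areas(self) -> np.ndarray:
        return triangle_areas(self.points, self.triangles)

    def point_areas(self) -> np.ndarray:
        """Lumped (one-third-of-triangle) areas per vertex, mm^2."""
        areas = self.triangle_areas()
        out = np.zeros(self.n_points)
        np.add.at(out, self.triangles.ravel(), np.repeat(areas / 3.0, 3))
        return out

    def area(self) -> float:
        return float(self.triangle_areas().sum())

    def boundary_edge_count(self) -> int:
        """Number of edges used by exactly one triangle (0 for a closed mesh)."""
        edges = self._undirected_edges()
        _, counts = np.unique(edges, axis=0, return_counts=True)
        return int((counts == 1).sum())

    def is_closed(self) -> bool:
        return self.boundary_edge_count() == 0

    def is_consistently_oriented(self) -> bool:
        """Each interior edge must be traversed once in each direction."""
        tri = self.triangles
        directed = np.concatenate(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]], axis=0
        )
        _, counts = np.unique(directed, axis=0, return_counts=True)
        return bool((counts == 1).all())

    def _undirected_edges(self) -> np.ndarray:
        tri = self.triangles
        edges = np.concatenate(
            [tri[:, [0, 1]], tri[:, [1, 2]], tri[:, [2, 0]]], axis=0
        )
        return np.sort(edges, axis=1)

    def validate(self) -> None:
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite point coordinates")
        if (self.triangle_areas() <= 0).any():
            bad = np.flatnonzero(self.triangle_areas() <= 0)
            raise ValueError(f"degenerate triangles: {bad[:10].tolist()}")


@dataclass
class VolumeMesh:
    """Tetrahedral volume mesh.

    Cell orientation is normalized on construction so every signed volume is
    positive.
    """

    points: np.ndarray
    tets: np.ndarray
    _adjacency_cache: object = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=float)
        self.tets = np.ascontiguousarray(self.tets, dtype=np.int64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be (N, 3)")
        if self.tets.ndim != 2 or self.tets.shape[1] != 4:
            raise ValueError("tets must be (M, 4)")
        if self.tets.size and (
            self.tets.min() < 0 or self.tets.max() >= len(self.points)
        ):
            raise ValueError("tet indices out of range")
        self._fix_orientation()

    def _signed_volumes(self) -> np.ndarray:
        p = self.points[self.tets]
        a = p[:, 1] - p[:, 0]
        b = p[:, 2] - p[:, 0]
        c = p[:, 3] - p[:, 0]
        return np.einsum("ij,ij->i", np.cross(a, b), c) / 6.0

    def _fix_orientation(self) -> None:
        sv = self._signed_volumes()
        flip = sv < 0
        if flip.any():
            self.tets[flip] = self.tets[flip][:, [0, 1, 3, 2]]

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_cells(self) -> int:
        return len(self.tets)

    def cell_volumes(self) -> np.ndarray:
        return self._signed_volumes()

    def total_volume(self) -> float:
        return float(self.cell_volumes().sum())

    def cell_centroids(self) -> np.ndarray:
        return self.points[self.tets].mean(axis=1)

    def validate(self) -> None:
        if not np.isfinite(self.points).all():
            raise ValueError("non-finite point coordinates")
        vols = self.cell_volumes()
        if (vols <= 0).any():
            bad = np.flatnonzero(vols <= 0)
            raise ValueError(f"degenerate/inverted tets: {bad[:10].tolist()}")

    def face_adjacency(self):
        """Sparse symmetric cell-cell adjacency over shared triangular faces."""
        if self._adjacency_cache is not None:
            return self._adjacency_cache
        faces_per_tet = np.array(
            [[0, 1, 2], [0, 1, 3], [0, 2, 3], [1, 2, 3]], dtype=np.int64
        )
        faces = self.tets[:, faces_per_tet].reshape(-1, 3)
        faces = np.sort(faces, axis=1)
        owner = np.repeat(np.arange(self.n_cells), 4)
        order = np.lexsort(faces.T)
        faces_sorted = faces[order]
        owner_sorted = owner[order]
        same = (faces_sorted[1:] == faces_sorted[:-1]).all(axis=1)
        i = owner_sorted[:-1][same]
        j = owner_sorted[1:][same]
        n = self.n_cells
        adj = coo_matrix(
            (np.ones(2 * len(i), dtype=np.int8), (np.r_[i, j], np.r_[j, i])),
            shape=(n, n),
        ).tocsr()
        self._adjacency_cache = adj
        return adj

    def connected_components(self, cell_mask: np.ndarray) -> tuple[int, np.ndarray]:
        """Connected components of the masked cells under shared-face adjacency.

        Returns (n_components, labels) where labels is -1 outside the mask.
        """
        cell_mask = np.asarray(cell_mask, dtype=bool)
        if cell_mask.shape != (self.n_cells,):
            raise ValueError("mask shape mismatch")
        idx = np.flatnonzero(cell_mask)
        labels = np.full(self.n_cells, -1, dtype=np.int64)
        if len(idx) == 0:
            return 0, labels
        sub = self.face_adjacency()[idx][:, idx]
        n_comp, sub_labels = connected_components(sub, directed=False)
        labels[idx] = sub_labels
        return int(n_comp), labels
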