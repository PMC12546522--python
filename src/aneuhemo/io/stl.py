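"""ASCII STL read/write with exact vertex welding on read."""

from __future__ import annotations

import numpy as np

from ..meshes import SurfaceMesh, triangle_normals

__all__ = ["write_stl", "read_stl"]

_FMT = "%.17g"


def write_stl(path, mesh: SurfaceMesh, name: str = "aneuhemo") -> None:
    normals = triangle_normals(mesh.points, mesh.triangles)
    with open(path, "w") as fh:
        fh.write(f"solid {name}\n")
        for tri, n in zip(mesh.triangles, normals):
            fh.write(
                f"  facet normal {_FMT % n[0]} {_FMT % n[1]} {_FMT % n[2]}\n"
                "    outer loop\n"
            )
            for v in mesh.points[tri]:
                fh.write(f"      vertex {_FMT % v[0]} {_FMT % v[1]} {_FMT % v[2]}\n")
            fh.write("    endloop\n  endfacet\n")
        fh.write(f"endsolid {name}\n")


def read_stl(path) -> SurfaceMesh:
    verts = []
    with open(path) as fh:
        first = fh.readline()
        if not first.lstrip().startswith("solid"):
            raise ValueError(f"{path}: only ASCII STL is supported")
        for line in fh:
            parts = line.split()
            if parts and parts[0] == "vertex":
                verts.append([float(parts[1]), float(parts[2]), float(parts[3])])
    if not verts or len(verts) % 3:
        raise ValueError(f"{path}: malformed STL ({len(verts)} vertices)")
    raw = np.asarray(verts)
    points, inverse = np.unique(raw, axis=0, return_inverse=True)
    triangles = inverse.reshape(-1, 3)
    return SurfaceMesh(points, triangles)
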