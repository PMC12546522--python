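"""Minimal legacy-VTK ASCII reader/writer (polydata and tet grids).

Only the subset this package emits is supported: POINTS, POLYGONS (all
triangles), CELLS/CELL_TYPES (all tets), and POINT_DATA/CELL_DATA sections
holding SCALARS or VECTORS in double precision.  Values are written with
17 significant digits so write-then-read round trips at machine precision.
"""

from __future__ import annotations

import numpy as np

from ..meshes import SurfaceMesh, VolumeMesh

__all__ = [
    "write_polydata",
    "read_polydata",
    "write_unstructured_grid",
    "read_unstructured_grid",
]

_FMT = "%.17g"


def _write_array_block(fh, name: str, data: np.ndarray) -> None:
    data = np.asarray(data)
    if data.ndim == 2 and data.shape[1] == 3:
        fh.write(f"VECTORS {name} double\n")
        np.savetxt(fh, data, fmt=_FMT)
    elif data.ndim == 1:
        if data.dtype == bool or np.issubdtype(data.dtype, np.integer):
            fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, data.astype(np.int64), fmt="%d")
        else:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, data, fmt=_FMT)
    else:
        raise ValueError(f"unsupported array shape {data.shape} for {name!r}")


def write_polydata(
    path,
    mesh: SurfaceMesh,
    point_data: dict[str, np.ndarray] | None = None,
    title: str = "aneuhemo surface",
) -> None:
    with open(path, "w") as fh:
        fh.write(f"# vtk DataFile Version 3.0\n{title}\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_points} double\n")
        np.savetxt(fh, mesh.points, fmt=_FMT)
        m = mesh.n_triangles
        fh.write(f"POLYGONS {m} {4 * m}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(m, 3, dtype=np.int64), mesh.triangles]),
            fmt="%d",
        )
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_points}\n")
            for name, data in point_data.items():
                _write_array_block(fh, name, data)


def write_unstructured_grid(
    path,
    mesh: VolumeMesh,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "aneuhemo volume",
) -> None:
    with open(path, "w") as fh:
        fh.write(
            f"# vtk DataFile Version 3.0\n{title}\nASCII\nDATASET UNSTRUCTURED_GRID\n"
        )
        fh.write(f"POINTS {mesh.n_points} double\n")
        np.savetxt(fh, mesh.points, fmt=_FMT)
        m = mesh.n_cells
        fh.write(f"CELLS {m} {5 * m}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(m, 4, dtype=np.int64), mesh.tets]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {m}\n")
        np.savetxt(fh, np.full(m, 10, dtype=np.int64), fmt="%d")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_points}\n")
            for name, data in point_data.items():
                _write_array_block(fh, name, data)
        if cell_data:
            fh.write(f"CELL_DATA {m}\n")
            for name, data in cell_data.items():
                _write_array_block(fh, name, data)


class _Tokens:
    def __init__(self, path):
        with open(path) as fh:
            lines = fh.readlines()
        if len(lines) < 4 or not lines[0].startswith("# vtk DataFile"):
            raise ValueError(f"{path}: not a legacy VTK file")
        if lines[2].strip().upper() != "ASCII":
            raise ValueError(f"{path}: only ASCII legacy VTK is supported")
        self.tokens = " ".join(lines[3:]).split()
        self.pos = 0

    def next(self) -> str:
        tok = self.tokens[self.pos]
        self.pos += 1
        return tok

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def floats(self, n: int) -> np.ndarray:
        out = np.array(self.tokens[self.pos : self.pos + n], dtype=float)
        if len(out) != n:
            raise ValueError("truncated VTK file")
        self.pos += n
        return out

    def ints(self, n: int) -> np.ndarray:
        out = np.array(self.tokens[self.pos : self.pos + n], dtype=np.int64)
        if len(out) != n:
            raise ValueError("truncated VTK file")
        self.pos += n
        return out


def _read_data_section(tk: _Tokens, n: int) -> dict[str, np.ndarray]:
    data = {}
    while tk.peek() is not None and tk.peek().upper() in ("SCALARS", "VECTORS"):
        kind = tk.next().upper()
        name = tk.next()
        dtype = tk.next()
        if kind == "SCALARS":
            ncomp = 1
            if tk.peek() is not None and tk.peek().isdigit():
                ncomp = int(tk.next())
            if ncomp != 1:
                raise ValueError("only 1-component scalars supported")
            if tk.peek() is not None and tk.peek().upper() == "LOOKUP_TABLE":
                tk.next()
                tk.next()
            vals = tk.floats(n)
            data[name] = (
                vals.astype(np.int64) if dtype.lower() in ("int", "long") else vals
            )
        else:
            data[name] = tk.floats(3 * n).reshape(n, 3)
    return data


def read_polydata(path) -> tuple[SurfaceMesh, dict[str, np.ndarray]]:
    tk = _Tokens(path)
    if tk.next().upper() != "DATASET" or tk.next().upper() != "POLYDATA":
        raise ValueError(f"{path}: expected DATASET POLYDATA")
    point_data: dict[str, np.ndarray] = {}
    points = triangles = None
    while tk.peek() is not None:
        section = tk.next().upper()
        if section == "POINTS":
            n = int(tk.next())
            tk.next()  # dtype
            points = tk.floats(3 * n).reshape(n, 3)
        elif section == "POLYGONS":
            m = int(tk.next())
            size = int(tk.next())
            raw = tk.ints(size)
            if not (raw.reshape(m, -1)[:, 0] == 3).all():
                raise ValueError("only triangle polygons supported")
            triangles = raw.reshape(m, 4)[:, 1:]
        elif section == "POINT_DATA":
            n = int(tk.next())
            point_data = _read_data_section(tk, n)
        else:
            raise ValueError(f"{path}: unsupported section {section}")
    if points is None or triangles is None:
        raise ValueError(f"{path}: missing POINTS or POLYGONS")
    return SurfaceMesh(points, triangles), point_data


def read_unstructured_grid(
    path,
) -> tuple[VolumeMesh, dict[str, np.ndarray], dict[str, np.ndarray]]:
    tk = _Tokens(path)
    if tk.next().upper() != "DATASET" or tk.next().upper() != "UNSTRUCTURED_GRID":
        raise ValueError(f"{path}: expected DATASET UNSTRUCTURED_GRID")
    points = tets = None
    point_data: dict[str, np.ndarray] = {}
    cell_data: dict[str, np.ndarray] = {}
    n_cells = 0
    while tk.peek() is not None:
        section = tk.next().upper()
        if section == "POINTS":
            n = int(tk.next())
            tk.next()
            points = tk.floats(3 * n).reshape(n, 3)
        elif section == "CELLS":
            n_cells = int(tk.next())
            size = int(tk.next())
            raw = tk.ints(size)
            if not (raw.reshape(n_cells, -1)[:, 0] == 4).all():
                raise ValueError("only tetrahedral cells supported")
            tets = raw.reshape(n_cells, 5)[:, 1:]
        elif section == "CELL_TYPES":
            m = int(tk.next())
            types = tk.ints(m)
            if not (types == 10).all():
                raise ValueError("only VTK_TETRA cells supported")
        elif section == "POINT_DATA":
            n = int(tk.next())
            point_data = _read_data_section(tk, n)
        elif section == "CELL_DATA":
            m = int(tk.next())
            cell_data = _read_data_section(tk, m)
        else:
            raise ValueError(f"{path}: unsupported section {section}")
    if points is None or tets is None:
        raise ValueError(f"{path}: missing POINTS or CELLS")
    return VolumeMesh(points, tets), point_data, cell_data
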