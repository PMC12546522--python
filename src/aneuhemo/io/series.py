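"""Time-series field storage: a directory with a JSON index, one mesh file,
and either per-phase VTK files or a single long-format CSV."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from ..fields import TimeSeriesVectorField
from ..meshes import SurfaceMesh, VolumeMesh
from .vtk import (
    read_polydata,
    read_unstructured_grid,
    write_polydata,
    write_unstructured_grid,
)

__all__ = ["write_field_series", "read_field_series"]

INDEX_NAME = "series.json"


def write_field_series(
    directory,
    field: TimeSeriesVectorField,
    array_name: str = "vectors",
    fmt: str = "vtk",
) -> Path:
    """Write ``field`` under ``directory`` and return the index path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    is_surface = isinstance(field.mesh, SurfaceMesh)
    mesh_file = "mesh.vtk"
    if is_surface:
        write_polydata(directory / mesh_file, field.mesh)
    else:
        write_unstructured_grid(directory / mesh_file, field.mesh)

    index = {
        "format": fmt,
        "kind": "surface" if is_surface else "volume",
        "mesh": mesh_file,
        "array_name": array_name,
        "phase_times": field.phase_times.tolist(),
        "cycle_duration": field.cycle_duration,
        "units": field.units,
        "n_points": field.n_points,
    }
    if fmt == "vtk":
        phase_files = []
        for p in range(field.n_phases):
            fname = f"phase_{p:03d}.vtk"
            data = {array_name: field.values[p]}
            if is_surface:
                write_polydata(directory / fname, field.mesh, point_data=data)
            else:
                write_unstructured_grid(directory / fname, field.mesh, point_data=data)
            phase_files.append(fname)
        index["phases"] = phase_files
    elif fmt == "csv":
        P, N, _ = field.values.shape
        df = pd.DataFrame(
            {
                "point_id": np.tile(np.arange(N), P),
                "phase": np.repeat(np.arange(P), N),
                "vx": field.values[:, :, 0].ravel(),
                "vy": field.values[:, :, 1].ravel(),
                "vz": field.values[:, :, 2].ravel(),
            }
        )
        df.to_csv(directory / "values.csv", index=False, float_format="%.17g")
        index["values"] = "values.csv"
        index["n_phases"] = P
    else:
        raise ValueError(f"unknown series format {fmt!r}")

    path = directory / INDEX_NAME
    with open(path, "w") as fh:
        json.dump(index, fh, indent=2, sort_keys=True)
    return path


def read_field_series(directory) -> TimeSeriesVectorField:
    """Load a series written by :func:`write_field_series`, validating
    per-phase mesh topology along the way."""
    directory = Path(directory)
    index_path = directory / INDEX_NAME
    if not index_path.exists():
        raise FileNotFoundError(f"no {INDEX_NAME} in {directory}")
    with open(index_path) as fh:
        index = json.load(fh)

    is_surface = index["kind"] == "surface"
    if is_surface:
        mesh, _ = read_polydata(directory / index["mesh"])
    else:
        mesh, _, _ = read_unstructured_grid(directory / index["mesh"])

    name = index["array_name"]
    phase_times = np.asarray(index["phase_times"], dtype=float)
    if index["format"] == "vtk":
        values = []
        for p, fname in enumerate(index["phases"]):
            fpath = directory / fname
            if not fpath.exists():
                raise FileNotFoundError(f"missing phase file {fname}")
            if is_surface:
                pmesh, pdata = read_polydata(fpath)
            else:
                pmesh, pdata, _ = read_unstructured_grid(fpath)
            if pmesh.n_points != mesh.n_points or not np.array_equal(
                pmesh.points, mesh.points
            ):
                raise ValueError(f"phase {p} mesh topology differs from {index['mesh']}")
            if name not in pdata:
                raise KeyError(f"phase file {fname} lacks array {name!r}")
            values.append(pdata[name])
        values = np.stack(values)
    elif index["format"] == "csv":
        df = pd.read_csv(directory / index["values"], float_precision="round_trip")
        P = int(index["n_phases"])
        N = int(index["n_points"])
        if len(df) != P * N:
            raise ValueError("values.csv row count does not match index")
        df = df.sort_values(["phase", "point_id"])
        values = df[["vx", "vy", "vz"]].to_numpy().reshape(P, N, 3)
    else:
        raise ValueError(f"unknown series format {index['format']!r}")

    return TimeSeriesVectorField(
        mesh,
        values,
        phase_times,
        cycle_duration=float(index["cycle_duration"]),
        units=index.get("units", ""),
    )
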