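"""Reading and writing the package's on-disk formats.

Centerlines travel as plain CSV (columns ``x,y,z`` in mm) or VTK-legacy
ASCII polyline files; meshes as PLY/STL/OFF through trimesh; cohorts and
metric tables as CSV through pandas.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import trimesh

from .curves import SampledCurve

PathLike = Union[str, Path]

__all__ = [
    "write_curve_csv",
    "read_curve_csv",
    "write_curve_vtk",
    "read_curve_vtk",
    "write_mesh",
    "read_mesh",
    "write_cohort_csv",
    "read_cohort_csv",
]


def write_curve_csv(curve: SampledCurve, path: PathLike) -> None:
    df = pd.DataFrame(curve.points, columns=["x", "y", "z"])
    df.to_csv(path, index=False)


def read_curve_csv(path: PathLike) -> SampledCurve:
    df = pd.read_csv(path)
    missing = {"x", "y", "z"} - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV lacks columns: {sorted(missing)}")
    return SampledCurve(df[["x", "y", "z"]].to_numpy(dtype=float))


def write_curve_vtk(curve: SampledCurve, path: PathLike) -> None:
    """Write a VTK-legacy ASCII POLYDATA file holding one polyline."""
    pts = curve.points
    n = len(pts)
    lines = [
        "# vtk DataFile Version 3.0",
        "vessel centerline",
        "ASCII",
        "DATASET POLYDATA",
        f"POINTS {n} double",
    ]
    lines += [f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}" for p in pts]
    lines.append(f"LINES 1 {n + 1}")
    lines.append(" ".join([str(n)] + [str(i) for i in range(n)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_curve_vtk(path: PathLike) -> SampledCurve:
    """Read the single polyline from a VTK-legacy ASCII POLYDATA file."""
    tokens = Path(path).read_text().split("\n")
    it = iter(tokens)
    pts = None
    order = None
    for line in it:
        fields = line.split()
        if not fields:
            continue
        if fields[0] == "POINTS":
            n = int(fields[1])
            flat: list[float] = []
            while len(flat) < 3 * n:
                flat.extend(float(v) for v in next(it).split())
            pts = np.asarray(flat, dtype=float).reshape(n, 3)
        elif fields[0] == "LINES":
            rec = [int(v) for v in next(it).split()]
            order = rec[1 : 1 + rec[0]]
    if pts is None:
        raise ValueError(f"{path}: no POINTS section found")
    if order is not None:
        pts = pts[order]
    return SampledCurve(pts)


def write_mesh(mesh, path: PathLike, ascii: bool = False) -> None:
    """Write a tube mesh as PLY/STL/OFF (format chosen by extension)."""
    tm = mesh.to_trimesh() if hasattr(mesh, "to_trimesh") else mesh
    path = Path(path)
    suffix = path.suffix.lower().lstrip(".")
    if suffix == "ply":
        data = trimesh.exchange.ply.export_ply(
            tm, encoding="ascii" if ascii else "binary"
        )
    elif suffix == "stl":
        if ascii:
            data = trimesh.exchange.stl.export_stl_ascii(tm).encode()
        else:
            data = trimesh.exchange.stl.export_stl(tm)
    elif suffix == "off":
        data = tm.export(file_type="off")
        if isinstance(data, str):
            data = data.encode()
    else:
        raise ValueError(f"unsupported mesh format: .{suffix}")
    path.write_bytes(data)


def read_mesh(path: PathLike) -> trimesh.Trimesh:
    tm = trimesh.load(str(path), force="mesh", process=False)
    if not isinstance(tm, trimesh.Trimesh):
        raise ValueError(f"{path} did not contain a triangle mesh")
    return tm


def write_cohort_csv(cohort: pd.DataFrame, path: PathLike) -> None:
    for col in ("iss", "co"):
        if col not in cohort.columns:
            raise ValueError(f"cohort table must carry a {col!r} column")
    cohort.to_csv(path, index=False)


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("iss", "co"):
        if col not in df.columns:
            raise ValueError(f"cohort CSV must carry a {col!r} column")
        vals = set(df[col].unique())
        if not vals <= {0, 1}:
            raise ValueError(f"{col!r} must be binary 0/1, found {sorted(vals)}")
    return df
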