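"""File formats: STL/PLY meshes, landmark JSON, distance-table CSV.

Meshes are read through trimesh (``process=False`` so vertex order and
coordinates are preserved).  ASCII PLY is written by a small local writer
using shortest-round-trip float formatting, so a save/load cycle reproduces
the float64 coordinates bit-exactly; STL and binary PLY go through trimesh.
Per-vertex component labels, which neither STL nor PLY carries portably, are
persisted in a ``<name>.labels.json`` sidecar and re-attached on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .anatomy import LandmarkSet
from .geometry import SurfaceMesh
from .registration import DistanceTable

__all__ = [
    "load_mesh",
    "save_mesh",
    "read_landmarks",
    "write_landmarks",
    "write_distance_table",
    "read_distance_table",
    "write_selection",
]


def _labels_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.json")


def load_mesh(path) -> SurfaceMesh:
    """Read an STL or PLY mesh (mm), preserving vertex order and labels."""
    path = Path(path)
    tm = trimesh.load_mesh(path, process=False)
    mesh = SurfaceMesh(
        np.asarray(tm.vertices, dtype=np.float64), np.asarray(tm.faces, dtype=np.int64)
    )
    sidecar = _labels_path(path)
    if sidecar.exists():
        labels = np.asarray(json.loads(sidecar.read_text())["labels"])
        if labels.shape == (mesh.n_vertices,):
            mesh.vertex_labels = labels
    return mesh


def save_mesh(mesh: SurfaceMesh, path, binary: bool = False) -> None:
    """Write STL (via trimesh) or PLY (ASCII by default, bit-exact floats)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".ply" and not binary:
        _write_ply_ascii(mesh, path)
    else:
        tm = trimesh.Trimesh(mesh.vertices, mesh.faces, process=False)
        path.write_bytes(tm.export(file_type=suffix.lstrip(".")))
    if mesh.vertex_labels is not None:
        _labels_path(path).write_text(
            json.dumps({"labels": [str(x) for x in mesh.vertex_labels]})
        )


def _write_ply_ascii(mesh: SurfaceMesh, path: Path) -> None:
    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {mesh.n_vertices}",
        "property double x",
        "property double y",
        "property double z",
        f"element face {mesh.n_faces}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    for v in mesh.vertices:
        lines.append(f"{float(v[0])!r} {float(v[1])!r} {float(v[2])!r}")
    for f in mesh.faces:
        lines.append(f"3 {f[0]} {f[1]} {f[2]}")
    path.write_text("\n".join(lines) + "\n")


def read_landmarks(path) -> LandmarkSet:
    """Landmark JSON: {"side": ..., "units": "mm", "landmarks": {name: [x,y,z]}}.

    Unknown landmark names are preserved; missing required names raise with
    the offending names listed (via :class:`LandmarkSet` validation).
    """
    data = json.loads(Path(path).read_text())
    units = data.get("units", "mm")
    if units != "mm":
        raise ValueError(f"landmark file units must be 'mm', got {units!r}")
    if "landmarks" not in data:
        raise ValueError("landmark file missing 'landmarks' object")
    return LandmarkSet(dict(data["landmarks"]), data.get("side", "right"))


def write_landmarks(lm: LandmarkSet, path) -> None:
    payload = {
        "side": lm.side,
        "units": "mm",
        "landmarks": {k: [float(x) for x in v] for k, v in lm.points.items()},
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_distance_table(table: DistanceTable, path) -> None:
    """CSV: comma, dot decimal, header row, LF newlines; provenance sidecar."""
    path = Path(path)
    table.rows.to_csv(path, index=False, lineterminator="\n")
    if table.provenance or table.failures:
        meta = {"provenance": table.provenance, "failures": table.failures}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta, indent=2) + "\n")


def read_distance_table(path) -> DistanceTable:
    path = Path(path)
    rows = pd.read_csv(path)
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    provenance, failures = {}, []
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        provenance = meta.get("provenance", {})
        failures = [tuple(f) for f in meta.get("failures", [])]
    return DistanceTable(rows, provenance, failures)


def write_selection(selection, path, config_hash: str = "") -> None:
    """Selection JSON: one entry per model with (axis, theta, crossing, flag)."""
    entries = [
        {
            "axis": m.plan.axis.label,
            "theta_deg": float(m.plan.theta),
            "crossing_pct": float(res.crossing_pct),
            "acceptable": bool(res.acceptable),
        }
        for m, res in selection
    ]
    Path(path).write_text(
        json.dumps({"config_hash": config_hash, "selection": entries}, indent=2) + "\n"
    )
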