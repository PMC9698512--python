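"""Mesh and landmark file I/O, plus serialization of fitted artifacts.

Formats: STL (ASCII and binary), OBJ, PLY (ascii). Landmarks are CSV
(``name,x,y,z`` header required) or JSON (list of objects with those keys).
All coordinates are millimetres; no unit metadata is read from files.

Binary STL stores float32 coordinates, so a binary round trip quantizes to
~1e-7 relative; ASCII STL, OBJ and PLY round-trip at full float precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import (
    HomologousModel,
    LandmarkSchemeError,
    LandmarkSet,
    MeshInvariantError,
    Scheme,
    TriangleMesh,
)

__all__ = [
    "MeshFormatError",
    "read_mesh",
    "write_mesh",
    "read_landmarks",
    "write_landmarks",
    "save_homologous_model",
    "load_homologous_model",
    "save_shape_space",
    "load_shape_space",
]

_FORMATS = ("stl", "obj", "ply")


class MeshFormatError(ValueError):
    """A mesh file could not be parsed in the requested format."""


def _infer_format(path: Path, format: str) -> str:
    if format != "auto":
        if format not in _FORMATS:
            raise MeshFormatError(f"unknown mesh format {format!r}; expected {_FORMATS}")
        return format
    suffix = path.suffix.lower().lstrip(".")
    if suffix not in _FORMATS:
        raise MeshFormatError(
            f"cannot infer mesh format from suffix {path.suffix!r}; pass format="
        )
    return suffix


def read_mesh(path: str | Path, format: str = "auto") -> TriangleMesh:
    """Read a surface mesh, merging STL's per-facet duplicate vertices exactly.

    Duplicate vertices are merged by exact (bitwise) coordinate equality, so
    the resulting topology is deterministic; no tolerance welding is applied.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if path.stat().st_size == 0:
        raise MeshFormatError(f"{path}: empty file (0 bytes) — no mesh to read")
    try:
        raw = trimesh.load_mesh(str(path), file_type=fmt, process=False)
    except Exception as exc:  # noqa: BLE001 - reraise with location context
        raise MeshFormatError(f"{path}: failed to parse as {fmt}: {exc}") from exc
    if isinstance(raw, trimesh.Scene):
        geoms = list(raw.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: file contains no mesh geometry")
        raw = trimesh.util.concatenate(geoms)
    if raw.vertices.shape[0] == 0 or raw.faces.shape[0] == 0:
        raise MeshFormatError(f"{path}: empty mesh (no vertices/faces)")
    mesh = TriangleMesh.from_trimesh(raw).merge_duplicate_vertices()
    return mesh.validate()


def write_mesh(mesh: TriangleMesh, path: str | Path, format: str = "auto") -> None:
    """Write a mesh; invariants are checked before anything touches disk."""
    path = Path(path)
    fmt = _infer_format(path, format)
    mesh.validate()
    tm = mesh.to_trimesh()
    try:
        if fmt == "stl":
            data = tm.export(file_type="stl_ascii")
            path.write_text(data)
        elif fmt == "obj":
            path.write_text(tm.export(file_type="obj"))
        else:  # ply
            path.write_bytes(tm.export(file_type="ply", encoding="ascii"))
    except OSError as exc:
        raise OSError(f"cannot write mesh to {path}: {exc}") from exc


def write_mesh_binary_stl(mesh: TriangleMesh, path: str | Path) -> None:
    """Write little-endian binary STL (80-byte header + uint32 facet count).

    Coordinates are quantized to float32 by the format.
    """
    mesh.validate()
    Path(path).write_bytes(mesh.to_trimesh().export(file_type="stl"))


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------

def read_landmarks(path: str | Path, scheme: Scheme | str) -> LandmarkSet:
    """Read named 3D landmarks (CSV with ``name,x,y,z`` header, or JSON list).

    Entries are reordered to the scheme's canonical order; missing, unknown or
    duplicated names raise :class:`LandmarkSchemeError` naming the offenders.
    """
    path = Path(path)
    scheme = Scheme(scheme)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
        names = [r["name"] for r in records]
        pts = np.array([[r["x"], r["y"], r["z"]] for r in records], dtype=float)
    else:
        df = pd.read_csv(path)
        required = {"name", "x", "y", "z"}
        if not required.issubset(df.columns):
            raise LandmarkSchemeError(
                f"{path}: landmark CSV must have header columns {sorted(required)}, "
                f"got {list(df.columns)}"
            )
        names = df["name"].astype(str).tolist()
        pts = df[["x", "y", "z"]].to_numpy(dtype=float)
    return LandmarkSet(names, pts, scheme)


def write_landmarks(landmarks: LandmarkSet, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = [
            {"name": n, "x": p[0], "y": p[1], "z": p[2]}
            for n, p in zip(landmarks.names, landmarks.points)
        ]
        path.write_text(json.dumps(records, indent=1))
    else:
        df = pd.DataFrame(
            {
                "name": landmarks.names,
                "x": landmarks.points[:, 0],
                "y": landmarks.points[:, 1],
                "z": landmarks.points[:, 2],
            }
        )
        df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Homologous models
# ---------------------------------------------------------------------------

def save_homologous_model(model: HomologousModel, path: str | Path) -> None:
    """Write the mesh plus a JSON sidecar (template id, landmark vertex ids)."""
    path = Path(path)
    write_mesh(model.mesh, path)
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(
        json.dumps(
            {
                "template_id": model.template_id,
                "landmark_vertex_ids": {
                    k: int(v) for k, v in model.landmark_vertex_ids.items()
                },
            },
            indent=1,
        )
    )


def save_shape_space(space, dirpath: str | Path) -> None:
    """Serialize a fitted shape space as a directory.

    Layout: ``mean.stl`` (mean mesh), ``components.npy`` (K x 3V float64),
    ``space.json`` (eigenvalues, contribution rates, template id, landmark
    vertex ids), ``variance_report.csv``.
    """
    from .shape_space import variance_report

    dirpath = Path(dirpath)
    dirpath.mkdir(parents=True, exist_ok=True)
    write_mesh(TriangleMesh(space.mean_.reshape(-1, 3), space.faces_), dirpath / "mean.stl")
    np.save(dirpath / "components.npy", space.components_)
    (dirpath / "space.json").write_text(
        json.dumps(
            {
                "template_id": space.template_id,
                "n_components": int(space.n_components),
                "eigenvalues": space.eigenvalues_.tolist(),
                "contribution_pct": space.contribution_.tolist(),
                "cumulative_pct": space.cumulative_.tolist(),
                "total_variance": space.total_variance_,
                "n_samples": int(space.n_samples_),
                "landmark_vertex_ids": {
                    k: int(v) for k, v in space.landmark_vertex_ids_.items()
                },
                "mean": space.mean_.tolist(),
                "faces": space.faces_.tolist(),
            }
        )
    )
    variance_report(space).to_csv(dirpath / "variance_report.csv", index=False)


def load_shape_space(dirpath: str | Path):
    from .shape_space import ShapeSpacePCA

    dirpath = Path(dirpath)
    meta = json.loads((dirpath / "space.json").read_text())
    space = ShapeSpacePCA(
        n_components=meta["n_components"], template_id=meta["template_id"]
    )
    space.components_ = np.load(dirpath / "components.npy")
    space.mean_ = np.asarray(meta["mean"], dtype=float)
    space.faces_ = np.asarray(meta["faces"], dtype=np.int64)
    space.eigenvalues_ = np.asarray(meta["eigenvalues"], dtype=float)
    space.contribution_ = np.asarray(meta["contribution_pct"], dtype=float)
    space.cumulative_ = np.asarray(meta["cumulative_pct"], dtype=float)
    space.total_variance_ = float(meta["total_variance"])
    space.n_samples_ = int(meta["n_samples"])
    space.landmark_vertex_ids_ = {
        k: int(v) for k, v in meta["landmark_vertex_ids"].items()
    }
    return space


def load_homologous_model(path: str | Path) -> HomologousModel:
    path = Path(path)
    mesh = read_mesh(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise FileNotFoundError(f"missing homologous-model sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    return HomologousModel(
        mesh, meta["template_id"], {k: int(v) for k, v in meta["landmark_vertex_ids"].items()}
    )
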