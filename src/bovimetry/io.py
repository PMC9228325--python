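"""File I/O: meshes (PLY/OBJ/STL), point clouds, and unit-aware CSV tables.

CSV trait/weight tables carry the unit in the header suffix (_m, _cm, _mm,
_m2, _m3, _kg); values are normalized to SI on read. Mesh formats are
chosen by extension and round-trip vertices to float32 precision and face
indices exactly.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh

from .geometry import PointCloud
from .records import TraitRecord, WeighRecord

log = logging.getLogger(__name__)

_MESH_EXTS = {".ply", ".obj", ".stl"}

_LENGTH_FACTOR = {"m": 1.0, "cm": 0.01, "mm": 0.001}


class MeshIOError(RuntimeError):
    pass


class TableError(RuntimeError):
    pass


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    path = Path(path)
    if path.suffix.lower() not in _MESH_EXTS:
        raise MeshIOError(f"unsupported mesh format {path.suffix!r}")
    mesh.export(path)


def read_mesh(path) -> trimesh.Trimesh:
    path = Path(path)
    if not path.exists():
        raise MeshIOError(f"no such file: {path}")
    if path.suffix.lower() not in _MESH_EXTS:
        raise MeshIOError(f"unsupported mesh format {path.suffix!r}")
    try:
        loaded = trimesh.load(path, force="mesh", process=False)
    except Exception as err:
        size = os.path.getsize(path)
        raise MeshIOError(
            f"failed to parse {path} (file size {size} bytes): {err}"
        ) from err
    if loaded is None or len(loaded.faces) == 0:
        size = os.path.getsize(path)
        raise MeshIOError(f"no triangles parsed from {path} ({size} bytes)")
    return loaded


def write_point_cloud(cloud: PointCloud, path) -> None:
    """Point cloud as PLY with per-vertex nx, ny, nz when normals exist."""
    path = Path(path)
    pc = trimesh.PointCloud(cloud.points)
    if cloud.normals is not None:
        # trimesh PointCloud has no normal support in PLY export; write by hand
        n = len(cloud.points)
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {n}\n"
                "property float x\nproperty float y\nproperty float z\n"
                "property float nx\nproperty float ny\nproperty float nz\n"
                "end_header\n"
            )
            arr = np.hstack([cloud.points, cloud.normals]).astype(np.float32)
            np.savetxt(fh, arr, fmt="%.7g")
        return
    pc.export(path)


def read_point_cloud(path) -> PointCloud:
    """Read a point cloud from PLY or whitespace XYZ[+normals] text."""
    path = Path(path)
    if path.suffix.lower() == ".xyz":
        arr = np.loadtxt(path, dtype=float)
        if arr.ndim == 1:
            arr = arr[None, :]
        if arr.shape[1] >= 6:
            return PointCloud(points=arr[:, :3], normals=arr[:, 3:6])
        return PointCloud(points=arr[:, :3])
    parsed = _parse_ascii_ply_cloud(path)
    if parsed is not None:
        return parsed
    loaded = trimesh.load(path, process=False)
    return PointCloud(points=np.asarray(loaded.vertices, dtype=float))


def _parse_ascii_ply_cloud(path) -> PointCloud | None:
    """Parse an ASCII PLY vertex list, keeping nx/ny/nz when present."""
    with open(path, "rb") as fh:
        head = fh.readline().strip()
        if head != b"ply":
            return None
        props: list[str] = []
        n_vertex = None
        fmt_ascii = False
        while True:
            line = fh.readline()
            if not line:
                return None
            line = line.strip()
            if line.startswith(b"format"):
                fmt_ascii = b"ascii" in line
            elif line.startswith(b"element vertex"):
                n_vertex = int(line.split()[-1])
            elif line.startswith(b"element") and n_vertex is not None:
                break  # only leading vertex elements supported here
            elif line.startswith(b"property") and n_vertex is not None:
                props.append(line.split()[-1].decode())
            elif line == b"end_header":
                break
        if not fmt_ascii or n_vertex is None:
            return None
        data = np.loadtxt(fh, dtype=float, max_rows=n_vertex)
    if data.ndim == 1:
        data = data[None, :]
    cols = {name: i for i, name in enumerate(props)}
    if not {"x", "y", "z"} <= set(cols):
        return None
    pts = data[:, [cols["x"], cols["y"], cols["z"]]]
    normals = None
    if {"nx", "ny", "nz"} <= set(cols):
        normals = data[:, [cols["nx"], cols["ny"], cols["nz"]]]
        normals = normals / np.clip(
            np.linalg.norm(normals, axis=1, keepdims=True), 1e-12, None
        )
    return PointCloud(points=pts, normals=normals)


def _parse_unit_column(col: str):
    """Split 'hg_cm' -> ('hg', factor 0.01). Returns None for non-unit columns."""
    if "_" not in col:
        return None
    base, suffix = col.rsplit("_", 1)
    if suffix in _LENGTH_FACTOR and base in ("hg", "wh", "cd", "hw", "kw"):
        return base, _LENGTH_FACTOR[suffix]
    if suffix == "m2" and base == "bsa":
        return base, 1.0
    if suffix == "m3" and base == "volume":
        return base, 1.0
    if suffix == "kg" and base == "bw":
        return base, 1.0
    return None


def read_traits(path) -> list:
    """Read a trait table; headers like animal_id, age_days, hg_cm, bsa_m2 ..."""
    df = pd.read_csv(path)
    if "animal_id" not in df.columns or "age_days" not in df.columns:
        raise TableError("trait table needs animal_id and age_days columns")
    if df.duplicated(subset=["animal_id", "age_days"]).any():
        raise TableError("duplicate (animal_id, age_days) rows in trait table")
    known = {}
    for col in df.columns:
        if col in ("animal_id", "age_days", "quality"):
            continue
        parsed = _parse_unit_column(col)
        if parsed is None:
            raise TableError(f"unknown column or unit suffix: {col!r}")
        known[col] = parsed
    if "quality" not in df.columns:
        log.warning("trait table has no quality column; defaulting to 4")
        df["quality"] = 4
    df["quality"] = df["quality"].fillna(4).astype(int)
    out = []
    for _, row in df.iterrows():
        vals: dict = {}
        for col, (base, factor) in known.items():
            v = row[col]
            if pd.isna(v):
                continue
            v = float(v)
            if v < 0:
                raise TableError(f"negative value in column {col!r}: {v}")
            vals[base] = v * factor
        out.append(
            TraitRecord(
                animal_id=str(row["animal_id"]),
                age=float(row["age_days"]),
                quality=int(row["quality"]),
                **vals,
            )
        )
    return out


def read_weights(path) -> list:
    df = pd.read_csv(path)
    need = {"animal_id", "age_days", "bw_kg"}
    if not need <= set(df.columns):
        raise TableError(f"weight table needs columns {sorted(need)}")
    if df.duplicated(subset=["animal_id", "age_days"]).any():
        raise TableError("duplicate (animal_id, age_days) rows in weight table")
    if (df["bw_kg"] <= 0).any():
        raise TableError("non-positive body weight in weight table")
    return [
        WeighRecord(
            animal_id=str(r["animal_id"]),
            age=float(r["age_days"]),
            bw=float(r["bw_kg"]),
            interpolated=bool(r.get("interpolated", False)),
        )
        for _, r in df.iterrows()
    ]


def read_tables(traits_path, weights_path):
    return read_traits(traits_path), read_weights(weights_path)


def traits_frame(records: list, extra_units: bool = True) -> pd.DataFrame:
    """TraitRecords as a DataFrame with SI columns (plus cm/mm convenience)."""
    rows = []
    for r in records:
        row = {
            "animal_id": r.animal_id,
            "age_days": r.age,
            "hg_m": r.hg,
            "wh_m": r.wh,
            "cd_m": r.cd,
            "hw_m": r.hw,
            "kw_m": r.kw,
            "bsa_m2": r.bsa,
            "volume_m3": r.volume,
            "quality": r.quality,
        }
        rows.append(row)
    df = pd.DataFrame(rows)
    if extra_units:
        for t in ("hg", "wh"):
            df[f"{t}_cm"] = df[f"{t}_m"] * 100.0
        for t in ("cd", "hw", "kw"):
            df[f"{t}_mm"] = df[f"{t}_m"] * 1000.0
    return df


def write_traits(records: list, path) -> None:
    traits_frame(records).to_csv(path, index=False)


def write_weights(records: list, path) -> None:
    pd.DataFrame(
        [
            {
                "animal_id": r.animal_id,
                "age_days": r.age,
                "bw_kg": r.bw,
                "interpolated": r.interpolated,
            }
            for r in records
        ]
    ).to_csv(path, index=False)
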