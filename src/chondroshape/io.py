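"""Shared readers/writers: cell tables (CSV), surface patches (CSV),
meshes (OFF/PLY via trimesh, PLY carrying per-vertex factors as named
float properties), JSON reports and YAML configs.

Coordinates are real-valued and right-handed with z along the sheet
normal for slab data.  CSV dialect: comma-separated, dot decimal, UTF-8,
header required.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import trimesh
import yaml

CELL_TABLE_COLUMNS = ["id", "clone_id", "x", "y", "z", "radius", "birth_time"]
SURFACE_TABLE_COLUMNS = ["locality_id", "patch", "x", "y", "z"]


class FormatError(ValueError):
    """Malformed input file."""


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Validated cell table; row order preserved.

    Raises FormatError naming the offending row for a missing column,
    non-numeric coordinate or duplicate id.
    """
    df = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    for col in ["x", "y", "z", "radius", "birth_time"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise FormatError(f"{path}: non-numeric value in column {col!r} at row {row}")
        df[col] = coerced
    dup = df["id"].duplicated()
    if dup.any():
        row = int(dup.idxmax())
        raise FormatError(f"{path}: duplicate id {df['id'].iloc[row]} at row {row}")
    return df[CELL_TABLE_COLUMNS]


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    df[CELL_TABLE_COLUMNS].to_csv(path, index=False)


def read_surface_table(path: str | Path) -> pd.DataFrame:
    """Surface patch samples: locality_id, patch (a|b), x, y, z."""
    df = pd.read_csv(path)
    missing = [c for c in SURFACE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    bad = ~df["patch"].isin(["a", "b"])
    if bad.any():
        row = int(bad.idxmax())
        raise FormatError(f"{path}: patch must be 'a' or 'b' at row {row}")
    return df[SURFACE_TABLE_COLUMNS]


def write_surface_table(pairs: dict, path: str | Path) -> None:
    """Write {locality_id: SurfacePatchPair} to the surface CSV dialect."""
    rows = []
    for loc, pair in pairs.items():
        for name, pts in (("a", pair.patch_a), ("b", pair.patch_b)):
            for p in pts:
                rows.append((loc, name, p[0], p[1], p[2]))
    pd.DataFrame(rows, columns=SURFACE_TABLE_COLUMNS).to_csv(path, index=False)


def canvas_to_trimesh(canvas) -> trimesh.Trimesh:
    mesh = trimesh.Trimesh(
        vertices=canvas.vertices.copy(), faces=canvas.triangles.copy(), process=False
    )
    for name, values in canvas.factors.items():
        mesh.vertex_attributes[name] = values.astype(np.float32)
    return mesh


def write_mesh(canvas, path: str | Path, fmt: str | None = None) -> Path:
    """Export a canvas as OFF or PLY (inferred from the suffix).

    PLY carries the per-vertex factors (POL, MID, CHEEKS) as named float
    properties; OFF stores geometry only.
    """
    path = Path(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt not in ("off", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r}")
    mesh = canvas_to_trimesh(canvas)
    if fmt == "ply":
        data = mesh.export(file_type="ply", encoding="ascii", include_attributes=True)
    else:
        data = mesh.export(file_type="off")
    if isinstance(data, str):
        data = data.encode()
    path.write_bytes(data)
    return path


def read_mesh(path: str | Path) -> trimesh.Trimesh:
    return trimesh.load_mesh(str(path), process=False)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")


def read_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: top level of config must be a mapping")
    return cfg
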