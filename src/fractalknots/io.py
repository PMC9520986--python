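"""File formats: XYZ trajectories of ring conformations, CSV/JSON tables.

Conformations travel as multi-frame XYZ (one frame per ring; the comment
line carries N, d_f, seed and the spatial dimension).  Tables use CSV
with ``# key=value`` metadata header lines, mirrored as JSON bundles.
Round trips are lossless to 17 significant digits.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_csv_table",
    "read_csv_table",
    "write_json_bundle",
]

_ELEMENT = "C"


def write_xyz(path, frames, d_f=None, seed=None, d: int | None = None) -> None:
    """Write ring conformations as multi-frame XYZ.

    ``frames`` is an iterable of (N, dim) arrays (dim 2 or 3; 2D rings
    are stored with z = 0 and flagged d=2 in the comment line).
    """
    path = Path(path)
    with path.open("w") as fh:
        for idx, pts in enumerate(frames):
            pts = np.asarray(pts, dtype=float)
            if pts.ndim != 2 or pts.shape[1] not in (2, 3):
                raise ValueError("each frame must be (N, 2) or (N, 3)")
            dim = d if d is not None else pts.shape[1]
            meta = f"frame={idx} N={pts.shape[0]} d={dim}"
            if d_f is not None:
                meta += f" d_f={d_f!r}"
            if seed is not None:
                meta += f" seed={seed}"
            fh.write(f"{pts.shape[0]}\n{meta}\n")
            for row in pts:
                x, y = row[0], row[1]
                z = row[2] if pts.shape[1] == 3 else 0.0
                fh.write(f"{_ELEMENT} {x:.17g} {y:.17g} {z:.17g}\n")


def read_xyz(path) -> tuple[list[np.ndarray], list[dict]]:
    """Read a multi-frame XYZ file; returns (frames, per-frame metadata).

    Frames flagged ``d=2`` in their comment line come back as (N, 2)
    arrays.  Malformed files raise ValueError with the offending line
    number.
    """
    path = Path(path)
    frames: list[np.ndarray] = []
    metas: list[dict] = []
    lines = path.read_text().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(
                f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}"
            ) from exc
        if i + 1 + natoms >= len(lines) + 1 and natoms > 0:
            raise ValueError(f"{path}:{i + 1}: truncated frame of {natoms} atoms")
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        meta: dict = {}
        for token in comment.split():
            if "=" in token:
                key, _, val = token.partition("=")
                try:
                    meta[key] = json.loads(val)
                except json.JSONDecodeError:
                    meta[key] = val
        coords = np.empty((natoms, 3))
        for a in range(natoms):
            ln = i + 2 + a
            if ln >= len(lines):
                raise ValueError(f"{path}:{ln + 1}: truncated frame")
            parts = lines[ln].split()
            if len(parts) < 4:
                raise ValueError(
                    f"{path}:{ln + 1}: expected 'element x y z', got {lines[ln]!r}"
                )
            try:
                coords[a] = [float(parts[1]), float(parts[2]), float(parts[3])]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln + 1}: bad coordinate") from exc
        if meta.get("d") == 2:
            coords = coords[:, :2]
        frames.append(coords)
        metas.append(meta)
        i += 2 + natoms
    return frames, metas


def write_csv_table(path, df: pd.DataFrame, meta: dict | None = None) -> None:
    """Write a DataFrame as CSV preceded by ``# key=value`` metadata lines."""
    path = Path(path)
    with path.open("w") as fh:
        for key, val in (meta or {}).items():
            fh.write(f"# {key}={json.dumps(val)}\n")
        df.to_csv(fh, index=False)


def read_csv_table(path, expected_columns=None) -> tuple[pd.DataFrame, dict]:
    """Read a metadata-annotated CSV table; returns (frame, metadata).

    When ``expected_columns`` is given, a header mismatch raises
    ValueError naming the offending header line.
    """
    path = Path(path)
    meta: dict = {}
    header_line = 0
    with path.open() as fh:
        pos = fh.tell()
        lineno = 0
        while True:
            line = fh.readline()
            lineno += 1
            if not line.startswith("#"):
                header_line = lineno
                break
            key, _, val = line[1:].strip().partition("=")
            try:
                meta[key.strip()] = json.loads(val)
            except json.JSONDecodeError:
                meta[key.strip()] = val
            pos = fh.tell()
        fh.seek(pos)
        df = pd.read_csv(fh)
    if expected_columns is not None and list(df.columns) != list(expected_columns):
        raise ValueError(
            f"{path}:{header_line}: header {list(df.columns)} does not match "
            f"expected {list(expected_columns)}"
        )
    return df, meta


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="list")
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_json_bundle(path, bundle: dict) -> None:
    """Write a nested result bundle (DataFrames allowed) as JSON."""
    Path(path).write_text(json.dumps(_jsonable(bundle), indent=2, sort_keys=True))
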