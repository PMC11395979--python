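"""File formats: STL surface meshes, cohort CSV tables, results JSON.

STL reading auto-detects the ASCII and binary dialects (malformed binary
files are reported with the byte offset where the record structure breaks
down).  The cohort CSV schema is fixed and documented in
:data:`aortameta.config.COHORT_COLUMNS`; hemodynamic columns are optional
on read so that morphometry-only tables still support the diameter
classifier.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path
import pandas as pd
import trimesh

from .config import (
    COHORT_COLUMNS,
    DIAMETER_NAMES,
    PRESSURE_COLUMNS,
    VELOCITY_COLUMNS,
)

__all__ = ["STLFormatError", "read_stl", "write_stl", "read_cohort_csv",
           "write_cohort_csv", "write_json"]


class STLFormatError(ValueError):
    """The file is not a valid ASCII or binary STL."""


def _looks_ascii(head: bytes, data: bytes) -> bool:
    if not head.lstrip().lower().startswith(b"solid"):
        return False
    # binary files may also start with "solid": check the facet-count math
    if len(data) >= 84:
        (n,) = struct.unpack("<I", data[80:84])
        if len(data) == 84 + 50 * n:
            return b"facet" not in data[:200].lower() or b"\x00" in data
    return True


def read_stl(path: str | Path) -> trimesh.Trimesh:
    """Read an ASCII or binary STL surface mesh (units: mm).

    The dialect is auto-detected.  Structurally broken binary files raise
    :class:`STLFormatError` naming the byte offset at which the facet
    records end prematurely.
    """
    path = Path(path)
    data = path.read_bytes()
    if len(data) < 15:
        raise STLFormatError(f"{path}: too short to be an STL ({len(data)} bytes)")
    ascii_dialect = _looks_ascii(data[:80], data)
    if not ascii_dialect:
        if len(data) < 84:
            raise STLFormatError(
                f"{path}: binary STL truncated in the 84-byte header "
                f"(file ends at byte {len(data)})")
        (n,) = struct.unpack("<I", data[80:84])
        expected = 84 + 50 * n
        if len(data) != expected:
            bad = min(len(data), expected)
            raise STLFormatError(
                f"{path}: binary STL declares {n} facets ({expected} bytes) "
                f"but the facet records break at byte offset {bad}")
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except Exception as exc:  # malformed ASCII facet etc.
        raise STLFormatError(f"{path}: malformed STL: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.faces) == 0:
        raise STLFormatError(f"{path}: STL contains no facets")
    return mesh


def write_stl(mesh: trimesh.Trimesh, path: str | Path,
              ascii_dialect: bool = False) -> None:
    """Write a mesh as STL; binary by default, ASCII on request.

    Round-tripping preserves vertex coordinates to well below 1e-6 mm
    (binary STL stores float32; ASCII is written with full precision).
    """
    path = Path(path)
    if ascii_dialect:
        data = trimesh.exchange.stl.export_stl_ascii(mesh)
        path.write_text(data)
    else:
        path.write_bytes(trimesh.exchange.stl.export_stl(mesh))


# ---------------------------------------------------------------------------
# cohort CSV
# ---------------------------------------------------------------------------

_MANDATORY = ("patient_id", "label", *DIAMETER_NAMES)
_HEMO = (*VELOCITY_COLUMNS, *PRESSURE_COLUMNS)


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort table; diameters are mandatory, hemodynamics optional.

    Unknown columns are preserved.  The returned frame's
    ``attrs["has_hemodynamics"]`` records whether the full hemodynamic
    block is present.
    """
    df = pd.read_csv(path)
    missing = [c for c in _MANDATORY if c not in df.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing mandatory columns: {missing}")
    for c in (*DIAMETER_NAMES, *[h for h in _HEMO if h in df.columns]):
        df[c] = pd.to_numeric(df[c])
    bad = [lab for lab in df["label"].unique() if lab not in ("normal", "coa")]
    if bad:
        raise ValueError(f"unknown class labels: {bad}")
    df.attrs["has_hemodynamics"] = all(c in df.columns for c in _HEMO)
    return df


def write_cohort_csv(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table with deterministic column order.

    Schema columns come first in canonical order; unknown columns follow in
    their original order.  Identical frames produce byte-identical files.
    """
    known = [c for c in COHORT_COLUMNS if c in df.columns]
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    df[known + extra].to_csv(path, index=False, lineterminator="\n",
                             float_format="%.12g")


def write_json(obj, path: str | Path) -> None:
    """Write a JSON result file with stable key order."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
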