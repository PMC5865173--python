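"""Readers and writers for the toolkit's on-disk formats.

Event tables round-trip as CSV (numeric fields to 6 significant digits)
or as minimal FCS 3.1 (list mode, 32-bit float, little endian — written
by hand since the format is simple and self-describing).  Slice records
are a cells CSV plus a boundary/metadata JSON; masks are single-channel
TIFFs; time courses and result tables are tidy CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import SliceRecord, ValidationError


class ParseError(ValidationError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# event tables

def write_events_csv(events: pd.DataFrame, path) -> None:
    events.to_csv(path, index=False, float_format="%.6g")


def read_events_csv(path, channel_map: dict[str, str] | None = None) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:  # pragma: no cover - passthrough detail
        raise ParseError(f"{path}: {e}") from e
    if channel_map:
        df = df.rename(columns=channel_map)
    if "dead" in df.columns:
        df["dead"] = df["dead"].astype(bool)
    return df


def write_fcs(events: pd.DataFrame, path) -> None:
    """Write the numeric channels of an event table as FCS 3.1.

    List mode, $DATATYPE F (float32), $BYTEORD 1,2,3,4.  The boolean
    viability flag is stored as a 0/1 channel named ``dead``; string
    ground-truth columns are not representable in FCS and are dropped.
    """
    num = events.select_dtypes(include=[np.number, bool]).astype(np.float32)
    channels = list(num.columns)
    data = np.ascontiguousarray(num.to_numpy(dtype="<f4"))
    n_tot, n_par = data.shape

    kw = {
        "$BEGINANALYSIS": "0", "$ENDANALYSIS": "0",
        "$BEGINSTEXT": "0", "$ENDSTEXT": "0",
        "$BYTEORD": "1,2,3,4", "$DATATYPE": "F", "$MODE": "L",
        "$NEXTDATA": "0", "$TOT": str(n_tot), "$PAR": str(n_par),
        # placeholders, fixed width so offsets are stable
        "$BEGINDATA": "0" * 10, "$ENDDATA": "0" * 10,
    }
    for i, name in enumerate(channels, start=1):
        kw[f"$P{i}N"] = name
        kw[f"$P{i}B"] = "32"
        kw[f"$P{i}E"] = "0,0"
        kw[f"$P{i}R"] = "262144"

    def render(d):
        return ("/" + "/".join(f"{k}/{v}" for k, v in d.items()) + "/").encode("ascii")

    header_len = 58
    text = render(kw)
    data_start = header_len + len(text)
    data_end = data_start + data.nbytes - 1
    kw["$BEGINDATA"] = f"{data_start:010d}"
    kw["$ENDDATA"] = f"{data_end:010d}"
    text = render(kw)

    header = b"FCS3.1    " + (
        f"{header_len:8d}{header_len + len(text) - 1:8d}"
        f"{data_start:8d}{0 if data_end > 99_999_999 else data_end:8d}"
        f"{0:8d}{0:8d}"
    ).encode("ascii")
    assert len(header) == header_len
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(text)
        fh.write(data.tobytes())


def read_fcs(path, channel_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read an FCS 3.0/3.1 list-mode file with float32 data."""
    raw = Path(path).read_bytes()
    if not raw[:6] in (b"FCS3.0", b"FCS3.1"):
        raise ParseError(f"{path}: not an FCS 3.x file (magic {raw[:6]!r})")
    try:
        text_start = int(raw[10:18])
        text_end = int(raw[18:26])
    except ValueError as e:
        raise ParseError(f"{path}: malformed header offsets") from e
    text = raw[text_start: text_end + 1].decode("ascii", errors="replace")
    delim = text[0]
    parts = text.strip(delim).split(delim)
    if len(parts) % 2:
        raise ParseError(f"{path}: odd TEXT keyword count at offset {text_start}")
    kw = dict(zip(parts[0::2], parts[1::2]))
    if kw.get("$DATATYPE") != "F" or kw.get("$MODE") != "L":
        raise ParseError(f"{path}: only list-mode float FCS is supported")
    n_tot, n_par = int(kw["$TOT"]), int(kw["$PAR"])
    data_start = int(kw.get("$BEGINDATA") or raw[26:34])
    fmt = "<" if kw.get("$BYTEORD", "1,2,3,4").startswith("1") else ">"
    need = n_tot * n_par * 4
    buf = raw[data_start: data_start + need]
    if len(buf) < need:
        raise ParseError(f"{path}: data segment truncated at byte {data_start + len(buf)}")
    arr = np.frombuffer(buf, dtype=f"{fmt}f4").reshape(n_tot, n_par)
    names = [kw.get(f"$P{i}N", f"ch{i}") for i in range(1, n_par + 1)]
    df = pd.DataFrame(np.asarray(arr, dtype=float), columns=names)
    if channel_map:
        df = df.rename(columns=channel_map)
    if "dead" in df.columns:
        df["dead"] = df["dead"] > 0.5
    return df


def require_channels(events: pd.DataFrame, required) -> None:
    missing = [c for c in required if c not in events.columns]
    if missing:
        raise ParseError(
            f"event table lacks channels {missing}; provide a channel map"
        )


# ---------------------------------------------------------------------------
# slices

def write_slice(rec: SliceRecord, cells_path, boundary_path) -> None:
    rec.cells.to_csv(cells_path, index=False, float_format="%.6g")
    payload = {
        "boundary": np.asarray(rec.boundary, dtype=float).round(6).tolist(),
        "metadata": _jsonable(rec.metadata),
    }
    with open(boundary_path, "w") as fh:
        json.dump(payload, fh)


def read_slice(cells_path, boundary_path) -> SliceRecord:
    cells = pd.read_csv(cells_path)
    try:
        with open(boundary_path) as fh:
            payload = json.load(fh)
    except json.JSONDecodeError as e:
        raise ParseError(f"{boundary_path}: line {e.lineno} col {e.colno}: {e.msg}") from e
    boundary = np.asarray(payload["boundary"], dtype=float)
    if boundary.ndim != 2 or boundary.shape[1] != 2:
        raise ParseError(f"{boundary_path}: boundary must be an (N, 2) vertex list")
    for col in cells.columns:
        if cells[col].dtype == object and set(cells[col].unique()) <= {"True", "False"}:
            cells[col] = cells[col] == "True"
    return SliceRecord(boundary=boundary, cells=cells,
                       metadata=payload.get("metadata", {}))


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


# ---------------------------------------------------------------------------
# masks and stacks

def write_mask_tiff(mask: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(mask).astype(np.uint8))


def read_mask_tiff(path) -> np.ndarray:
    return tifffile.imread(path) > 0


def write_stack_tiff(stack: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(stack, dtype=np.float32),
                     photometric="minisblack")


def read_stack_tiff(path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_density_tiff(grid: np.ndarray, path) -> None:
    tifffile.imwrite(path, np.asarray(grid, dtype=np.float32))


# ---------------------------------------------------------------------------
# tables

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format="%.6g")


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
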