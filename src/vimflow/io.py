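"""File formats and provenance-stamped result records.

Traces travel as plain CSV (columns ``time_s, i405, i594``; comma
separated, UTF-8, '.' decimal); header names are matched
case-insensitively.  Results are written as JSON with a schema version,
the software version, the seed in effect and SHA-256 hashes of the input
files, so every number in an output file can be traced to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .simulate import StoppedFlowTrace

__all__ = ["ParseError", "read_trace", "write_trace", "read_table", "write_results"]

SCHEMA_VERSION = 1

_TRACE_COLUMNS = ("time_s", "i405", "i594")


class ParseError(ValueError):
    """Malformed input file (bad header, NaN rows, non-monotone time)."""


def _canonical_columns(columns, required, path):
    mapping = {}
    lowered = {c.lower().strip(): c for c in columns}
    for want in required:
        if want not in lowered:
            raise ParseError(f"{path}: missing column {want!r} (found {list(columns)})")
        mapping[lowered[want]] = want
    return mapping


def read_trace(path, state: str = "raw", meta: dict | None = None) -> StoppedFlowTrace:
    """Read a two-channel trace CSV.

    Rows containing NaN or non-numeric entries are rejected with their
    line number; time must be strictly increasing.
    """
    path = Path(path)
    df = pd.read_csv(path)
    df = df.rename(columns=_canonical_columns(df.columns, _TRACE_COLUMNS, path))
    df = df[list(_TRACE_COLUMNS)].apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        # +2: header line plus 1-based numbering
        lines = (df.index[bad] + 2).tolist()
        raise ParseError(f"{path}: non-numeric or missing values on line(s) {lines}")
    time = df["time_s"].to_numpy()
    if time.size >= 2 and not np.all(np.diff(time) > 0):
        i = int(np.argmax(np.diff(time) <= 0))
        raise ParseError(f"{path}: time not strictly increasing at line {i + 3}")
    return StoppedFlowTrace(
        time_s=time, i405=df["i405"].to_numpy(), i594=df["i594"].to_numpy(),
        state=state, meta=meta or {},
    )


def write_trace(trace: StoppedFlowTrace, path) -> Path:
    path = Path(path)
    trace.to_frame().to_csv(path, index=False)
    return path


def read_table(path, columns) -> pd.DataFrame:
    """Read a delimited table with the given required columns (lengths,
    diameters, (l_fil, sigma) pairs...)."""
    path = Path(path)
    df = pd.read_csv(path)
    df = df.rename(columns=_canonical_columns(df.columns, tuple(columns), path))
    df = df[list(columns)].apply(pd.to_numeric, errors="coerce")
    bad = df.isna().any(axis=1)
    if bad.any():
        lines = (df.index[bad] + 2).tolist()
        raise ParseError(f"{path}: non-numeric or missing values on line(s) {lines}")
    return df


def file_sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if hasattr(obj, "to_dict"):
        return _jsonable(obj.to_dict())
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_results(record, path, seed=None, inputs=None) -> Path:
    """Write a result record as provenance-stamped JSON.

    ``record`` may be a dict or any result object with ``to_dict``.
    Output is deterministic (sorted keys); the seed and the SHA-256 of
    every input file are embedded.
    """
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "software": {"name": "vimflow", "version": __version__},
        "seed": seed,
        "inputs": {str(p): file_sha256(p) for p in (inputs or [])},
        "result": _jsonable(record),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
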