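"""COLVAR-style whitespace tables with a ``#! FIELDS ...`` header.

This is the de-facto interchange dialect of the enhanced-sampling ecosystem:
the first line names the columns, subsequent lines are whitespace-separated
numbers. Comment lines starting with ``#`` after the header are preserved as
metadata (e.g. a config hash) but ignored for data.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
import pandas as pd


class ColvarParseError(ValueError):
    """Raised when a COLVAR file is malformed; carries the offending line number."""


def read_colvar(path: str | Path) -> pd.DataFrame:
    """Read a COLVAR-style table into a DataFrame with named columns.

    The first line must be ``#! FIELDS name1 name2 ...``. Parsing is strict:
    every data row must have exactly one value per field and parse as a float.

    Raises
    ------
    ColvarParseError
        If the header is missing or a row is ragged/non-numeric; the message
        names the offending 1-based line number.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("#! FIELDS"):
            raise ColvarParseError(
                f"{path}: line 1: expected '#! FIELDS ...' header, got {first[:40]!r}"
            )
        names = first.split()[2:]
        if not names:
            raise ColvarParseError(f"{path}: line 1: header names no fields")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != len(names):
                raise ColvarParseError(
                    f"{path}: line {lineno}: expected {len(names)} columns, "
                    f"got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts])
            except ValueError as exc:
                raise ColvarParseError(f"{path}: line {lineno}: {exc}") from None
    data = np.asarray(rows, dtype=float).reshape(len(rows), len(names))
    return pd.DataFrame(data, columns=names)


def write_colvar(
    df: pd.DataFrame, path: str | Path, metadata: dict[str, str] | None = None
) -> None:
    """Write a DataFrame as a COLVAR table, 12 significant digits.

    ``metadata`` entries are written as ``# key: value`` comment lines after
    the header, so artifacts can embed e.g. the config hash that produced them.
    """
    path = Path(path)
    buf = io.StringIO()
    buf.write("#! FIELDS " + " ".join(str(c) for c in df.columns) + "\n")
    for key, value in (metadata or {}).items():
        buf.write(f"# {key}: {value}\n")
    np.savetxt(buf, df.to_numpy(dtype=float), fmt="%.12g")
    path.write_text(buf.getvalue())


def read_colvar_metadata(path: str | Path) -> dict[str, str]:
    """Return the ``# key: value`` comment entries of a COLVAR file."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#! FIELDS"):
                continue
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" in body:
                key, _, value = body.partition(":")
                meta[key.strip()] = value.strip()
    return meta
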