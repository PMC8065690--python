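"""Draw-table and result I/O.

Draw tables live on disk as delimited text (TSV by default, CSV for ``.csv``
paths): a header row of coordinate names, then one draw per row, serialized
at 17 significant digits so a save/load round trip is bit-lossless. Provenance
travels in a JSON sidecar ``<path>.meta.json``; a missing sidecar loads with
``source="unknown"`` and a warning.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .draws import DrawMatrix
from .errors import ParseError

__all__ = ["save_draws", "load_draws", "sidecar_path"]


def sidecar_path(path) -> Path:
    return Path(str(path) + ".meta.json")


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def save_draws(dm: DrawMatrix, path) -> None:
    """Write a draw table plus its metadata sidecar."""
    path = Path(path)
    dm.draws.to_csv(path, sep=_delimiter(path), index=False, float_format="%.17g")
    with open(sidecar_path(path), "w") as fh:
        json.dump(dm.metadata(), fh, indent=1)


def load_draws(path) -> DrawMatrix:
    """Read a draw table, validating shape and numeric content.

    Malformed input (ragged rows, non-numeric cells, empty/duplicate header)
    raises :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    sep = _delimiter(path)
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}: empty or missing header row")
        columns = [c.strip() for c in header.rstrip("\n").split(sep)]
        if len(set(columns)) != len(columns) or any(not c for c in columns):
            raise ParseError(f"{path}: header has empty or duplicate column names")
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            cells = line.rstrip("\n").split(sep)
            if len(cells) != len(columns):
                raise ParseError(
                    f"{path}:{lineno}: ragged row with {len(cells)} cells, "
                    f"expected {len(columns)}"
                )
            try:
                rows.append([float(c) for c in cells])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
    if not rows:
        raise ParseError(f"{path}: no draws")
    df = pd.DataFrame(np.asarray(rows, dtype=float), columns=columns)

    meta_path = sidecar_path(path)
    meta: dict = {}
    if meta_path.exists():
        with open(meta_path) as fh:
            meta = json.load(fh)
    else:
        warnings.warn(f"no metadata sidecar at {meta_path}; loading with source='unknown'")
    return DrawMatrix(
        df,
        source=meta.get("source", "unknown"),
        model_id=meta.get("model_id", ""),
        seed=meta.get("seed"),
        n_iterations=meta.get("n_iterations"),
        burn_in=meta.get("burn_in"),
    )
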