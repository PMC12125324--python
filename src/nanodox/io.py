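"""Readers/writers for the package's plain-text artifacts.

Trajectories and sweep tables are CSV; parameter profiles, fit results and
surrogate models are JSON.  Floats are serialized with ``repr`` so a
round-trip reproduces the exact double-precision values.
"""

from __future__ import annotations

import csv
import hashlib
import json
import time
from pathlib import Path

import pandas as pd

from .errors import InputError

__all__ = ["write_trajectory", "read_trajectory", "write_sidecar",
           "param_hash"]


def write_trajectory(df: pd.DataFrame, path: str | Path) -> None:
    """Write a trajectory/sweep table as CSV with repr-exact floats."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(df.columns)
        for row in df.itertuples(index=False):
            writer.writerow([repr(v) if isinstance(v, float) else v
                             for v in row])


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back; NaN cells are treated as corruption."""
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise InputError(f"malformed CSV {path}: {exc}") from exc
    if df.isna().any().any():
        col = df.columns[df.isna().any()][0]
        row = int(df[df[col].isna()].index[0])
        raise InputError(
            f"malformed CSV {path}: missing/NaN value at row {row}, "
            f"column {col!r}")
    return df


def param_hash(params) -> str:
    """Stable short hash of a parameter registry, for run metadata."""
    doc = json.dumps(params.to_dict(), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def write_sidecar(path: str | Path, command: str, params=None,
                  seed: int | None = None, extra: dict | None = None) -> None:
    """Write the reproducibility sidecar next to an output file."""
    from . import __version__

    meta = {
        "version": __version__,
        "command": command,
        "seed": seed,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    if params is not None:
        meta["param_hash"] = param_hash(params)
    if extra:
        meta.update(extra)
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(meta, indent=2))
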