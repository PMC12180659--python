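"""Plain-text I/O: snapshot CSV/TSV tables and flat JSON records."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["read_snapshot", "write_snapshot", "save_json", "load_json"]

REQUIRED_COLUMNS = ("worm_id", "time_h", "load", "condition")


def read_snapshot(path, sep: str | None = None) -> pd.DataFrame:
    """Read a per-worm snapshot table (CSV, or TSV for .tsv files).

    Validates the required columns (worm_id, time_h, load, condition),
    nonnegative loads and times.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"snapshot file {path} is missing columns: {missing}")
    df["time_h"] = df["time_h"].astype(float)
    df["load"] = df["load"].astype(float)
    if (df["load"] < 0).any():
        raise ValueError("loads must be nonnegative")
    if (df["time_h"] < 0).any():
        raise ValueError("times must be nonnegative")
    return df


def write_snapshot(df: pd.DataFrame, path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def save_json(record: dict, path) -> None:
    Path(path).write_text(json.dumps(record, indent=2, cls=_NumpyEncoder) + "\n")


def load_json(path) -> dict:
    return json.loads(Path(path).read_text())
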