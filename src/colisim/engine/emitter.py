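"""Serialization of emitted time series: JSONL records and CSV export."""

from __future__ import annotations

import json
from pathlib import Path as FilePath

import numpy as np
import pandas as pd


def _jsonable(value):
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating,)):
        return float(value)
    if isinstance(value, dict):
        return {k: _jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_jsonable(v) for v in value]
    return value


def write_jsonl(records: list[dict], path: str | FilePath) -> None:
    """One JSON record per line: time plus flattened variable paths."""
    with open(path, "w") as handle:
        for record in records:
            handle.write(json.dumps(_jsonable(record)) + "\n")


def read_jsonl(path: str | FilePath) -> list[dict]:
    with open(path) as handle:
        return [json.loads(line) for line in handle if line.strip()]


def to_dataframe(records: list[dict]) -> pd.DataFrame:
    """Emitted records as a DataFrame indexed by time (scalars only)."""
    rows = []
    for record in records:
        rows.append(
            {
                k: v
                for k, v in record.items()
                if np.isscalar(v) or isinstance(v, (int, float, str, bool))
            }
        )
    return pd.DataFrame(rows).set_index("time")


def write_csv(records: list[dict], path: str | FilePath) -> None:
    to_dataframe(records).to_csv(path)
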