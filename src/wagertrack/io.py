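"""CSV reading/writing for transaction logs and derived tables.

Timestamps are written as ISO-8601 UTC (``2020-11-27T09:15:02.250000+00:00``)
and parsed back to timezone-aware pandas datetimes.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["read_transactions", "write_transactions", "read_table", "write_table"]


def write_transactions(events: pd.DataFrame, path) -> None:
    out = events.copy()
    ts = pd.to_datetime(out["timestamp"], utc=True)
    out["timestamp"] = ts.dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


def read_transactions(path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = pd.to_datetime(out[col], utc=True).dt.strftime(
                "%Y-%m-%dT%H:%M:%S.%f%z"
            )
    out.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
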