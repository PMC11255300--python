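"""CSV table schemas and round-trip-safe readers/writers."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from . import simulate as _sim

__all__ = ["SchemaError", "SCHEMAS", "write_table", "read_table"]


class SchemaError(ValueError):
    """A table does not match its documented schema."""


#: Required columns per table kind.
SCHEMAS: dict[str, list[str]] = {
    "cells": _sim.CELL_COLUMNS,
    "truth": _sim.TRUTH_COLUMNS,
    "observations": _sim.OBS_COLUMNS,
    "events": _sim.EVENT_COLUMNS,
    "divisions": _sim.DIVISION_COLUMNS,
    "landmarks": _sim.LANDMARK_COLUMNS,
    "trajectories": ["trajectory_id", "channel", "trap", "cell_id", "frame",
                     "time_min", "x_um", "y_um"],
    "detected_events": ["event_id", "trap", "cell_id", "frame", "time_min",
                        "area_um2", "trajectory_ids"],
}

_INT_COLUMNS = {"cell_id", "trap", "parent_id", "frame", "obs_id", "event_id",
                "trajectory_id", "landmark_id", "old_pole_sign", "mother_id",
                "daughter_kept_id", "daughter_flushed_id"}


def _check(df: pd.DataFrame, kind: str) -> None:
    if kind not in SCHEMAS:
        raise SchemaError(f"unknown table kind {kind!r}")
    for i, col in enumerate(SCHEMAS[kind]):
        if col not in df.columns:
            raise SchemaError(f"{kind} table is missing column {col!r} "
                              f"(position {i})")


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> Path:
    """Validate against the schema and write CSV (full float precision)."""
    _check(df, kind)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read a CSV table and validate its schema.

    Raises :class:`SchemaError` naming the missing column, or the first
    row whose value cannot take the expected dtype.
    """
    df = pd.read_csv(path)
    _check(df, kind)
    for col in SCHEMAS[kind]:
        if col in _INT_COLUMNS:
            try:
                df[col] = df[col].astype(int)
            except (ValueError, TypeError) as exc:
                bad = df[pd.to_numeric(df[col], errors="coerce").isna()]
                row = int(bad.index[0]) if len(bad) else -1
                raise SchemaError(
                    f"{kind} table column {col!r} row {row}: {exc}") from exc
    return df
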