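"""Tidy-CSV readers and writers shared by all pipeline stages.

One observation per row, units in the column names (time_min, od600,
halflife_min). Readers validate the header against a named schema and report
offending rows with line numbers before any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["TableSchema", "SCHEMAS", "read_table", "write_table"]


@dataclass(frozen=True)
class TableSchema:
    name: str
    required: tuple[str, ...]
    numeric: tuple[str, ...]
    optional: tuple[str, ...] = ()


SCHEMAS: dict[str, TableSchema] = {
    s.name: s
    for s in (
        TableSchema(
            "abundance",
            required=("time_min", "abundance"),
            numeric=("time_min", "abundance", "od600", "sd"),
            optional=("od600", "sd", "label"),
        ),
        TableSchema(
            "chase",
            required=("condition", "replicate", "time_min", "intensity"),
            numeric=("time_min", "intensity"),
        ),
        TableSchema(
            "ct",
            required=("sample", "gene", "replicate", "ct"),
            numeric=("ct", "od600"),
            optional=("od600", "qc_pass"),
        ),
        TableSchema("growth", required=("time_min", "od600"), numeric=("time_min", "od600")),
        TableSchema(
            "halflife_map",
            required=("time_min", "halflife_min"),
            numeric=("time_min", "halflife_min"),
        ),
    )
}


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def read_table(path, schema: str | TableSchema) -> pd.DataFrame:
    """Read and validate a tidy CSV against a schema.

    Raises :class:`SchemaError` naming missing columns or, for non-numeric
    cells in numeric columns, the offending 1-based data line numbers.
    """
    if isinstance(schema, str):
        schema = SCHEMAS[schema]
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    missing = [c for c in schema.required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing} "
                          f"for schema {schema.name!r}")
    for col in schema.numeric:
        if col not in df.columns:
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad):
            lines = ", ".join(str(i + 2) for i in bad[:5])  # +2: header + 1-based
            raise SchemaError(f"{path}: non-numeric value(s) in column {col!r} "
                              f"at line(s) {lines}")
        df[col] = coerced
    return df


def write_table(df: pd.DataFrame, path) -> Path:
    """Write a tidy CSV (no index); floats at full round-trip precision."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
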