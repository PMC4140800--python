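"""Schema-checked TSV table I/O and Newick export.

All tabular exchange formats are tab-separated, UTF-8, dot-decimal, with a
mandatory header row.  ``read_table`` validates required columns and numeric
cells up front and reports the offending row and column, so malformed input
fails loudly at the boundary instead of deep inside an analysis.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

__all__ = ["SchemaError", "read_table", "write_table", "write_newick"]

# column -> dtype kind ("numeric" | "integer" | "string") per known schema
SCHEMAS: dict[str, dict[str, str]] = {
    "colony_counts": {
        "sample_id": "string",
        "land_use": "string",
        "season": "string",
        "replicate": "integer",
        "day1": "integer",
        "day2": "integer",
        "day6": "integer",
        "dilution_exponent": "integer",
    },
    "band_table": {
        "lane_id": "string",
        "rf": "numeric",
        "height": "numeric",
    },
    "chemistry": {
        "sample_id": "string",
        "C_org": "numeric",
        "C_ext": "numeric",
        "C_HAFA": "numeric",
        "C_mic": "numeric",
    },
    "respiration": {
        "sample_id": "string",
        "day": "numeric",
        "cumulative_CO2_C": "numeric",
    },
}


class SchemaError(ValueError):
    """A table does not match its declared schema."""


def _maybe_numeric(col: pd.Series) -> pd.Series:
    try:
        return pd.to_numeric(col)
    except (ValueError, TypeError):
        return col


def read_table(
    path: str | Path,
    schema: str | Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Read a TSV table, validating against a named or inline schema.

    Unknown columns are preserved untouched.  A missing required column or a
    non-numeric cell in a numeric column raises :class:`SchemaError` naming
    the column (and row, for cell errors).
    """
    spec: Mapping[str, str] | None
    if isinstance(schema, str):
        if schema not in SCHEMAS:
            raise SchemaError(f"unknown schema {schema!r}")
        spec = SCHEMAS[schema]
    else:
        spec = schema
    df = pd.read_csv(path, sep="\t", dtype=str)
    if spec is None:
        return df.apply(_maybe_numeric)
    missing = [c for c in spec if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    for col, kind in spec.items():
        if kind == "string":
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[converted.isna() & df[col].notna()]
        if len(bad) > 0:
            row = int(bad[0])
            raise SchemaError(
                f"{path}: malformed numeric cell in column {col!r}, "
                f"row {row + 2} (value {df.loc[row, col]!r})"
            )
        if converted.isna().any():
            row = int(df.index[converted.isna()][0])
            raise SchemaError(f"{path}: empty cell in column {col!r}, row {row + 2}")
        df[col] = converted.astype(int) if kind == "integer" else converted
    # convert any extra columns that happen to be numeric
    for col in df.columns:
        if col not in spec:
            df[col] = _maybe_numeric(df[col])
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a TSV with full float precision (round-trip safe)."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def write_newick(newick: str, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(newick + "\n", encoding="utf-8")


def write_matrix(
    values, labels: Sequence[str], path: str | Path
) -> None:
    """Write a labeled square matrix (e.g. distances) as TSV."""
    df = pd.DataFrame(values, index=list(labels), columns=list(labels))
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label="id", float_format="%.17g")
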