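"""Delimited-table I/O with declared schemas.

All pipeline tables are tab-separated UTF-8 text with a header row and
``.`` for missing values — the convention of proteomics/transcriptomics
result tables.  A schema maps required column names to semantic types
(``str``, ``int``, ``float``); unknown columns pass through untouched so
annotation columns survive a round trip.
"""

from __future__ import annotations

import decimal
from typing import Mapping

import numpy as np
import pandas as pd

MISSING = "."


class SchemaError(ValueError):
    """A table does not conform to its declared schema."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (78.05 -> 78.1), not banker's rounding."""
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP))


def _coerce(df: pd.DataFrame, schema: Mapping[str, str], path: str) -> pd.DataFrame:
    names = {str: "str", int: "int", float: "float"}
    for col, kind in schema.items():
        kind = names.get(kind, kind)
        if kind not in ("str", "int", "float"):
            raise SchemaError(f"{path}: unknown schema type {kind!r} for column {col!r}")
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required column {col!r}")
        if kind == "str":
            df[col] = df[col].astype("string")
            continue
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise SchemaError(
                f"{path}: malformed numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, row {row + 2} (1-based, incl. header)"
            )
        df[col] = coerced.astype("Int64") if kind == "int" else coerced.astype(float)
    return df


def read_table(path, schema: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Read a TSV table, validating and typing ``schema`` columns."""
    df = pd.read_csv(
        path, sep="\t", dtype="string", na_values=[MISSING], keep_default_na=False
    )
    if schema:
        df = _coerce(df, schema, str(path))
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV table; missing values become ``.``."""
    df.to_csv(path, sep="\t", index=False, na_rep=MISSING)
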