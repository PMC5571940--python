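"""Abundance-table input/output.

Canonical table: one row per sampling point x date with columns
``field, site, date, count, x, y`` — count is the number of pollen beetles
per ten plants, x/y are planar metric coordinates (m), date is the weekly
index 1..T.  The reader also accepts the column names used by the published
supplementary abundance spreadsheet and maps them onto the canonical header.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

CANONICAL_COLUMNS = ["field", "site", "date", "count", "x", "y"]

# lower-cased, stripped header aliases -> canonical name
_ALIASES = {
    "field": "field",
    "site": "site",
    "date": "date",
    "count": "count",
    "pollen beetles number": "count",
    "pollen beetle number": "count",
    "number of pollen beetles": "count",
    "x": "x",
    "y": "y",
}


def _normalize_columns(df: pd.DataFrame) -> pd.DataFrame:
    mapping = {}
    for col in df.columns:
        key = str(col).strip().lower().replace("_", " ")
        key = " ".join(key.split())
        if key in _ALIASES:
            mapping[col] = _ALIASES[key]
    df = df.rename(columns=mapping)
    missing = [c for c in CANONICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"abundance table missing columns: {missing}")
    return df[CANONICAL_COLUMNS].copy()


def _map_dates(dates: pd.Series) -> pd.Series:
    """Map the date column to integer indices 1..T.

    Integer-valued input is used as-is; anything else (ISO dates, labels)
    is mapped to 1..T by sorted order of the distinct values.
    """
    numeric = pd.to_numeric(dates, errors="coerce")
    if numeric.notna().all() and np.allclose(numeric, np.round(numeric)):
        return numeric.astype(int)
    parsed = pd.to_datetime(dates, errors="coerce")
    key = parsed if parsed.notna().all() else dates.astype(str)
    levels = sorted(key.unique())
    lookup = {lev: i + 1 for i, lev in enumerate(levels)}
    return key.map(lookup).astype(int)


def validate_abundance(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and coerce an abundance table to canonical dtypes.

    Errors name the offending rows (0-based, in table order).
    """
    df = _normalize_columns(df)
    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = df.index[counts.isna() | (counts < 0) | (counts != np.round(counts))]
    if len(bad):
        raise ValueError(
            f"count must be a non-negative integer; bad rows: {list(bad[:10])}"
        )
    for coord in ("x", "y"):
        vals = pd.to_numeric(df[coord], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(f"{coord} must be numeric; bad rows: {list(bad[:10])}")
        df[coord] = vals.astype(float)
    df["count"] = counts.astype(int)
    df["date"] = _map_dates(df["date"])
    df["field"] = df["field"].astype(str)
    df["site"] = df["site"].astype(str)
    return df.reset_index(drop=True)


def read_abundance(path) -> pd.DataFrame:
    """Read an abundance table from CSV or XLSX and validate it."""
    p = str(path)
    if p.endswith((".xlsx", ".xls")):
        raw = pd.read_excel(path)
    else:
        raw = pd.read_csv(path)
    return validate_abundance(raw)


def write_abundance(df: pd.DataFrame, path) -> None:
    """Write an abundance table with the canonical header."""
    validate_abundance(df).to_csv(path, index=False)
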