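"""Descriptive summaries of abundance tables."""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
import pandas as pd

from .io import validate_abundance
from .landscape import WoodRaster

_GROUPINGS = {
    "site": ["site"],
    "date": ["date"],
    "field": ["field"],
    "site×date": ["site", "date"],
    "site:date": ["site", "date"],
}


class UnitCounts(NamedTuple):
    n_sites: int
    n_fields: int
    n_points: int
    n_dates: int


def _agg(df: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    g = df.groupby(keys, sort=True)["count"]
    out = g.agg(mean="mean", sd=lambda x: x.std(ddof=1), n="count").reset_index()
    return out


def summarize_abundance(table: pd.DataFrame, by: str = "site×date") -> pd.DataFrame:
    """Per-group mean, sample SD (denominator n-1) and n of the counts.

    For site-by-date groupings an all-dates row per site and a grand row
    are appended (labelled "all").
    """
    df = validate_abundance(table)
    if df.empty:
        raise ValueError("empty abundance table")
    if by not in _GROUPINGS:
        raise ValueError(f"unknown grouping {by!r}; choose from {sorted(_GROUPINGS)}")
    keys = _GROUPINGS[by]
    out = _agg(df, keys)
    if len(keys) == 2:
        per_site = _agg(df, ["site"]).assign(date="all")
        grand = pd.DataFrame(
            {
                "site": ["all"],
                "date": ["all"],
                "mean": [df["count"].mean()],
                "sd": [df["count"].std(ddof=1)],
                "n": [len(df)],
            }
        )
        out = pd.concat(
            [out.astype({"date": object}), per_site, grand], ignore_index=True
        )
    return out


def total_count(table: pd.DataFrame) -> int:
    """Total number of individuals captured."""
    df = validate_abundance(table)
    if df.empty:
        raise ValueError("empty abundance table")
    return int(df["count"].sum())


def count_units(table: pd.DataFrame) -> UnitCounts:
    """Distinct sites, fields, sampling points and dates."""
    df = validate_abundance(table)
    if df.empty:
        raise ValueError("empty abundance table")
    n_points = len(df[["field", "x", "y"]].drop_duplicates())
    return UnitCounts(
        n_sites=df["site"].nunique(),
        n_fields=df["field"].nunique(),
        n_points=n_points,
        n_dates=df["date"].nunique(),
    )


def distance_profile(table: pd.DataFrame, raster: WoodRaster, bins) -> pd.DataFrame:
    """Mean count by distance-to-nearest-woodland bin.

    Distance is to the nearest pixel center with positive wooded area (m).
    ``bins`` are ordered edges; rows outside them are dropped.
    """
    df = validate_abundance(table)
    bins = np.asarray(bins, dtype=float)
    if len(bins) < 2 or (np.diff(bins) <= 0).any():
        raise ValueError("bins must be ordered edges")
    wooded = raster.area_total > 0
    wx, wy = raster.x[wooded], raster.y[wooded]
    if len(wx) == 0:
        raise ValueError("raster has no wooded pixels")
    d = np.empty(len(df))
    for i, (x, y) in enumerate(zip(df["x"], df["y"])):
        d[i] = np.min(np.hypot(wx - x, wy - y))
    idx = np.digitize(d, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        sel = idx == b
        if sel.any():
            rows.append(
                {
                    "bin_left": bins[b],
                    "bin_right": bins[b + 1],
                    "mean": float(df.loc[sel, "count"].mean()),
                    "n": int(sel.sum()),
                }
            )
    return pd.DataFrame(rows)
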