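"""Occurrence-record quality control.

Raw georeferenced records are cleaned in a fixed chain before any
modelling: taxonomic name resolution against an accepted-name list,
rejection of points falling outside the species' expert range polygon,
removal of coarse-resolution records (> 2 km by default), assignment to a
temporal period (pre/post a cutoff year, default 1950), and grid-cell
deduplication that keeps records observed in *different* periods.

Records travel as pandas DataFrames with columns
``species, lon, lat, year, precision_km, source`` (plus ``period`` once
assigned). Every filter returns a subset of its input — nothing is ever
fabricated — and each one reports how many rows it dropped via the
returned frame's ``attrs``.
"""

from __future__ import annotations

import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import nearest_points

from .env_stack import GridSpec

__all__ = [
    "REQUIRED_COLUMNS",
    "load_occurrences",
    "resolve_taxonomy",
    "filter_by_range_polygon",
    "filter_resolution",
    "assign_period",
    "deduplicate",
    "run_qc_chain",
    "haversine_km",
]

REQUIRED_COLUMNS = ["species", "lon", "lat", "year", "precision_km", "source"]

EARTH_RADIUS_KM = 6371.0088  # mean Earth radius


def haversine_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km between points in decimal degrees."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float)) for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0, 1)))


def load_occurrences(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"occurrence CSV missing columns: {sorted(missing)}")
    bad_lon = (df["lon"] < -180) | (df["lon"] > 180)
    bad_lat = (df["lat"] < -90) | (df["lat"] > 90)
    if bad_lon.any() or bad_lat.any():
        raise ValueError("coordinates outside WGS84 bounds")
    return df


def resolve_taxonomy(
    records: pd.DataFrame,
    accepted_names: set[str],
    synonym_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Keep records whose name is accepted or maps to an accepted name.

    Synonyms are remapped onto the accepted name; anything matching neither
    list is rejected. The number of rejected rows is reported in
    ``attrs['n_dropped_taxonomy']``.
    """
    if not accepted_names:
        raise ValueError("accepted_names must be non-empty")
    synonym_map = dict(synonym_map or {})
    bad_targets = set(synonym_map.values()) - set(accepted_names)
    if bad_targets:
        raise ValueError(f"synonym_map targets not in accepted_names: {sorted(bad_targets)}")
    names = records["species"]
    remapped = names.map(lambda n: synonym_map.get(n, n))
    keep = remapped.isin(accepted_names)
    out = records.loc[keep].copy()
    out["species"] = remapped.loc[keep]
    out.attrs["n_dropped_taxonomy"] = int((~keep).sum())
    return out


def filter_by_range_polygon(
    records: pd.DataFrame,
    polygon: BaseGeometry,
    tolerance_km: float = 0.0,
) -> pd.DataFrame:
    """Drop records outside the range polygon (plus a km tolerance belt).

    Containment is exact; the tolerance is a great-circle distance from the
    point to the nearest vertex-interpolated location on the polygon
    boundary (computed via shapely nearest-point then haversine).
    """
    if polygon.is_empty:
        raise ValueError("range polygon is empty")
    if not polygon.is_valid:
        raise ValueError("range polygon is invalid (self-intersecting?)")
    pts_x = records["lon"].to_numpy(dtype=float)
    pts_y = records["lat"].to_numpy(dtype=float)
    inside = shapely.contains_xy(polygon, pts_x, pts_y) | shapely.intersects_xy(polygon, pts_x, pts_y)
    keep = inside.copy()
    if tolerance_km > 0:
        boundary = polygon.boundary
        for i in np.nonzero(~inside)[0]:
            p = shapely.Point(pts_x[i], pts_y[i])
            nearest = nearest_points(boundary, p)[0]
            d = float(haversine_km(pts_x[i], pts_y[i], nearest.x, nearest.y))
            if d <= tolerance_km:
                keep[i] = True
    out = records.loc[keep].copy()
    out.attrs["n_dropped_range"] = int((~keep).sum())
    return out


def filter_resolution(
    records: pd.DataFrame,
    max_precision_km: float = 2.0,
    keep_missing: bool = False,
) -> pd.DataFrame:
    """Remove records coarser than ``max_precision_km`` (boundary inclusive).

    Records with missing precision are dropped by default (conservative);
    set ``keep_missing=True`` to retain them.
    """
    if max_precision_km <= 0:
        raise ValueError("max_precision_km must be positive")
    prec = records["precision_km"]
    keep = prec <= max_precision_km
    if keep_missing:
        keep = keep | prec.isna()
    out = records.loc[keep].copy()
    out.attrs["n_dropped_resolution"] = int((~keep).sum())
    return out


def assign_period(
    records: pd.DataFrame,
    cutoff_year: int = 1950,
    missing_year: str = "drop",
) -> pd.DataFrame:
    """Tag each record pre/post the cutoff year.

    ``year < cutoff`` -> ``pre1950``-style label, ``year >= cutoff`` ->
    ``post1950``. Missing years are dropped (default) or assigned to the
    recent period with ``missing_year='post'``.
    """
    if missing_year not in ("drop", "post"):
        raise ValueError("missing_year must be 'drop' or 'post'")
    pre_label = f"pre{cutoff_year}"
    post_label = f"post{cutoff_year}"
    out = records.copy()
    year = out["year"]
    if missing_year == "drop":
        n_missing = int(year.isna().sum())
        out = out.loc[year.notna()].copy()
        out["period"] = np.where(out["year"] < cutoff_year, pre_label, post_label)
        out.attrs["n_dropped_no_year"] = n_missing
    else:
        period = np.where(year.isna(), post_label, np.where(year < cutoff_year, pre_label, post_label))
        out["period"] = period
        out.attrs["n_dropped_no_year"] = 0
    return out


def deduplicate(records: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Collapse to one record per (species, grid cell, period).

    "Duplicate" means the same cell of the working grid; records from
    different temporal periods in the same cell are both retained. Within a
    duplicate group the earliest-year record wins, ties broken by
    lexicographic source, so output is deterministic and order-free.
    """
    if "period" not in records.columns:
        raise ValueError("records must carry periods before deduplication")
    out = records.copy()
    row, col = grid.cell_of(out["lon"].to_numpy(), out["lat"].to_numpy())
    out["_row"], out["_col"] = row, col
    out["_src"] = out["source"].astype(str)
    out = out.sort_values(["species", "_row", "_col", "period", "year", "_src"], kind="mergesort")
    dedup = out.drop_duplicates(subset=["species", "_row", "_col", "period"], keep="first")
    n_dropped = len(out) - len(dedup)
    dedup = dedup.drop(columns=["_row", "_col", "_src"]).sort_index()
    dedup.attrs["n_dropped_duplicates"] = n_dropped
    return dedup


def run_qc_chain(
    records: pd.DataFrame,
    accepted_names: set[str],
    grid: GridSpec,
    synonym_map: Mapping[str, str] | None = None,
    range_polygons: Mapping[str, BaseGeometry] | None = None,
    tolerance_km: float = 0.0,
    max_precision_km: float = 2.0,
    cutoff_year: int = 1950,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full QC chain; returns (clean records, per-species report).

    Chain order: taxonomy -> range polygon -> resolution -> period ->
    grid-cell deduplication. The chain is idempotent: a second pass over
    its own output drops nothing.
    """
    report_rows = []
    stages = {}
    rec = resolve_taxonomy(records, accepted_names, synonym_map)
    stages["taxonomy"] = rec.attrs.get("n_dropped_taxonomy", 0)
    if range_polygons:
        kept = []
        n_dropped_range = 0
        for sp, sub in rec.groupby("species", sort=False):
            poly = range_polygons.get(sp)
            if poly is None:
                warnings.warn(f"no range polygon for {sp}; records kept unfiltered")
                kept.append(sub)
                continue
            filt = filter_by_range_polygon(sub, poly, tolerance_km)
            n_dropped_range += filt.attrs.get("n_dropped_range", 0)
            kept.append(filt)
        rec = pd.concat(kept, ignore_index=False) if kept else rec.iloc[0:0]
        stages["range"] = n_dropped_range
    else:
        stages["range"] = 0
    rec = filter_resolution(rec, max_precision_km)
    stages["resolution"] = rec.attrs.get("n_dropped_resolution", 0)
    rec = assign_period(rec, cutoff_year)
    stages["no_year"] = rec.attrs.get("n_dropped_no_year", 0)
    rec = deduplicate(rec, grid)
    stages["duplicates"] = rec.attrs.get("n_dropped_duplicates", 0)

    for sp, sub in rec.groupby("species"):
        counts = sub["period"].value_counts()
        report_rows.append(
            {
                "species": sp,
                "n_records": len(sub),
                f"n_pre{cutoff_year}": int(counts.get(f"pre{cutoff_year}", 0)),
                f"n_post{cutoff_year}": int(counts.get(f"post{cutoff_year}", 0)),
            }
        )
    report = pd.DataFrame(report_rows)
    for stage, n in stages.items():
        report.attrs[f"n_dropped_{stage}"] = n
    rec = rec.reset_index(drop=True)
    rec.attrs["qc_dropped"] = stages
    return rec, report
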