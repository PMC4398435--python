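"""Geographic post-processing of predictions.

Covers the land-class habitat restriction, the minimum convex polygon
(MCP) of a species' records, outward buffering of the MCP by a dispersal
distance in kilometres, the elapsed-years rule that grows the buffer for
future scenario years (annual dispersal rate x years since 1975, the
midpoint of the 1950-2000 baseline), and clipping of prediction rasters to
the buffered accessibility region by cell-center containment.

Buffering is done in a spherical azimuthal-equidistant projection centred
on the geometry's centroid, so "kilometres" means kilometres at any
latitude rather than degrees-as-distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import shapely
from shapely.geometry import MultiPoint, Point
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform

from .env_stack import EnvStack, GridSpec
from .occurrence_qc import EARTH_RADIUS_KM

__all__ = [
    "DispersalSpec",
    "ClipRegion",
    "land_class_mask",
    "minimum_convex_polygon",
    "buffer_km",
    "future_buffer_distance",
    "clip_map",
    "build_clip_region",
]


@dataclass(frozen=True)
class DispersalSpec:
    species: str
    annual_distance_km: float
    provenance: Literal["observed", "literature", "group_average"] = "literature"

    def __post_init__(self):
        if self.annual_distance_km <= 0:
            raise ValueError("annual dispersal distance must be positive")


def load_dispersal_table(path) -> dict[str, DispersalSpec]:
    """Read a dispersal CSV (`species,annual_km,provenance`)."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"species", "annual_km", "provenance"} - set(df.columns)
    if missing:
        raise ValueError(f"dispersal CSV missing columns: {sorted(missing)}")
    return {
        row.species: DispersalSpec(row.species, float(row.annual_km), row.provenance)
        for row in df.itertuples()
    }


@dataclass
class ClipRegion:
    mcp: BaseGeometry
    current_buffer_km: float
    future_buffer_km: dict[str, float]
    degenerate: bool = False  # <3 non-collinear records

    def region(self, buffer_distance_km: float) -> BaseGeometry:
        return buffer_km(self.mcp, buffer_distance_km)


# ---------------------------------------------------------------------------
# Habitat restriction
# ---------------------------------------------------------------------------

def land_class_mask(
    suitability: np.ndarray,
    land_cover: np.ndarray,
    grid: GridSpec,
    record_lon,
    record_lat,
) -> tuple[np.ndarray, set[int]]:
    """Zero suitability on land classes the species does not occupy.

    Occupied classes are those of the land-cover cells holding at least
    one occurrence record. Records on nodata land cover are ignored for
    class collection with a warning. Returns (masked map, occupied classes).
    """
    if land_cover.shape != suitability.shape:
        raise ValueError("land cover and suitability rasters not co-registered")
    row, col = grid.cell_of(record_lon, record_lat)
    inside = grid.inside(row, col)
    classes_at = land_cover[row[inside], col[inside]]
    n_nodata = int(np.isnan(classes_at).sum())
    if n_nodata:
        warnings.warn(f"{n_nodata} records on nodata land cover ignored for class collection")
    occupied = set(int(c) for c in classes_at[~np.isnan(classes_at)])
    keep = np.isin(np.where(np.isnan(land_cover), -(10**9), land_cover).astype(int), list(occupied))
    out = np.where(keep, suitability, 0.0)
    out = np.where(np.isnan(suitability), np.nan, out)
    return out, occupied


# ---------------------------------------------------------------------------
# Minimum convex polygon
# ---------------------------------------------------------------------------

def minimum_convex_polygon(
    lon, lat, fallback_buffer_deg: float = 0.0
) -> tuple[BaseGeometry, bool]:
    """Convex hull of occurrence points; returns (geometry, degenerate).

    With fewer than 3 distinct non-collinear points the hull degenerates
    to a point or line; it is then buffered by ``fallback_buffer_deg``
    (typically one cell) and flagged.
    """
    pts = MultiPoint(list(zip(np.asarray(lon, float), np.asarray(lat, float))))
    hull = pts.convex_hull
    if hull.geom_type == "Polygon":
        return hull, False
    return hull.buffer(max(fallback_buffer_deg, 1e-9)), True


# ---------------------------------------------------------------------------
# Geodesic-approximate buffering (spherical AEQD)
# ---------------------------------------------------------------------------

def _aeqd_forward(lon0: float, lat0: float):
    """Forward spherical azimuthal-equidistant projection (km) at a center."""
    lam0, phi0 = np.radians(lon0), np.radians(lat0)

    def fwd(lon, lat):
        lam, phi = np.radians(np.asarray(lon, float)), np.radians(np.asarray(lat, float))
        cos_c = np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam - lam0)
        cos_c = np.clip(cos_c, -1.0, 1.0)
        c = np.arccos(cos_c)
        k = np.where(c > 1e-12, c / np.maximum(np.sin(c), 1e-300), 1.0)
        x = EARTH_RADIUS_KM * k * np.cos(phi) * np.sin(lam - lam0)
        y = EARTH_RADIUS_KM * k * (
            np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam - lam0)
        )
        return x, y

    return fwd


def _aeqd_inverse(lon0: float, lat0: float):
    lam0, phi0 = np.radians(lon0), np.radians(lat0)

    def inv(x, y):
        x = np.asarray(x, float)
        y = np.asarray(y, float)
        rho = np.hypot(x, y)
        c = rho / EARTH_RADIUS_KM
        with np.errstate(invalid="ignore", divide="ignore"):
            sin_c, cos_c = np.sin(c), np.cos(c)
            phi = np.arcsin(
                np.clip(cos_c * np.sin(phi0) + np.where(rho > 0, y * sin_c * np.cos(phi0) / np.maximum(rho, 1e-300), 0.0), -1, 1)
            )
            lam = lam0 + np.arctan2(
                x * sin_c, rho * np.cos(phi0) * cos_c - y * np.sin(phi0) * sin_c
            )
        phi = np.where(rho > 0, phi, phi0)
        lam = np.where(rho > 0, lam, lam0)
        return np.degrees(lam), np.degrees(phi)

    return inv


def buffer_km(
    geometry: BaseGeometry,
    distance_km: float,
    quad_segs: int = 64,
    antimeridian: Literal["error", "clip"] = "error",
) -> BaseGeometry:
    """Outward buffer in kilometres via a centroid-centred AEQD projection.

    distance 0 returns the geometry unchanged. Results whose longitudes
    leave [-180, 180] either raise (default) or are clipped to the world
    rectangle with ``antimeridian='clip'``.
    """
    if distance_km < 0:
        raise ValueError("buffer distance must be non-negative")
    if distance_km == 0:
        return geometry
    c = geometry.centroid
    fwd, inv = _aeqd_forward(c.x, c.y), _aeqd_inverse(c.x, c.y)
    projected = transform(fwd, geometry)
    buffered = projected.buffer(distance_km, quad_segs=quad_segs)
    out = transform(inv, buffered)
    minx, _, maxx, _ = out.bounds
    if minx < -180 or maxx > 180:
        if antimeridian == "error":
            raise ValueError("buffer crosses the antimeridian; no split handling configured")
        out = out.intersection(shapely.box(-180, -90, 180, 90))
    return out


def future_buffer_distance(dispersal: DispersalSpec, target_year: int, baseline_year: int = 1975) -> float:
    """Dispersal-constrained reach: annual rate x years since the baseline.

    The baseline is the midpoint of the 1950-2000 reference period. Target
    years at or before it give 0 km with a warning.
    """
    if target_year <= baseline_year:
        warnings.warn(f"target year {target_year} <= baseline {baseline_year}; buffer 0 km")
        return 0.0
    return dispersal.annual_distance_km * (target_year - baseline_year)


def build_clip_region(
    lon,
    lat,
    dispersal: DispersalSpec,
    scenario_years: dict[str, int],
    current_multiplier_years: float = 1.0,
    cell_size_deg: float = 0.0,
) -> ClipRegion:
    """MCP of the records plus current and per-scenario buffer distances.

    The current-model clip buffer is the annual dispersal distance times
    ``current_multiplier_years`` (default one year); future buffers add the
    elapsed-years rule on top of the current buffer.
    """
    mcp, degenerate = minimum_convex_polygon(lon, lat, fallback_buffer_deg=cell_size_deg)
    current = dispersal.annual_distance_km * current_multiplier_years
    future = {
        label: current + future_buffer_distance(dispersal, year)
        for label, year in scenario_years.items()
    }
    return ClipRegion(mcp=mcp, current_buffer_km=current, future_buffer_km=future, degenerate=degenerate)


def clip_map(values: np.ndarray, grid: GridSpec, polygon: BaseGeometry) -> np.ndarray:
    """Zero every cell whose center falls outside the polygon.

    Works for binary or continuous maps; nodata cells stay nodata. An
    empty intersection yields an all-absence map with a warning.
    """
    lons = grid.col_longitudes()
    lats = grid.row_latitudes()
    lon_g, lat_g = np.meshgrid(lons, lats)
    inside = shapely.contains_xy(polygon, lon_g.ravel(), lat_g.ravel()).reshape(values.shape)
    out = np.where(inside, values, 0.0)
    out = np.where(np.isnan(values), np.nan, out)
    if not inside.any():
        warnings.warn("clip polygon does not intersect the grid; all-absence map")
    return out
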