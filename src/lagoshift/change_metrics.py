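"""Per-period range metrics, between-period change, and richness rasters.

Range size is the sum of presence-cell areas on the sphere (cell areas
shrink with cos(latitude)); mean latitude is area-weighted; elevation
statistics are taken over presence cells of a co-registered elevation
raster. Change between two periods is expressed as percentage range
change, degrees of poleward movement (sign flipped in the southern
hemisphere so "+" always means toward the pole), and metres of elevation
change.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .env_stack import GridSpec
from .occurrence_qc import EARTH_RADIUS_KM

__all__ = [
    "RangeMetrics",
    "ChangeSummary",
    "cell_areas_km2",
    "range_metrics",
    "change_summary",
    "richness_map",
    "richness_change",
]


@dataclass(frozen=True)
class RangeMetrics:
    period: str
    area_km2: float
    mean_latitude: float
    min_latitude: float
    max_latitude: float
    min_longitude: float
    max_longitude: float
    min_elev: float
    mean_elev: float
    max_elev: float
    n_cells: int

    @property
    def extinct(self) -> bool:
        return self.n_cells == 0


@dataclass(frozen=True)
class ChangeSummary:
    species: str
    range_change_pct: float
    poleward_deg: float
    min_elev_change_m: float
    mean_elev_change_m: float
    max_elev_change_m: float
    hemisphere: str
    extinct: bool = False
    hemisphere_ambiguous: bool = False


def cell_areas_km2(grid: GridSpec) -> np.ndarray:
    """Per-row cell area on the sphere: R^2 dlambda (sin(top) - sin(bottom))."""
    dlam = np.radians(grid.cell_size)
    lat_top = np.radians(grid.y_origin - np.arange(grid.n_rows) * grid.cell_size)
    lat_bot = lat_top - np.radians(grid.cell_size)
    return EARTH_RADIUS_KM**2 * dlam * (np.sin(lat_top) - np.sin(lat_bot))


def range_metrics(
    binary_map: np.ndarray, grid: GridSpec, elevation: np.ndarray, period: str = ""
) -> RangeMetrics:
    """Area, area-weighted mean latitude, and elevation stats of a range.

    A map with zero presence cells yields NaN metrics and is flagged
    extinct-in-scenario via ``n_cells == 0``.
    """
    if elevation.shape != binary_map.shape:
        raise ValueError("elevation raster not co-registered with binary map")
    present = np.nan_to_num(binary_map, nan=0.0) > 0
    n = int(present.sum())
    if n == 0:
        return RangeMetrics(period, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan,
                            np.nan, np.nan, np.nan, 0)
    row_area = cell_areas_km2(grid)
    rows, cols = np.nonzero(present)
    areas = row_area[rows]
    lats = grid.row_latitudes()[rows]
    elevs = elevation[rows, cols]
    return RangeMetrics(
        period=period,
        area_km2=float(areas.sum()),
        mean_latitude=float(np.average(lats, weights=areas)),
        min_latitude=float(lats.min()),
        max_latitude=float(lats.max()),
        min_longitude=float(grid.col_longitudes()[cols].min()),
        max_longitude=float(grid.col_longitudes()[cols].max()),
        min_elev=float(np.nanmin(elevs)),
        mean_elev=float(np.nanmean(elevs)),
        max_elev=float(np.nanmax(elevs)),
        n_cells=n,
    )


def change_summary(
    species: str,
    metrics_t0: RangeMetrics,
    metrics_t1: RangeMetrics,
    hemisphere: str | None = None,
) -> ChangeSummary:
    """Between-period change with the poleward sign convention.

    hemisphere 'N' or 'S'; if None it is inferred from the sign of the
    baseline mean latitude (flagged ambiguous when the baseline range is
    within half a degree of the equator). A species with no presence cells
    in the later period is reported as -100% range change with undefined
    latitude/elevation changes.
    """
    if metrics_t0.extinct:
        raise ValueError(f"{species}: no baseline range; change undefined")
    ambiguous = False
    if hemisphere is None:
        ambiguous = abs(metrics_t0.mean_latitude) < 0.5
        hemisphere = "N" if metrics_t0.mean_latitude >= 0 else "S"
        if ambiguous:
            warnings.warn(
                f"{species}: range straddles the equator; hemisphere taken from "
                "the larger area fraction"
            )
    sign = 1.0 if hemisphere == "N" else -1.0
    if metrics_t1.extinct:
        return ChangeSummary(
            species=species,
            range_change_pct=-100.0,
            poleward_deg=np.nan,
            min_elev_change_m=np.nan,
            mean_elev_change_m=np.nan,
            max_elev_change_m=np.nan,
            hemisphere=hemisphere,
            extinct=True,
            hemisphere_ambiguous=ambiguous,
        )
    return ChangeSummary(
        species=species,
        range_change_pct=100.0 * (metrics_t1.area_km2 - metrics_t0.area_km2) / metrics_t0.area_km2,
        poleward_deg=sign * (metrics_t1.mean_latitude - metrics_t0.mean_latitude),
        min_elev_change_m=metrics_t1.min_elev - metrics_t0.min_elev,
        mean_elev_change_m=metrics_t1.mean_elev - metrics_t0.mean_elev,
        max_elev_change_m=metrics_t1.max_elev - metrics_t0.max_elev,
        hemisphere=hemisphere,
        hemisphere_ambiguous=ambiguous,
    )


def richness_map(binary_maps: Mapping[str, np.ndarray]) -> np.ndarray:
    """Per-cell count of species predicted present."""
    maps = list(binary_maps.values())
    if not maps:
        raise ValueError("no maps")
    shape = maps[0].shape
    out = np.zeros(shape, dtype=float)
    for m in maps:
        if m.shape != shape:
            raise ValueError("richness inputs not co-registered")
        out += np.nan_to_num(m, nan=0.0) > 0
    return out


def richness_change(
    past_maps: Mapping[str, np.ndarray],
    future_maps: Mapping[str, np.ndarray],
    unmodellable_maps: Mapping[str, np.ndarray] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """(future - past) richness plus an uncertainty mask.

    The mask marks cells occupied only by unmodellable species, whose
    outcome the analysis cannot resolve.
    """
    past = richness_map(past_maps)
    future = richness_map(future_maps)
    change = future - past
    if unmodellable_maps:
        unmod = richness_map(unmodellable_maps)
        modelled_any = (past > 0) | (future > 0)
        uncertain = (unmod > 0) & ~modelled_any
    else:
        uncertain = np.zeros_like(change, dtype=bool)
    return change, uncertain
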