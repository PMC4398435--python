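"""Co-registered environmental raster stacks and samples-with-data extraction.

Rasters are plain 2D float arrays on a geographic (WGS84) grid with
cell-center registration: row 0 is the northernmost row, and a point maps to
the cell whose half-open interval [edge, edge + cell_size) contains it.
Nodata is represented as NaN in memory and round-trips through ESRI
ASCII-grid (.asc) files, a single-band text format readable by any GIS.

No resampling or reprojection happens anywhere in this module: stacks whose
layers disagree on the grid are rejected outright rather than silently
aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "EnvStack",
    "GridMismatchError",
    "read_ascii_grid",
    "write_ascii_grid",
    "load_stack",
    "derive_layer",
    "extract_swd",
]


class GridMismatchError(ValueError):
    """Raised when layers that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a geographic raster grid.

    ``x_origin``/``y_origin`` are the *outer edges* of the top-left cell
    (west edge of column 0, north edge of row 0). ``cell_size`` is in
    decimal degrees and is shared by both axes.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    x_origin: float
    y_origin: float

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    # -- point <-> cell mapping (half-open cell intervals) ------------------

    def cell_of(self, lon, lat):
        """Return (row, col) arrays for points; half-open convention."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.x_origin) / self.cell_size).astype(int)
        row = np.floor((self.y_origin - lat) / self.cell_size).astype(int)
        return row, col

    def inside(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col):
        """Return (lon, lat) of cell centers."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        lon = self.x_origin + (col + 0.5) * self.cell_size
        lat = self.y_origin - (row + 0.5) * self.cell_size
        return lon, lat

    def row_latitudes(self) -> np.ndarray:
        """Latitudes of row centers, north to south."""
        rows = np.arange(self.n_rows)
        return self.y_origin - (rows + 0.5) * self.cell_size

    def col_longitudes(self) -> np.ndarray:
        cols = np.arange(self.n_cols)
        return self.x_origin + (cols + 0.5) * self.cell_size


@dataclass
class EnvStack:
    """A named set of co-registered environmental layers for one period."""

    period_label: str
    grid: GridSpec
    layers: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        for name, arr in self.layers.items():
            self._check_layer(name, arr)

    def _check_layer(self, name: str, arr: np.ndarray):
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (self.grid.n_rows, self.grid.n_cols):
            raise GridMismatchError(
                f"layer {name!r} has shape {arr.shape}, grid expects "
                f"{(self.grid.n_rows, self.grid.n_cols)}"
            )
        self.layers[name] = arr

    def add_layer(self, name: str, arr: np.ndarray):
        self._check_layer(name, arr)

    @property
    def variable_names(self) -> list[str]:
        return list(self.layers)

    def nodata_mask(self) -> np.ndarray:
        """True where any layer is nodata (masks propagate across layers)."""
        mask = np.zeros((self.grid.n_rows, self.grid.n_cols), dtype=bool)
        for arr in self.layers.values():
            mask |= np.isnan(arr)
        return mask

    def values_at(self, lon, lat, variables: Iterable[str] | None = None):
        """Sample layers at points. Returns (DataFrame, valid_mask).

        Points outside the grid or on a nodata cell of any requested layer
        are marked invalid (their rows contain NaN).
        """
        variables = list(variables) if variables is not None else self.variable_names
        row, col = self.grid.cell_of(lon, lat)
        ok = self.grid.inside(row, col)
        out = {}
        rs = np.clip(row, 0, self.grid.n_rows - 1)
        cs = np.clip(col, 0, self.grid.n_cols - 1)
        for name in variables:
            vals = self.layers[name][rs, cs]
            vals = np.where(ok, vals, np.nan)
            out[name] = vals
        df = pd.DataFrame(out)
        valid = ok & ~df.isna().any(axis=1).to_numpy()
        return df, valid


# ---------------------------------------------------------------------------
# ESRI ASCII grid I/O
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def read_ascii_grid(path) -> tuple[GridSpec, np.ndarray]:
    """Read a single-band ESRI ASCII grid; nodata becomes NaN."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in (
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value",
            ):
                header[parts[0].lower()] = float(parts[1])
            else:
                fh.seek(pos)
                break
        data = np.loadtxt(fh, dtype=float, ndmin=2)
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"{path}: missing ASCII grid header field {key!r}")
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if data.shape != (n_rows, n_cols):
        raise ValueError(f"{path}: data shape {data.shape} != header {(n_rows, n_cols)}")
    nodata = header.get("nodata_value", _NODATA)
    data = np.where(data == nodata, np.nan, data)
    grid = GridSpec(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"] + n_rows * header["cellsize"],
    )
    return grid, data


def write_ascii_grid(path, grid: GridSpec, data: np.ndarray) -> None:
    data = np.asarray(data, dtype=float)
    if data.shape != (grid.n_rows, grid.n_cols):
        raise GridMismatchError("data shape does not match grid")
    out = np.where(np.isnan(data), _NODATA, data)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {grid.x_origin!r}\n")
        fh.write(f"yllcorner {grid.y_origin - grid.n_rows * grid.cell_size!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        np.savetxt(fh, out, fmt="%.10g")


def load_stack(paths: Mapping[str, str | Path], period_label: str) -> EnvStack:
    """Load named .asc layers into a stack, refusing misaligned grids."""
    if not paths:
        raise ValueError("no layers given")
    stack = None
    for name, p in paths.items():
        grid, data = read_ascii_grid(p)
        if stack is None:
            stack = EnvStack(period_label=period_label, grid=grid)
        elif grid != stack.grid:
            raise GridMismatchError(
                f"layer {name!r} grid {grid} does not match stack grid {stack.grid}"
            )
        stack.add_layer(name, data)
    return stack


# ---------------------------------------------------------------------------
# Derived layers
# ---------------------------------------------------------------------------

def _elementwise_mean(*arrays):
    return np.mean(np.stack([np.asarray(a, dtype=float) for a in arrays]), axis=0)


def _elementwise_min(*arrays):
    return np.min(np.stack([np.asarray(a, dtype=float) for a in arrays]), axis=0)


def _elementwise_max(*arrays):
    return np.max(np.stack([np.asarray(a, dtype=float) for a in arrays]), axis=0)


def derive_layer(stack: EnvStack, expression: str) -> np.ndarray:
    """Evaluate an arithmetic expression over layer names.

    Supported: +, -, *, /, unary minus, parentheses, numeric literals, and
    the elementwise functions mean(...), min(...), max(...), abs(...).
    Division by zero yields nodata at the offending cells with a single
    warning carrying the cell count. Nodata in any input propagates.
    """
    namespace: dict[str, object] = {
        "mean": _elementwise_mean,
        "min": _elementwise_min,
        "max": _elementwise_max,
        "abs": np.abs,
    }
    namespace.update({k: v for k, v in stack.layers.items()})
    code = compile(expression, "<derive_layer>", "eval")
    for name in code.co_names:
        if name not in namespace:
            raise KeyError(f"expression references unknown layer or function {name!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        result = eval(code, {"__builtins__": {}}, namespace)  # noqa: S307 - vetted names only
    result = np.asarray(result, dtype=float)
    if result.shape != (stack.grid.n_rows, stack.grid.n_cols):
        result = np.broadcast_to(result, (stack.grid.n_rows, stack.grid.n_cols)).copy()
    bad = ~np.isfinite(result) & ~np.isnan(result)  # inf/-inf from division by zero
    n_bad = int(bad.sum())
    if n_bad:
        warnings.warn(f"derive_layer: {n_bad} cells divided by zero set to nodata")
        result = np.where(bad, np.nan, result)
    return result


# ---------------------------------------------------------------------------
# Samples-with-data extraction
# ---------------------------------------------------------------------------

def extract_swd(
    records: pd.DataFrame,
    stacks: Mapping[str, EnvStack],
    variables: Iterable[str] | None = None,
    label: str = "presence",
) -> pd.DataFrame:
    """Build an SWD table by reading each record's period-matched stack.

    ``records`` needs columns lon, lat, period; every period present must
    have a stack. Rows landing outside the grid or on nodata are dropped;
    the count of dropped rows is attached as ``df.attrs['n_dropped_nodata']``.
    """
    missing = set(records["period"].unique()) - set(stacks)
    if missing:
        raise KeyError(f"no environmental stack for period(s): {sorted(missing)}")
    if variables is None:
        first = next(iter(stacks.values()))
        variables = first.variable_names
    variables = list(variables)

    chunks = []
    n_dropped = 0
    for period, sub in records.groupby("period", sort=False):
        stack = stacks[period]
        vals, valid = stack.values_at(sub["lon"].to_numpy(), sub["lat"].to_numpy(), variables)
        out = pd.DataFrame(
            {
                "label": label,
                "period": period,
                "lon": sub["lon"].to_numpy(),
                "lat": sub["lat"].to_numpy(),
            }
        )
        out = pd.concat([out, vals.reset_index(drop=True)], axis=1)
        n_dropped += int((~valid).sum())
        chunks.append(out.loc[np.asarray(valid)])
    swd = pd.concat(chunks, ignore_index=True) if chunks else pd.DataFrame(
        columns=["label", "period", "lon", "lat", *variables]
    )
    swd.attrs["n_dropped_nodata"] = n_dropped
    return swd
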