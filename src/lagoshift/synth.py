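"""Synthetic worlds with known ground truth.

Everything the pipeline consumes can be generated here: multi-period
climate stacks with prescribed future shifts (additive warming and/or an
exact poleward translation of the whole field), virtual species whose
environment-suitability function is known exactly, occurrence records
with survey bias hooks (coarse-precision records, period mixes), land
cover, dispersal rates, expert-rating fixtures derived from truth-overlap,
and, for the comparative statistics, pure-birth trees with Brownian-motion
traits and responses built under a known Pagel's lambda and coefficient
vector.

Every generator is a pure function of its parameters and a seed, and the
files it writes use the exact formats the pipeline reads, so synthetic
and real inputs are interchangeable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy.linalg import cholesky
from scipy.ndimage import gaussian_filter

from .comparative import bm_covariance, lambda_transform
from .env_stack import EnvStack, GridSpec

__all__ = [
    "ScenarioShift",
    "VirtualSpeciesSpec",
    "gen_climate",
    "gen_virtual_species",
    "gen_land_cover",
    "gen_elevation",
    "gen_comparative",
    "default_world_grid",
    "PERIODS",
]

#: Pipeline period labels in temporal order.
PERIODS = ("past1900_1949", "current1950_2000", "f2020s", "f2050s", "f2080s")


def default_world_grid(n_rows: int = 120, n_cols: int = 160, cell_size: float = 0.1,
                       x_origin: float = 0.0, y_origin: float = 60.0) -> GridSpec:
    """The desk-scale default world: 120 x 160 cells of 0.1 deg, spanning
    latitudes 48-60 N so every cell is unambiguously northern hemisphere."""
    return GridSpec(n_rows=n_rows, n_cols=n_cols, cell_size=cell_size,
                    x_origin=x_origin, y_origin=y_origin)


@dataclass(frozen=True)
class ScenarioShift:
    """Prescribed change of one future period relative to the baseline."""

    additive: Mapping[str, float] = field(default_factory=dict)
    poleward_deg: float = 0.0


@dataclass
class VirtualSpeciesSpec:
    """A species with a known suitability function.

    ``optima``/``widths`` define a Gaussian response per variable on the
    raw variable scale; climatic suitability is the product of the
    per-variable responses (a quadratic form in the exponent), so the
    truth is exactly representable by the linear+quadratic feature
    expansion. ``occupied_land_classes``, when set, zeroes suitability on
    other land classes — the habitat dimension the restricted model
    variants are meant to capture.
    """

    name: str
    optima: Mapping[str, float]
    widths: Mapping[str, float]
    n_presences: int = 200
    pre1950_fraction: float = 0.1
    coarse_fraction: float = 0.1       # fraction violating the 2-km rule
    dispersal_km_per_yr: float = 1.0
    occupied_land_classes: frozenset[int] | None = None
    group: str = "rabbits"


# ---------------------------------------------------------------------------
# Climate
# ---------------------------------------------------------------------------

def gen_climate(
    grid: GridSpec,
    shifts: Mapping[str, ScenarioShift] | None = None,
    n_extra_variables: int = 2,
    noise_sd: float = 0.6,
    noise_smooth_cells: float = 4.0,
    seed: int = 0,
) -> dict[str, EnvStack]:
    """Generate co-registered stacks for all five periods.

    Variables: ``temp`` falls linearly with latitude, ``precip`` rises
    with longitude, plus ``bio3``, ``bio4``, ... smooth random fields; all
    carry Gaussian-filtered noise. Future periods apply their
    ScenarioShift: additive offsets per variable and/or an exact poleward
    translation of every field (implemented by generating the fields on a
    latitudinally extended grid and windowing, so the translated values
    are bit-identical to the baseline values further equatorward).
    """
    shifts = dict(shifts or {})
    max_shift_cells = 0
    for s in shifts.values():
        cells = s.poleward_deg / grid.cell_size
        if abs(cells - round(cells)) > 1e-9:
            raise ValueError("poleward_deg must be a whole number of cells")
        max_shift_cells = max(max_shift_cells, int(round(cells)))

    rng = np.random.default_rng(seed)
    ext_rows = grid.n_rows + max_shift_cells
    # extended grid adds rows on the equatorward (southern) side
    lat_ext = grid.y_origin - (np.arange(ext_rows) + 0.5) * grid.cell_size
    lon = grid.col_longitudes()
    lat2d = np.repeat(lat_ext[:, None], grid.n_cols, axis=1)
    lon2d = np.repeat(lon[None, :], ext_rows, axis=0)

    def noise():
        return gaussian_filter(rng.standard_normal((ext_rows, grid.n_cols)), noise_smooth_cells) * noise_sd * (noise_smooth_cells * 2)

    fields = {
        "temp": 28.0 - 1.5 * (lat2d - lat_ext.min()) + noise(),
        "precip": 400.0 + 30.0 * (lon2d - lon.min()) + noise() * 30.0,
    }
    for i in range(n_extra_variables):
        fields[f"bio{i + 3}"] = 10.0 * noise() / max(noise_sd, 1e-9)

    def window(arr: np.ndarray, shift_cells: int) -> np.ndarray:
        # shift_cells rows of poleward translation: the climate that sat
        # shift_cells rows equatorward (south, larger row index) arrives at
        # row r, so isotherms migrate poleward. The baseline window starts
        # at row 0; futures start further down the extended array.
        return arr[shift_cells:shift_cells + grid.n_rows].copy()

    stacks: dict[str, EnvStack] = {}
    for period in PERIODS:
        shift = shifts.get(period, ScenarioShift())
        cells = int(round(shift.poleward_deg / grid.cell_size))
        layers = {}
        for name, arr in fields.items():
            layer = window(arr, cells)
            layer = layer + float(shift.additive.get(name, 0.0))
            layers[name] = layer
        stacks[period] = EnvStack(period_label=period, grid=grid, layers=layers)
    return stacks


def gen_land_cover(grid: GridSpec, n_classes: int = 4, seed: int = 0,
                   smooth_cells: float = 6.0) -> np.ndarray:
    """Integer land-class raster from a smoothed random field quantised
    into ``n_classes`` equal-frequency bands."""
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal((grid.n_rows, grid.n_cols)), smooth_cells)
    qs = np.quantile(f, np.linspace(0, 1, n_classes + 1)[1:-1])
    return np.digitize(f, qs).astype(float)


def gen_elevation(grid: GridSpec, relief_m: float = 2000.0, seed: int = 0,
                  smooth_cells: float = 8.0) -> np.ndarray:
    """Smooth non-negative elevation raster (metres)."""
    rng = np.random.default_rng(seed)
    f = gaussian_filter(rng.standard_normal((grid.n_rows, grid.n_cols)), smooth_cells)
    f = f - f.min()
    return f / max(f.max(), 1e-12) * relief_m


# ---------------------------------------------------------------------------
# Virtual species
# ---------------------------------------------------------------------------

def truth_suitability(
    spec: VirtualSpeciesSpec, stack: EnvStack, land_cover: np.ndarray | None = None
) -> np.ndarray:
    """The species' known suitability on a stack's grid, in [0, 1]."""
    log_s = np.zeros((stack.grid.n_rows, stack.grid.n_cols))
    for var, opt in spec.optima.items():
        w = spec.widths[var]
        log_s -= 0.5 * ((stack.layers[var] - opt) / w) ** 2
    s = np.exp(log_s)
    if spec.occupied_land_classes is not None and land_cover is not None:
        s = np.where(np.isin(land_cover, list(spec.occupied_land_classes)), s, 0.0)
    return s


def gen_virtual_species(
    spec: VirtualSpeciesSpec,
    current_stack: EnvStack,
    past_stack: EnvStack,
    seed: int = 0,
    land_cover: np.ndarray | None = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Sample occurrence records proportional to truth suitability.

    Post-1950 presences are drawn against the current stack, the pre-1950
    fraction against the past stack. Records are placed at cell centers;
    a ``coarse_fraction`` of them get precision > 2 km so the resolution
    filter has something to remove (those rows are *extra*, on top of
    ``n_presences`` clean ones). Returns (truth suitability on the current
    stack, occurrence DataFrame).
    """
    rng = np.random.default_rng(seed)
    grid = current_stack.grid
    truth_cur = truth_suitability(spec, current_stack, land_cover)
    truth_past = truth_suitability(spec, past_stack, land_cover)

    n_pre = int(round(spec.n_presences * spec.pre1950_fraction))
    n_post = spec.n_presences - n_pre

    def draw(truth: np.ndarray, n: int, year_range: tuple[int, int]) -> pd.DataFrame:
        p = truth.ravel() / truth.sum()
        if truth.sum() <= 0:
            raise ValueError("truth suitability sums to zero")
        idx = rng.choice(truth.size, size=n, replace=True, p=p)
        rows, cols = np.unravel_index(idx, truth.shape)
        lon, lat = grid.cell_center(rows, cols)
        years = rng.integers(year_range[0], year_range[1] + 1, size=n)
        return pd.DataFrame(
            {
                "species": spec.name,
                "lon": lon,
                "lat": lat,
                "year": years,
                "precision_km": np.round(rng.uniform(0.1, 2.0, size=n), 2),
                "source": "synthetic",
            }
        )

    parts = []
    if n_pre:
        parts.append(draw(truth_past, n_pre, (1900, 1949)))
    parts.append(draw(truth_cur, n_post, (1950, 2000)))
    n_coarse = int(round(spec.n_presences * spec.coarse_fraction))
    if n_coarse:
        coarse = draw(truth_cur, n_coarse, (1950, 2000))
        coarse["precision_km"] = np.round(rng.uniform(2.5, 25.0, size=n_coarse), 2)
        parts.append(coarse)
    records = pd.concat(parts, ignore_index=True)
    return truth_cur, records


# ---------------------------------------------------------------------------
# Comparative data
# ---------------------------------------------------------------------------

def gen_comparative(
    n_tips: int = 100,
    birth_rate: float = 1.0,
    lambda_true: float = 1.0,
    beta_true: Sequence[float] = (0.0, 0.5),
    noise_sd: float = 1.0,
    n_traits: int | None = None,
    seed: int = 0,
) -> dict:
    """Pure-birth tree + Brownian traits + response with known truth.

    The tree is a Yule tree with ``n_tips`` extant tips, rescaled to unit
    depth (ultrametric by construction). Traits (one per non-intercept
    element of ``beta_true`` unless ``n_traits`` overrides) evolve by
    Brownian motion on the tree; the response is
    X beta_true + eps with eps ~ N(0, noise_sd^2 V(lambda_true)).
    Returns a dict with the tree (dendropy), newick string, trait table,
    response, V, tip order, and the truth parameters.
    """
    if n_tips < 10:
        raise ValueError("need at least 10 tips")
    rng = np.random.default_rng(seed)
    beta_true = np.asarray(beta_true, dtype=float)
    p = len(beta_true) - 1 if n_traits is None else n_traits

    tree = _yule_tree(n_tips, birth_rate, rng)
    V, labels = bm_covariance(tree)
    depth = float(np.max(np.diag(V)))
    # rescale to unit depth for numerical comfort
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length /= depth
    V = V / depth

    L = cholesky(V, lower=True)
    traits = pd.DataFrame(
        {f"trait{j + 1}": L @ rng.standard_normal(n_tips) for j in range(p)},
        index=labels,
    )
    X = np.column_stack([np.ones(n_tips), traits.to_numpy()[:, : len(beta_true) - 1]])
    Lv = cholesky(lambda_transform(V, lambda_true), lower=True)
    eps = noise_sd * (Lv @ rng.standard_normal(n_tips))
    y = X @ beta_true + eps
    return {
        "tree": tree,
        "newick": tree.as_string(schema="newick").strip(),
        "traits": traits,
        "response": pd.Series(y, index=labels, name="response"),
        "V": V,
        "tip_order": labels,
        "truth": {"lambda": lambda_true, "beta": beta_true, "noise_sd": noise_sd},
    }


def _yule_tree(n_tips: int, birth_rate: float, rng: np.random.Generator) -> dendropy.Tree:
    """Simulate a pure-birth ultrametric tree with exponential waiting times."""
    taxa = dendropy.TaxonNamespace([f"t{i + 1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node.edge.length = 0.0
    tips = [tree.seed_node]
    ages = {id(tree.seed_node): 0.0}
    t = 0.0
    while len(tips) < n_tips:
        t += rng.exponential(1.0 / (birth_rate * len(tips)))
        parent = tips.pop(rng.integers(len(tips) + 1) % len(tips) if len(tips) > 1 else 0)
        parent_age = ages.pop(id(parent))
        parent.edge.length = (parent.edge.length or 0.0) + (t - parent_age)
        for _ in range(2):
            child = parent.new_child(edge_length=0.0)
            ages[id(child)] = t
            tips.append(child)
    # final stretch so all tips end at the same time
    t_end = t + rng.exponential(1.0 / (birth_rate * len(tips)))
    for node in tips:
        node.edge.length = (node.edge.length or 0.0) + (t_end - ages[id(node)])
    for node, taxon in zip(tree.leaf_node_iter(), taxa):
        node.taxon = taxon
    return tree
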