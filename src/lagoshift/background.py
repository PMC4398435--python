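"""Temporally stratified target-group background sampling.

Background (pseudo-absence) points are drawn only from grid cells where
*any* species of the target group was recorded — the target-group scheme
that cancels shared survey bias — and the pre/post-period mix of the
sample is forced to match the focal species' own record mix, so temporal
sampling bias cancels too.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .env_stack import EnvStack, GridSpec, extract_swd

__all__ = ["BackgroundSpec", "target_group_cells", "sample_background"]


@dataclass
class BackgroundSpec:
    """How many background points to draw and from which cells."""

    n_points: int = 10_000
    eligible_cells: dict[str, set[tuple[int, int]]] = field(default_factory=dict)
    seed: int = 0


def target_group_cells(
    all_records: pd.DataFrame, grid: GridSpec
) -> dict[str, set[tuple[int, int]]]:
    """Cells eligible per period: >=1 record of any target-group species.

    ``all_records`` must be period-tagged and cleaned. Cells are (row, col)
    indices on the working grid.
    """
    if len(all_records) == 0:
        raise ValueError("no records: cannot build target-group background")
    row, col = grid.cell_of(all_records["lon"].to_numpy(), all_records["lat"].to_numpy())
    inside = grid.inside(row, col)
    eligible: dict[str, set[tuple[int, int]]] = {}
    periods = all_records["period"].to_numpy()
    for period in np.unique(periods):
        sel = (periods == period) & inside
        eligible[str(period)] = set(zip(row[sel].tolist(), col[sel].tolist()))
    return eligible


def sample_background(
    spec: BackgroundSpec,
    focal_period_counts: Mapping[str, int],
    stacks: Mapping[str, EnvStack],
    pre_label: str = "pre1950",
    post_label: str = "post1950",
) -> pd.DataFrame:
    """Draw the stratified background sample as SWD rows.

    The pre-period share of the ``n_points`` sample equals the focal
    species' pre-period record share (banker's rounding of
    n_points x fraction, remainder to the post period). Cells are sampled
    without replacement from the period's eligible set, points are placed
    at cell centers, and environmental values come from the period-matched
    stack. If a period has fewer eligible cells than requested, all of them
    are used and a warning is emitted.
    """
    n_pre_rec = int(focal_period_counts.get(pre_label, 0))
    n_post_rec = int(focal_period_counts.get(post_label, 0))
    total = n_pre_rec + n_post_rec
    if total == 0:
        raise ValueError("focal species has no records")
    pre_fraction = n_pre_rec / total
    n_pre = int(round(spec.n_points * pre_fraction))  # round-half-to-even
    n_post = spec.n_points - n_pre

    rng = np.random.default_rng(spec.seed)
    rows = []
    for period, n_wanted in ((pre_label, n_pre), (post_label, n_post)):
        if n_wanted == 0:
            continue
        cells = sorted(spec.eligible_cells.get(period, set()))
        if not cells:
            raise ValueError(f"no eligible background cells for period {period!r}")
        if len(cells) < n_wanted:
            warnings.warn(
                f"only {len(cells)} eligible cells for {period}, "
                f"requested {n_wanted}; sampling all"
            )
            chosen = np.arange(len(cells))
        else:
            chosen = rng.choice(len(cells), size=n_wanted, replace=False)
        grid = stacks[period].grid
        cell_arr = np.asarray(cells)[np.sort(chosen)]
        lon, lat = grid.cell_center(cell_arr[:, 0], cell_arr[:, 1])
        rows.append(pd.DataFrame({"lon": lon, "lat": lat, "period": period}))
    pts = pd.concat(rows, ignore_index=True)
    swd = extract_swd(pts, stacks, label="background")
    return swd
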