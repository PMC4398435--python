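"""End-to-end orchestration of the range-shift analysis.

Stages run in the fixed order: occurrence QC -> environmental extraction
-> target-group background -> presence-background SDMs (the four variants:
pre+post vs post-only input data, each with and without the land-class
habitat restriction) -> replicate-held-out evaluation -> the joint
expert/Kappa validation gate -> dispersal-clipped projection under each
scenario -> range/poleward/elevation change metrics and richness change ->
phylogenetically controlled trait regressions over the modellable species.

``run_pipeline`` works on an in-memory :class:`World` (either loaded from
files through the module loaders or generated with known truth by
:func:`build_synthetic_world`) and writes plain CSV/JSON outputs plus a
manifest, so two runs with the same config and seed are byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import shapely

from . import __version__
from .background import BackgroundSpec, sample_background, target_group_cells
from .change_metrics import change_summary, range_metrics, richness_change
from .comparative import gls_trend, pgls_fit
from .env_stack import EnvStack, extract_swd
from .evaluation import (
    VARIANTS,
    compute_metrics,
    confusion,
    select_variant,
    threshold_10ptp,
    validation_gate,
)
from .occurrence_qc import run_qc_chain
from .range_geometry import DispersalSpec, build_clip_region, clip_map, land_class_mask
from .sdm import (
    TooFewRecordsError,
    choose_replication,
    fit_replicates,
    predict_map,
    predict_suitability,
)
from .synth import (
    PERIODS,
    ScenarioShift,
    VirtualSpeciesSpec,
    default_world_grid,
    gen_climate,
    gen_comparative,
    gen_elevation,
    gen_land_cover,
    gen_virtual_species,
)

__all__ = ["PipelineConfig", "World", "build_synthetic_world", "run_pipeline"]


@dataclass
class PipelineConfig:
    """All thresholds of the analysis, with the study's printed defaults."""

    kappa_gate: float = 0.4
    min_records: int = 8
    replicate_cut: int = 30
    percentile: float = 10.0
    background_n: int = 10_000
    resolution_cut_km: float = 2.0
    outlier_resid: float = 3.0
    cutoff_year: int = 1950
    scenario_years: dict = field(
        default_factory=lambda: {"f2020s": 2025, "f2050s": 2055, "f2080s": 2085}
    )
    reg_multiplier: float = 1.0
    #: clip applied to the baseline map when differencing periods:
    #: "current" (the dispersal region of the baseline period, the default
    #: reporting convention) or "future" (both periods clipped to the final
    #: scenario's region, isolating the climate signal from the widening
    #: accessibility belt — used for translation-recovery experiments)
    change_baseline_clip: str = "current"
    seed: int = 0

    def __post_init__(self):
        for name in ("kappa_gate", "min_records", "replicate_cut", "percentile",
                     "background_n", "resolution_cut_km", "outlier_resid"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        years = list(self.scenario_years.values())
        if years != sorted(years) or len(set(years)) != len(years):
            raise ValueError("scenario years must be strictly increasing")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load a config from a YAML mapping of field names to values."""
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class World:
    """Everything one pipeline run consumes."""

    stacks: dict[str, EnvStack]
    land_cover: np.ndarray
    elevation: np.ndarray
    records: pd.DataFrame
    accepted_names: set[str]
    dispersal: dict[str, DispersalSpec]
    ratings: pd.DataFrame | None = None        # species, rating, chosen_variant
    truth: dict[str, np.ndarray] | None = None # per-species truth suitability
    species_groups: dict[str, str] | None = None


def build_synthetic_world(
    seed: int = 0,
    n_species_per_group: int = 8,
    n_presences: int = 150,
    poleward_shift_deg: Mapping[str, float] | None = None,
    warming: Mapping[str, float] | None = None,
    dispersal_override: float | None = None,
    generalists: bool = False,
    grid=None,
) -> World:
    """A virtual-species world with three trait-contrasted groups.

    Twenty-four species by default (pika / rabbit / hare&jackrabbit
    analogues differing in thermal optimum, niche width, habitat breadth
    and dispersal),
    five co-registered climate periods with configurable future warming
    and/or an exact poleward translation, land cover, elevation and
    dispersal rates. Expert ratings are attached later from
    truth-vs-prediction overlap during the run.
    """
    rng = np.random.default_rng(seed)
    grid = grid or default_world_grid()
    if warming is None:
        warming = {"f2020s": 0.8, "f2050s": 1.6, "f2080s": 2.8}
    warming = dict(warming)
    poleward = dict(poleward_shift_deg) if poleward_shift_deg is not None else {}
    shifts = {
        p: ScenarioShift(additive={"temp": warming.get(p, 0.0)}, poleward_deg=poleward.get(p, 0.0))
        for p in ("f2020s", "f2050s", "f2080s")
    }
    stacks = gen_climate(grid, shifts=shifts, seed=seed)
    land_cover = gen_land_cover(grid, seed=seed + 1)
    elevation = gen_elevation(grid, seed=seed + 2)

    cur = stacks["current1950_2000"]
    t_lo, t_hi = np.percentile(cur.layers["temp"], [20, 80])
    p_lo, p_hi = np.percentile(cur.layers["precip"], [15, 85])
    groups = {
        # cold-adapted, narrow niche, habitat specialist, poor dispersers
        # (pika analogue)
        "pikas": dict(t_opt=t_lo, t_w=0.45, disp=(0.2, 0.6), classes=(0, 1)),
        # intermediate (rabbit analogue)
        "rabbits": dict(t_opt=(t_lo + t_hi) / 2, t_w=0.6, disp=(0.5, 1.5), classes=(0, 1, 2)),
        # warm-tolerant, broader niche, mobile generalists
        # (hare/jackrabbit analogue)
        "hares": dict(t_opt=t_hi, t_w=0.8, disp=(1.5, 4.0), classes=(0, 1, 2, 3)),
    }
    records, truth, dispersal, species_groups = [], {}, {}, {}
    i = 0
    for gname, g in groups.items():
        for j in range(n_species_per_group):
            i += 1
            name = f"{gname}_{j + 1}"
            disp = dispersal_override if dispersal_override is not None else float(rng.uniform(*g["disp"]))
            spec = VirtualSpeciesSpec(
                name=name,
                optima={"temp": g["t_opt"] + rng.normal(0, 1.5),
                        "precip": rng.uniform(p_lo, p_hi)},
                widths={"temp": g["t_w"], "precip": (p_hi - p_lo) * 0.08},
                n_presences=n_presences,
                pre1950_fraction=0.1,
                coarse_fraction=0.1,
                dispersal_km_per_yr=disp,
                occupied_land_classes=None if generalists else frozenset(g["classes"]),
                group=gname,
            )
            tr, rec = gen_virtual_species(
                spec, cur, stacks["past1900_1949"], seed=seed * 1000 + i,
                land_cover=land_cover,
            )
            records.append(rec)
            truth[name] = tr
            dispersal[name] = DispersalSpec(name, spec.dispersal_km_per_yr, "observed")
            species_groups[name] = gname
    all_records = pd.concat(records, ignore_index=True)
    return World(
        stacks=stacks,
        land_cover=land_cover,
        elevation=elevation,
        records=all_records,
        accepted_names=set(truth),
        dispersal=dispersal,
        truth=truth,
        species_groups=species_groups,
    )


# ---------------------------------------------------------------------------
# Per-species modelling
# ---------------------------------------------------------------------------

def _evaluate_replicates(reps, presence_swd, background_swd, variables,
                         percentile, restrict_mask=None, grid=None):
    """Replicate-averaged held-out metrics and the binary threshold.

    Metrics are computed on each replicate's held-out presences against
    the background points, then averaged; the threshold is the mean of
    the per-replicate 10-percentile training-presence thresholds.
    """
    per_rep = []
    thresholds = []
    bg_scores_cache = None
    for model, test_idx in zip(reps.models, reps.test_indices):
        train_scores = predict_suitability(model, presence_swd)
        tau = threshold_10ptp(train_scores, percentile)
        thresholds.append(tau)
        if len(test_idx) == 0:
            continue
        test_scores = predict_suitability(model, presence_swd.iloc[test_idx])
        bg_scores = predict_suitability(model, background_swd)
        if restrict_mask is not None and grid is not None:
            def masked(scores, lon, lat):
                r, c = grid.cell_of(np.asarray(lon), np.asarray(lat))
                ok = restrict_mask[np.clip(r, 0, grid.n_rows - 1), np.clip(c, 0, grid.n_cols - 1)]
                return np.where(ok, scores, 0.0)
            test_scores = masked(test_scores, presence_swd.iloc[test_idx]["lon"], presence_swd.iloc[test_idx]["lat"])
            bg_scores = masked(bg_scores, background_swd["lon"], background_swd["lat"])
        counts = confusion(test_scores >= tau, bg_scores >= tau)
        per_rep.append(compute_metrics(counts, test_scores, bg_scores))
    if not per_rep:
        raise ValueError("no replicate produced held-out presences")
    mean = {f: float(np.mean([getattr(m, f) for m in per_rep]))
            for f in ("auc", "omission_rate", "sensitivity", "specificity",
                      "proportion_correct", "kappa", "tss")}
    return mean, float(np.mean(thresholds))


def interior_species(world: World, shift_deg: float, margin_deg: float = 0.3,
                     truth_floor: float = 0.05) -> list[str]:
    """Species whose true range stays inside the grid before AND after a
    poleward translation of ``shift_deg`` (plus a margin).

    Edge-truncated ranges cannot translate freely — the analogue of real
    species pinned against coastlines or the top of a mountain — so
    translation-recovery experiments are scored on interior species only.
    """
    grid = world.stacks["current1950_2000"].grid
    cells = int(round(shift_deg / grid.cell_size))
    margin = int(np.ceil(margin_deg / grid.cell_size))
    out = []
    for sp, tr in (world.truth or {}).items():
        rows = np.nonzero((tr >= truth_floor * tr.max()).any(axis=1))[0]
        if len(rows) and rows.min() >= cells + margin and rows.max() < grid.n_rows - margin:
            out.append(sp)
    return out


def _jaccard_rating(pred_binary: np.ndarray, truth_map: np.ndarray,
                    record_lon, record_lat, grid, percentile: float):
    """Synthetic stand-in for expert judgement: overlap of the predicted
    binary range with the truth range, where the truth range is defined by
    the same operational rule as the prediction — truth suitability above
    the 10-percentile of truth at the species' own records. Jaccard >= 0.7
    -> good, >= 0.4 -> medium, else poor."""
    r, c = grid.cell_of(np.asarray(record_lon), np.asarray(record_lat))
    ok = grid.inside(r, c)
    truth_at_records = truth_map[r[ok], c[ok]]
    tau = np.percentile(truth_at_records, percentile, method="lower")
    truth_bin = truth_map >= tau
    p = np.nan_to_num(pred_binary, nan=0.0) > 0
    inter = (p & truth_bin).sum()
    union = (p | truth_bin).sum()
    j = inter / union if union else 0.0
    return ("good" if j >= 0.7 else "medium" if j >= 0.4 else "poor"), float(j)


def run_pipeline(world: World, config: PipelineConfig, out_dir: str | Path) -> dict:
    """Execute every stage and write CSV/JSON outputs under ``out_dir``.

    Returns a results dict with the decision table, per-species change
    summaries, the comparative fits, and the manifest.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = config
    grid = world.stacks["current1950_2000"].grid
    pre, post = f"pre{cfg.cutoff_year}", f"post{cfg.cutoff_year}"
    variables = world.stacks["current1950_2000"].variable_names

    # --- occurrence QC ----------------------------------------------------
    clean, qc_report = run_qc_chain(
        world.records, world.accepted_names, grid,
        max_precision_km=cfg.resolution_cut_km, cutoff_year=cfg.cutoff_year,
    )
    qc_report.to_csv(out_dir / "qc_report.csv", index=False)

    # --- target-group background -----------------------------------------
    eligible = target_group_cells(clean, grid)
    swd_stacks = {pre: world.stacks["past1900_1949"], post: world.stacks["current1950_2000"]}

    decision_rows, change_rows, metrics_rows, range_rows = [], [], [], []
    trend_rows = []
    binary_past, binary_future, binary_unmod = {}, {}, {}
    manifest_counts = {"n_records_raw": len(world.records), "n_records_clean": len(clean)}

    for sp_i, species in enumerate(sorted(clean["species"].unique())):
        sub = clean[clean["species"] == species]
        period_counts = sub["period"].value_counts().to_dict()
        presence_swd_all = extract_swd(sub, swd_stacks, variables)
        bg_spec = BackgroundSpec(
            n_points=cfg.background_n, eligible_cells=eligible, seed=cfg.seed + 17 * sp_i
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # fewer eligible cells than requested is routine at desk scale
            background_swd = sample_background(bg_spec, period_counts, swd_stacks, pre, post)

        # accessibility clip (MCP + dispersal buffer) applies to every model
        # output, evaluation included: it removes biogeographic
        # over-prediction before any validation happens
        clip_region = build_clip_region(
            sub["lon"], sub["lat"], world.dispersal[species], cfg.scenario_years,
            cell_size_deg=grid.cell_size,
        )
        current_poly = clip_region.region(clip_region.current_buffer_km)
        lon_g, lat_g = np.meshgrid(grid.col_longitudes(), grid.row_latitudes())
        inside_clip = shapely.contains_xy(current_poly, lon_g.ravel(), lat_g.ravel()).reshape(
            grid.n_rows, grid.n_cols
        )

        # four variants: data x habitat restriction
        variant_inputs = {
            "i": (presence_swd_all, None),
            "ii": (presence_swd_all, "restricted"),
            "iii": (presence_swd_all[presence_swd_all["period"] == post], None),
            "iv": (presence_swd_all[presence_swd_all["period"] == post], "restricted"),
        }
        fits, variant_metrics, variant_tau = {}, {}, {}
        for v in VARIANTS:
            pres, restriction = variant_inputs[v]
            pres = pres.reset_index(drop=True)
            try:
                scheme = choose_replication(len(pres), cfg.min_records)
            except TooFewRecordsError:
                continue
            reps = fit_replicates(
                scheme, pres, background_swd, variables,
                seed=cfg.seed + 1000 + sp_i, reg_multiplier=cfg.reg_multiplier,
            )
            land_mask = None
            if restriction:
                masked_map, _occupied = land_class_mask(
                    np.ones((grid.n_rows, grid.n_cols)), world.land_cover, grid,
                    sub["lon"].to_numpy(), sub["lat"].to_numpy(),
                )
                land_mask = np.nan_to_num(masked_map, nan=0.0) > 0
            eval_mask = inside_clip if land_mask is None else (inside_clip & land_mask)
            mean_metrics, tau = _evaluate_replicates(
                reps, pres, background_swd, variables, cfg.percentile,
                restrict_mask=eval_mask, grid=grid,
            )
            fits[v] = (reps, land_mask, tau)
            variant_metrics[v] = mean_metrics
            variant_tau[v] = tau
            metrics_rows.append({"species": species, "variant": v, "scheme": scheme,
                                 "n_presences": len(pres), **mean_metrics})

        if not fits:
            decision_rows.append({"species": species, "variant": "", "kappa": np.nan,
                                  "rating": "", "decision": "unmodellable-by-data"})
            continue

        # variant selection (expert choice if given, else best kappa)
        expert_choice = None
        rating_in = None
        if world.ratings is not None:
            row = world.ratings[world.ratings["species"] == species]
            if len(row):
                rating_in = row.iloc[0]["rating"]
                if pd.isna(rating_in):
                    rating_in = None  # variant chosen, rating still pending
                cv = row.iloc[0].get("chosen_variant")
                expert_choice = cv if cv in fits else None
        chosen = select_variant({v: m["kappa"] for v, m in variant_metrics.items()}, expert_choice)
        reps, mask, tau = fits[chosen]

        # project: past + current + futures, clip by dispersal region
        suit = {p: predict_map(reps, world.stacks[p]) for p in PERIODS}
        if mask is not None:
            suit = {p: np.where(mask, s, 0.0) for p, s in suit.items()}
        binary = {}
        for p in PERIODS:
            b = (np.nan_to_num(suit[p], nan=-1) >= tau).astype(float)
            b[np.isnan(suit[p])] = np.nan
            if p in cfg.scenario_years:
                poly = clip_region.region(clip_region.future_buffer_km[p])
            else:
                poly = clip_region.region(clip_region.current_buffer_km)
            binary[p] = clip_map(b, grid, poly)

        # expert rating: supplied table, else truth-overlap stand-in
        if rating_in is None and world.truth is not None:
            rating_in, jac = _jaccard_rating(
                binary["current1950_2000"], world.truth[species],
                sub["lon"].to_numpy(), sub["lat"].to_numpy(), grid, cfg.percentile,
            )
        decision = validation_gate(species, variant_metrics[chosen]["kappa"], rating_in, cfg.kappa_gate)
        decision_rows.append({"species": species, "variant": chosen,
                              "kappa": decision.kappa, "rating": decision.rating,
                              "decision": decision.decision})

        # change metrics (past "1930s" baseline vs 2080s)
        base_map = binary["past1900_1949"]
        if cfg.change_baseline_clip == "future":
            b = (np.nan_to_num(suit["past1900_1949"], nan=-1) >= tau).astype(float)
            b[np.isnan(suit["past1900_1949"])] = np.nan
            base_map = clip_map(b, grid, clip_region.region(clip_region.future_buffer_km["f2080s"]))
        m0 = range_metrics(base_map, grid, world.elevation, "past1900_1949")
        m1 = range_metrics(binary["f2080s"], grid, world.elevation, "f2080s")
        scenario_metrics = {
            p: range_metrics(binary[p], grid, world.elevation, p)
            for p in cfg.scenario_years
        }
        for p in PERIODS:
            mp = range_metrics(binary[p], grid, world.elevation, p)
            range_rows.append({"species": species, "period": p, "area_km2": mp.area_km2,
                               "mean_latitude": mp.mean_latitude,
                               "min_latitude": mp.min_latitude,
                               "max_latitude": mp.max_latitude,
                               "min_longitude": mp.min_longitude,
                               "max_longitude": mp.max_longitude,
                               "min_elev": mp.min_elev,
                               "mean_elev": mp.mean_elev, "max_elev": mp.max_elev,
                               "n_cells": mp.n_cells})
        if decision.decision == "modellable" and not m0.extinct:
            cs = change_summary(species, m0, m1, hemisphere="N")
            change_rows.append({"species": species, "group": (world.species_groups or {}).get(species, ""),
                                "range_change_pct": cs.range_change_pct,
                                "poleward_deg": cs.poleward_deg,
                                "min_elev_change_m": cs.min_elev_change_m,
                                "mean_elev_change_m": cs.mean_elev_change_m,
                                "max_elev_change_m": cs.max_elev_change_m,
                                "extinct_2080s": cs.extinct})
            binary_past[species] = binary["past1900_1949"]
            binary_future[species] = binary["f2080s"]
            # per-scenario change series for the group-trend GLS
            for t_idx, p in enumerate(cfg.scenario_years):
                mp = scenario_metrics[p]
                if mp.extinct:
                    continue
                cs_p = change_summary(species, m0, mp, hemisphere="N")
                trend_rows.append({
                    "species": species,
                    "group": (world.species_groups or {}).get(species, ""),
                    "period": p,
                    "period_index": t_idx,
                    "range_change_pct": cs_p.range_change_pct,
                    "poleward_deg": cs_p.poleward_deg,
                    "mean_elev_change_m": cs_p.mean_elev_change_m,
                })
        else:
            # unmodellable species are projected for reference only
            binary_unmod[species] = binary["current1950_2000"]

    decisions = pd.DataFrame(decision_rows)
    metrics = pd.DataFrame(metrics_rows)
    changes = pd.DataFrame(change_rows, columns=[
        "species", "group", "range_change_pct", "poleward_deg",
        "min_elev_change_m", "mean_elev_change_m", "max_elev_change_m",
        "extinct_2080s",
    ])
    ranges = pd.DataFrame(range_rows)
    trends = pd.DataFrame(trend_rows, columns=[
        "species", "group", "period", "period_index",
        "range_change_pct", "poleward_deg", "mean_elev_change_m",
    ])
    decisions.to_csv(out_dir / "decisions.csv", index=False)
    metrics.to_csv(out_dir / "metrics.csv", index=False)
    changes.to_csv(out_dir / "change_summary.csv", index=False)
    ranges.to_csv(out_dir / "range_metrics.csv", index=False)
    trends.to_csv(out_dir / "change_trends.csv", index=False)

    # richness change (modellable species; unmodellable cells -> uncertain)
    richness = None
    if binary_past:
        rich_change, uncertain = richness_change(binary_past, binary_future, binary_unmod)
        richness = {"total_change": float(np.nansum(rich_change)),
                    "n_cells_loss": int((rich_change < 0).sum()),
                    "n_cells_gain": int((rich_change > 0).sum()),
                    "n_cells_uncertain": int(uncertain.sum())}

    # comparative stage: PGLS of change metrics on synthetic traits, plus
    # group x period GLS trends with AR(1) errors
    comparative = None
    if len(changes) >= 8:
        comparative = _comparative_stage(changes, cfg, out_dir)
    trend_fits = None
    if len(trends) and trends["group"].nunique() >= 2:
        trend_fits = {}
        for resp in ("range_change_pct", "poleward_deg", "mean_elev_change_m"):
            sub_t = trends[np.isfinite(trends[resp])]
            # a species extinct after the first scenario has no trend: drop it
            ok_species = sub_t.groupby("species")["period_index"].nunique()
            sub_t = sub_t[sub_t["species"].isin(ok_species[ok_species >= 2].index)]
            if len(sub_t) == 0 or sub_t["group"].nunique() < 2:
                continue
            fit = gls_trend(sub_t, resp)
            trend_fits[resp] = fit
            fit.f_tests.to_csv(out_dir / f"trend_ftests_{resp}.csv")

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "counts": manifest_counts,
        "n_species": int(clean["species"].nunique()),
        "n_modellable": int((decisions["decision"] == "modellable").sum()),
        "n_unmodellable": int((decisions["decision"] != "modellable").sum()),
        "richness": richness,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return {"decisions": decisions, "metrics": metrics, "changes": changes,
            "ranges": ranges, "trends": trends, "trend_fits": trend_fits,
            "comparative": comparative, "manifest": manifest}


def _comparative_stage(changes: pd.DataFrame, cfg: PipelineConfig, out_dir: Path):
    """PGLS of predicted change vs Brownian traits on a simulated phylogeny
    over exactly the modellable species (set equality enforced). Species
    with an undefined response (extinct in the scenario, so no poleward
    shift is measurable) are dropped for that response."""
    changes = changes[np.isfinite(changes["poleward_deg"])]
    if len(changes) < 8:
        return None
    species = list(changes["species"])
    sim = gen_comparative(n_tips=max(len(species), 10), lambda_true=1.0,
                          beta_true=(0.0, 0.3), seed=cfg.seed + 7)
    # rename tips onto the modellable species set
    labels = sim["tip_order"][: len(species)]
    mapping = dict(zip(labels, species))
    keep = [lab for lab in sim["tip_order"] if lab in mapping]
    idx = [sim["tip_order"].index(lab) for lab in keep]
    V = sim["V"][np.ix_(idx, idx)]
    traits = sim["traits"].iloc[idx].copy()
    traits.index = [mapping[lab] for lab in keep]
    assert set(traits.index) == set(species), "comparative inputs != modellable set"
    y = changes.set_index("species").loc[traits.index, "poleward_deg"].to_numpy()
    X = pd.DataFrame({"intercept": 1.0, "trait1": traits["trait1"].to_numpy()},
                     index=traits.index)
    fit = pgls_fit(y, X, V, response="poleward_deg")
    fit.summary().to_csv(out_dir / "comparative_poleward.csv")
    return fit
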