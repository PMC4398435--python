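# lagoshift

Bioclimatic range-shift analysis for multi-species groups: build
presence-background species distribution models (SDMs) from
quality-controlled occurrence records, validate them with a joint
expert-rating / Cohen's-kappa gate, project them onto changed climates
with dispersal-constrained clipping, quantify range, poleward and
elevational change, and relate the predicted changes to species traits
with phylogenetically controlled regressions.

The package is organised as an analysis project: every computation lives
in the library under `src/lagoshift/`, and the numbered scripts under
`analysis/` are thin drivers that run the studies and write tables under
`results/`.

## The problem

Projecting how species ranges respond to climate change from presence-only
occurrence data requires a long chain of methods, each with pitfalls:

* **Occurrence QC** — taxonomy resolution against an accepted-name list,
  rejection of records outside expert range polygons, removal of records
  coarser than 2 km, temporal stratification (pre/post 1950), and
  grid-cell deduplication that keeps records from different periods.
* **Target-group background** — pseudo-absences are drawn only from cells
  where *any* species of the group was recorded, cancelling shared survey
  bias; the sample's pre/post-1950 mix is forced to match the focal
  species' own record mix.
* **The SDM** — a background-normalised exponential (Gibbs) model with
  linear, quadratic and product features and per-feature L1 penalties:
  with feature vector f(x) scaled to [0,1],

      q(x) = exp(β·f(x)) / Σ_bg exp(β·f(x_b)),

  and β minimises `−mean_pres[β·f] + log Σ_bg exp(β·f) + Σ_j λ_j|β_j|`.
  At the optimum each feature's model expectation matches its presence
  mean to within λ_j. Species with < 30 records get 10 bootstrap
  replicates; ≥ 30 get 4-fold cross-validation.
* **Validation** — predictions are made binary at the 10-percentile
  training-presence threshold and clipped to the dispersal-buffered
  minimum convex polygon (MCP) of the records; held-out confusion-matrix
  metrics (sensitivity, specificity, omission, proportion correct, TSS,
  Cohen's κ, rank AUC) are averaged over replicates. A species is
  **modellable** only if κ > 0.4 *and* an expert rated the map good or
  medium.
* **Projection** — future clips grow by the species' annual dispersal rate
  × years elapsed since 1975 (the 1950–2000 midpoint); per-period range
  area (spherical cell areas), area-weighted mean latitude and elevation
  statistics are differenced between the past baseline and the 2080s.
* **Comparative statistics** — group×period trends by GLS with AR(1)
  errors within species; trait regressions by PGLS with Pagel's λ
  estimated by profile ML, studentized-residual outlier removal,
  Shapiro–Wilk residual checks, AICc all-subsets ranking and Akaike-weight
  model averaging.

Because real inputs (occurrence archives, climate rasters, expert panels)
are not reproducible at desk scale, a first-class synthetic-data module
generates every input with known ground truth — virtual species with
known suitability functions on multi-period climate stacks with
prescribed future shifts, and Brownian-motion traits on simulated
phylogenies with known λ and β — so every stage is verifiable.

## Worked example

```python
from lagoshift.pipeline import PipelineConfig, build_synthetic_world, run_pipeline

world = build_synthetic_world(seed=0)            # 24 virtual species, warming future
cfg = PipelineConfig(seed=0, background_n=1000)  # thresholds: kappa 0.4, 10-percentile, <30/>=30 rule, 2-km cut
res = run_pipeline(world, cfg, "results/warming")
print(res["manifest"]["n_modellable"], "modellable")
print(res["changes"].groupby("group")[["range_change_pct", "poleward_deg"]].mean())
```

Running `python analysis/03_warming_scenario.py` (which does the above
plus the trend models) prints:

```
20 of 24 species modellable (kappa > 0.4 and rated good/medium)

mean change (past baseline -> 2080s) by group:
         range_change_pct  poleward_deg  mean_elev_change_m
group
hares               98.54          1.03              107.51
pikas              -92.97          0.72             -130.89
rabbits            -18.81          1.29              181.99

range_change_pct: AR(1) phi = 0.84; F-tests:
                    F  df1  df2       p
period         9.4892    1   49  0.0034
group          1.4525    2   49  0.2439
group:period  17.8834    2   49  0.0000
```

Reading this: 20 of the 24 virtual species pass the joint expert/kappa
gate. Under the prescribed warming, the cold-adapted, dispersal-limited
pika analogues lose almost all of their range (−93% on average, some
going extinct in-scenario) while the mobile, warm-tolerant hare analogues
track the shifting climate poleward (~1° by the 2080s) and expand. The
group × period interaction for range change (F = 17.9, p < 10⁻⁴) says the
groups' temporal trajectories genuinely diverge, after accounting for
AR(1) correlation between a species' successive scenario periods.

The other drivers:

* `analysis/01_validate_components.py` — metric-oracle agreement, the
  gate truth table, SDM niche recovery (AUC vs truth ≈ 0.998, solver vs
  generic-optimiser coefficient gap ≈ 7×10⁻⁶), PGLS λ/β recovery and
  AR(1) φ recovery.
* `analysis/02_poleward_shift_recovery.py` — prescribes an exact 1.0°
  poleward climate translation and recovers it end to end through the
  full pipeline to within 0.001° for every interior, well-sampled
  species.

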