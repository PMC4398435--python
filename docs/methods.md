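# Methods

This note documents the models and procedures implemented in `lagoshift`,
the parameters that matter, the synthetic data used to validate them, and
the numerical and design choices that were genuinely open.

## Occurrence quality control

Records (`species, lon, lat, year, precision_km, source`) pass a fixed
chain: taxonomy resolution (accepted-name set plus a synonym map;
unmatched names rejected), range-polygon screening (point-in-polygon with
an optional great-circle tolerance belt, computed as shapely
nearest-boundary-point followed by the haversine distance), a resolution
cut (records coarser than 2 km removed; the boundary is inclusive, and
records with *missing* precision are dropped by default — a conservative
choice, overridable), period assignment (year < 1950 → `pre1950`,
otherwise `post1950`; missing years dropped by default), and grid-cell
deduplication. "Duplicate" means the same cell of the working grid after
snapping, because that is the resolution at which the models operate;
records from different temporal periods in one cell are both kept, and
ties break by earliest year then lexicographic source so output never
depends on input order. The chain is idempotent and never fabricates
records.

## Grids and environmental stacks

Rasters are plain arrays on a geographic WGS84 grid, cell-center
registered, row 0 northernmost, with half-open cell intervals for
point-to-cell mapping and NaN nodata propagated across layers. I/O is
ESRI ASCII grid — a single-band text format any GIS reads. There is no
resampling or reprojection anywhere: stacks with mismatched grids are
rejected, never silently aligned. Derived layers evaluate arithmetic
expressions (`+ - * /`, `mean`, `min`, `max`, `abs`) over layer names;
division by zero becomes nodata with a warning count. Samples-with-data
(SWD) extraction pairs each record with the stack of *its own period* —
pre-1950 records read the 1900–1949 means, post-1950 records the
1950–2000 means.

## Target-group background

A cell is eligible for a period iff at least one record of any species of
the target group falls in it in that period; this is computed once,
globally, and shared across species. The background sample (default
10,000 points; analyses in this repository use 1,000, see "Problem
sizes") allocates `round(n × pre_fraction)` points to the pre-1950
stratum — the focal species' own pre/post record ratio, banker's rounding,
remainder to post-1950 — and draws cells without replacement, placing
points at cell centers. If a stratum has fewer eligible cells than
requested, all are used with a warning.

## The presence-background model

The estimator is the background-normalised exponential (Gibbs) model —
the mathematical core of maximum-entropy presence-background modelling —
with linear, quadratic and pairwise-product features, min-max scaled to
[0,1] on the training rows. Variables constant on the training data are
excluded entirely (their scaling is undefined). The per-feature L1
weights follow the published feature-class schedules (interpolated on
presence count) scaled by the feature's presence-sample spread over
√m, times a global multiplier (default 1.0).

Optimisation is proximal Newton: gradient = model expectation − presence
mean, Hessian = feature covariance under the current density; the
L1-penalised quadratic subproblem is solved by soft-threshold coordinate
descent and an Armijo backtracking line search accepts the step.
Convergence is declared on the KKT conditions (default tolerance 1e-6,
well below the smallest λ in practice). A tiny elastic stabiliser
(1e-8·‖β‖²) keeps the optimum finite under complete separation — which
genuinely occurs when a narrow-niche species' presences are separable
from a discrete background — and keeps the Hessian positive definite; it
is orders of magnitude below the L1 weights for any plausible coefficient
size. Non-convergence raises with the residual attached.

Predictions use the complementary log-log transform
`1 − exp(−e^H q(x))` of the raw density (H = entropy of the fitted
density over the training background; `raw` is available by flag), with
feature scaling clamped to the training [0,1] range when projecting onto
new climates so the exponential response is never extrapolated.

Replication: < 30 presences → 10 bootstrap replicates (resample
presences with replacement, background fixed, out-of-bag presences held
out); ≥ 30 → 4-fold cross-validation stratified by period. Fewer than 8
presences (≈ the minimum that leaves ~8 points per fold) → the species
is flagged unmodellable-by-data and never fitted. Replicate fits
warm-start from a fit to the full presence set; this changes iteration
counts, not optima. The replicate-set prediction is the arithmetic mean
of the replicate predictions.

## Evaluation and the validation gate

The binary threshold is the 10-percentile training presence value
(lower-interpolation on the sorted training-presence scores; cells ≥ τ
are presence), computed per replicate and averaged for map thresholding.
Metrics are computed on each replicate's held-out presences against the
background points (background = absence) and averaged across replicates:
sensitivity, specificity, omission, proportion correct, Cohen's
κ = (Po − Pe)/(1 − Pe), TSS = sensitivity + specificity − 1, and rank
AUC (Mann–Whitney with midrank ties) — AUC is reported for completeness
but never used for selection or gating. Degenerate margins (Pe = 1)
report κ = 0 with a flag.

Crucially, the accessibility clip (below) and, for restricted variants,
the land-class mask are applied to predictions *before* evaluation: the
clip exists to remove biogeographic over-prediction, and evaluating the
unclipped map would count every climatically similar but inaccessible
background cell as commission error, structurally capping κ near ~0.3
regardless of model quality.

Four model variants are fitted per species — (pre+post vs post-only
input data) × (habitat-restricted vs climate-only). An expert's chosen
variant wins outright; absent one, the highest κ wins with a
deterministic tie-break (habitat-restricted first, then pre+post data).
The gate: **modellable ⇔ κ > 0.4 AND rating ∈ {good, medium}**; only
modellable species enter projections-for-analysis and the comparative
stage (unmodellable species are still projected, for reference only).

## Geometry

The accessibility region is the convex hull (MCP) of the species'
records (degenerate point/line inputs are buffered by one cell and
flagged) buffered outward in kilometres via a spherical
azimuthal-equidistant projection centred on the geometry centroid — so a
"10 km" buffer is 10 km at any latitude. The current-model clip buffer is
the annual dispersal rate × 1 year (configurable); future clips add
rate × (scenario year − 1975), with scenario midpoints 2025/2055/2085 for
the 2020s/2050s/2080s. Future regions therefore nest over time. Clipping
zeroes every cell whose center falls outside the polygon; buffers
crossing the antimeridian raise by default.

## Change metrics

Range area sums spherical cell areas `R² Δλ (sin φ_top − sin φ_bot)`
(latitude-corrected, sub-0.5% of the spheroid truth); mean latitude is
area-weighted; elevation statistics are taken over presence cells of a
co-registered elevation raster; range extents (min/max latitude and
longitude) are recorded so downstream analyses can detect
boundary-pinned ranges. Change between two periods is expressed as %
range change, poleward degrees (sign flipped in the southern hemisphere;
an equator-straddling baseline takes its hemisphere from the larger area
fraction, flagged), and metres of elevation change. A species with no
presence cells in the later period is reported as −100% range change
with undefined latitude/elevation changes (extinct-in-scenario).
Richness maps sum per-cell presences over species; richness change masks
cells occupied only by unmodellable species as uncertain.

By default the baseline map is clipped to its own (current) dispersal
region — the reporting convention. `PipelineConfig.change_baseline_clip
= "future"` instead clips both differenced periods to the final
scenario's region; translation-recovery experiments use this because
differencing a tightly clipped baseline against a widely clipped future
measures the growing accessibility belt, not the climate signal.

## Comparative statistics

* **VIF screen** — iteratively drop the highest-VIF trait while any VIF
  exceeds 5 (VIF_j = 1/(1−R²_j) from regressing trait j on the others;
  perfect collinearity → immediate drop). The tolerance formulation
  (1/VIF) is available as an alternative cutoff.
* **Tip grafting** — a missing species attaches at the midpoint of its
  designated (monophyletic) clade's stem branch, with a pendant length
  restoring ultrametricity; pre-existing pairwise tip distances are
  unchanged exactly.
* **PGLS** — V_ij is the shared root-to-MRCA branch length (accumulated
  in one tree pass); Pagel's λ multiplies the off-diagonal entries.
  λ ∈ [0,1] is estimated by profile maximum likelihood with a 21-point
  grid pre-scan and bounded Brent refinement (tolerance 1e-6) — ML
  rather than REML, with the grid guarding against profile multimodality
  — and tested against both boundaries by χ²₁ likelihood-ratio tests.
  β̂ = (XᵀV⁻¹X)⁻¹XᵀV⁻¹y at λ̂ via Cholesky solves; a singular design
  raises naming the collinear terms. Outliers are flagged at
  |externally studentized residual| > 3 in the whitened (V^{-1/2})
  space, with one removal pass and a single refit; Shapiro–Wilk runs on
  whitened residuals.
* **AICc / all-subsets / averaging** — AICc = −2logL + 2k +
  2k(k+1)/(n−k−1) with k = #coefficients + 2 (σ², λ) for PGLS fits; the
  dredge enumerates every subset of the non-intercept terms (refusing
  > 20 terms), refits each in full (λ re-estimated), and Akaike weights
  w ∝ exp(−Δ/2) feed full (zero-substituted) model averaging;
  conditional averaging is available by flag.
* **Group trends** — GLS of a change metric on group × period with AR(1)
  correlation within species (exact Prais–Winsten whitening), fitted by
  REML by default (the convention for GLS correlation parameters, whose
  plain-ML estimates are biased low by ~(1+3φ)/n at short series
  lengths); Wald F-tests for the period, group, and interaction blocks.
  The AR(1) order is the minimal structure honouring the non-independent
  scenario periods; the order is a deliberate simplification, not a fit.
* **Spearman rank correlation** with midrank ties and the t
  approximation.

## Synthetic data: what it emulates and what it does not

`gen_climate` builds five co-registered periods (past 1900–1949, current
1950–2000, 2020s/2050s/2080s) of smooth latitudinal/longitudinal
gradients plus Gaussian-filtered noise. Future shifts are exact by
construction: additive offsets are added verbatim, and poleward
translations window a latitudinally extended field, so the future raster
equals the baseline translated by a whole number of cells — the property
the recovery experiments rely on. Virtual species have Gaussian
per-variable responses (so the truth is exactly representable by the
linear+quadratic feature space), optional land-class restriction, and
occurrence sampling proportional to truth suitability, with a pre-1950
fraction drawn against the past stack and a deliberate fraction of
coarse-precision records for the QC stage to remove. Expert ratings are
emulated by the Jaccard overlap between the predicted binary range and
the truth range (both defined by the same 10-percentile rule): ≥ 0.7
good, ≥ 0.4 medium, else poor. Comparative data are pure-birth (Yule)
trees rescaled to unit depth, Brownian traits via the covariance
Cholesky, and responses X β_true + ε with ε ~ N(0, σ²V(λ_true)).

The default world is 120 × 160 cells of 0.1° (latitudes 48–60°N), four
variables, and 24 species in three trait-contrasted groups: cold-adapted
narrow-niche habitat-specialist poor dispersers (0.2–0.6 km/yr; the pika
analogue), intermediates (rabbits), and warm-tolerant broad-niche mobile
generalists (1.5–4 km/yr; hares/jackrabbits). Group counts, niche widths
(~2–8% of the grid per range) and the background subsample were chosen so
that the focal species' share of the target-group cloud and the
cloud-to-sample ratio sit in the regime where the κ > 0.4 gate separates
good from poor models — the same proportions, scaled down, that a global
multi-species dataset produces. What the synthetic world does *not*
emulate: real spatial sampling bias, coastlines and barriers, climate
model ensembles and their disagreement, niche responses outside the
quadratic family, and observer error in expert ratings. Passing tests
demonstrate that the machinery recovers known truth under its own
assumptions, not that those assumptions hold for any real dataset.

## Recovery experiments

* **Poleward translation** (`experiments.poleward_recovery`): future =
  baseline translated 1.0° poleward, zero warming, habitat generalists,
  uniform 4 km/yr dispersal so accessibility does not bind, expert
  choice pinned to the climate-only pre+post variant (the restricted
  variants are meaningless without a habitat dimension), both
  differenced periods under the 2080s clip. Species whose estimated
  range touches the study-area boundary or its accessibility envelope in
  either period are excluded mechanically (ranges pinned against a
  coastline-like edge cannot translate freely). Every retained species
  recovers the shift within a small fraction of a cell.
* **PGLS recovery**: 100 replicates at 100 tips in two regimes
  (λ_true = 1 and 0) measure λ̂, the boundary LRT power, and β bias.
* **AR(1) recovery**: 200 independent series of length 60 at φ = 0.6.

## Problem sizes

Analyses and experiments in this repository run at desk scale: 24
species × 150–300 presences, 1,000 background points (the config default
remains the conventional 10,000, which is proportioned for continental
grids), 100–200 replicate simulations. These sizes were chosen so each
study completes in minutes on one core while leaving every statistical
conclusion comfortably away from its threshold.

## Known limitations

* The solver's λ schedule follows the published feature-class defaults;
  with very few presences (< 10) the schedule is extrapolated at its
  boundary value.
* The hemisphere convention resolves equator-straddling ranges by the
  larger area fraction; a range genuinely centred on the equator has no
  meaningful poleward direction.
* Clip polygons are fixed in space; a range moving within a slanted hull
  boundary shows small clip-geometry artefacts in its mean latitude.
  This is a property of the method (accessibility is anchored to where
  the species was recorded), not an implementation error.
* Composite environmental variables are user-defined expressions; no
  fixed bioclimatic variable set is prescribed.
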