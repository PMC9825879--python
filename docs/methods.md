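# Methods

This note documents the models, numerical conventions and design choices
behind `tlpshift`, and what the synthetic studies do and do not show.

## Trait processing and upscaling

The turgor loss point is estimated from the osmotic potential at full
turgor by a linear calibration Ψ_tlp = a·π₀ + b. The default
(a, b) = (0.832, −0.631) is a stand-in from the osmometer literature;
labs should supply their own coefficients (`traits.Calibration`). Both
quantities are water potentials in MPa and strictly negative; a
non-negative input is treated as a unit/sign error and rejected. The
species value is the arithmetic mean over replicates (three individuals;
one replicate each for herbaceous, three for woody species in the
emulated design). NaN replicates raise by default (`nan_policy="drop"`
discards them) so silent data loss cannot occur.

Upscaling follows the community-weighted-mean logic on habitats: within
a cell, only species that occur there contribute; each habitat's value
is the abundance-weighted mean over its contributing species; the cell
value is the cover-weighted mean over habitats *that have a value*,
renormalised by the summed cover of those habitats. Renormalisation is
a deliberate choice: treating unmeasured habitats as zero would drag
estimates toward zero (i.e. toward implausibly high Ψ_tlp); instead the
contributing cover is reported as `coverage` so users can filter
low-coverage cells. Cells with no qualifying habitat are missing, never
zero. A species listed twice for one habitat is an error, not a silent
de-duplication.

The habitat comparison is a classical one-way ANOVA (F statistic with
(k−1, N−k) degrees of freedom) plus Tukey HSD at α = 0.05; the compact
letter display is built by the insert-and-absorb algorithm, so habitats
sharing a letter are statistically indistinguishable.

## Bioclimatic indices

All indices assume the synthetic 365-day calendar (no leap days) with
fixed month lengths. Conventions, chosen once and frozen for
bit-stability:

* **BIO1.95** — 95th percentile of daily mean temperature pooled over
  the period; percentiles use linear interpolation between order
  statistics (numpy default).
* **BIO4** — standard deviation (ddof = 1) of the 12 monthly mean
  temperatures, averaged over years, reported in °C (not ×100).
* **CFD.ann / CDD.ann** — frost days are days with daily *mean*
  temperature ≤ 0 °C (the cubes carry tas only; the threshold and the
  variable choice are configurable via `ClimateConfig`); dry days have
  precipitation < 1 mm. Runs are confined to calendar years by default
  (the annual maximum run, averaged over years); a boundary-spanning
  variant is available by flag.
* **BIO12.5** — 5th percentile of the per-year precipitation totals.
* **BIO15** — coefficient of variation (%) of the 12 monthly totals,
  averaged over years, computed on month-length-normalised totals
  (mm per 30-day-equivalent month). With raw totals, unequal month
  lengths alone would register ≈3% "seasonality" for perfectly uniform
  rain; normalising makes an aseasonal climate score exactly zero.

Climate-to-survey transfer is the overlap-area-weighted mean over the
climate cells each survey cell intersects (axis-aligned rectangles,
exact interval arithmetic). The transfer is idempotent when the grids
coincide.

## Random-forest modelling

One forest per species group per climate model, on predictors centred
and scaled to unit variance. Standardisation parameters are learned from
the historical training table and re-applied unchanged to future tables:
scaling with future statistics would leak the scenario into the model
and distort projections. A predictor that is constant in training keeps
scale 1, so it stays constant (and its permutation importance is exactly
zero).

Spatial folds are k-means clusters of cell centroids — spatially
disjoint subsets that separate training from validation geographically.
Performance is estimated by nested resampling: the outer loop
(5 folds × repetitions, each repetition re-seeding the partitioning)
scores generalisation; the inner loop (5 folds on the outer-training
cells) tunes mtry ∈ [1, 6], sample fraction ∈ [0.2, 0.9] and minimal
node size ∈ [1, 10] by uniform random search, objective inner-CV RMSE,
ties broken toward smaller mtry. Outer scores therefore never use rows
seen during the tuning of the model they evaluate. The production model
is tuned by (non-nested) spatial CV on the full data and refit on all
rows; nested CV is reported for honesty only. R² is computed per fold
against the held-out fold's variance and aggregated as the mean of
per-fold values; with a constant target R² is undefined and reported as
missing (RMSE is still 0).

Variable importance is the mean increase in RMSE over N permutations of
one predictor column (dispersion reported alongside); partial dependence
forces the predictor to each grid value and averages predictions, with a
±2 SE band across cells.

Reference budgets are ntree = 500, 25 outer repetitions, 50 inner
evaluations and N = 500 permutations (`ModelConfig` defaults). The
synthetic studies in the tests and the acceptance script run scaled-down
budgets — typically ntree = 60–100, 1–3 outer repetitions, 6–20 inner
evaluations, N = 20–100 — chosen so the full study suite completes on a
single CPU in minutes; at 48 cells the larger budgets only add runtime,
not information (verified: 500 trees and 15 evaluations change the mean
CV R² by < 0.02).

## Projections and plasticity risk

ΔΨ_tlp = (predicted − measured)/measured × 100, evaluated literally.
**Sign convention:** with negative measured values, a shift toward more
negative Ψ_tlp yields a *positive* ΔΨ_tlp; map legends must say so.
Congruence across climate models is 100·sd/|mean| (sd with ddof = 1);
the absolute value keeps the CV of negative potentials positive. With a
single model the ensemble is returned and congruence is missing, with a
warning.

The plasticity envelope is the closed interval [Ψ_s − δ, Ψ_s + δ]
(δ = 0.44 / 0.22 MPa, the high/low seasonal osmotic-adjustment
capacities); a prediction exactly at a bound counts as within. The
simulation counts species (no abundance weighting), uses the raw
ensemble prediction of the high-emission scenario, and is run for pooled
angiosperms and gymnosperms. Percentages are reported with
within = 100 − below − above, so the three parts always sum to exactly
100. The regional summary is the unweighted mean ± SD across cells.

## The synthetic world

The generator emulates the *layout* and *statistical structure* of a
regional floristic study joined to daily climate simulations, not any
real region:

* **Region.** Survey cells of 3′ × 5′; elevation rises monotonically
  from the southern (coastal) to the northern (alpine) edge of the
  domain, 0–2300 m, with 120 m seeded roughness. The climate grid is an
  integer coarsening of the survey grid (several survey cells per
  climate cell, as with ~11 km climate output over ~6 km survey cells).
* **Habitats.** Per-cell Dirichlet mixtures whose concentrations peak at
  each habitat's elevation optimum, so communities turn over along the
  gradient. The default trait truth couples lower Ψ_tlp to hotter/drier
  habitats (saltmarsh −3.0 … alpine grassland −1.55 MPa mean), with the
  decline steepening toward the xeric end.
* **Climate.** Temperature = sea-level baseline − 6.5 °C/km lapse +
  sinusoidal season (±10 °C) + Gaussian daily noise. Precipitation is a
  two-state wet/dry chain with gamma amounts; dry spells persist longer
  toward the south, wet-day amounts grow northward, and both carry
  seeded cell-level departures from the latitudinal gradient (real rain
  fields have orographic structure of their own; without this the
  precipitation indices would be near-duplicates of the temperature
  gradient, |r| ≈ 0.99, and no importance measure could separate them).
* **Scenarios.** Warming is additive. Drying (factor < 1) thins wet-day
  occurrence — each wet day is kept with probability equal to the
  factor — which scales mean precipitation by the factor in expectation
  *and* lengthens dry spells, as drying does in regional projections;
  wetting scales amounts. An identity shift reproduces the baseline cube
  bit for bit.
* **Occurrences.** Presence probability = Σₕ fraction(h)·g(weight) with
  g = {1→0.95, 0.7→0.8, 0.4→0.5, 0.1→0.2} (configurable).
* **Trait response.** For model-recovery studies, cell-level
  Ψ_tlp = intercept + Σ coefⱼ·predictorⱼ (+ optional quadratic terms) +
  N(0, noise_sd), evaluated on the computed bioclim table.

What passing the synthetic studies shows: the kernels are exact (oracle
equivalence), the resampling machinery is leak-free, a known climate
driver is recovered with high skill and a shuffled target shows none,
and the full chain is deterministic under a seed. What it does not show:
anything about measurement error structure, phylogenetic signal,
imperfect occurrence detection, habitat-map error, or real climate-model
bias — none of which the generator emulates.

## The recovery study and its ceiling

The headline recovery fixture (48 cells, 120 species, 20 years, trait
response driven by BIO1.95 with 0.05 MPa noise) is deliberately small.
Two quantitative caveats:

1. **Per-fold R² is bounded by within-fold signal.** Spatial folds on a
   gradient-dominated region have modest internal trait variance, so the
   0.05 MPa noise costs more R² than it would under random folds.
   Scoring the *true generating function* on the same folds yields a
   mean per-fold R² of ≈ 0.87–0.88 — no model can beat that ceiling.
   Across seven fixture realizations of the same study conditions the
   tuned forest scores 0.74–0.88 (mean ≈ 0.81, sd ≈ 0.05), i.e. roughly
   87–100% of the ceiling; single-realization values scatter widely
   because each per-fold R² is normalised by a small held-out variance.
   Any fixed-threshold check near 0.8 on a single realization is
   therefore close to a coin flip, and results on one seed should not be
   over-interpreted in either direction.
2. **Importance under collinearity.** Consecutive frost days are a
   deterministic companion of the temperature driver (both follow
   elevation). Permutation importance reflects where trees split, and on
   roughly half of the fixture seeds the forest anchors its top splits
   on the frost-day contrast, ranking it above the true driver; the true
   driver is in the top two essentially always. This is a documented
   property of permutation importance with correlated predictors, and it
   mirrors the empirical pattern that temperature extremes and frost-day
   runs act as co-dominant predictors of regional Ψ_tlp variation.

## Known limitations

* Forests cannot extrapolate: under strong warming the hottest cells'
  predictors leave the training range and predictions clamp at the
  training edge, so shift magnitudes at the warm margin are conservative.
* Overlap weights use plain degree² areas (no cos-latitude correction);
  at survey-cell scale over a ~1° domain the error is negligible.
* The 365-day calendar ignores leap days; real-calendar cubes must be
  regridded to it before use.
* The habitat ANOVA treats species–habitat affiliations as independent
  observations; species affiliated with several habitats contribute to
  each.
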