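# Methods

This note documents the models, conventions, numerical choices, and known
limitations of the package. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## The pipeline model

The package treats climate sensitivity as a property of *climatic* range:
a species' broad-scale distribution is assumed to track climate, so the
change in the area classified as climatically suitable between a baseline
and a future period measures its exposure. The chain is: monthly climate →
bioclimatic covariates → per-species occurrence model → suitability
surfaces under future climates → binary ranges → loss/expansion →
category. Biotic interactions, dispersal limitation, and demography are
deliberately outside the model: "potential expansion" is climatic
opportunity, not a prediction of colonisation.

## Synthetic data: what it emulates and what it does not

The generator stands in for continental volunteer-survey archives (a
breeding-season route program and an early-winter count-circle program) and
for gridded climate products.

* **Landscape.** An `ny × nx` grid (default 100×100 cells of 10 km).
  Elevation is a smooth Gaussian-filtered random field (mean 500 m, relief
  150 m, floored at sea level); the westernmost column is coastline, with
  distance-to-coast the Euclidean distance transform; latitude runs
  linearly 30–60 °N across rows.  The relief is deliberately gentle: at
  the default lapse rate it adds under 1 °C of scatter to annual mean
  temperature, keeping the cell-density of climate values close to uniform
  along the latitudinal gradient so that the archetype calibration below
  behaves the same on every landscape realization (strong relief lumps the
  density and distorts loss/expansion fractions unpredictably).
* **Baseline climate.** Annual-mean tmin = 14 °C at the southern edge
  − 0.6 °C per degree latitude + lapse rate (−6.5 °C/km) × elevation + a
  small smooth noise field (SD 0.5 °C); a 10 °C seasonal sinusoid peaking
  in July (mean-zero over the year, so the monthly mean equals the annual
  field exactly); tmax = tmin + 8 °C. Monthly precipitation decays from
  100 mm/month at the coast to 40 mm inland (e-folding 250 km) with a 30%
  seasonal cycle, floored at 0.
* **Futures.** Additive warming per scenario × period
  (A2: 1.1/2.2/4.0 °C, A1B: 1.0/1.9/3.2, B2: 0.8/1.3/2.8 for
  2020/2050/2080) — SRES-like ordering with scenarios diverging late in the
  century; the mildest scenario's wide 2050→2080 gap keeps a safe corridor
  between the two classification horizons on any landscape realization — plus a spatially smooth per-GCM jitter field (SD 0.3 °C)
  shared by tmin and tmax; precipitation is scaled by a mild drying
  multiplier (0.88–0.98). In the generator, temperature anomalies are
  additive and precipitation anomalies multiplicative (conventional delta
  practice); the downscaling *operation* is additive for all variables with
  a floor at zero for precipitation.
* **Species.** Occupancy probability is `p_max · Π_v exp(−(x_v − μ_v)² /
  2σ_v²)` over a configurable set of bioclim variables (default: BIO1
  only, which keeps the archetype calibration analytic). Three archetypes
  place the optimum at quantiles of the baseline BIO1 distribution:
  shrinkers at the 2nd percentile with σ = 0.6 °C (their climate band
  retreats past the cold edge of the landscape by 2050: loss ≫ 0.5 and
  expansion ≈ 0, because both retention and expansion require cold cells
  that barely exist — robust even though fitted ranges are somewhat wider
  than truth ranges), shifters at the 40th percentile with σ = 1.6 °C (the
  band translates north; under the mildest scenario loss stays below 0.5
  at 2050 but exceeds it by 2080 in every scenario), stable species at the
  median with σ = 5 °C (maximum loss ≈ 0.4). σ values and the scenario
  table were calibrated once against these analytic targets — checked over
  many landscape seeds, since loss/expansion fractions respond to the
  realized cell-density of BIO1 — before any model fitting, and are fixed. Truth ranges are cells with
  suitability ≥ 0.5·p_max; truth categories are produced by applying the
  package's own classifier to exact truth loss/expansion, so truth is
  self-consistent with the classification rules by construction.
* **Surveys.** 500 sites surveyed every year 1980–2009 (training
  2000–2009, testing 1980–1999), plus a 10% reserve of sites surveyed only
  in the test decades to support a spatially independent re-evaluation.
  Effort is lognormal (median 8 h, log-SD 0.4); ordinal dates are uniform
  over early summer (days 152–196).
* **Detection.** `P(record) = suitability(site) · (1 − exp(−β · effort))`
  with β = 0.3 h⁻¹. Occupancy and detection are deliberately conflated
  into one Bernoulli probability and effort enters the fitted model as a
  covariate, not as a separate detection layer — volunteer count data of
  this kind violate the closure assumptions occupancy models require. The
  saturating-exponential form is a stand-in (no canonical form exists for
  these programs) and is isolated behind the `detect_beta` parameter.

What passing tests on these data do **not** show: robustness to spatial
sampling bias, observer heterogeneity, interannual climate variability
(the generator matches one baseline climate to all survey years),
non-Gaussian or interacting niche responses, and land-cover constraints.
Quantities that depend on the real continental geometry — mean turnover
values, mean shift distances in km — are properties of the synthetic world
and are not comparable to published continental estimates.

## Bioclim conventions

Monthly mean temperature is (tmin+tmax)/2. Quarters are all 12 consecutive
3-month windows with December→January wrap-around; ties in
wettest/driest/warmest/coldest are broken toward the earliest starting
month (as in the dominant SDM toolchain). BIO4 is the *sample* standard
deviation (ddof = 1) of monthly mean temperature × 100; BIO15 is sample SD
of monthly precipitation over (mean + 1) × 100 — the +1 guards arid cells.
All 19 variables are computed; the pipeline consumes a configurable subset
(default: all 19). Grid extraction is nearest-cell with no interpolation,
and delta downscaling resamples coarse anomalies to the fine grid by
nearest cell; if tmin and tmax anomalies differ enough to invert the
diurnal ordering, tmax is clipped up to tmin.

## Model settings

Boosted regression trees via xgboost (`tree_method=hist`, single thread,
seeded): learning rate 0.01, `max_depth` 5 (the conventional analog of
interaction depth 5), logistic loss, bag fraction 0.5. The tree count is
the argmin of 10-fold cross-validated log-loss, searched up to
`max_trees` = 3000 with early stopping after 50 stagnant rounds, floored
at `min_trees` = 1000. Species need ≥ 20 presences and ≥ 20 absences to be
modelled (the inclusion rule is configurable; any skip is logged). QC
drops species whose AUC *or* deviance explained falls more than 2 sample
SDs below the cohort mean — one-sided, since "performing well" can only be
violated downward; zero spread keeps everything.

## Ranges and classification

The max-Kappa threshold is fitted once per species on training-period
predictions versus observations and reused for all projections
(recomputing per projection would require future observations). Ties in κ
break toward the smallest threshold, the more conservative choice for rare
species (larger ranges). Consensus forecasting averages suitability
*before* thresholding; a majority-vote-after-thresholding variant would be
a one-line change but is not the cited practice. Loss comparisons are
strict (">50%"), so exactly half lost is stable. The endangered "no net
gain" clause is evaluated at 2050 per scenario (E₂₀₅₀ < L₂₀₅₀), required in
all scenarios; expansion is never truncated at 1 internally (that is a
plotting convention only).

## Biogeographic summaries

Centroid weights use the binary range with equal cell weights (each cell's
share of the distribution); a suitability-weighted variant is available
via the `weights` argument. Latitude converts at 111.32 km/degree with no
cos-latitude area weighting, appropriate for an equal-area-style grid.
Cells empty in both periods have Bray–Curtis dissimilarity 0 by convention
and are excluded from the study-area mean.

## Rank statistics and variance components

All priority schemes are heavily tied 3-level ordinals, so Kendall τ_b
(tie-corrected, asymptotic tie-adjusted p) is primary; τ_a is computed
alongside because published analyses often do not state the variant.
Climate-sensitivity ranks collapse to 3 levels (endangered 1, threatened
2, stable 3); "other" species are excluded. PIF threat scores are kept as
published and also re-expressed as ranks with the shared polarity (highest
threat → lowest rank).

Variance components use a dedicated REML estimator for the
random-intercepts-only model (the only model this analysis needs):
the criterion is evaluated in the q-dimensional level space via the
Woodbury identity, optimised over log-variances by L-BFGS-B with a bounded
Nelder–Mead polish. σ²ₑ is floored at 10⁻⁶·var(y): with exactly zero
residual noise the REML likelihood diverges on the boundary, and the floor
regularises the problem while leaving factor variances and proportions
identified (verified against the closed-form balanced one-way ANOVA
estimator and simulated crossed designs). Variances are optimised in log
space, so negative components cannot arise; estimates at the lower bound
report as 0. Factors with fewer than two levels are dropped with a log
entry; a constant response returns zero variance everywhere with the
residual proportion defined as 1.

## Pipeline and interfaces

A single `RunConfig` (YAML-loadable) drives the run; sub-seeds for every
stochastic stage derive from the run seed via named seed sequences, so
runs are reproducible end to end and every output table carries the config
hash. Grids are written as ESRI ASCII rasters (rows stored north-down,
arrays kept south-up internally); tables as CSV. The CLI exposes `run`,
`simulate`, and `reproduce`; the remaining stages are library functions
exercised inside `run` — a per-stage file-shuffling CLI would duplicate
the library surface without adding capability, so the functions are the
interface for stage-level work.

`reproduce_published` consumes CSV exports of published per-species
supplementary tables through a user-editable schema map (the journal ships
spreadsheets whose column names vary by export path), normalises
percent-versus-proportion automatically, recovers expansion from relative
range-size change (E = change + loss) when expansion is not given
directly, and reports computed counts/correlations side by side with any
user-supplied published values. The package does not hard-code published
numbers.

## Problem sizes

The default experiment — also used by `scripts/acceptance.py` and the
full-scale test — is 30 species (10 per archetype), a 100×100 grid of
10 km cells, 500 sites × 30 years (plus 50 test-only sites), and
3 scenarios × 3 GCMs × 3 periods. These sizes give stable category
recovery and Monte-Carlo errors well inside the tolerances asserted in the
tests while keeping a full run in the minutes range on one CPU. The
default GCM ensemble for applied runs is 13 scenario×GCM combinations
(5/4/4).

## Known limitations

* Single-variable default niches make covariate-importance patterns
  unrealistically sparse; pass multi-variable responses to `NicheSpec` for
  collinearity studies.
* The delta-method exercise coarsens the synthetic future by block means
  before adding anomalies, so per-GCM jitter is only resolved at the
  coarse scale.
* No reprojection between coordinate systems, no statistical
  (quantile-mapping) downscaling, no dispersal constraints, no regional
  zonal summaries.
* AUC and deviance explained on temporally split synthetic data are
  optimistic relative to real-survey settings because the synthetic world
  has no climate trend between training and test decades.
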