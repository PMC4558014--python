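# rangecast

Climate-sensitivity assessment of species geographic ranges: from
presence/absence survey records and monthly climate grids to species
distribution models, thresholded range maps under future emissions
scenarios, a *climate endangered / threatened / stable* classification, and
the downstream biogeographic and statistical summaries conservation
planners use.

The package is aimed at conservation biogeographers and quantitative
ecologists who want a tested, reusable implementation of this pipeline.
Because real continental survey archives and downscaled climate rasters are
large and access-restricted, every stage can be exercised end to end on
**synthetic data with exact ground truth**: virtual species with known
Gaussian niches, a seeded landscape and climate generator, and a truth
table against which the fitted pipeline's classifications are scored.

## The method

1. **Bioclimatic covariates.** Monthly minimum/maximum temperature and
   precipitation grids are summarised into the 19 standard bioclimatic
   variables BIO1–BIO19 (annual means, extremes, seasonality, and
   wettest/driest/warmest/coldest quarter summaries, with quarters the 12
   wrapped consecutive 3-month windows).
2. **Occurrence models.** One boosted-regression-tree model per species and
   season, P(presence) ~ BIO1..BIO19 + survey covariate (party-hours of
   effort for early-winter count circles; ordinal survey date for breeding
   routes), with Bernoulli loss, learning rate 0.01, tree complexity
   (interaction depth) 5, tree count chosen by 10-fold cross-validated loss
   and floored at 1000. Models train on one decade and are evaluated on
   earlier decades by AUC and Bernoulli deviance explained, optionally at
   sites never used in training; species whose metrics fall more than 2 SD
   below the cohort mean are excluded.
3. **Future climates by the delta method.** Coarse model anomalies
   (future − reference, per month and variable) are added to the fine-scale
   baseline; precipitation is floored at 0. Projections for the general
   circulation models within each scenario × period are averaged cell-wise
   (consensus forecasting), giving 9 suitability surfaces per species
   (SRES A2/A1B/B2 × 2020/2050/2080).
4. **Range maps by maximum Kappa.** The continuous suitability surface is
   binarised at the threshold maximising Cohen's κ = (p_o − p_e)/(1 − p_e)
   against the training observations; the same per-species threshold is
   reused for every projection.
5. **Classification.** With S = |current ∩ future| / |current| (stability),
   L = 1 − S (loss) and E = |future \ current| / |current| (potential
   expansion): *climate endangered* = L₂₀₅₀ > 0.5 with E₂₀₅₀ < L₂₀₅₀ in all
   scenarios; *climate threatened* = not endangered and L₂₀₈₀ > 0.5 in all
   scenarios; otherwise *climate stable*; introduced or marginal species are
   *other*.
6. **Summaries.** Range centroids (latitude, elevation, distance to coast)
   weighted by each cell's share of the binary range and their shifts
   (km north, m upslope, km inland); per-cell species gains/losses and
   binary Bray–Curtis turnover d = 1 − 2a/(2a + b + c); Kendall τ_b between
   climate-sensitivity ranks and existing priority schemes (IUCN,
   federal/BCC, PIF); REML variance components attributing variation in
   range outcomes to species, scenario, and cohort factors.

## Worked example

```python
from rangecast import pipeline

cfg = pipeline.RunConfig(gcms_per_scenario={"A2": 3, "A1B": 3, "B2": 3},
                         seed=1, outdir="out")
res = pipeline.run_end_to_end(cfg)  # ~7 min on one CPU

print(res.recovery_rate)                          # 1.0
print(res.recovery.groupby(["archetype", "assigned"]).size())
#  shifter    threatened    10
#  shrinker   endangered    10
#  stable     stable        10
print(res.metrics["auc"].mean())                  # 0.889
print({s: c["mean_dissimilarity"] for s, c in res.community.items()})
# {'breeding': 0.718, 'nonbreeding': 0.690}
print(res.centroid_shifts.groupby("season")["northward_km"].mean())
# breeding 705.3, nonbreeding 713.6
```

Thirty virtual species (10 range-shrinkers, 10 range-shifters, 10 stable)
are simulated on a 100×100 grid of 10 km cells and surveyed at 500 sites
over three decades. Every species is assigned the sensitivity category its
generating archetype implies (`recovery_rate = 1.0`): shrinkers — whose
cold-edge climates disappear under warming — come out *climate endangered*,
shifters *climate threatened*, broad-tolerance species *climate stable*.
The held-out AUC of 0.90 shows the fitted models recover the niches; the
Bray–Curtis means quantify community turnover by 2080 under the
high-emissions scenario; and the centroid shifts are northward, tracking
the imposed warming against the landscape's 0.6 °C/degree latitudinal
gradient.

The same run writes an appendix-style per-species summary
(`species_summaries.csv`), category count tables, centroid shifts,
gain/loss/turnover grids (ESRI ASCII), rank correlations, and variance
components to `out/`, all stamped with the config hash.

A command-line interface wraps the library:

```bash
rangecast run --seed 1 --outdir out      # full pipeline
rangecast simulate --nx 100 --ny 100     # landscape + climate + bioclim layers
rangecast reproduce --s1 s1_export.csv --s7 s7_export.csv
```

`rangecast reproduce` re-derives headline classification counts and rank
correlations from CSV exports of published per-species supplementary
tables, with a schema map for arbitrary column naming and optional
side-by-side display against published values.

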