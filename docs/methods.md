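# Methods

This note documents the models behind `sorgenv`, the choices made where the
design was genuinely open, and what the synthetic data can and cannot show.

## Problem

Breeding programs need to know which *types* of season their target region
actually produces — the target population of environments (TPE) — because a
hybrid's ranking depends on when and how hard water deficit and heat hit the
crop. `sorgenv` characterizes a sorghum TPE by simulating two daily stress
indices over many site-years, clustering the seasonal trajectories into
water stress patterns (WSP) and heat stress patterns (HSP), and collapsing
the WSP × HSP pair into four yield-relevant environment categories (ECG):
no stress, heat, water, and combined heat-and-water stress.

## Crop and soil model

The season simulator is intentionally minimal: the pipeline consumes the
*shape* of the stress trajectories, not absolute yields, so the model keeps
only the processes that set stress timing and intensity.

**Phenology.** Thermal time accumulates daily from a broken-stick response
on mean temperature: zero at or below the base temperature (11 °C), linear
to `t_opt − t_base` at the optimum (30 °C), declining linearly to zero at
the maximum (42 °C). Emergence, anthesis and maturity occur at fixed
thermal-time targets (defaults 60, 700 and 1250 °Cd for `hybrid_1`; the
slightly later `hybrid_2` uses 730/1300). These targets are calibrated to
the bundled synthetic climate so that mid-May through early-July sowings
reach maturity before the season cools; they are cultivar parameters, not
universal constants, and are fully configurable.

**Canopy and growth.** Leaf area follows a logistic in thermal time
(midpoint 360 °Cd, slope 0.013 °Cd⁻¹, maximum 4.0 at the reference density
of 28 plants m⁻²) and scales linearly with plant density. No senescence is
modelled. Radiation interception uses an extinction coefficient of 0.55;
daily biomass gain is radiation-use efficiency (1.25 g MJ⁻¹) times
intercepted radiation times the water-stress index RT.

**Water balance and RT.** The soil is a layered bucket (default: 1.5 m
silt-loam-like profile, ~255 mm plant-available water). Each day rain
infiltrates top-down to the drained upper limit, excess cascades and leaves
as drainage; stage-one soil evaporation (≤ 6 mm) comes from the surface
layer; root uptake is removed from rooted layers in proportion to each
layer's extractable supply `kl × (water − LL·thickness)`. Mass balance
closes to numerical precision and is asserted in the tests. Transpiration
demand is the water needed to realize the radiation-limited gain at a
transpiration-efficiency coefficient of 9 Pa (0.009 kg kPa m⁻² mm⁻¹), using
a daytime vapour-pressure deficit of 75% of the Tetens span between Tmax
and Tmin. The relative transpiration index is

    RT = min(1, supply / demand),   RT = 1 when demand = 0,

recorded daily from emergence to maturity. Roots deepen at
1.5 mm °Cd⁻¹ until anthesis, capped by the profile.

**Heat and GT.** The heat-sensitive window spans 50 °Cd before to 100 °Cd
after anthesis. The seed-set factor is 1 − f where f is the fraction of the
window — weighted by daily thermal time by default (`weighting="days"` is
available; sources differ and neither choice changes the qualitative
patterns) — on which Tmax exceeds 32 °C. For trajectory building the daily
heat index is binary: 0 on window days above the threshold, 1 otherwise;
only the windowed aggregate has an established definition, so the daily
form is the simplest consistent one.

**Yield.** Grain number is proportional (1500 grains per g m⁻² d⁻¹) to the
mean growth rate over the anthesis window; yield is the minimum of the sink
(grain number × 28 mg maximal grain weight) and the source (80% of
post-anthesis biomass gain), multiplied by the GT factor. Nitrogen is not
simulated: the two fertility managements are represented solely by their
paired plant densities (28 and 14 plants m⁻²), and the NO₃ initial
condition is accepted in config but ignored.

## Synthetic weather and soils

`SiteClimate` describes a site by monthly Tmax/Tmin means (interpolated to
day-of-year), a shared AR(1) temperature residual (SD 3 °C, lag-1
correlation 0.6 — sharing the residual between Tmax and Tmin preserves the
diurnal range, so Tmax ≥ Tmin by construction), independent per-day
Bernoulli rain occurrence with monthly probabilities, exponential wet-day
depths, and a clear-sky radiation sinusoid reduced 25% on wet days. Three
presets span a west→east Great Plains gradient: `dry_west` (~250 mm yr⁻¹),
`intermediate` (~500 mm) and `wet_east` (~850 mm), with annual mean
temperatures near 13–14 °C and July Tmax means of 34/32/31 °C.

What the generator does **not** emulate: rainfall persistence (no Markov
chain — occurrence is independent day to day), spatial correlation between
sites, real station topography or soils, frost termination, and any trend
or teleconnection structure. Passing tests therefore demonstrate that the
*machinery* (simulation → binning → clustering → classification →
variance decomposition) behaves correctly under known generative truth, not
that the bundled presets reproduce any particular station's climatology.

`gen_trial_table` builds unbalanced site × year × hybrid yield tables from
an additive random-effects truth (site, ECG-of-site-year, hybrid,
residual), with a configurable fraction of records deleted at random — the
ground truth for the variance-component recovery tests. Default variances
(site 1.2, ECG-in-site 1.8, hybrid 0.15, residual 0.6, ×10⁶ (kg ha⁻¹)²
about a 6000 kg ha⁻¹ mean) give realistic trial-to-trial spreads.

## Envirotyping

Daily indices are averaged into 100 °Cd bins from emergence; every
trajectory is truncated or right-padded (repeating the final bin) to
`floor(tt_maturity/100)` bins of the reference cultivar (12 by default), so
k-means sees equal-length vectors. Water and heat matrices are clustered
independently with Euclidean k-means (best of 25 k-means++ restarts,
deterministic per seed); bins share units in [0, 1], so no standardization
is applied. Cluster labels are renamed 1..k by descending membership for
reporting stability.

The number of clusters can be chosen by a majority vote of three internal
validity indices (silhouette, Calinski–Harabasz, Davies–Bouldin); with no
majority the smallest candidate wins (no common structure → parsimony).
The pipeline default fixes k at 4 water and 3 heat patterns, the structure
the method is designed to expose; `"auto"` enables the vote.

New seasons are classified by minimum sum of squared differences to the
stored centroids (ties toward the lowest label). The ECG mapping is a total
function of the (WSP, HSP) pair given two membership sets: the non-stress
water patterns and the low heat patterns. The mapping's own defaults are
({2}, {1}); the pipeline chooses the sets data-driven as the pattern with
the highest centroid mean (least stress), which is robust to the
frequency-based renaming.

## Evaluation statistics

* **Agreement**: RMSE, NRMSE = 100·RMSE/mean(obs) (the normalizer is by
  observed mean — stated prominently because other conventions exist), NSE
  (1 = perfect, 0 = mean predictor), Pearson r. Degenerate inputs (zero
  observed mean or variance) yield NaN plus an explicit flag rather than an
  exception.
* **Variance components**: the random-effects model
  `yield = μ + site + ECG(site) + residual` is fitted by REML
  (statsmodels MixedLM with a variance component for ECG within site).
  Estimates are non-negative by construction; percentages of the component
  total are reported. Hybrid is excluded by default and available behind a
  flag as an additional within-site component. On balanced data the REML
  estimates coincide with the expected-mean-squares ANOVA estimator, which
  the tests verify independently.
* **Gap imputation**: missing cells of the hybrid × environment table are
  initialized with column means and refined by iterating column-centering,
  a rank-2 truncated SVD, and overwriting only the missing cells, until the
  largest imputed-cell change falls below an absolute tolerance. Observed
  cells are never modified. On exactly low-rank truth the scheme converges
  to the deleted values; on noisy data the final iterations move by
  amounts far below agronomic relevance, so the pipeline uses a tolerance
  of 0.1% of the mean yield.
* **Biplot**: the completed matrix is aggregated to hybrid × ECG means,
  column-centered and decomposed; hybrid scores are U·S and category
  loadings the right singular vectors on the first two components. Angles
  between loading vectors summarize between-category correlation (≈180°
  antipodal, ≈90° uncorrelated).

## Pipeline scale and determinism

The default demonstration grid is 3 sites × 20 years × 4 sowing dates
(May 15, Jun 1, Jun 15, Jul 1) × 2 managements × 2 cultivars = 960 seasons
(~15 s on one core); test fixtures use smaller grids (tens of seasons).
Seasons that fail to reach maturity (cold-year late sowings, ~2% of the
default grid) are excluded from clustering with a logged count. All
randomness descends from one integer seed; outputs are written sorted with
fixed float formatting, so a rerun with the same config and seed is
byte-identical (the run manifest, which carries a wall-clock timestamp, is
the one exception).

## Known limitations

* No tillering, senescence, stay-green, night-temperature or grain-size
  heat effects; no frost; no nitrogen dynamics. Absolute yields are
  indicative only — the deliverable is the stress-pattern classification.
* The daily heat indicator is binary, so heat trajectories are coarser
  than water trajectories.
* The ECG membership sets assume the least-stressed pattern is a meaningful
  non-stress reference; in a region with no mild seasons the four-way
  regrouping degenerates.
* The variance model treats the ECG effect as independent across site-years
  sharing a label; with few ECG levels per site the nested component is
  weakly identified, and fully confounded designs (one ECG per site) are
  flagged as inestimable.
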