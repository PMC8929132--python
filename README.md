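# sorgenv

Water-deficit and heat envirotyping for sorghum (*Sorghum bicolor* L.)
breeding regions.

Multi-environment trials sample a breeding region's seasons unevenly, so
genotype-by-environment interaction is hard to interpret without knowing
*which kinds of season* the region actually produces — the target
population of environments (TPE). `sorgenv` characterizes a TPE the way
crop-model-based envirotyping studies do:

1. **Simulate** a simplified daily sorghum season over a site × year ×
   sowing-date × management × cultivar grid, recording two stress indices:
   the relative transpiration index `RT = min(1, supply/demand)` from a
   layered soil water bucket (1 = unstressed), and a binary heat index
   derived from days with Tmax > 32 °C inside the thermal-time window
   50 °Cd pre- to 100 °Cd post-anthesis, which also yields the seed-set
   factor `GT = 1 − (stressed fraction of the window)`.
2. **Cluster** the seasonal trajectories (averaged into 100 °Cd bins from
   emergence) with k-means into water stress patterns (WSP) and heat
   stress patterns (HSP), independently; cluster counts come from a
   majority vote of silhouette, Calinski–Harabasz and Davies–Bouldin
   indices, or are fixed in config.
3. **Classify** independent site-years by minimum sum of squared
   differences to the stored centroids and **regroup** each (WSP, HSP)
   pair into four environment categories (ECG): no stress, heat, water,
   heat-and-water.
4. **Quantify** how much observed trial yield variance the ECG explains
   with the REML random-effects model `yield = μ + site + ECG(site) + ε`,
   and display hybrids against categories in an SVD biplot after low-rank
   imputation of the unbalanced hybrid × environment table.

Because station weather, survey soils and university trial records are not
bundled, the `synthetic_data` module generates statistically controlled
stand-ins (a stochastic daily weather generator with three Great Plains
presets, labelled stress-trajectory prototypes, and trial tables with known
variance structure), so every stage is testable against ground truth.

## Worked example

Simulate one dry-western season and inspect the outcome:

```python
import json
from sorgenv import crop_sim, synthetic_data

weather = synthetic_data.gen_weather(
    synthetic_data.SITE_PRESETS["dry_west"], 2005, 1, seed=7
)
res = crop_sim.simulate_season(
    weather,
    crop_sim.default_soil_profile(),
    crop_sim.CULTIVAR_PRESETS["hybrid_1"],
    {"sowing_date": "2005-06-01", "density": 28.0},
)
print(json.dumps(res.summary(), indent=2))
```

```json
{
  "sowing_date": "2005-06-01",
  "emergence_date": "2005-06-07",
  "anthesis_date": "2005-07-28",
  "maturity_date": "2005-09-26",
  "yield_kg_ha": 3149.6673712775064,
  "gt_factor": 0.5870828203916465
}
```

The crop emerged after 60 °Cd, flowered in late July and matured in late
September; heat during the flowering window removed ~41% of potential seed
set (`gt_factor` 0.59), and water limitation held yield near 3.1 t ha⁻¹.
`res.daily` carries the day-by-day `rt`/`gt` trajectory that the
envirotyping stage consumes.

The full study runs from the command line:

```bash
sorgenv --seed 1 --outdir out demo
```

which sweeps the default grid (3 sites × 20 years × 4 sowing dates ×
2 managements × 2 cultivars), clusters the trajectories, writes pattern
frequencies per site, classifies each site-year into an ECG, builds an
ECG-driven synthetic trial table, and reports the variance decomposition —
on the default conditions the ECG accounts for roughly 70% of trial yield
variance, far above the residual share, with the dry-west site dominated by
terminal water-stress patterns and the wet-east site by low-stress ones.
Individual stages are available as `synth-weather`, `simulate`,
`characterize`, `classify` and `evaluate` subcommands; see
`sorgenv --help`.

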