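# biogaps

Gaps and biases in digital accessible biodiversity information: how
completely do point-occurrence records (of the kind mobilized through
data-sharing networks such as GBIF) document the species that expert range
maps expect in each grid cell — and what drives those gaps?

The package is aimed at biodiversity informaticians and macroecologists.
It provides, end to end and with a synthetic-world generator so that every
stage is testable against known ground truth:

- **Nested equal-area grids** (four grain levels, each doubling the cell
  edge) on a planar rectangle of unit cells, with exact parent/child maps.
- **Inventory completeness.** Per cell, per taxon and per grain:
  expected richness *S*<sub>exp</sub> (species whose range overlaps the
  cell), documented richness *S*<sub>doc</sub> (expected species with at
  least one validated record in the cell), record count *N*<sub>rec</sub>,
  and completeness *C* = *S*<sub>doc</sub>/*S*<sub>exp</sub>; plus the
  minimum grain at which a cell reaches a completeness threshold, and the
  redundancy histogram of duplicated species–cell combinations.
- **Twelve per-cell driver variables** spanning appeal (endemism
  richness, topographic range, protected-area fraction), accessibility
  (travel time, airport proximity, proximity to contributing
  institutions), security, scientific integration (country H-index ×
  international collaboration, data-network participation) and resources
  (national research funding, funding and size of contributing
  publishers), with log/z standardization.
- **Multi-model inference.** Completeness enters a binomial GLM as the
  composite response (*S*<sub>doc</sub> successes out of *S*<sub>exp</sub>
  trials, logit link). All 2^p predictor subsets are fitted and ranked by
  AIC; every subset with ΔAIC < 10 is refitted as a spatial model with a
  residuals autocovariate (RAC: the neighbourhood mean of the non-spatial
  model's residuals, radius chosen by AIC). The minimum adequate model
  (MAM) is the spatial refit with the lowest AIC. Importance is reported
  as the MAM's standardized coefficients β and as the %SS of each
  predictor in a type III ANOVA whose response is the AIC of all 2^p
  models and whose factors code predictor presence/absence.
- **Spatially honest tests.** Moran's *I*; Pearson/Spearman correlations
  and group contrasts whose p-values (*P*<sub>Dut</sub>) are computed on
  geographically effective degrees of freedom following the
  Clifford–Richardson/Dutilleul approach; Tukey-style multi-group
  comparisons; Kruskal–Wallis across grains.
- **Country report.** Required vs documented species–cell combinations
  per country, each country's share of the globally missing combinations,
  and an OLS of country completeness on log10 per-capita wealth.

## Worked example

```python
import biogaps as bg

world = bg.generate_world(bg.WorldConfig(seed=1))   # 32x32 cells, 250 species,
res = bg.analyze_world(world)                       # 50k records, 8 countries
r = res.results
print(r["mam_d2"], r["density_d2"], r["shared_deviance_fraction"])
```

prints (seed 1):

```
0.7917717557985301 0.8652734454790637 0.9500203863249335
```

i.e. the minimum adequate spatial model explains **79%** of the deviance
in completeness, record density alone achieves *d*² = **0.87**, and
**95%** of the MAM-explained deviance is shared with density — gaps are
mostly where few records are. `res.importance` ranks the drivers; on this
world the generator's true effects (national research funding +,
data-network participation +, endemism +, travel time −) head both the β
and %SS columns with the right signs, while the ten null predictors stay
near zero.

The `examples/` directory holds one short narrative script per
capability (world generation, completeness/redundancy, driver inference,
spatial tests, country report); each prints its numbers with a line on
what they mean. A thin CLI mirrors the pipeline stages:

```sh
biogaps run --config config.yaml          # simulate -> ... -> report
biogaps infer --config config.yaml        # just the driver models
```

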