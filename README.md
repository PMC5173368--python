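# cavenet

Quantitative tools for cave-biodiversity conservation baselines: multi-scale
spatial autocorrelation over irregular cave point networks, mixed-model
identification of biodiversity drivers, and an indicator-based relevance
ranking for conservation prioritization.

The package is aimed at speleologists, conservation analysts and
environmental-licensing practitioners who work with cave survey tables — one
row per cave with projected coordinates, size measures (length, area,
volume), trophic resources (guano, detritus, roots, water), species richness
and presence of troglobites (obligate cave dwellers), rare troglobites and
resident bat populations. It ships a synthetic-landscape generator that
emulates such surveys (by default, an 844-cave / 8-report iron-cave
landscape on a 40 km canga extent), so the whole pipeline is testable
without restricted survey data.

## What it computes

**Spatial structure.** For a value vector *x* on cave locations, distance-band
neighbor graphs (`i ~ j` iff `0 < d(i,j) ≤ band`) are coded binary (`B`),
row-standardized (`W`) or globally standardized (`C`), and global
autocorrelation is measured per band:

- Moran's I for interval data (species richness, model residuals):
  `I = (n/S₀) · Σᵢⱼ wᵢⱼ zᵢ zⱼ / Σᵢ zᵢ²`, with expectation `−1/(n−1)` and
  variance under the randomization null;
- the single-colour (presence–presence) join-count statistic for binary
  data: `BB = ½ Σᵢⱼ wᵢⱼ xᵢ xⱼ`, with non-free-sampling (hypergeometric)
  null moments and a one-sided test for clustering.

`scale_profile` sweeps 20 bands from the 1st percentile of pairwise
distances to the maximal extent, yielding a correlogram with 95% CIs.

**Drivers of biodiversity.** Species richness is modeled by a Gaussian
linear mixed model with a random intercept per source report (the survey
that contributed each cave); presence outcomes by Bernoulli GLMMs (mixed
logistic regressions) whose marginal likelihood is evaluated by adaptive
Gauss–Hermite quadrature. Model selection follows a likelihood-ratio-test
protocol: backward elimination of main effects at α = 0.05 (dropping the
highest non-significant p first), a search over first-degree interactions
among retained effects, an optional per-stratum residual-variance
extension under REML, and residual correlograms as a spatial diagnostic.

**Relevance ranking.** Each cave scores one point per biodiversity
indicator present — richness above the upper quartile, troglobites, rare
troglobites, resident bat population — and the score maps to a proposed
relevance category (3–4 → maximal, 2 → high, 1 → mid, 0 → low), which is
cross-tabulated against the reported legislation-based category.

## Worked example

```python
from cavenet import (SimulationConfig, simulate_landscape, scale_profile,
                     ModelSpec, fit_lmm, rank_caves, score_caves,
                     compare_to_reported)

table = simulate_landscape(SimulationConfig(seed=1))   # 844 caves, 8 reports
coords = table[["x_m", "y_m"]].to_numpy()

prof = scale_profile(coords, table.richness.to_numpy(float), stat="moran")
print(prof.to_frame()[["band_m", "estimate", "expected", "p"]].head(3).round(4))

spec = ModelSpec("richness", "gaussian",
                 fixed_terms=("log(area_m2)", "guano", "water_reservoirs",
                              "detritus", "roots", "bat_population"),
                 interactions=(("log(area_m2)", "guano"),))
print(fit_lmm(spec, table).summary_frame().round(2).to_string(index=False))

ranking = rank_caves(score_caves(table))
print({k: round(100 * v, 1) for k, v in ranking.category_shares.items()})
print("reported maximal+high: %.1f%%" %
      (100 * compare_to_reported(ranking, table).reported_high_or_above_share))
```

prints

```
      band_m  estimate  expected       p
0  1024.2821    0.0853   -0.0012  0.0001
1  3104.0279    0.0626   -0.0012  0.0000
2  5183.7737    0.0497   -0.0012  0.0000
              term  estimate   se  t_or_z    p
         intercept      6.61 3.11    2.12 0.03
      log(area_m2)      9.11 0.30   30.81 0.00
             guano    -13.04 2.48   -5.26 0.00
  water_reservoirs     -3.62 1.21   -2.99 0.00
          detritus      6.06 0.86    7.01 0.00
             roots     14.85 0.98   15.14 0.00
    bat_population     25.26 1.64   15.41 0.00
guano:log(area_m2)      5.88 0.48   12.35 0.00
{'low': 46.9, 'mid': 27.1, 'high': 15.3, 'maximal': 10.7}
reported maximal+high: 72.7%
```

Reading it: simulated richness is spatially autocorrelated at small scales
(Moran's I ≈ 0.085 in the ~1 km band against a null expectation of −0.001,
p < 0.001) and the autocorrelation decays with distance; the refitted mixed
model recovers the generative effects (e.g. richness rises by ≈ 9.1 species
per log-unit of cave area against a generative 9.32, more steeply in caves
with guano); and under the indicator scheme ~11% of caves rank maximal
while ~73% carry a maximal-or-high reported label — the status-quo offset
burden the ranking is designed to relieve.

The same analysis runs from a shell:

```bash
cavenet simulate --n-caves 844 --seed 1 -o caves.csv
cavenet run --input caves.csv -o out/        # profiles, models, ranking
cavenet rank caves.csv -o ranking.csv
```

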