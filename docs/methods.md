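# Methods

This note documents the statistical machinery in `cavenet`: the spatial
statistics and their null models, the mixed models and the selection
protocol, the relevance ranking, the synthetic-landscape generator, and the
numerical and design choices behind them.

## Spatial autocorrelation on cave point networks

Caves are treated as points with projected planar coordinates in meters
(a helper projects lon/lat through a configurable UTM zone, default 22S,
the zone of the emulated study region). Neighbor graphs are distance-band
graphs: `i ~ j` iff `0 < d(i,j) ≤ band`, with half-open band semantics so
coincident points are never their own neighbors and the upper bound is
inclusive. Weight coding styles follow the standard convention — `B`
binary, `W` row-standardized (each connected cave's weights sum to 1,
favoring observations with few neighbors), `C` globally standardized to
sum to the number of connected nodes.

**Moran's I** uses the classical randomization (permutation-moment) null:
`E[I] = −1/(n−1)` and the variance formula involving `S₀, S₁, S₂` and the
sample kurtosis, with a two-sided normal p-value. **The presence–presence
join count** `BB = ½ Σ wᵢⱼ xᵢ xⱼ` uses non-free-sampling moments
(conditioning on the observed number of presences, i.e. hypergeometric
sampling) and a one-sided test for an excess of presence–presence joins.
Both choices match the defaults of the standard spatial-econometrics
tooling, which makes cross-validation against existing scripts possible.
Correctness is enforced in the test suite by O(n²) brute-force double-sum
oracles (agreement to 1e-12) and by permutation oracles for the null
moments and p-values.

**Islands.** Nodes with no neighbor inside a band are excluded from the
statistic: they carry zero weight rows and are dropped from the effective
`n` and from the mean-centering, and their count is reported per band.

**Scale profiles.** The default correlogram uses 20 equally spaced band
thresholds from the 1st percentile of pairwise distances to the maximal
pairwise distance ("the maximal extent of the study region"); the spacing
and count are configurable. The per-band 95% CI is `estimate ±
1.96·√variance`. Two degeneracies are inherent at the largest scales and
worth knowing about: on a complete row-standardized graph Moran's I is
identically `−1/(n−1)` (variance 0), and the one-sided join-count normal
approximation becomes skew-limited as the graph saturates. Type-I
calibration of both tests is therefore verified (empirical level in
[0.03, 0.07] at α = 0.05 on i.i.d. fields over clustered points) for bands
below half the maximal extent; beyond that no implementation can hold a
nominal level because the statistic itself degenerates.

## Mixed models

**Gaussian LMM.** One random intercept per source report:
`y = Xβ + Z u + ε`, `u ~ N(0, τ²)`, `ε ~ N(0, σ²)`. The fit profiles β and
σ² analytically and optimizes the variance ratio `λ = τ²/σ²` on the log
scale in one dimension (with an explicit boundary comparison at λ = 0, so
a fit with no between-report heterogeneity reduces exactly to OLS).
ML is used for every likelihood-ratio test on fixed effects; REML is
available for final reporting and is required for the variance-function
comparison. The optional variance function (one residual SD per stratum of
a grouping column, the `varIdent` idiom) is fitted by direct Nelder-Mead
optimization of the exact marginal likelihood using rank-one
Sherman–Morrison updates per report. Standard errors come from
`(X'V⁻¹X)⁻¹`; Wald p-values use the normal reference. The implementation
is cross-checked against an independent ML fit (statsmodels MixedLM) and a
closed-form balanced one-way oracle in the tests.

**Bernoulli GLMM.** Mixed logistic regression with the same random-intercept
structure. The marginal likelihood integrates each report's intercept out
by adaptive Gauss–Hermite quadrature centered at the conditional mode
(found by a damped Newton iteration per report) and scaled by the local
curvature; one node reproduces the Laplace approximation, and the default
15 nodes matches a dense-integration oracle to better than 1e-8 at
realistic heterogeneity (σ ≲ 2; extreme σ needs more nodes, and stability
is audited by node doubling). β and log σ are optimized jointly (BFGS with
a Nelder–Mead polish); standard errors come from the observed information
(numerical Hessian). Complete separation is detected as diverging
coefficients and flagged, never silently truncated; fits collapsing to the
σ = 0 boundary are flagged and reduce exactly to ordinary logistic
regression.

**Likelihood-ratio tests.** `χ² = 2(ℓ_full − ℓ_reduced)` clamped at zero,
df = difference in fixed-parameter count (k−1 for a k-level categorical
term; +1 per extra residual SD in a variance-function comparison), upper
tail of the χ² reference. Nested fits must share identical rows; the
selection protocol guarantees this by fixing the complete-case row set of
the starting specification for the whole trace. Random-effect variances at
the boundary are reported with a flag but the χ² reference is left
unadjusted, matching common practice. A monotonicity audit warns whenever
adding parameters decreases the log-likelihood beyond numerical tolerance.

**Selection protocol.** Backward elimination drops, one per round, the
term with the highest single-term LRT p among those with p ≥ α (α = 0.05
by default), recording every test; ties are broken by term name so traces
are deterministic. The subsequent interaction search evaluates pairwise
products of the retained main effects by greedy forward addition (smallest
p < α each round). Since "all combinations" of interactions is ambiguous
and exhaustive enumeration is exponential, the greedy search is the
default and an exhaustive mode (all interaction subsets, each member
required to be individually significant, best log-likelihood wins) is
available for ≤ 5 retained mains. Complete-case subsets are built per
response, not by global row deletion, so models for different responses
may legitimately use different sample sizes.

**Diagnostics.** Residual correlograms use conditional residuals
(response-scale minus the estimated report effect for the LMM; Pearson for
the GLMM). Extra predictors (e.g. troglobite richness, observed only on a
subset of caves) are tested by refitting both the base and augmented model
on the intersection of complete cases and comparing by LRT.

## Relevance ranking

The richness threshold is the 75th percentile with linear interpolation
between order statistics (the common default in both major statistical
ecosystems), and "high richness" means strictly exceeding it, so a
constant richness vector flags no cave. Indicator weights default to 1;
non-default weights produce non-integer scores and therefore require an
explicit score→category mapping, since the 3–4/2/1/0 mapping is defined
only on the integer scale. Missing indicator values yield a missing score
— reported, never imputed as absence — to avoid silently demoting
under-surveyed caves. The comparison against reported relevance produces
the proposed×reported contingency table, the share of caves reported
maximal-or-high (the status-quo offset burden), the distribution of
reported categories per indicator count, the median area of caves with ≥ 3
indicators, and a χ² association statistic.

## Synthetic landscape generator

The generator emulates a multi-report iron-cave survey:

- **Locations**: Gaussian clusters (default 15 clusters, SD 1.5 km) inside
  a 40 km square extent; reports cover spatially coherent blocks of
  clusters (8 reports by default), so report effects are regional.
- **Sizes**: log cave area ~ N(meanlog 5, sdlog 2) m²; log length and log
  volume are tied to area through power-law exponents 0.56 and 1.35 with
  an equicorrelated Gaussian dependence (default ρ = 0.925, giving a
  size-PCA first-component share of (1+2ρ)/3 ≈ 95%). The length allometry
  puts the median/mean cave length near 16.4/31.0 m, the scale reported
  for iron-cave surveys.
- **Resources**: independent Bernoulli attributes (guano 0.35, detritus
  0.50, roots 0.25, water reservoirs 0.15, percolating water 0.40),
  prevalences chosen once as field-realistic.
- **Richness**: generated on the response scale from the published
  mixed-model estimates (area effect 9.32 per log m², guano −15.99 with
  interaction 6.41, water reservoirs −3.88, detritus 5.61, roots 16.70,
  bat population 22.26), a free intercept of 10 species, a report random
  intercept (SD 8), an optional exponential-covariance Gaussian field
  (SD 5, range 10 km — the distance at which correlation falls to 1/e),
  and N(0, 12²) residual noise, then clamped at zero and rounded. The
  Gaussian-then-round construction mirrors the fitted model (a Gaussian
  LMM on counts) rather than an ecological count process; the intercept
  and noise scales keep the clamped fraction negligible (< 0.5%) so the
  generative coefficients remain recoverable.
- **Presence outcomes**: logistic models on log area (troglobites 0.69,
  rare troglobites 0.85 with water −0.81, bat populations 1.65) with free
  intercepts calibrated so marginal prevalences are ≈ 0.45 / 0.15 / 0.10,
  plus a report intercept on the logit scale (SD 0.5). Troglobites and
  rare troglobites are drawn jointly — troglobites ~ Bern(p_t), then
  rare | troglobites ~ Bern(min(1, p_r/p_t)) — which preserves **both**
  marginal logistic models exactly while making "rare ⇒ troglobite"
  structural. (Independent draws with post-hoc masking would distort the
  rare-troglobite marginal and bias coefficient recovery.)
- **Reported relevance**: rare troglobites force "maximal"; other caves
  are "high" with probability 0.667 (so maximal+high ≈ 70% of caves, the
  offset burden reported for the emulated regime), the rest split evenly
  between mid and low. The full legal criteria are out of scope.
- **Troglobite richness**: a thinned count (1 + Binomial(richness, 0.08))
  for troglobite caves, observed with probability 0.39, emulating the
  partial availability of that variable across reports.

Identical config + seed yields a byte-identical table.

**What the generator does not emulate** — and hence what passing tests do
not show about real surveys: measurement error and report-specific survey
effort; resources correlated with cave size or with each other; seasonal
structure (dry/wet rounds are collapsed into one richness total);
non-Gaussian richness noise (real counts are heteroscedastic and skewed,
which is why the printed standard errors of the original survey are larger
than those obtained under the generator's cleaner noise); stygofauna; and
the geological/cultural components of legal relevance.

**Recovery experiments** (acceptance tests and `scripts/acceptance.py`)
simulate with the spatial field switched off: the fitted models assume
residuals independent given report, and the emulated study's residual
diagnostics support exactly that assumption, so it defines the study
condition for coefficient recovery. The landscape-level default keeps a
positive field so correlograms show the documented decay of
autocorrelation with scale.

## Numerical choices and limitations

- Variance-ratio optimization bounded on log λ ∈ [−25, 15] with an exact
  λ = 0 comparison; boundary fits flagged.
- GLMM random-intercept SD optimized as log σ, clipped to [e⁻¹⁰, e⁵];
  log σ < −6 is treated as the σ = 0 boundary.
- Singular designs raise an error naming the aliased terms (pivoted QR);
  zero or negative areas are rejected at validation rather than dropped.
- Log transforms are natural logs of areas in m²; rescaling the area unit
  shifts only the intercept (tested invariance).
- Selection traces, model tables, profiles and rankings are serialized as
  JSON/CSV; the pipeline writes a manifest with the exact config and seed,
  and never mutates its input table.
- Problem sizes used by the test suite and the acceptance script — 2000
  caves / 8 reports / 20 seeds for recovery, 300 points / 4000 replicates
  for test calibration, 844 caves for the survey-scale landscape — were
  chosen so each experiment has enough resolution for its tolerance while
  the whole suite stays desk-scale.
- Known limitations: a single (non-nested, non-crossed) random intercept;
  Gaussian and Bernoulli families only; no AIC-based selection; no local
  indicators of spatial association or kernel-weighted graphs; LRT χ²
  references unadjusted at variance boundaries.
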