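# Methods

This note documents the statistical machinery, the choices made where the
design was genuinely open, and what the synthetic-data tests do and do not
demonstrate about real data.

## Detrending and chronology building

Ring-width series carry a biological age/size trend (wide juvenile rings,
declining with age) that must be removed before climate analysis. Each core
is detrended by a **natural cubic smoothing spline** fitted on the year grid
and used as a divisor: TRIₜ = TRWₜ / trendₜ. The spline is parameterized by
its *frequency response*: a penalty weight λ is solved in closed form from
the discrete symbol of the curvature penalty,

```
A(ω) = 1 / (1 + λ · 3(2 − 2cos ω)² / (2 + cos ω)),    ω = 2π/period,
```

so that A = 0.5 at the chosen cutoff period (default 15 years, response
0.5). The implementation is the Reinsch banded solve
`s = y − λQ(R + λQᵀQ)⁻¹Qᵀy`; it agrees with
`scipy.interpolate.make_smoothing_spline` to ~5·10⁻¹⁴ and additionally
supports series as short as 4 rings. The transfer function is verified
empirically: a 15-year sinusoid is attenuated to 50 % ± 5 % and a 100-year
sinusoid retained above 90 %.

Degenerate fits (trend ≤ 0, possible near suppressed series ends) drop the
affected years with a warning; values are never clamped.

Cores are detrended individually and then averaged per tree (plain mean per
year); species chronologies are the per-year **Tukey biweight robust mean**
(c = 9, median start, MAD scale, iterated to 10⁻¹⁰; median fallback when
MAD = 0) of tree-level indices. The chronology's standard deviation over the
analysis period (`sd_tri`) is kept as an omnibus indicator of climate
sensitivity. Where the study design leaves the core-combination order open,
we average *after* detrending because the mixed model's response is the
tree-level mean index; chronology-level `sd_tri` (not per-tree) matches the
one-value-per-species use downstream.

### Signal attenuation by detrending — a real property, not a bug

A 15-year-cutoff spline on a 44–64-year series absorbs the low-frequency
share of *any* signal, including the climate signal of interest. On
noise-free synthetics the full path (rings → spline → mixed model) returns
single-species coefficients at roughly 0.75–0.9 × the planted value (e.g.
0.046–0.050 for a planted 0.060). Practitioners should read Table-2-style
coefficients as *post-detrending* sensitivities. Consequently the pipeline's
parameter-recovery guarantees are stated at two levels: unbiased CI coverage
for the mixed model on directly constructed panels, and bounded attenuation
(sign and magnitude preserved, mean ratio > 0.6) for the full path.

## Climate covariates

* **Frost days**: strict `tmin < 0 °C`; a day at exactly 0 °C is not frost.
  Spring frost = March + April total.
* **Winter temperature**: day-weighted mean of January–March monthly means.
  The regression covariate follows this Methods-style definition even though
  winter correlations are often displayed for Dec–Feb; season boundaries are
  function arguments, so monthly exploration is unaffected.
* **PET** (Thornthwaite, 1948 formulation): annual heat index
  I = Σ(T/5)^1.514 over the year's months with T > 0; exponent
  a = 6.75·10⁻⁷I³ − 7.71·10⁻⁵I² + 1.792·10⁻²I + 0.49239;
  PETₘ = 16(10T/I)ᵃ · (daylength/12) · (days/30), zero for T ≤ 0.
  Daylength comes from standard solar-declination geometry at the mid-month
  day; latitude defaults to 52.25°N (the maritime site the defaults mimic).
  Valid for |latitude| < 66.5°.
* **SPEI**: the k-month rolling sum (default 3) of D = P − PET is fitted
  *per calendar month* over a calibration window with a three-parameter
  log-logistic distribution by unbiased probability-weighted moments, then
  mapped through the standard-normal quantile (Abramowitz–Stegun rational
  approximation). The fit uses the generalized-logistic (Hosking L-moment)
  parameterization κ = −τ₃, identical to the log-logistic for positively
  skewed samples and well-defined for the occasional left-skewed sample that
  a strict positive-skew parameterization cannot fit. Calibration defaults
  to the analysis common period; within it each calendar month's index has
  mean ≈ 0 and sd ≈ 1 (verified to ±0.05 on 44-year synthetics). The summer
  covariate is the 3-month index read at August, i.e. the June–August
  balance.

## Bootstrapped correlation grids

For each species, TRI is paired with each of 5 monthly variables
(frost days, mean temperature, PET, precipitation, SPEI) over the 16-month
window from previous June to current September. Pairs (years) are resampled
with replacement (default 1000 draws); a cell is *significant* when the
95 % percentile interval excludes zero — the standard dendroclimatic
convention, since the test form behind "P < 0.05" marks in published grids
is rarely stated. Degenerate resamples (zero variance, possible for sparse
frost counts) are dropped from the bootstrap distribution; fully degenerate
cells are reported as NaN rather than invented. Per-species RNG substreams
are derived from (seed, CRC32 of species code), making results independent
of processing order. Null calibration: on no-signal synthetics the
significant-cell rate is ~5 % (asserted ≤ 8–9 %).

## Sensitivity mixed model

`tri ~ 0 + C(species) + C(species):z_frost + … + C(species):z_winter`,
random intercept per tree, REML (statsmodels MixedLM). Cell-means coding
gives one directly readable coefficient per species and covariate; the
response is left unstandardized (only climate is z-scored over the common
period) so coefficients are TRI change per SD of covariate, the scale on
which published coefficients of this design run ~0.01–0.13. Wald p-values
use the normal approximation (the residual degrees of freedom here are in
the thousands, where t and z are indistinguishable; the exact-df method is
deliberately not configurable until a concrete need appears). R²m/R²c
follow the variance-partition formulation: var(Xβ̂) over
(fixed + random + residual), and (fixed + random) over total. Because
ratio-detrending removes each tree's multiplicative level, the random
intercept variance is typically ≈ 0 and R²m ≈ R²c — the expected behaviour
for this design, not a fitting failure. Per-species R² is the squared
Pearson correlation of fixed-effect predictions with observations, over
tree-years ("individual") and over yearly species means ("chronology");
chronology-level R² ≥ individual-level on shared-signal data because
averaging removes idiosyncratic noise.

VIF is computed per covariate as 1/(1 − R²ⱼ) from regressing it on the
others (with intercept); the four seasonal covariates from synthetic climate
stay well below 5. An optional outlier screen (|TRI − 1| > k·SD, default
k = 4, off by default) is provided for damaged-core workflows; removal
counts are logged.

## Growth potential

* **Diameter growth** (cm yr⁻¹): from `radius ~ species + species:age` over
  the first 20 cambial years with per-tree random age slopes (REML); the
  species radius slope (mm yr⁻¹) × 2 ÷ 10. A constant 3.05 mm ring width
  therefore yields 0.61 cm yr⁻¹ diameter growth, which pins the unit
  conventions. Trees shorter than 20 rings contribute their available early
  ages. When the between-tree slope variance is numerically zero the REML
  fit is singular; the model then degenerates to (and is replaced by) the
  identical fixed-effect least-squares solution, with a warning.
* **BAI** (cm² yr⁻¹): π(r²ₜ − r²ₜ₋₁) from cumulative widths, assuming
  circular cross-sections; for a to-pith series ΣBAI = πr²_final to 10⁻⁹
  relative (a conservation identity used as a test). Series not reaching
  the pith are flagged (radius offset unknown; BAI biased low near pith).
* **Mass growth** (kg yr⁻¹ m⁻¹): area growth (m² yr⁻¹) × wood density
  (kg m⁻³), densities supplied as a per-species CSV.
* Sensitivity–potential correlations use species means (one value per
  species, N = number of species), matching the published design.

## Phylogenetic signal

Blomberg's K as in the README formula, with C built from root-to-MRCA
depths (computed via root distances and patristic distances; Cholesky
solves, no explicit inverse in the statistic). Exact identities used as
tests: K ≡ 1 on a star tree (C ∝ I), and affine invariance K(ax+b) = K(x).
Significance is a permutation test: trait values shuffled across tips
(default 999 permutations), statistic = phylogenetically weighted MSE
(smaller = more signal), p = (1 + #{MSE_perm ≤ MSE_obs})/(n_perm + 1).
Calibration on a fixed 19-tip tree: mean K over ≥ 200 Brownian simulations
is 1.0 ± 0.1, type-I error 5 % ± 2 %, power against Brownian alternatives
≥ 80 %. A designated outgroup tip is pruned before analysis;
non-ultrametric trees are accepted (the statistic does not require
ultrametricity).

## Synthetic data generator

The generator emulates the study conditions the pipeline was designed for:

* **Climate**: daily mean temperature = 10.1 °C annual mean + 7.5 °C
  sinusoid (peak mid-July) + AR(1) weather noise (φ = 0.7, σ = 1.8 °C);
  tmin = tmean − seasonal diurnal offset (2.5 + 2.0 cos, peak mid-January)
  − half-normal depression (σ = 1.5 °C), which concentrates frost in late
  winter/early spring and makes May frost rare; precipitation is Bernoulli
  (0.6) × Gamma(shape 2, scale 1.9 mm), giving ≈ 830 mm yr⁻¹ with an
  annual SD (~53 mm) calibrated so that every year of 20 seeded 44-year
  runs stays within 600–1100 mm.
* **Rings**: log TRWₜ = log(a·e^(−b·age) + c) + Σβₖzₖ(t) + u_tree + ε, with
  u ~ N(0, 0.10²), ε ~ N(0, 0.08²), and two cores per tree differing by
  multiplicative noise at one tenth of the year-noise SD. The log link
  keeps widths positive and makes TRI ≈ 1 + β·z, i.e. planted β are on the
  same scale as the fitted coefficients. The negative-exponential asymptote
  c > 0 avoids zero-trend divisions.
* **Traits**: multivariate normal(0, σ²C) via Cholesky; random ultrametric
  trees from a seeded random-coalescence construction, rescaled to a fixed
  root-to-tip depth.

Every dataset carries a truth record (betas, trend parameters, tree
effects, seeds) and regeneration from (config, seed) is bit-identical.

**What passing tests do not show**: the generator has no spatial
autocorrelation between trees, no disturbance/release events, no missing or
mis-dated rings, exchangeable years (no climate trend), and independent
year noise across trees. Real cores violate all of these; the tests
establish the correctness and calibration of the machinery, not robustness
to field pathologies.

## Problem sizes and numerical choices

Default test problem sizes — 6 species × 5 trees × 50 years for end-to-end
runs, 5 species × 10 trees × 44 years × 100 replicates for recovery, 300
Brownian replicates and 499–999 permutations for K — were chosen as the
smallest sizes at which the calibration quantities stabilize well inside
their tolerances. Ties and degenerate inputs: readers reject rather than
repair invariant violations; constant traits, constant covariates and
zero-variance correlations raise errors naming the offender; bootstrap and
permutation RNG is a single seeded `numpy` Generator per run with
deterministic substreams, so reruns are byte-identical.
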