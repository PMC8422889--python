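# ringsense

Climate–growth analysis for multi-species tree-ring data, built for the
common-garden setting: many conifer species on one site, ten trees per
species, two increment cores per tree, and several decades of annual rings.
The question it answers is *which seasonal climate factors limit each
species' stem growth, how strongly, and whether that sensitivity — and the
species' growth potential — track phylogeny*.

## What it computes

1. **Detrending and chronologies** — each core's ring-width series (TRW, mm)
   is divided by a cubic smoothing spline with a 50 % frequency cutoff at
   15 years, giving a dimensionless ring-width index (TRI ≈ 1). Cores are
   averaged per tree, and species chronologies are the year-by-year Tukey
   biweight robust mean of tree-level indices.
2. **Climate covariates** — from a daily station record: monthly means and
   totals, frost-day counts (t<sub>min</sub> < 0 °C), Thornthwaite potential
   evapotranspiration (PET), the climate–water balance *D = P − PET*, and
   the 3-month SPEI (log-logistic fitted per calendar month by unbiased
   probability-weighted moments, mapped to a standard normal scale). Four
   seasonal regression covariates per year: spring frost days (Mar–Apr),
   current and previous summer SPEI (Jun–Aug balance read at August), and
   mean winter temperature (Jan–Mar, day-weighted).
3. **Bootstrapped correlation grids** — Pearson correlations between each
   species chronology and 5 monthly climate variables over 16 lagged months
   (previous June → current September), with 1000 pair resamples and
   percentile confidence intervals.
4. **Sensitivity mixed model** — tree-level TRI regressed on the four
   standardized covariates with species × covariate interactions (cell-means
   coding) as fixed effects and a random intercept per tree (REML). Each
   coefficient is a species' growth response per SD of covariate; the fit
   reports VIF, marginal/conditional R², and per-species R² at tree-year and
   chronology level.
5. **Growth potential** — early-age diameter growth (2 × the species' fixed
   radius-vs-age slope over the first 20 years, from a random-slope mixed
   model), mean basal area increment BAI = π(r²ₜ − r²ₜ₋₁), and stem mass
   growth (area growth × wood density); plus the cross-species Pearson
   correlations between sensitivity and potential.
6. **Phylogenetic signal** — Blomberg's K with permutation p-values:

   K = (MSE₀/MSE) / ( [tr(C) − n/(1ᵀC⁻¹1)] / (n−1) ),

   where C is the Brownian-motion variance–covariance matrix of the tree's
   tips, MSE₀ the mean square error of tip values about the phylogenetic
   mean â = (1ᵀC⁻¹x)/(1ᵀC⁻¹1), and MSE the phylogenetically weighted
   version. K ≈ 1 under Brownian evolution.

Because raw core measurements of this kind of study are rarely deposited,
the package ships a first-class synthetic-data generator
(`ringsense.synthetic_data`) producing a daily maritime-temperate climate,
ring-width panels with known species responses, and Brownian traits — every
stage is testable end to end with recorded ground truth.

## Worked example

Generate a small synthetic study (6 species × 5 trees × 50 years) and run
the whole pipeline:

```bash
ringsense synth --seed 42 --preset small --outdir demo/fixture
cat > demo/run.yaml <<EOF
rwl: demo/fixture/rings.rwl
daily_climate: demo/fixture/daily_climate.csv
tree: demo/fixture/tree.nwk
wood_density: demo/fixture/wood_density.csv
outgroup: OUTG
outdir: demo/out
seed: 42
EOF
ringsense run-all --config demo/run.yaml
```

`demo/out/table2.csv` then holds the species sensitivity coefficients
(excerpt, rounded):

```
species_code  beta_frost  beta_spei_cur  beta_spei_prev  beta_winter
        SPAA      -0.029          0.000           0.024       -0.012
        SPBB      -0.087          0.054          -0.025        0.023
        SPCC      -0.071          0.062           0.027       -0.012
        SPDD      -0.070          0.041          -0.026        0.049
        SPEE       0.018          0.066          -0.028       -0.008
        SPFF      -0.010          0.053          -0.034        0.064
```

Each number is the expected TRI change per standard deviation of the
covariate: SPBB loses ~0.09 index units per SD of spring frost days and
gains ~0.05 per SD of summer water availability. The generator's truth file
(`demo/fixture/truth.json`) records the planted values — e.g. SPBB's true
frost response is −0.090 and summer response 0.058 — so the recovery is
direct to verify (estimates sit slightly below truth because spline
detrending absorbs part of any climate signal; see `docs/methods.md`).
`table4.csv` holds Blomberg's K per trait, e.g. frost sensitivity K = 1.23
(p = 0.11) on this 6-species toy tree, and `grid.csv` the bootstrap
correlation grid per species.

The same stages are available individually (`ringsense detrend`,
`climate`, `climgrowth`, `sensitivity`, `potential`, `phylosignal`) and as
library functions.

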