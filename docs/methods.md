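# Methods

This note documents the statistical machinery in `microgrowth`: the models,
their assumptions, the defaults and why they were chosen, what the
synthetic-cohort generator does and does not emulate, and the numerical
choices that affect results.

## Anthropometry: LMS standardisation

BMI-for-age z-scores use the LMS method: for reference skewness `L`,
median `M` (kg/m²) and coefficient of variation `S` at the child's age
(days) and sex,

```
z = ((BMI/M)^L − 1) / (L·S),   or   z = ln(BMI/M)/S  when L = 0.
```

`L`, `M`, `S` are linearly interpolated between tabulated ages; ages
outside the table raise rather than extrapolate. Reference tables are
user-supplied CSV (`sex,age_days,L,M,S`), so any growth standard drops in;
the shipped `synthetic_reference()` is a smooth, plausible—but synthetic—
LMS grid used by the tests and the simulator, not a real standard. The
special handling some standards apply beyond |z| > 3 is deliberately not
implemented: records with |z| > 3 (the 99.865th/0.135th percentiles) are
treated as probable measurement or entry errors and removed
*observation-wise* — a child keeps its other time points. The bound is
configurable.

## Compositional features

- Relative abundances at genus or phylum level; all-zero samples are an
  error naming the sample.
- F/B ratio = Firmicutes proportion / Bacteroidetes proportion, **missing**
  when Bacteroidetes is 0. Flooring the denominator would manufacture
  enormous pseudo-ratios exactly where the data are least informative
  (infancy), so undefined ratios are excluded from ratio analyses instead.
- CLR uses natural logs with a configurable pseudocount, default **0.5**
  added to every entry of the table being transformed (half a count, a
  conventional choice for integer counts; the log base only rescales
  slopes). CLR of any constant vector is 0; components sum to 0.
- The SCFA-producer score sums the raw counts of the 17 curated producer
  genera into one `SCFA_sum` feature replacing its constituents; the
  modified table (sum + non-proxy genera) is CLR-transformed and the
  `SCFA_sum` component is the per-sample score. Genus matching is exact
  after whitespace/case normalisation; Silva-style group names
  ("Eubacterium hallii group") are kept verbatim. Missing proxy genera are
  tolerated with a logged warning; zero overlap is an error. A flag in
  `scfa_sum_score(return_table=True)` exposes the full transformed table
  for analyses that need the non-proxy CLR components too.
- Observed richness = count of genera with nonzero counts.
- The optional input-side abundance filter zeroes per-sample entries below
  a relative-abundance threshold (default 0.1%) in a single pass against
  the original totals; surviving entries are not re-checked against the
  reduced total, which is the documented semantics of a one-pass filter.

## Multiple imputation (MICE with PMM)

Chained equations over all numeric variables: per sweep, each incomplete
variable is regressed on the others (OLS with a proper Bayesian draw:
residual variance from a scaled inverse-χ², coefficients from the
resulting normal), predictions are made with the posterior-mean
coefficients for observed cases and the drawn coefficients for missing
cases (type-1 matching), and each missing case copies the observed value
of one of its **k = 5** nearest-by-prediction donors (the conventional
donor-pool size; exposed in config). Visit order is increasing
missingness; initial fill is a random draw from the observed values.
Imputations therefore always lie on the observed support.

Defaults are desk-scale **m = 10 datasets × 10 sweeps**; production scale
(m = 100, 40 sweeps, as used when posterior tails must be estimated
precisely) is a config change. Frequentist fits across imputations pool by
Rubin's rules (total variance = within + (1 + 1/m)·between); Bayesian fits
instead mix an equal number of posterior draws per completed dataset. A
convergence trace of per-sweep chain means is recorded on the imputer.

## Descriptive screen

Spearman correlations on pairwise-complete data (average ranks,
t-approximation p), requiring n ≥ 3 per cell (fewer → missing cell, not an
error). Benjamini–Hochberg correction is applied over a configurable
"hypothesized cells" mask, defaulting to exposure→zBMI at the same and
next time point — correcting over a-priori cells rather than the full
matrix mirrors how such screens are used confirmatorily.

## Bayesian multilevel model

Stacked long over (T−1, T) pairs joined by subject (subjects missing a lag
contribute only available pairs):

```
y_i = x_i'β + u0_j(i) + u1_j(i)·e_i + ε_i,
ε ~ N(0, σ²),  u0 ~ N(0, τ0²),  u1 ~ N(0, τ1²)  (independent)
```

with fixed effects (intercept, exposure at T−1, zBMI at T−1, standardized
birthweight) and per-subject varying intercept and exposure slope. Priors:
slopes N(0, 0.5) — narrowed to N(0, 0.25) when many genus slopes enter one
model — intercept N(0, 1), τ and σ ~ exponential(rate 1), with rate 15 as
the stronger regularisation used when a variance component otherwise mixes
poorly. zBMI is left unstandardised (already standard-normal scale);
other covariates are standardised with the scaling recorded for reuse.
Where priors had to be chosen without external guidance (intercept,
residual SD), weakly informative defaults are declared and configurable.

**Sampler.** Conjugate Gibbs updates for β and the per-subject effects;
univariate slice sampling on log-scale for σ, τ0, τ1 (exponential priors
are non-conjugate); each centred τ update is interwoven with the
non-centred (ancillary) parameterisation, where holding η = u/τ fixed
makes τ a regression coefficient with an exact truncated-normal
conditional. The interweaving removes the funnel that freezes centred
Gibbs when a variance component is near zero. Chains start overdispersed
(draws from the priors); warmup equals the kept length. Known-variance /
no-random-effects reductions are supported (`sigma_fixed`,
`random_effects=False`) and are validated against the conjugate
closed form; sampling with no data reproduces the priors.

Diagnostics: split-R̂ and effective sample size (via arviz) for every
parameter; the example configurations in the tests reach R̂ < 1.01. Default
4 chains × 2,500 kept iterations for reported fits; smaller settings are
used in simulation studies (below). Posterior predictive checks compare
replicate-data mean/SD/min/max with Bayesian p-values; replicates draw
fresh noise and fresh random effects at the posterior scales.

The varying intercept and slope are independent by default; a correlation
prior would need the paired update generalised and is out of scope.

## Random-forest inference

Features are genus CLR abundances by default (relative abundances by
flag). Per stool time point, a cross-sectional model and a
next-time-point model. The statistic is the **median over repeats** of
repeated k-fold CV, where each repeat's Pearson r is computed on pooled
out-of-fold predictions (pooling chosen over per-fold averaging for
stability with small folds); OOB mean squared error from a full-data fit
is reported alongside. Hyperparameters (mtry, sample fraction) come from a
randomised search minimising OOB-MSE.

Significance is by outcome permutation with the add-one estimator —
p_pearson = (1 + #{null ≥ obs})/(B + 1), p_oob with the inequality
reversed — and by default the *entire* procedure including tuning is
re-run on each permuted outcome, so optimisation bias is inside the null.
Defaults: 500 trees, B = 199 permutations, 10×4-fold CV, 20 tuning
candidates; production scale (B = 1000) is a config change. BH q-values
are computed across the whole model family; per-feature inference uses
permutation importances (mean MSE increase when the feature is permuted,
measured in-sample — the identical measurement on B permuted-outcome
refits supplies the null, so the p-values are comparisons of like with
like) with constant features assigned importance 0 and p = 1 by
convention.

**Forest engine.** The trees are a compact numba implementation of the
classic regression forest (variance-reduction CART splits, mtry features
per node, bootstrap with configurable per-tree sample fraction drawn with
replacement, min leaf 5, OOB error). The permutation machinery refits
forests tens of thousands of times on small tables, and the engine keeps a
50-tree fit on ~100 samples under 1 ms; tests verify its predictions and
OOB error agree with an independent reference implementation
(scikit-learn's `RandomForestRegressor`).

## Synthetic cohort generator

Emulates the structure the analysis assumes: 5 stool time points (1m, 3m,
4m, 6y, 10y) and 8 anthropometry time points (adds 2y, 7y, 12y) per
subject.

- **Counts**: Dirichlet-multinomial per sample (chosen over
  logistic-normal for explicit overdispersion control). Per-time-point
  concentration profiles over a 26-genus catalog (the 17 SCFA producers
  plus common non-producers) are calibrated so that infancy is
  Bifidobacterium/Actinobacteria-dominated with Firmicutes ≈ 0.27→0.19 and
  Bacteroidetes ≈ 1%, and childhood is Firmicutes-dominated
  (≈ 0.63→0.72) with Bacteroidetes 0.18→0.11 and SCFA producers ≈ 0.6 of
  the community. Total concentration 6 in infancy and 30 in childhood
  makes >50% of infant samples contain no Bacteroidetes at all — so the
  F/B ratio is undefined for most infants, as in real infant cohorts.
- **Library size**: log-normal, median 20,000 reads, σ_log = 0.4 — typical
  16S depth; real depths are study-specific and configurable.
- **zBMI**: first-order autoregression (coefficient 0.5) with subject
  intercepts N(0, 0.3), a standardized-birthweight slope (0.1; birthweight
  N(3613 g, 477 g)), residual SD 0.5, and optional planted linear effects
  of the previous stool time point's CLR abundances (standardised within
  time point, so planted slopes are per-SD). Effects can be restricted to
  chosen stool time points to plant a signal at a single transition.
- **Anthropometry**: weight and length are generated by *inverting* the
  LMS transform at the drawn zBMI against the synthetic reference, so
  recomputing zBMI from raw measures round-trips exactly and the
  anthropometry stage is exercised end to end.
- **Missingness**: MCAR, or MAR-on-zBMI via a logistic link whose
  intercept targets the marginal rate; complete data are retained in
  `truth` for imputation-quality checks.

Not emulated: sequence-level artefacts (reads, ASVs, chimeras),
compositional autocorrelation of the microbiota across time points within
subject, diet/delivery-mode/antibiotic covariates, non-linear genus
effects, and measurement error in age. Passing tests therefore show the
*statistical machinery* is correct and calibrated under the stated
generative model — not that real cohorts satisfy that model.

## Simulation study sizes

The test suite validates calibration and recovery at sizes chosen to keep
a full run near ten minutes on one core: permutation type-I error on 500
null datasets (n = 100, B = 99, 50 trees, single 2-fold CV repeat);
multilevel recovery/coverage on 50 + 50 cohorts of 300 subjects (2 chains
× 400 kept draws); PMM coverage on 200 MCAR datasets (n = 150, m = 10);
planted-signal detection end to end on 20 cohorts of 150 subjects
(B = 49). `scripts/acceptance.py` re-runs the same computations at
similar sizes. The statistical thresholds asserted (type-I error in
(0.03, 0.07), coverage 95% ± 3 points, ≥ 90% recovery, ≥ 80% detection)
are properties of the methods; larger simulation sizes sharpen, not
change, them.

## Known limitations

- PMM is single-level: it ignores the subject grouping during imputation,
  which can attenuate cluster-level variance when missingness is heavy.
- The F/B analyses require Bacteroidetes > 0 and hence drop most infant
  samples; this mirrors the field's practice but limits infancy inference
  to the CLR-based models.
- The multilevel sampler treats random intercept and slope as
  uncorrelated; strongly correlated true effects would be misspecified.
- Altmann-style importance p-values inherit random-forest importance
  pathologies under strong feature collinearity (importance splits across
  duplicates); p-values remain valid but power drops.
- The generator's independence of compositions across time points means
  longitudinal microbiota autocorrelation is untested.
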