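# microgrowth

Longitudinal analysis of the gut microbiota in relation to child growth:
does early-life microbial composition — the Firmicutes/Bacteroidetes (F/B)
ratio, an aggregated short-chain-fatty-acid (SCFA) producer score, or
individual genera — predict age- and sex-standardised BMI (zBMI) across
infancy and childhood?

The package is a tested, reusable implementation of that analysis for
cohort studies with stool samples at a few time points and anthropometry at
more: it is aimed at microbiome epidemiologists who want the full chain —
compositional feature construction, multiple imputation, Bayesian
multilevel modelling, and permutation-calibrated random-forest screening —
reproducible from a single seed, plus a synthetic-cohort generator with
planted ground truth so every stage can be validated without access to
restricted cohort data.

## What it computes

**zBMI (LMS method).** With reference skewness *L*, median *M* and
coefficient of variation *S* interpolated at the child's age and sex,

    z = ((BMI/M)^L − 1) / (L·S),      z = ln(BMI/M)/S  if L = 0,

and observations with |z| > 3 (beyond the 99.865th/0.135th percentiles)
are flagged as probable entry errors and removed.

**Compositional features.** Genus counts are compositional, so analyses use
relative abundances, the F/B ratio (undefined — not floored — when
Bacteroidetes is absent, as in most infant samples), and the centred
log-ratio transform clr(x)ᵢ = log xᵢ − mean log x. The SCFA-producer proxy
sums the raw counts of 17 curated producer genera (Bifidobacterium …
Akkermansia) into one feature that replaces its constituents before the
CLR, standing in for unmeasured faecal SCFA concentrations.

**Confirmatory model.** After predictive-mean-matching multiple imputation
(MICE/PMM, implemented here), a Bayesian linear multilevel model

    zBMI(T) ~ exposure(T−1) + zBMI(T−1) + birthweight + (1 + exposure(T−1) | subject)

with N(0, 0.5) slope priors (N(0, 0.25) for many-genus models) and
exponential(1) priors on the random-effect and residual SDs, sampled by a
Gibbs/slice MCMC scheme with interwoven centred/non-centred updates;
posteriors are mixed equally across imputed datasets. Cross-time-point
Spearman matrices with Benjamini–Hochberg control over the a-priori cells
form the descriptive layer.

**Exploratory models.** Per stool time point, tuned random-forest
regressions of zBMI on genus CLR abundances (cross-sectional and
next-time-point), with significance from outcome permutation — the tuning
and repeated fourfold CV are re-run on every permuted outcome, p =
(1 + #{null ≥ observed})/(B + 1) — BH q-values across the model family,
and per-feature null-importance (Altmann-style) p-values.

## Worked example

Simulate a 300-subject cohort with a planted effect — each SD of CLR
Subdoligranulum abundance at the previous stool time point lowers zBMI by
0.3 — and recover it with the multilevel model:

```python
import pandas as pd
from microgrowth import SimulationConfig, simulate_cohort, ModelSpec, fit_multilevel
from microgrowth.multilevel import stack_lagged, standardize

cohort = simulate_cohort(
    SimulationConfig(n_subjects=300, seed=7, effect_vector={"Subdoligranulum": -0.3})
)
exposure = pd.DataFrame(
    {tp: clrz["Subdoligranulum"] for tp, clrz in cohort.truth["clr_standardized"].items()}
)
pairs = [("1m", "3m"), ("3m", "4m"), ("4m", "2y"), ("6y", "7y"), ("10y", "12y")]
data = stack_lagged(cohort.cohort, exposure, pairs).dropna()
data, _ = standardize(data, ["birthweight_g"])
fit = fit_multilevel(data, ModelSpec(), n_iter=1000, n_chains=4, seed=1)
print(fit.summary().round(3))
```

```
               median    l95    u95  p_positive   rhat       ess
param
intercept      -0.039 -0.075 -0.005       0.012  1.001  1566.230
exposure       -0.299 -0.327 -0.272       0.000  1.000  3333.892
zbmi_lag        0.644  0.581  0.706       1.000  1.004   372.835
birthweight_g   0.049  0.015  0.087       0.998  1.002  1460.932
sigma           0.513  0.492  0.540       1.000  1.004   634.960
tau_intercept   0.197  0.125  0.255       1.000  1.006   346.508
tau_slope       0.023  0.001  0.077       1.000  1.003   723.125
```

The planted slope −0.3 is recovered as −0.299 [−0.327, −0.272]; the lagged
zBMI coefficient absorbs part of the subject intercept (its marginal
coefficient exceeds the generative autoregression, as expected), and all
split-R̂ values are ≤ 1.01.

The same cohort can be written to disk and pushed through the whole
pipeline from the shell:

```bash
microgrowth simulate --n-subjects 200 --seed 7 --out cohort/
microgrowth zbmi --anthro cohort/anthro.csv --reference cohort/reference.csv --out zbmi.csv
microgrowth run-all --config pipeline.yaml
```

`run-all` emits `zbmi.csv`, `features.tsv`, `correlations.tsv`,
`posterior_summary.tsv`, `rf_report.tsv`, `rf_importances.tsv` and a
`manifest.json` with the config hash and seed; two runs with the same
config and seed are byte-identical.

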