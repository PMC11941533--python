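# spatialfrailty

Bayesian **spatial-frailty parametric proportional-hazards (PH) survival
models** for right-censored, block-clustered cohorts — built around the
setting of neonatal fungal sepsis in a NICU, where each neonate's time to
death or discharge is modeled with clinical covariates plus a random effect
for their administrative block of residence.

## Who this is for

Biostatisticians and epidemiologists analyzing time-to-event data grouped
into a small number of geographic units (districts, blocks, facilities) who
want to (a) estimate covariate effects as hazard ratios with credible
intervals, (b) map which units carry excess hazard ("hotspots"), and
(c) choose among parametric baseline families with Bayesian fit indices.

## The model

For record *i* with covariates *x_i* (gestational age in weeks, birth
weight in kg, platelet count in 10³/µL, hemorrhage grade 0/1/2, PT_APTT
coagulation status 0/1) living in block *g(i)*:

```
h(t | x_i) = h0(t) · exp(x_i'β + w_{g(i)})
```

* `h0` — Weibull, log-normal, or log-logistic baseline hazard (all used as
  PH models, not AFT).
* `β` — regression coefficients; `exp(β_j)` is the hazard ratio (HR).
* `w_g ~ N(0, σ²)` — i.i.d. Gaussian block frailties on the log-hazard
  scale; positive posterior means flag hotspot blocks.
* Priors: `β_j ~ N(0, 1000)`, log-baseline parameters `~ N(0, 100)`,
  `σ² ~ Inverse-Gamma(2.001, 1)`.

The posterior is sampled by adaptive random-walk Metropolis–Hastings
(joint full-covariance block for baseline + coefficients, diagonal block
for frailties, Robbins–Monro step tuning toward 0.234 acceptance) with a
conjugate Gibbs update for σ². Models are compared by neg-LPML
(conditional predictive ordinates), DIC, and WAIC — lowest wins; fit is
checked with Cox–Snell residuals, whose Nelson–Aalen cumulative hazard
should follow a slope-one line when the model is adequate.

Because the motivating patient data are not publicly deposited, the package
ships a synthetic cohort generator that reproduces the study conditions
(n = 80 over six blocks, ~62.5% deaths, the published covariate marginals
and effect sizes) and a parameter-recovery harness.

## Worked example

```sh
spatialfrailty simulate --n 80 --seed 1 --out demo
# wrote demo/cohort.csv (80 records, 53 events, 6 blocks)

spatialfrailty fit demo/cohort.csv --seed 3 --out demo_fit
```

```
 parameter   mean     hr  median    sd  ci_low  ci_high  hr_ci_low  hr_ci_high  significant
  ga_weeks -0.026  0.974  -0.027 0.038  -0.104    0.054      0.901       1.055        False
  b_weight -0.195  0.822  -0.194 0.286  -0.758    0.399      0.469       1.491        False
  platelet  0.004  1.004   0.004 0.004  -0.004    0.011      0.996       1.011        False
hemorrhage  0.785  2.193   0.770 0.224   0.325    1.222      1.385       3.394         True
   pt_aptt  3.936 51.204   3.889 0.647   2.763    5.267     15.840     193.806         True
pooled MH acceptance rate: 0.241
```

Reading the table: each row is one covariate's posterior. Abnormal PT_APTT
multiplies the death hazard by `exp(3.936) ≈ 51` in this realization (the
generating truth is HR `exp(2.92) ≈ 18.5`; at n = 80 with only ~51 abnormal
cases the posterior is wide — the credible interval on the HR scale runs
from 16 to 194) and is flagged significant because the 95% interval
excludes zero. Hemorrhage grade roughly doubles the hazard per grade. The
pooled Metropolis–Hastings acceptance rate near 0.24 indicates a healthy
random-walk sampler.

```sh
spatialfrailty compare demo/cohort.csv --seed 3 --out demo_cmp
```

```
      model  neg_lpml    dic   p_d   waic  p_waic  ...  criteria_won  consensus_winner
    weibull    244.55 489.23 10.59 488.46    8.69  ...             2              True
  lognormal    246.78 488.02  5.23 492.70    8.80  ...             1             False
loglogistic    245.59 490.70 10.70 490.09    8.89  ...             0             False
```

The cohort was generated from a Weibull-PH truth, and the Weibull fit wins
the consensus (lowest on 2 of the 3 criteria). `predict` draws posterior
survival curves with 95% bands for a covariate profile, and `residuals`
writes the Cox–Snell table, plot, and slope.

The same functionality is available as a library:

```python
from spatialfrailty import (GeneratorConfig, SamplerConfig, generate_cohort,
                            run_mcmc, summarize_coefficients)

cohort, truth = generate_cohort(GeneratorConfig(n=80, seed=1))
samples = run_mcmc(cohort, "weibull", config=SamplerConfig(seed=3))
print(summarize_coefficients(samples))
```

## Layout

* `src/spatialfrailty/cohort.py` — cohort CSV I/O, validation, design
  encoding, frailty-table export for GIS joins
* `src/spatialfrailty/likelihood.py` — baseline families and the
  right-censored frailty log-likelihood
* `src/spatialfrailty/mcmc.py` — adaptive MH + Gibbs sampler, ESS/trace
  summaries
* `src/spatialfrailty/selection.py` — CPO/LPML, DIC, WAIC, consensus
  ranking
* `src/spatialfrailty/diagnostics.py` — Cox–Snell residuals, slope-one
  check, trace export
* `src/spatialfrailty/reporting.py` — coefficient/frailty tables, posterior
  survival curves
* `src/spatialfrailty/simulate.py` — synthetic cohorts + recovery harness
* `src/spatialfrailty/cli.py` — the `spatialfrailty` command

See `docs/methods.md` for modeling details, numerical choices, and
limitations.
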