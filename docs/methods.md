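# Methods

## Model

Each record is a right-censored survival time `t_i` (hours in the NICU)
with event indicator `δ_i` (1 = death, 0 = discharged alive), covariate
vector `x_i` and block label `g(i)` from a finite set of `G` regions. The
hazard is proportional:

```
h(t | x_i) = h0(t) · exp(η_i),    η_i = x_i'β + w_{g(i)}
```

with three interchangeable baseline families in standard shape/scale form:

| family       | cumulative baseline hazard Λ0(t)          | parameters        |
|--------------|-------------------------------------------|-------------------|
| Weibull      | `(t/λ)^α`                                 | shape α, scale λ  |
| log-logistic | `log(1 + (t/λ)^α)`                        | shape α, scale λ  |
| log-normal   | `−log(1 − Φ((log t − µ)/σ0))`             | location µ, scale σ0 |

All three are used as **PH** models — covariates multiply the hazard —
even though the log-normal and log-logistic are more often seen as AFT
models. There is no intercept in `β`; the baseline scale plays that role.
The right-censored log-likelihood decomposes pointwise as
`ℓ_i = δ_i(log h0(t_i) + η_i) − e^{η_i} Λ0(t_i)`, which is what CPO and
WAIC consume.

Covariates enter untransformed (hemorrhage as one ordinal 0/1/2 column,
platelets on the raw 10³/µL scale, no centering), matching how the
coefficient table is reported. Exact ties in time need no handling: the
likelihood is fully parametric.

## Priors

* `β_j ~ N(0, 1000)` — effectively non-informative on the log-hazard scale.
* `w_g ~ N(0, σ²)` i.i.d. — an exchangeable (not CAR/ICAR) spatial prior;
  the blocks are treated as unstructured random effects.
* `σ² ~ Inverse-Gamma(2.001, 1.0)` — proper and weakly informative
  (prior mean 1, infinite-ish variance); the hyperprior is configurable
  because no canonical default exists for this quantity.
* Each unconstrained baseline coordinate (log α, log λ, or µ, log σ0)
  `~ N(0, 100)`, placed directly on the sampling scale.

## Posterior computation

Positive parameters are sampled on the log scale, so invalid values are
unreachable. One sweep consists of:

1. **Joint (baseline, β) block** — random-walk MH with a full-covariance
   Gaussian proposal, 5 proposals per sweep. The proposal covariance is
   initialized from the inverse of a finite-difference Hessian of a
   penalized-likelihood fit (Nelder–Mead then BFGS, frailties at zero) and
   re-estimated from the chain's running covariance during burn-in.
   A joint block is essential here: the coefficient of a near-constant
   covariate (gestational age ≈ 35 for everyone) is strongly collinear
   with the baseline log-scale, and independent per-block proposals cannot
   follow that ridge — in recovery experiments they produced ~40% interval
   coverage where the joint proposal gives nominal coverage.
2. **Frailty block** — diagonal random-walk MH, 2 proposals per sweep,
   per-block scales initialized at `1/sqrt(events_in_block + 2)` and
   adapted from running variances. The frailty prior anchors these
   coordinates, so a diagonal proposal suffices.
3. **Gibbs update** of `σ² | w ~ Inverse-Gamma(a0 + G/2, b0 + Σw²/2)`.

Each MH block's global log step size follows a diminishing Robbins–Monro
recursion (`gain (iter+1)^-0.6`) toward 0.234 acceptance. All adaptation
stops at the end of burn-in so the retained chain is Markovian. Default
chain length is 1000 burn-in + 1000 retained draws — the configuration the
headline analyses use — and the config documents that longer chains are
preferable for final reporting. Both per-block and pooled post-burn-in
acceptance rates are recorded; on default synthetic cohorts the pooled rate
lands near 0.2.

Frailty identifiability: no sum-to-zero constraint is imposed — the
`N(0, σ²)` prior anchors the frailty mean. An optional per-iteration
recentring flag exists; it compensates exactly through the scale parameter
for the Weibull family (`λ → λ·e^{−w̄/α}`), and performs plain subtraction
for the other two families, whose cumulative hazards are not closed under
scaling.

Seeded determinism is a contract: identical inputs and seed give
bit-identical draws.

## Model comparison

* **CPO/LPML** — `CPO_i = [mean_m exp(−ℓ_im)]^{−1}` (harmonic mean),
  computed via log-sum-exp; the package reports `neg_lpml = −Σ log CPO_i`
  so that *lower is better* uniformly across all three indices, and also
  exposes the raw LPML.
* **DIC** — plug-in deviance at the posterior mean of the *unconstrained*
  parameters (invariant to the sampler's working scale);
  `p_D = mean(D) − D(θ̄)`.
* **WAIC** — pointwise-variance penalty (`p_waic = Σ_i var_m ℓ_im`, the
  "WAIC-2" form) with the M−1 denominator.
* **Consensus** — the model lowest on a majority of the three criteria;
  ties break by neg-LPML.

## Diagnostics

Cox–Snell residuals `r_i = e^{η̂_i} Λ̂0(t_i)` are computed at the single
plug-in posterior-mean state (a per-draw variant exists). Under a correct
model they are a censored unit-exponential sample, so the Nelson–Aalen
cumulative hazard of the residuals against the residuals should be a line
of slope one through the origin; the reported slope is a zero-intercept
least-squares fit through the event points, a quantitative surrogate for
the visual check. Effective sample sizes use Geyer's initial-monotone
positive-pair autocorrelation-sum estimator; constant chains are flagged
`degenerate` (ESS reported as the chain length) and antithetic chains
`superefficient` (ESS above the chain length).

## Synthetic cohorts

The generator emulates the study conditions:

* **n = 80** records over **6 blocks** (uniform block weights by default).
* Covariate marginals: GA ~ N(34.86, 4.05²) truncated to [26, 42] weeks;
  birth weight ~ N(2.08, 0.72²) truncated to [0.7, 4.0] kg; platelets
  log-normal moment-matched to mean 50.53 / SD 57.41 then truncated to
  [2, 260] (truncation shifts the realized mean slightly below the matched
  value; the law-of-large-numbers tests check against the truncated-law
  mean); hemorrhage categorical with probabilities (0.55, 0.26, 0.19),
  chosen so the coded mean is exactly 0.64; abnormal PT_APTT with
  probability 0.64. Covariates are **independent** — only marginals are
  published, so no joint dependence is emulated.
* Event times by the PH inverse transform `S0(t)^{e^η} = U`, exact in each
  family.
* Default truth: Weibull baseline with shape 1.2 and scale 1000 h and
  coefficients (0.01, 0.18, 0, 0.56, 2.92), the fitted values of the
  best-supported model; frailty SD 0.2. The baseline scale was chosen once
  so that the high-risk profile (GA 30, 1 kg, platelets 25, intracerebral
  hemorrhage, abnormal PT_APTT) has survival ≈ 0.04 by 60 h, matching the
  qualitative clinical picture.
* Censoring: an independent log-normal discharge time (sdlog 1.0) whose
  location is tuned by bisection so the **expected** censored fraction
  equals the 37.5% target exactly; the realized fraction varies binomially.
  Independence of discharge and event time is the weakest standard
  assumption — the real discharge mechanism is unknown and plausibly
  informative, which passing recovery tests cannot rule out.

What passing tests show: the sampler recovers known coefficients with
nominal interval coverage, the residual check distinguishes the generating
family from a misspecified one, and the fit indices select the generating
family — *under these idealized conditions*. Real cohorts with correlated
covariates, informative discharge, or model misspecification can behave
differently.

## Problem sizes and numerical choices

Recovery and selection experiments run at n = 400 with 20 and 10 seeded
replicates respectively, and the residual check at n = 1000 — sizes at
which effects of the published magnitude are comfortably identified while a
full experiment completes in well under a minute. Replicate seeds derive
from a root `SeedSequence`, kept below 2³¹.

* Likelihood terms are computed on the log scale; the log-normal survival
  uses `log_ndtr` to avoid cancellation for large t; the log-logistic
  cumulative hazard uses `logaddexp`.
* Non-finite log-posteriors (overflowing proposals) are treated as
  rejections, never exceptions; `log_posterior` returns −inf for invalid
  states.
* Cholesky factorizations of adapted covariances retry with escalating
  jitter and fall back to a diagonal scale guess.
* In the deep survival tail, a pointwise mean can exceed the 97.5% sample
  quantile (a few heavy draws dominate); credible bands are widened
  minimally to always contain the mean curve.
* The SD in descriptive tables uses the n−1 denominator; singleton strata
  report an undefined (NaN) SD rather than erroring.

## Known limitations

* Exchangeable frailties only — no CAR/ICAR neighborhood structure; with
  G = 6 blocks the frailty SD σ is weakly identified and its posterior
  leans on the Inverse-Gamma hyperprior.
* Single-chain inference; no split-R̂ across chains (multiple runs with
  different seeds are the available workaround).
* No left truncation, interval censoring, or time-varying covariates.
* DIC's plug-in uses unconstrained-scale means; other plug-in conventions
  give slightly different p_D on skewed posteriors.
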