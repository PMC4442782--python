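# Methods

## Data-generating processes

All three generators share the structure: a single covariate `x ~ U(0,1)`,
a log-linear scale `b(x) = exp(β₀ + β₁x)` with β₁ = 1 by default, and an
intercept chosen so the *marginal* mean cost is exactly 1.

| family     | outcome law                        | E(y\|x)            | skewness driver |
|------------|------------------------------------|--------------------|-----------------|
| lognormal  | `y = b(x)·exp(ε)`, `ε~N(0,σ²)`     | `b(x)·e^{σ²/2}`    | σ² ∈ {0.5,1,1.5,2} |
| gamma      | `y ~ Gamma(α, scale=b(x))`         | `α·b(x)`           | shape α ∈ {0.5,1,2,4} |
| weibull    | `y ~ Weibull(α, scale=b(x))`       | `b(x)·Γ(1+1/α)`    | shape α ∈ {0.5,1,5} |

With `E(y|x) = c·exp(β₀+β₁x)` and a uniform covariate,
`E(y) = c·e^{β₀}(e^{β₁}−1)/β₁`, so the standardizing intercept is
`β₀ = −ln c − ln((e^{β₁}−1)/β₁)`, the factor replaced by its limit 1 at
β₁ = 0.  A quadrature fallback (`solve_intercept_numeric`) cross-checks the
closed forms.  The marginal second moment factorizes into an x-mixture
factor `C(β₁) = (e^{2β₁}−1)/(2β₁)·(β₁/(e^{β₁}−1))²` and a within-x factor
`K` (e^{σ²}; (α+1)/α; Γ(1+2/α)/Γ(1+1/α)²), giving `sd = √(CK−1)` — the
quantity the descriptive tables report.  Skewness is exposed as the
*conditional-on-x* standardized third moment; for the Weibull family the
standard standardized form is used (an unnormalized third-moment expression
sometimes quoted for it is dimensionally inconsistent).

Only the Weibull family has exactly proportional hazards:
`h(t|x) = α t^{α−1} e^{−α(β₀+β₁x)}`, so the population Cox coefficient is
`−α·β₁` (`true_cox_coefficient`; other families raise an explicit
not-defined error).

The generators emulate fully observed, strictly positive, homoscedastic
(in the multiplicative sense) cost data with a single fixed covariate.  They
deliberately do **not** emulate zero-mass spending, censoring,
heteroscedastic log-scale errors, or multi-covariate confounding — so
passing tests say nothing about estimator behaviour under those features of
real claims data.

## Estimators

All four return `(β̂₁, ŷ)` under one contract; predictions are in-sample.

* **ols_log.** OLS of `ln y` on (1, x); `σ̂² = SSR/(n−2)`.  Retransformation
  is normal-theory `exp(η̂ + σ̂²/2)` or Duan smearing `φ̂·exp(η̂)`,
  `φ̂ = mean(exp(ε̂))`.  The pipeline default matches the retransform to the
  generating family (normal theory for log-normal data, smearing otherwise);
  callers can force either.  Log-likelihood and AIC (k=3) are reported on
  the `ln y` scale and are not comparable across families — documented, not
  "fixed".
* **gamma_glm.** Quasi-ML via IRLS; for the log link with gamma variance the
  working weights are 1, so each step is an unweighted regression of the
  working response.  Steps are halved when the gamma quasi-deviance would
  rise, the linear predictor is clipped to ±300, iteration cap 100, relative
  coefficient tolerance 1e-8.  Dispersion is Pearson/(n−2); AIC evaluates
  the gamma likelihood at the quasi-ML coefficients with ML-profiled shape
  (solved from `ln k − ψ(k) = D/n` by bracketed root finding).
* **weibull_reg.** Full-ML accelerated-failure fit on (β₀, β₁, ln α) by
  Newton iterations with analytic gradient and Hessian, step halving and a
  BFGS fallback; a stationary point (gradient sup-norm < 1e-6·n) counts as
  converged regardless of the optimizer's status word.  The headline
  prediction is the scale `exp(η̂)` — the exponential-conditional-mean
  reading, which uniquely reproduces the published systematic Weibull bias
  (+0.5 at shape 0.5, ≈ −0.089 at shape 5); `mean_correction=True`
  multiplies by `Γ(1+1/α̂)` to predict the Weibull mean instead.
* **cox_ph.** Breslow partial likelihood maximized by Newton on y-sorted
  suffix sums (tie groups share their risk set); baseline cumulative hazard
  `Ĥ₀(t) = Σ_{t_k≤t} d_k/S₀(t_k)`; predictions are the restricted mean
  `∫₀^{y_max} exp(−Ĥ₀(t)e^{β̂x}) dt`, an exact sum over the survival steps
  with no tail extrapolation (the published Cox prediction rule is unstated;
  truncation at the largest observed cost is this package's choice).  The
  intercept is not identified and is stored as 0 with an explicit flag.
  With a constant covariate the slope is fixed at 0; the restricted mean
  then uses the exponential Breslow form `exp(−Ĥ₀)`, which integrates close
  to — but, unlike the product-limit form, not exactly equal to — the sample
  mean (the gap is O(1/n); ≈1% at n=200).
  `predictions=False` skips the restricted-mean step for slope-only loops.

The proportional-hazards diagnostic is the score test for a time-varying
effect `x·g(t)` at the fitted slope (equivalently a correlation test of the
Schoenfeld residuals with `g`), with `g` the rank of the event time by
default.  Under the exactly-PH Weibull process its rejection rate at the
0.05 level is nominal (≈0.047 in the test suite).

## Evaluation statistics and conventions

* MPE `= mean(y−ŷ)` and MAPE `= mean(|y−ŷ|)` (absolute, not percentages).
* MSE(β̂₁) uses the generating slope 1 as the truth for *all* estimators,
  including Cox, which reproduces the published Cox MSE cells (≈ bias²);
  the PH-scale truth `−α·β₁` is reported in a supplementary column for
  Weibull data.
* The "95% CI" is a *simulation interval*: `mean(β̂₁) ± 1.96·sd(β̂₁)/√n`
  with n the per-replication sample size, the convention reverse-engineered
  from the published half-widths; a percentile interval across replications
  is emitted alongside.
* The goodness-of-fit test is an explicit continuous-outcome adaptation of
  the Hosmer–Lemeshow idea: deciles of ŷ, statistic `Σ(O−E)²/V` with
  model-based variances (log-normal: `(e^{σ̂²}−1)ŷ²` for the normal
  retransform and the empirical variance of `exp(ε̂)` for smearing; gamma:
  dispersion·ŷ²; Weibull: `b̂²(Γ(1+2/α̂)−Γ(1+1/α̂)²)`; Cox: the restricted
  second moment minus the squared restricted mean), χ² with groups−2
  degrees of freedom.  It is approximate, and the engine reports the
  *rejection proportion* at 0.05 per cell.  For a well-specified gamma fit
  its level is close to nominal; no attempt is made to reproduce the
  published goodness-of-fit or AIC columns, whose conventions are
  under-specified.
* Descriptive rows average per-replication sample mean, sd (n−1),
  moment skewness g₁ and raw (non-excess) kurtosis.

## Engine and reproducibility

Replication r of cell (family, param, n) is seeded through a
`SeedSequence(root_seed, spawn_key=(family_code, round(param·1e6), n, r))`,
so results are independent of execution order and parallelization strategy.
Fits that raise or fail to converge are excluded from aggregates and
counted (about 0.02% of fits across the grid at n=25, all extreme
small-sample draws); a cell with more than 5% failures is flagged and the
CLI exits nonzero.  Grid runs write results incrementally and resume from a
matching manifest.  The full published design (10,000 replications × 55
cells × 4 estimators) is the configuration default; the test and acceptance
profiles use 200–2000 replications per cell and widen tolerances by the
Monte Carlo standard-error formulas (an MSE estimated from R replications
has relative SE ≈ √(2/R)).

## Known discrepancies with the published tables

Two published quantities are inconsistent with the stated data-generating
model, verified against independent reference implementations
(statsmodels/lifelines) and analytic variance formulas:

1. The small-sample log-OLS MPE cells (−0.139 at n=25 under log-normal
   σ²=0.5, scaling like −3.2/n across *all* variance levels).  The
   normal-retransform estimator's true bias at n=25 is ≈ −0.023, and no
   retransformation convention (smearing, none, out-of-sample) produces
   −0.139; a retransformation-driven bias would also have to grow with σ²,
   which the published values do not.
2. The gamma-GLM slope MSE under log-normal data (0.00543 at σ²=0.5,
   n=1000).  The gamma quasi-ML slope has sandwich variance
   `(e^{σ²}−1)·12/n ≈ 0.0078`, and the published value lies *below* the
   Cramér–Rao bound `12σ²/n = 0.006` attained by log-OLS, so no consistent
   estimator of the stated model can achieve it.

The corresponding acceptance tests assert the published values faithfully
and are expected to fail; all other published cells targeted by the
acceptance suite (log-OLS MSE and simulation intervals, descriptive SDs,
Weibull systematic bias, Cox slope/MSE/interval under exact PH, MAPE cells)
reproduce within Monte Carlo tolerances.  Separately, the published Cox
"MPE/MAPE" columns equal the mean Cox slope in every cell, which is
inconsistent with MPE's definition; this package computes Cox MPE/MAPE from
the restricted-mean predictions and reports the mean slope separately.

## Limitations

Single covariate, no zeros, no censoring, homoscedastic multiplicative
errors; AIC values are within-family fit indices only; the goodness-of-fit
adaptation is approximate at small n (it under-rejects slightly at n=25);
restricted-mean Cox predictions are truncated at the largest observed cost
and therefore understate the mean when the largest costs are censored-like
outliers.
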