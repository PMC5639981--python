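# Methods

## Model and assumptions

CHE incidence is a country-year proportion strictly inside (0, 1); it is
modelled on the logit scale with a linear mixed model,

    logit(CHE_it) = β₀ + β₁ logit(OOP_EXP_it) + β₂ logit(HEX_GDP_it)
                    + β₃ ln(GDP_C_it) + u_i + ε_it,

u_i ~ N(0, σ_u²) per country, ε_it ~ N(0, σ_ε²). The model treats the
covariates as exogenous; it does not model feedback from CHE to financing
policy, country-specific slopes, or temporal autocorrelation in the
residuals. Estimation is REML (ML available) via statsmodels `MixedLM`;
inference on the fixed effects uses the normal approximation (no
degrees-of-freedom correction). If the optimizer stalls with the
random-effect variance on the zero boundary, the variance component is not
identifiable and the fit degrades, with a warning, to an OLS fixed-effects
fit — the coefficient vector and covariance matrix keep the same contract.

Two pseudo-R² definitions are available on the logit scale: *marginal*
(fixed-effect prediction variance over fixed + random-intercept + residual
variance, the default) and *conditional* (adds the random-intercept
variance to the numerator). The prediction-variance term uses the sample
variance (n−1) of the linear predictor over the fitting rows.

## Projection

GDP growth is annualised per country from a multi-year GDP-per-capita run
using the endpoint geometric rate `(v_T/v_0)^(1/(t_T−t_0)) − 1`; a
log-linear OLS alternative (`annualization: ols_log`) uses all years and
coincides with the endpoint rule for exactly geometric series. Rates are
summarised per income group by mean and sample SD (n−1; a single-country
group gets SD 0). Each country's base-year GDP is compounded at its
*group's* mean rate over the 27-year horizon (2013 → 2040 by default; both
years are config keys). Horizon CHE per country is the model prediction at
the forecast covariate means; the group value is the exact unweighted
arithmetic mean over countries — countries, not populations, are the unit.
Country random intercepts default to 0 in projections (population-level);
`use_blup` carries each fitted country's predicted intercept forward
instead, which is the better choice when projecting the same countries the
model was fitted on.

Annualised decline between base and horizon group levels is
`1 − (end/start)^(1/n)`; cumulative relative reduction over n years is
`1 − (1−r)^n`. Both the model-fitted base-year group level and the
observed-average variant are computed and labelled
(`baseline_group_che(fitted=True/False)`), since group decline statements
depend on that choice.

## Uncertainty propagation

Monte Carlo with n = 100 000 trials by default (tests use 10³–10⁴ except
where a check is explicitly about n = 10⁵ stability). Per trial:

* one coefficient vector from MVN(β̂, V̂) — sampled through a symmetric
  eigendecomposition; eigenvalues in [−1e−10, 0) are clipped to zero,
  anything more negative is rejected as non-PSD;
* per country, OOP_EXP and HEX_GDP from beta distributions fitted to the
  forecast (mean, 95 % UI); draws are independent across countries and
  between the two covariates (no correlation structure is assumed);
* one growth rate per income group from a gamma distribution
  moment-matched to the group (mean, SD) — shared by all group members in
  that trial (a per-country-draw variant is switchable); a zero SD yields a
  degenerate (constant) draw.

The random-intercept and residual terms are *excluded* by default — only
input-parameter and estimation uncertainty are propagated;
`include_residual` adds Gaussian draws of both for sensitivity analysis.
Group arrays are the row-wise arithmetic mean of member-country arrays,
stacked in sorted-country-id order so the accumulation order (and hence the
bit pattern) is reproducible. Percentiles use numpy's linear interpolation
between closest ranks. Target attainment uses strict `<` (a threshold is
"CHE below x"); gap comparisons use strict `>` on trial-paired decline
rates, so identical arrays give probability 0.

Per-trial decline rates need a base-year group level: by default
(`decline.baseline: per_trial`) it is recomputed per trial from the trial's
coefficient draw at each country's last observed covariates, so baseline
and endpoint share the same parameter state; `fixed` uses the mean
coefficients instead.

### Beta fit from mean and interval

The beta fit enforces the mean exactly by parameterizing
α = m·k, β = (1−m)·k and optimizes the concentration k (via
`scipy.optimize.least_squares` on log k, initialised by moment matching
with sd₀ = (hi−lo)/3.92) so the 2.5/97.5 quantiles match (lo, hi) in the
least-squares sense. A triple that is actually consistent with a beta
distribution is recovered to optimizer precision; inconsistent triples get
the closest compromise at the exact mean. A zero-width interval returns a
flagged point mass whose samples equal the mean. Gamma fitting is
closed-form moment matching: shape = (mean/sd)², scale = sd²/mean.

## Scenarios

An OOP cap replaces (mean, lo, hi) by min(·, cap) for targeted income
groups. The whole interval is clipped — not just the mean — so the capped
covariate can never be sampled above the cap; min(·, cap) is monotone, so
the interval ordering survives. Scenario application is pure (input
forecasts are never mutated) and idempotent. The capped HEX_GDP and GDP
forecasts are left untouched.

## Synthetic data generator

The generator is the forward model of the regression, so fitted-model
checks have exact ground truth. Defaults: 32/45/51/51 countries per income
group (LIC/LMIC/UMIC/HIC), years 1995–2013, slopes (0.67, 0.67, −0.38) and
random-intercept variance 0.29 — the published coefficient set this
pipeline is designed around — and, since no intercept or residual variance
is published anywhere, β₀ = 0.5 and σ_ε = 0.35, chosen once so synthetic
CHE incidence sits in the low single-digit percent range with a marginal
R² around 0.7. Covariates are i.i.d. across years within a country
(an AR(1) hook on the latent scale exists for robustness studies);
per-group beta/log-normal covariate distributions encode the qualitative
income gradient (poorer groups: higher OOP share, lower GDP); group growth
(mean, SD) defaults to 4.5(2.9)/4.5(2.7)/4.1(2.4)/3.4(2.0) percent per
year. Growth draws are re-drawn if ≤ −100 % so GDP stays positive.

Forecast emulation draws a true horizon covariate per country (a
logit-scale Gaussian step of SD 0.15 from its last observed value), reports
a mean perturbed by the same noise scale, and builds the UI symmetric on
the logit scale with half-width 1.96 · 0.15 · `ui_width_factor`; with
factor 1 the intervals reflect the true sampling noise of the reported
means. The generator's true horizon CHE includes the realized country
intercept, which is why calibration checks run the Monte Carlo with BLUPs.

What the generator does **not** emulate: real-world covariate
autocorrelation and trends, correlated measurement error across covariates,
income-group reclassification over time, non-random CHE missingness, and
survey-comparability noise. Passing tests therefore demonstrate the
pipeline's internal correctness and statistical calibration under its own
assumptions, not the accuracy of any real-world 2040 forecast.

## Problem sizes and numerical choices

Unit and property tests run on compact worlds (typically 12–42 countries,
4–10 years); parameter-recovery uses 50 replicates of 150 countries × 10
years; Wald-interval coverage uses 150 replicates of 20 countries × 6
years; UI calibration uses 50 replicates of 24 countries with n = 2000
trials — sizes chosen to make the statistical assertions sharp while
keeping the suite fast. Monte Carlo seed handling: a single
`numpy.random.default_rng(seed)` stream consumed in a fixed order
(coefficients, then per-country draws in sorted-id order, then group growth
draws), so identical seeds give bit-identical samples and reports.
Proportions at the 0/1 boundary (logit undefined) are clipped to
±1e−6 (configurable) on ingest, with a logged warning; interior values are
never altered.

## Known limitations

* The logit-linear trend model is deliberately rudimentary; it ignores the
  determinants' interaction (service availability vs prepayment shift) and
  can be badly wrong if their future balance differs from the past.
* Group aggregation weights every country equally; population-weighted
  results would differ materially (a population-weighted option is out of
  scope).
* The beta/gamma input distributions are fitted marginally; any real
  correlation between covariate forecasts, or between countries, is not
  propagated.
* Decline-rate summaries depend on the base-year definition (fitted vs
  observed, fixed vs per-trial); both switches are exposed rather than
  resolved.
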