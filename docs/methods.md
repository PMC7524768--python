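# Methods

## The belief-combination model

The analysis treats machine influence as a population-level DeGroot
update. On day *t* of a question, an exposed forecaster's report is

y(i,t) = α·x(i,t) + (1 − α)·m(t),

where x(i,t) is the forecaster's prior belief and m(t) the machine
forecast current on that day. Priors are modeled as normal,
x ~ N(μ(t), σ²(t)), with moments taken from the realized forecasts of
the randomized control group: the control group's sample mean and
unbiased sample variance of the correct-option probability within the
same rolling window (and skill stratum, when stratified) are plugged in
as μ and σ². Exposed forecasts then follow N(αμ + (1−α)m, α²σ²), and α
is the only free parameter.

Key consequences and assumptions:

* **Binary collapse.** Questions with 2–5 answer options are projected
  onto the probability assigned to the correct option before
  estimation. This avoids sparse-data covariance estimation and makes
  the likelihood univariate. It also means estimation is retrospective:
  the projection requires the resolved outcome.
* **Normal model on [0, 1] data.** The normal prior ignores the bounded
  support of probabilities. This is a deliberate misspecification kept
  for tractability; the synthetic generator clips prior draws to
  [0.01, 0.99] rather than sampling a truncated normal, and the clipped
  mass is negligible for the default prior scale (σ = 0.1) away from
  the boundaries.
* **Variance signature.** The model predicts Var(treatment) =
  α²·Var(control) for contemporaneous forecasts. The validation routine
  therefore measures dispersion *within days* (variance across same-day
  forecasts, averaged over days): the group prior drifts from day to
  day, and pooling across days would mix opinion diversity with the
  prior's motion. One published account of this design reports the
  relation with treatment variance *larger* than control variance,
  which contradicts the model equation it accompanies; this package
  follows the model equation (dispersion shrinks under exposure) and
  notes the discrepancy rather than resolving it.
* **Population weight.** α is a population-average weight per
  (question, window, stratum) cell, not an individual trait. All
  forecasts in a window are used, each paired with the machine forecast
  of its own day.

## Estimation

The log-likelihood Σ log N(y_i; αμ + (1−α)m_i, α²σ²) is maximized over
α ∈ [0.01, 1] by bounded scalar optimization (`scipy.optimize.
minimize_scalar`, xatol 1e-6), with explicit boundary checks and a
0.001-step grid-search fallback. The lower bound exists because the
density is singular at α = 0; weights above 1 (anti-machine
contrarianism) are outside the model. The optimizer is required — and
tested — to agree with an independent grid search of the density product
to within 0.002 on every window.

Windows are trailing and end-inclusive with length L = 7 days (weekly),
⌈duration/4⌉ days (quarter-duration), or max of the two (default),
advanced by a configurable stride (default 7 days, giving non-overlapping
regression rows). Windows with fewer than four forecasts in either
condition are discarded. A question shorter than L contributes a single
full-span window. The variance plug-in is floored at 1e-6 (flagged) to
keep the likelihood finite on degenerate windows.

## Scoring and skill

Density Brier: Σ(p_i − o_i)² against the one-hot outcome, in [0, 2],
time-averaged over a forecast series. Ordinal questions use the
cumulative-probability variant (squared error of cumulative vectors), in
[0, n−1], which penalizes near misses less; for binary questions it is
exactly half the density score.

The skill split uses the independent machine-free question set. The
normalization of per-question scores is not uniquely determined by the
design; the default z-scores each question's user scores before
averaging per user (removing question-difficulty level effects from the
median split), with rank and raw alternatives exposed in configuration.
Users at or below the median normalized score are labeled high-skill
(lower is better); exact median ties fill the high stratum in user-id
order for reproducibility.

## Covariates

One row per (question, window, stratum), response α̂:

| covariate | definition | default details |
|---|---|---|
| uncertainty | mean per-option variance of control vectors | unbiased (ddof 1) |
| difficulty | mean Brier of control forecasts in window | ordinal variant on ordinal questions |
| confirming | machine at least as close to the reference group's nearest one-hot extreme as the reference mean itself | reference = treatment mean (configurable to control; the two operational definitions in circulation disagree, so both are implemented) |
| helpfulness | fraction of control users with worse window Brier than the machine; ties count ½ | per-user Brier averages the user's forecasts in the window |
| lifetime | (window end − open) / duration | in [0, 1] |
| distance | mean ‖cum(m) − cum(p)‖₂ over same-day pairs | cumulative probabilities |
| reputation | −mean machine Brier over questions resolved before this one opened | information cutoff at open date (no look-ahead); first questions imputed with the eventual global mean and flagged |
| skill | stratum label | cell-means coding in the regression |

## Regression

OLS of α̂ on the standardized covariates. Continuous predictors are
z-scored over the regression sample; binary predictors stay dummy-coded;
the response is untransformed. Skill enters as per-stratum indicator
columns with no global intercept (cell-means coding), so both stratum
baselines are reported directly — a global intercept plus one dummy
could not report both. Interactions are products of the standardized
mains. Model 1 is the main-effects model (plus lifetime as a control);
Model 2 adds helpfulness, uncertainty and confirming interactions with
the high-skill indicator; Model 3 adds distance × confirming to Model 1
(each extends Model 1 independently). The "eq3" variant drops lifetime
and matches the counterfactual predictor set. Standard errors are
classical by default; window-level clustering by question is available
by flag, since the appropriate clustering level is genuinely open.

## Counterfactuals

The fitted "eq3" model predicts α̂ for each cell (linear predictor
clamped to [0.01, 1]). Realized control forecasts are deterministically
blended with the same-day machine forecast at α̂ — fresh prior draws
would only add Monte Carlo noise to a comparison of coefficients — and
scored. Sweeping one coefficient over learned value ± 3 SE (13 steps,
grid always containing the learned value) re-predicts, re-blends and
re-scores; the summary is the median and IQR of per-cell percent change
in Brier versus the learned-coefficient baseline, stratified by machine
helpfulness (> 0.5 = "high quality"). Stratification uses the
unmodified helpfulness values, so stratum membership cannot change along
a sweep and the curves are continuous. At the learned value the change
is identically zero by construction. Covariates are standardized once
with the fit's transform and never re-standardized per grid point.

## Machine forecasts

The production path fits ARIMA models with a stepwise AICc search
(p, q ≤ 3; d ≤ 2 chosen by repeated KPSS tests; ties toward the smaller
model), implemented over `statsmodels`' ARIMA. Forecast uncertainty at
multi-day horizons uses the model's analytic forecast-variance growth,
and the normal predictive distribution at the resolution date is
integrated over the answer-option bins (outer bins take the open
tails). The 95% interval is point ± 1.96·sd. Orders are selected when a
question opens; coefficients are re-estimated every 14 days and the
Kalman state is extended with each new observation in between, so every
forecast conditions on the latest data. Constant series yield a flagged
degenerate point-mass model.

## The synthetic tournament

The generator emulates the study design the analysis assumes:

* **Questions** (default 50) track daily AR(1)-with-drift series;
  durations are gamma with mean 53 and sd 33 days, redrawn below 7 days
  so a weekly window fits; open dates are staggered over 180 days so
  the reputation covariate has a resolution calendar; 2–5 answer-option
  bins come from quantiles of the 60-day pre-open history and the
  question resolves to the bin containing the closing value.
* **Control forecasts**: 30 users per condition, each active on a
  Bernoulli(0.5) daily schedule (real arrival patterns are unknown;
  this stand-in produces the sparse uneven streams the windows must
  tolerate). Each active user draws the correct-option probability from
  N(μ_t, 0.1²) clipped to [0.01, 0.99], the residual mass spread evenly
  over incorrect options. μ_t drifts linearly from a per-question
  initial offset (uniform in [0.3, 0.6]) halfway toward certainty by
  close, emulating a crowd converging on the answer.
* **Treatment forecasts** draw an independent prior from the same
  distribution and report the convex combination with the day's machine
  forecast, applied to the full probability vector so forecasts stay on
  the simplex by construction. The planted weight is constant (default
  0.86, the scale of population-average weights this kind of study
  reports) or linear in per-question standard-normal covariates with
  chosen coefficients plus N(0, 0.05) noise, clipped to [0.05, 1].
* **Machine**: by default a closed-form AR(1) plug-in predictive
  distribution fitted to the data seen through each day (near-unit-root
  fits fall back to a random walk with drift) — an autoregressive
  forecaster that is fast enough for the many-seed property checks; the
  full stepwise-ARIMA path is available via `machine_method="arima"`.
  Quality knobs add observation noise and point-forecast bias.
* **Skill questions** (default 126, binary, machine-free): each user's
  correct-option draw centers on a latent skill level uniform in
  [0.35, 0.85], so accuracy orders users by skill.

What passing tests on this generator do **not** show: robustness to
real-world forecast behavior absent from the generator — herding within
conditions, strategic or discrete reporting (round numbers, 0/1
reports), attrition, per-individual heterogeneity in the trust weight,
and machine series whose structure ARIMA cannot capture. The parameter-
recovery results certify the estimator under its own assumptions, not
the assumptions themselves.

## Numerical choices and degenerate inputs

* Simplex tolerance 1e-6 on input; vectors with sub-1e-12 drift are
  kept bitwise to make file round trips lossless.
* Prior variance floor 1e-6 (flagged); degenerate ARIMA series produce
  point-mass bins; uniform reference forecasts break the extreme-vertex
  tie toward the lowest index (logged).
* Median ties in the skill split resolve by user-id order; AICc ties in
  order selection resolve toward fewer parameters.
* Problem sizes in the test suite and acceptance script (50-question
  tournaments, 30 users per condition, 20-seed significance loops,
  100-replicate coverage runs) were chosen as the smallest designs
  whose sampling error is well inside the tested tolerances.

## Known limitations

A weight near 1 cannot distinguish high confidence in the prior from
low trust in the machine. The normal likelihood is misspecified near
the probability boundaries. Plug-in priors ignore estimation error in
μ and σ², slightly narrowing the implied confidence in α̂. The
regression treats α̂ as an error-free response. Counterfactual sweeps
assume the fitted linear model stays valid away from the learned
coefficients (a one-at-a-time perturbation, not a causal claim).
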