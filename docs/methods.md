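# Methods

## The model

Hourly GPS fixes from fur seal pups are reduced to step lengths
`x_t` (great-circle metres between consecutive regularised fixes).  A
two-state hidden Markov model describes them:

- **Emissions.** Conditional on the latent state, steps are gamma distributed
  in the mean/sd parametrisation, `x_t | S_t = i ~ Gamma(mean mu_i, sd
  sigma_i)`, with the label convention `mu_1 < mu_2` (state 1 = "inactive",
  state 2 = "active").
- **Transitions.** The 2x2 transition matrix varies per step.  Each
  off-diagonal entry is a logistic function of a design row built from the
  step's covariates: `logit(gamma_12,t) = beta_1' x_t`,
  `logit(gamma_21,t) = beta_2' x_t` — the row-wise multinomial logit with
  "stay" as reference, which reduces to the logistic link for two states.
  Both logits carry the same design columns.
- **Design.** Columns are: intercept; the colony indicator; main effects for
  season, sex, age, body condition, air temperature, wind speed; one harmonic
  pair `sin(2*pi*h/24), cos(2*pi*h/24)` for hour of day; and a colony
  interaction for every non-colony term.  Metric covariates are standardised
  (pooled mean/sd over the analysis data set); the constants are persisted so
  later stages reuse identical scaling.  One harmonic pair is the default
  because a single sinusoid through a monotone link reproduces a single daily
  activity peak; `K` is configurable.
- **Timing convention.** The transition from step `t-1` to step `t` is
  parameterised by the covariate row of the *origin* step `t-1`; the
  simulator and the likelihood share this convention.
- **Bursts.** Maximal runs of fixes with no observation gap over 4 h are
  treated as independent realisations.  Each burst is initialised from the
  stationary distribution of the transition matrix at its first step's
  covariates — this adds no parameters and is well defined because the chain
  at fixed covariates is a two-state ergodic chain with
  `pi = (gamma_21, gamma_12) / (gamma_12 + gamma_21)`.
- **Missing steps** contribute a unit emission vector; the transition
  structure still advances across them.

## Fitting

Direct numerical maximum likelihood on the unconstrained working vector
`theta = (log mu, log sigma, vec beta)` with a scaled forward recursion
(per-step normalisation; log-scale accumulation).  L-BFGS-B quasi-Newton
ascent, relative function tolerance 1e-10, gradient tolerance 1e-6, up to 500
iterations.  Restarts: the first start splits the observed steps at the
median and uses the half-sample means/sds for the emissions with `beta = 0`
(intercepts -1); further restarts perturb emissions multiplicatively
(log-normal, sd 0.2) and coefficients additively (normal, sd 0.1).  The best
optimum is kept and relabelled so `mu_1 < mu_2` (relabelling swaps emission
parameters and exchanges the two logit rows).  The covariance of `theta` is
the inverse of a central finite-difference observed information; if it is not
positive definite the fit is returned with the covariance flagged
unavailable.

Zero steps are offset to half the smallest positive observed step (the gamma
density is degenerate at zero; with 5 m GPS accuracy exact zeros are rare)
and the count is recorded.

Bursts are padded to a common length with missing steps for vectorised
recursion; padding is likelihood-neutral because a normalised forward vector
advanced through a stochastic matrix with unit emissions contributes
`log 1 = 0`.

## Preprocessing

Fixed order: regularise -> steps -> censor -> split/filter -> covariates.

- Fixes snap to the nearest grid instant (window = interval/2; the nearer fix
  wins a contention, with a warning).
- Distances are haversine on the mean-radius sphere (R = 6,371,000 m); at the
  sub-kilometre scales involved this differs from projected distance by far
  less than the 5 m GPS accuracy.
- Steps implying more than 400 m/h are censored to missing (the threshold is
  stated per hour and scaled to the sampling interval, so 5-minute data are
  screened at 400/12 m per step).  Censoring produces missing steps, not
  missing fixes, so it does not alter burst structure; it is applied before
  splitting.
- Tracks are cut where more than 4 h of consecutive grid time lacks a fix;
  bursts spanning (first-to-last instant) less than 48 h are dropped.  Span,
  not fix count, implements the 48-h rule.
- Every raw grid interval is classified kept / dropped-fragment / gap and the
  reconciliation report checks the classes sum to the total exactly.
- Body condition is the scaled mass index `SMI_i = M_i (L0 / L_i)^b` with
  `b` the standardised-major-axis slope of ln mass on ln length (OLS slope
  divided by Pearson r) and `L0` the population mean length.  Condition is
  carried forward from the most recent measurement; age is whole days since
  the pup's first fix (tracking starts at first capture).
- Weather gaps: interior values linearly interpolated in time; leading and
  trailing gaps take the nearest value (interpolation is undefined there).

## Decoding and diagnostics

- **Viterbi** in log space under the time-varying transition matrices; ties
  break toward the lower state index; missing steps contribute unit
  emissions.
- **Occupancy curves** report the stationary distribution of `Gamma(x)` at a
  covariate configuration (the other covariates at their standardised mean or
  reference category), not the smoothed posterior frequency.  95% bands are
  2.5/97.5 percentiles over parameter vectors drawn from a multivariate
  normal centred at the MLE with the fit covariance (percentiles, not a
  normal approximation, to respect the [0,1] range).
- **Pseudo-residuals** are forecast (one-step-ahead): `z_t` is the standard
  normal quantile of `P(X_t <= x_t | x_1..t-1)`, mixing the per-state gamma
  CDFs with predicted state probabilities from the normalised forward
  recursion.  Probabilities are clamped to `[1e-12, 1 - 1e-12]` before the
  probit.  Under a correct model they are standard normal and serially
  uncorrelated.
- **Marginal fit**: the two-component gamma mixture weighted by the
  time-averaged stationary probabilities over all observed covariate rows,
  compared with the empirical histogram by total variation distance.
- Time-in-state summaries are unweighted means of per-pup fractions (a pooled
  variant is available behind a flag).

## Model selection

The exclusion ladder refits the model twice per non-colony covariate
(dropping its colony-interaction columns; dropping all its columns) and once
for colony (dropping the indicator and every interaction column), ranking
covariates by `delta AIC = AIC(reduced) - AIC(full)` with
`AIC = -2 loglik + 2 dim(theta)`.  Reduced fits are warm-started from the
full fit's surviving coefficients plus fresh restarts, which enforces the
nesting inequality in practice.  The relevance threshold (default 40) is a
configuration value, and the ladder never changes the inference model.

## Post-hoc statistics

- **Random-intercept logistic regression** (response: hourly decoded state,
  0 = inactive / 1 = active; one normal random intercept per pup).  The
  marginal likelihood integrates each pup's Bernoulli likelihood over the
  intercept by adaptive Gauss-Hermite quadrature: 15 nodes centred at each
  group's conditional mode and scaled by its curvature (1 node = Laplace).
  Wald tests from the observed information of (intercept, slope, log sd).
  The implementation agrees with lme4::glmer (nAGQ = 15) to ~1e-5 on a frozen
  reference dataset.  Attendance is daily, so every step on a calendar day
  inherits that day's maternal presence; survival is constant per pup.
  Complete separation (a predictor level with constant response) is refused
  with an explicit error.  A Pearson-residual dispersion ratio against a
  parametric simulation envelope (500 simulations) is provided as a
  lightweight dispersion diagnostic, not a full simulated-residual suite.
- **Rank-sum test** for the colony contrast in per-pup mean displacement:
  exact enumeration when `m*n <= 10,000` and tie-free, otherwise the
  tie-corrected normal approximation with continuity correction (scipy's
  Mann-Whitney implementation; the package fixes the method policy and also
  reports the rank-sum statistic `W = U + m(m+1)/2`).

## The synthetic cohort

The generator emulates the study conditions: 2 colonies x 2 seasons x 16
pups, hourly sampling, deployments drawn 20-80 days, state mean step lengths
22.5 m and 75.8 m, seasonal temperature means 3.7/3.9 degC (sd 1.3/1.4,
AR(1) with coefficient 0.97), ~20% early mortality truncating tracks,
alternating maternal attendance bouts (~2 days ashore / ~5 at sea), 2%
missing fixes, 0.4% displaced-fix outliers, and occasional 5-12 h signal
lapses so burst splitting is exercised.

Movement geometry: the track starts at a per-pup home patch (colony
reference plus scatter — 60 m at the reference colony, 160 m at the other,
which also produces the between-colony displacement contrast).  Step lengths
are drawn from the state's gamma distribution, so the emission marginals stay
exactly gamma.  Inactive headings are isotropic; active headings persist
(previous heading + normal noise, sd 0.45 rad) blended with a home-attraction
bearing whose weight grows linearly with distance and saturates at 300 m —
excursions return, giving the star-shaped central-place-exploration pattern.
Excursion geometry (lengths, return times) is illustrative, not calibrated:
no quantitative description of it exists to calibrate against.

Generating coefficients (on the standardised scale) default to: transition
logit intercepts -2.0 (inactive to active) and -1.0 (active to inactive),
giving mean sojourns of ~8 h inactive / ~4 h active and about two thirds of
time inactive; a midday activity peak (`hour_cos = -0.6` on the activation
logit); an age effect (+0.35) present only at the reference colony
(interaction -0.35); a weaker second season (-0.4, interaction +0.3); sex,
condition, temperature and wind null.  Displaced outlier fixes are moved
1200-2500 m and kept at least two rows apart, so each flanking step is
anchored at a true position and must exceed the 400 m/h screen — the
censoring filter is testable end-to-end against the exact injected set.

What the generator does *not* emulate: at-sea movement, tides, topography or
habitat classes; behavioural coupling between activity and maternal
attendance or fate (both are generated independently of the state sequence);
day-to-day variation of condition within a 10-day window.  Passing recovery
tests therefore show the estimator is correct under the model, not that the
model is correct for real tracks.

## Problem sizes and numerical choices

Statistical checks run at: parameter recovery 30 pups x 720 steps; residual
calibration ~20,000 steps; ladder discrimination 20 pups x 1000 steps with a
strong age effect and a null wind covariate; GLMM recovery 60 groups x 500
observations plus 500 null-permutation refits at 30 x 40.  The bundled
analysis scripts default to 12 pups; all sizes are arguments.

Known limitations:

- With emission sd equal to the mean (shape-1 gammas), state overlap caps
  decoded-state accuracy near 0.85 regardless of estimator quality; accuracy
  above 0.9 requires better-separated emissions (e.g. sd = mean/2) or
  multi-day sojourns.  The recovery harness keeps the realistic sub-daily
  sojourn regime.
- The observed-information covariance uses finite differences; for very flat
  directions (near-collinear design columns) it can be flagged unavailable,
  in which case occupancy bands are omitted rather than fabricated.
- Gradients are finite-difference; fitting cost grows linearly in the
  parameter count, so the full 8-term interaction model is markedly slower
  than the reduced harness models.
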