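# pupmove

Behavioural-state analysis of terrestrial GPS tracks from Antarctic fur seal
pups (*Arctocephalus gazella*) — or any central-place-exploring animal
sampled at a regular interval.  Newborn pups cannot yet swim; between birth
and moulting they alternate bouts of rest at a "home patch" with short
directed excursions, and the drivers of that activity (colony of birth,
season, age, time of day, sex, body condition, weather) are the scientific
question this package addresses.

## What it does

The core is a **two-state hidden Markov model on hourly step lengths** with
covariate-dependent transition probabilities:

- step lengths `x_t | S_t = i ~ Gamma(mu_i, sigma_i)` (mean/sd
  parametrisation; state 1 "inactive", state 2 "active", `mu_1 < mu_2`),
- `logit(gamma_12,t) = beta_1' x_t` and `logit(gamma_21,t) = beta_2' x_t`,
  where the design row `x_t` holds colony, season, sex, age, scaled-mass
  body condition, temperature, wind, a diel harmonic pair
  `(sin, cos)(2 pi h / 24)`, and colony interactions for every term,
- fitted by direct numerical maximum likelihood (scaled forward recursion,
  quasi-Newton, multiple restarts), decoded with the Viterbi algorithm,
  checked with forecast pseudo-residuals, and summarised through
  stationary-occupancy curves `pi_active(x) = gamma_12 / (gamma_12 +
  gamma_21)` with Monte-Carlo confidence bands.

Around it: a full preprocessing pipeline (grid regularisation, haversine
steps, 400 m/h speed censoring, burst splitting at 4 h gaps, 48 h minimum
span, covariate standardisation, scaled mass index), an AIC
covariate-exclusion ladder, post-hoc random-intercept logistic regressions
on the decoded states (maternal attendance; survival) and a rank-sum colony
comparison — and a **synthetic cohort generator** with known ground truth, so
the entire pipeline runs and is tested without any field data.

## Layout

    src/pupmove/        library: simulate, preprocessing, design, hmm,
                        decoding, selection, posthoc, harness
    analysis/           numbered drivers: 01_simulate_tracks ... 06_posthoc
    tests/              pytest suite (unit, property and statistical checks)
    scripts/acceptance.py   end-to-end recomputation of headline numbers
    docs/methods.md     model, assumptions, defaults, limitations

## Worked example

```
$ python analysis/01_simulate_tracks.py
cohort: 12 pups ({'FWB': 6, 'SSB': 6} by colony, {2019: 6, 2020: 6} by season)
fixes: 11588 | died early: 3

$ python analysis/02_preprocess.py
raw fixes 11588 -> grid rows 11915 (327 missing)
censored steps >400 m/h: 115
bursts kept 25, dropped 0; interval accounting balanced: True
mean hourly distance: 37.2 m

$ python analysis/03_fit_hmm.py
state means: inactive 21.9 m, active 76.1 m (sd 22.1 / 70.7)
loglik -51499.5, AIC 103079.1, 40 parameters

$ python analysis/04_decode_and_diagnose.py
time inactive: mean 79.8% (range 66.9-91.9%) across 12 pups
occupancy(age, colony=0): active prob 0.06-0.43
occupancy(age, colony=1): active prob 0.14-0.15
pseudo-residuals: KS 0.0067, lag-1 ACF 0.0052, |z|>1.96 fraction 0.048

$ python analysis/05_model_selection.py     # slow: 15 refits of the 40-parameter model
...
 hour               all terms 103136.0      56.9      True       True
...
relevant (delta AIC >= 40): hour

$ python analysis/06_posthoc.py
survival GLMM (n=11240, 12 pups): slope 0.312 (se 0.276), p 0.257
colony displacement rank-sum: W 25, p 0.0260 (exact)
```

The generating truth behind this cohort has state means 22.5 / 75.8 m, a
diel activity cycle, and an age effect on activation only at the reference
colony — the fit recovers the means within a few percent, the occupancy
curves show the age trend at colony 0 (0.06 -> 0.43) and none at colony 1
(flat ~0.14), and the exclusion ladder flags the diel cycle (delta AIC 56.9)
while ranking the age effect next (30.4, under-threshold at this small
cohort) and every generated-null covariate at negative delta AIC.
Pseudo-residual statistics near zero and a 4.8% tail rate say the fitted
model reproduces its own data-generating process.

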