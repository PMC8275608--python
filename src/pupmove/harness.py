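"""Parameter-recovery and selection-discrimination harnesses.

These build controlled synthetic cohorts directly on the step scale (states
from the covariate-driven Markov chain, steps from the state-conditional
gamma distributions) without the geometric track layer, which leaves the
step-length marginals exactly gamma and makes estimator checks clean.
Covariate streams mimic the study design: a diel hour cycle, age in days
standardised over the deployment, two colonies, and an optional white
wind-like covariate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pupmove.design import Term, build_design
from pupmove.hmm import HMMSpec
from pupmove.simulate import simulate_state_sequence, simulate_steps

#: emission truth: the two state mean step lengths (m), sd = mean
RECOVERY_MU = (22.5, 75.8)
RECOVERY_SIGMA = (22.5, 75.8)

#: generating transition coefficients on the standardised covariate scale
RECOVERY_COEF = {
    "1->2": {"intercept": -2.0, "age": 0.35, "hour_cos1": -0.6, "age:colony": -0.35},
    "2->1": {"intercept": -1.0, "age": -0.15, "hour_cos1": 0.3, "age:colony": 0.15},
}


def _beta_from_coef(columns: list[str], coef: dict) -> np.ndarray:
    beta = np.zeros((2, len(columns)))
    for j, c in enumerate(columns):
        beta[0, j] = coef["1->2"].get(c, 0.0)
        beta[1, j] = coef["2->1"].get(c, 0.0)
    return beta


def _covariate_frame(pup: int, T: int, colony: float, rng: np.random.Generator,
                     include_wind: bool) -> pd.DataFrame:
    days = -(-T // 24)
    age = np.repeat(np.arange(days), 24)[:T].astype(float)
    age_z = (age - age.mean()) / max(age.std(), 1.0)
    hour = np.tile(np.arange(24.0), days)[:T]
    df = pd.DataFrame({"id": f"p{pup:03d}", "burst": 1, "colony": colony,
                       "age": age_z, "hour": hour})
    if include_wind:
        # AR(1) smooth standardised wind-like series
        w = np.empty(T)
        w[0] = rng.normal()
        for t in range(1, T):
            w[t] = 0.9 * w[t - 1] + rng.normal(0, np.sqrt(1 - 0.81))
        df["wind"] = w
    return df


def make_recovery_dataset(n_pups: int = 30, T: int = 720, seed: int = 0,
                          coef: dict | None = None) -> dict:
    """Cohort for the parameter-recovery check.

    ``n_pups`` pups (alternating colonies) x ``T`` hourly steps, gamma
    emissions at the study's state means (sd = mean), transition logits driven
    by age, a single diel harmonic, and an age x colony interaction.
    Returns the spec, the long burst table, the true beta and the per-pup true
    state sequences.
    """
    rng = np.random.default_rng(seed)
    spec = HMMSpec([Term("colony"), Term("age"), Term("hour")])
    coef = RECOVERY_COEF if coef is None else coef
    frames, states_by_pup = [], {}
    beta = None
    for i in range(n_pups):
        df = _covariate_frame(i, T, colony=float(i % 2), rng=rng, include_wind=False)
        X, info = build_design(df, spec.terms, spec.harmonics)
        if beta is None:
            beta = _beta_from_coef(info.columns, coef)
        states = simulate_state_sequence(beta, X, rng=rng)
        df["step_m"] = simulate_steps(states, RECOVERY_MU, RECOVERY_SIGMA, rng)
        states_by_pup[df.id.iloc[0]] = states
        frames.append(df)
    return {"spec": spec, "bursts": pd.concat(frames, ignore_index=True),
            "beta": beta, "columns": info.columns, "states": states_by_pup,
            "mu": np.array(RECOVERY_MU), "sigma": np.array(RECOVERY_SIGMA)}


def make_selection_dataset(n_pups: int = 20, T: int = 1000, seed: int = 0) -> dict:
    """Cohort for the exclusion-ladder discrimination check.

    Strong age effect (recovery-harness effect sizes), a wind covariate whose
    true coefficients are zero, colony interactions for both.
    """
    rng = np.random.default_rng(seed)
    spec = HMMSpec([Term("colony"), Term("age"), Term("wind")])
    coef = {"1->2": {k: v for k, v in RECOVERY_COEF["1->2"].items() if "hour" not in k},
            "2->1": {k: v for k, v in RECOVERY_COEF["2->1"].items() if "hour" not in k}}
    frames, states_by_pup = [], {}
    beta = None
    for i in range(n_pups):
        df = _covariate_frame(i, T, colony=float(i % 2), rng=rng, include_wind=True)
        X, info = build_design(df, spec.terms, spec.harmonics)
        if beta is None:
            beta = _beta_from_coef(info.columns, coef)
        states = simulate_state_sequence(beta, X, rng=rng)
        df["step_m"] = simulate_steps(states, RECOVERY_MU, RECOVERY_SIGMA, rng)
        states_by_pup[df.id.iloc[0]] = states
        frames.append(df)
    return {"spec": spec, "bursts": pd.concat(frames, ignore_index=True),
            "beta": beta, "columns": info.columns, "states": states_by_pup}


def make_glmm_dataset(n_groups: int = 60, n_per_group: int = 500, slope: float = 0.75,
                      re_sd: float = 0.8, intercept: float = -0.6, seed: int = 0) -> dict:
    """Grouped binary data from a random-intercept logistic model."""
    rng = np.random.default_rng(seed)
    g = np.repeat(np.arange(n_groups), n_per_group)
    x = rng.integers(0, 2, g.size).astype(float)
    b = rng.normal(0.0, re_sd, n_groups)
    eta = intercept + slope * x + b[g]
    from scipy.special import expit
    y = (rng.random(g.size) < expit(eta)).astype(float)
    return {"y": y, "x": x, "groups": g,
            "slope": slope, "re_sd": re_sd, "intercept": intercept}
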