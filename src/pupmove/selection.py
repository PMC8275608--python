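"""AIC covariate-exclusion ladder for the transition formula.

For every non-colony covariate two reduced models are refitted: one dropping
only its colony-interaction columns, one dropping all of its terms; for the
colony covariate a single reduced model drops the colony indicator and every
interaction column.  Covariates are ranked by
``delta_AIC = AIC_reduced - AIC_full``; a covariate is flagged relevant when
its largest delta exceeds a configurable threshold (default 40).  The ladder
only reports relevance — inference always stays with the full model.

Reduced fits are warm-started from the full fit's surviving coefficients
(plus fresh random restarts), which enforces the nesting inequality
loglik_reduced <= loglik_full in practice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from pupmove.design import COLONY_TERM
from pupmove.hmm import HMMFit, HMMSpec, fit as fit_hmm, pack_theta, stack_bursts


def aic(fit: HMMFit) -> float:
    """Akaike information criterion: -2 loglik + 2 dim(theta)."""
    return -2.0 * fit.loglik + 2.0 * fit.n_params


def _warm_theta(full_fit: HMMFit, full_columns: list[str], reduced_columns: list[str]) -> np.ndarray:
    """Full-fit working vector with the dropped beta columns removed."""
    keep = [full_columns.index(c) for c in reduced_columns]
    return pack_theta(full_fit.mu, full_fit.sigma, full_fit.beta[:, keep])


def _reduced_spec(spec: HMMSpec, name: str, mode: str) -> HMMSpec:
    if name == COLONY_TERM:
        reduced = spec.with_dropped(drop_main_of=[COLONY_TERM], drop_interaction_of=[])
        # without a colony term no interaction can remain
        reduced = HMMSpec(terms=[type(t)(t.name, False) for t in reduced.terms],
                          harmonics=spec.harmonics, n_states=spec.n_states)
        return reduced
    if mode == "interaction":
        return spec.with_dropped(drop_main_of=[], drop_interaction_of=[name])
    return spec.with_dropped(drop_main_of=[name], drop_interaction_of=[])


def exclusion_ladder(full_spec: HMMSpec, bursts: pd.DataFrame, threshold: float = 40.0,
                     n_restarts: int = 3, seed: int | None = None,
                     full_fit: HMMFit | None = None, maxiter: int = 500) -> dict:
    """Fit the exclusion ladder and rank covariates by delta AIC.

    Returns ``{"table": DataFrame, "full_fit": HMMFit, "fits": dict}`` where
    the table mirrors the (covariate, exclusion mode, AIC, delta AIC,
    relevant) layout.  A reduced fit that fails to converge yields a row
    marked failed and the ladder continues.
    """
    if COLONY_TERM not in [t.name for t in full_spec.terms]:
        raise ValueError("exclusion ladder requires a colony term in the full model")
    full_stack = stack_bursts(bursts, full_spec)
    if full_fit is None:
        full_fit = fit_hmm(full_spec, full_stack, n_restarts=n_restarts, seed=seed,
                           compute_covariance=False, maxiter=maxiter)
    full_cols = full_stack.info.columns
    rows = [dict(covariate="(none: full model)", exclude="-", aic=aic(full_fit),
                 delta_aic=0.0, relevant=np.nan, converged=True)]
    fits = {}
    names = [t.name for t in full_spec.terms if t.name != COLONY_TERM]
    jobs = [(n, m) for n in names for m in ("interaction", "all")] + [(COLONY_TERM, "all")]
    rng = np.random.default_rng(seed)
    for name, mode in jobs:
        spec_red = _reduced_spec(full_spec, name, mode)
        red_stack = stack_bursts(bursts, spec_red)
        warm = _warm_theta(full_fit, full_cols, red_stack.info.columns)
        label = "interaction with colony" if mode == "interaction" else "all terms"
        try:
            f = fit_hmm(spec_red, red_stack, n_restarts=n_restarts,
                        seed=int(rng.integers(2**31)), warm_start=warm,
                        compute_covariance=False, maxiter=maxiter)
            rows.append(dict(covariate=name, exclude=label, aic=aic(f),
                             delta_aic=aic(f) - aic(full_fit), relevant=np.nan,
                             converged=True))
            fits[(name, mode)] = f
        except RuntimeError:
            rows.append(dict(covariate=name, exclude=label, aic=np.nan,
                             delta_aic=np.nan, relevant=np.nan, converged=False))
    table = pd.DataFrame(rows)
    relevance = {
        name: bool(table.loc[table.covariate == name, "delta_aic"].max() >= threshold)
        for name in names + [COLONY_TERM]
    }
    table["relevant"] = table.covariate.map(relevance).astype("boolean")
    return {"table": table, "full_fit": full_fit, "fits": fits}
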