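"""State decoding, occupancy curves, and model-fit diagnostics.

- Viterbi decoding of the most probable state path under the time-varying
  transition matrices (log-space dynamic program, ties toward the lower state
  index, missing steps contribute unit emissions).
- Occupancy curves: the active-state stationary probability of the transition
  matrix evaluated along a covariate grid with the other covariates fixed at
  their means / reference categories, with 95% Monte-Carlo confidence bands
  drawn from the estimator's approximate normal distribution.
- Forecast pseudo-residuals: probit transform of the one-step-ahead predictive
  CDF; standard normal and white when the model is correct.
- Marginal-distribution comparison: fitted gamma mixture (weighted by the
  time-averaged stationary probabilities) against the empirical step histogram.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from pupmove.hmm import (BurstStack, HMMFit, forward_pass, gamma_logpdf,
                         stack_bursts, stationary_distribution, unpack_theta)


def _gamma_cdf(x, mu, sigma):
    return gamma_dist.cdf(x, a=mu**2 / sigma**2, scale=sigma**2 / mu)


def _check_signature(fit: HMMFit, stack: BurstStack):
    if fit.design_signature != stack.info.signature():
        raise ValueError("fit and data were built from different design signatures")


# ---------------------------------------------------------------------------
# Viterbi
# ---------------------------------------------------------------------------

def viterbi(fit: HMMFit, stack: BurstStack) -> list[np.ndarray]:
    """Most probable state path (1/2) per burst under the fitted model."""
    _check_signature(fit, stack)
    B, T = stack.steps.shape
    eta = stack.X @ fit.beta.T
    g12, g21 = expit(eta[..., 0]), expit(eta[..., 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        logp = np.zeros((B, T, 2))
        obs = np.isfinite(stack.steps)
        for s in range(2):
            logp[obs, s] = gamma_logpdf(stack.steps[obs], fit.mu[s], fit.sigma[s])

    paths = []
    for b in range(B):
        Tb = int(stack.lengths[b])
        delta = np.empty((Tb, 2))
        back = np.zeros((Tb, 2), dtype=int)
        pi0 = stationary_distribution(
            np.array([[1 - g12[b, 0], g12[b, 0]], [g21[b, 0], 1 - g21[b, 0]]]))
        with np.errstate(divide="ignore"):
            delta[0] = np.log(pi0) + logp[b, 0]
            for t in range(1, Tb):
                lg = np.log(np.array([[1 - g12[b, t - 1], g12[b, t - 1]],
                                      [g21[b, t - 1], 1 - g21[b, t - 1]]]))
                cand = delta[t - 1][:, None] + lg          # (from, to)
                back[t] = np.argmax(cand, axis=0)          # first max: lower index wins ties
                delta[t] = cand[back[t], [0, 1]] + logp[b, t]
        path = np.empty(Tb, dtype=int)
        path[-1] = int(np.argmax(delta[-1]))
        for t in range(Tb - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        paths.append(path + 1)
    return paths


def decode_table(fit: HMMFit, bursts: pd.DataFrame) -> pd.DataFrame:
    """Long decoded table: the burst table plus ``state`` and ``observed`` flags."""
    stack = stack_bursts(bursts, fit.spec)
    paths = viterbi(fit, stack)
    out = bursts.copy()
    out["state"] = np.nan
    grouped = bursts.groupby(["id", "burst"], sort=True).indices
    for key, path in zip(stack.burst_keys, paths):
        out.loc[grouped[key], "state"] = path
    out["state"] = out.state.astype(int)
    out["observed"] = np.isfinite(out.step_m.to_numpy())
    return out


def viterbi_path_logprob(fit: HMMFit, stack: BurstStack, paths: list[np.ndarray]) -> float:
    """Joint log-probability of given state paths and observations (for checks)."""
    eta = stack.X @ fit.beta.T
    g12, g21 = expit(eta[..., 0]), expit(eta[..., 1])
    total = 0.0
    for b, path in enumerate(paths):
        Tb = path.size
        s = path - 1
        pi0 = stationary_distribution(
            np.array([[1 - g12[b, 0], g12[b, 0]], [g21[b, 0], 1 - g21[b, 0]]]))
        lp = np.log(pi0[s[0]])
        for t in range(1, Tb):
            G = np.array([[1 - g12[b, t - 1], g12[b, t - 1]],
                          [g21[b, t - 1], 1 - g21[b, t - 1]]])
            lp += np.log(G[s[t - 1], s[t]])
        x = stack.steps[b, :Tb]
        obs = np.isfinite(x)
        lp += gamma_logpdf(x[obs], fit.mu[s[obs]], fit.sigma[s[obs]]).sum()
        total += lp
    return float(total)


# ---------------------------------------------------------------------------
# occupancy
# ---------------------------------------------------------------------------

def occupancy_fraction(decoded: pd.DataFrame, pooled: bool = False) -> dict:
    """Fraction of time per state from decoded sequences.

    Per-pup fractions over observed steps, summarised by the unweighted mean
    across pups (the default) or pooled over observations (``pooled=True``).
    """
    obs = decoded[decoded.observed]
    per_pup = obs.groupby("id").state.apply(lambda s: float((s == 1).mean()))
    mean_inactive = float(obs.state.eq(1).mean()) if pooled else float(per_pup.mean())
    return {
        "per_pup_inactive": per_pup,
        "mean_inactive": mean_inactive,
        "mean_active": 1.0 - mean_inactive,
        "range_inactive": (float(per_pup.min()), float(per_pup.max())),
    }


@dataclass
class OccupancyCurve:
    """Active-state stationary probability along one covariate's grid."""

    covariate: str
    grid: np.ndarray
    point: np.ndarray
    lower: np.ndarray | None
    upper: np.ndarray | None
    colony_level: float
    fixed: dict

    def has_band(self) -> bool:
        return self.lower is not None


def _curve_design(spec, covariate: str, grid: np.ndarray, colony_level: float) -> np.ndarray:
    """Design rows along the grid with other covariates at mean/reference."""
    names = [t.name for t in spec.terms]
    df = pd.DataFrame({n: np.zeros(grid.size) for n in names if n != "hour"})
    df["hour"] = 0.0
    df["colony"] = colony_level
    df[covariate] = grid
    from pupmove.design import build_design
    X, _ = build_design(df, spec.terms, spec.harmonics)
    return X


def _active_prob(beta: np.ndarray, X: np.ndarray) -> np.ndarray:
    g12 = expit(X @ beta[0])
    g21 = expit(X @ beta[1])
    return g12 / (g12 + g21)


def occupancy_curve(fit: HMMFit, covariate: str, grid: np.ndarray,
                    n_draws: int = 1000, seed: int | None = None,
                    colony_level: float = 0.0) -> OccupancyCurve:
    """Occupancy curve with percentile Monte-Carlo band.

    The point curve is the active-state stationary probability at each grid
    value with the other covariates at 0 (standardised mean / reference
    category) and the colony indicator at ``colony_level``.  The band is the
    2.5/97.5 percentile over ``n_draws`` parameter vectors sampled from a
    multivariate normal centred at the MLE with the fit covariance; absent if
    the covariance is unavailable.
    """
    grid = np.asarray(grid, dtype=float)
    X = _curve_design(fit.spec, covariate, grid, colony_level)
    point = _active_prob(fit.beta, X)
    lower = upper = None
    if n_draws > 0 and fit.covariance_ok and fit.covariance is not None:
        rng = np.random.default_rng(seed)
        draws = rng.multivariate_normal(fit.theta, fit.covariance, size=n_draws,
                                        method="svd")
        p = X.shape[1]
        probs = np.empty((n_draws, grid.size))
        for i, th in enumerate(draws):
            _, _, beta_i = unpack_theta(th, p)
            probs[i] = _active_prob(beta_i, X)
        lower, upper = np.percentile(probs, [2.5, 97.5], axis=0)
    return OccupancyCurve(covariate=covariate, grid=grid, point=point,
                          lower=lower, upper=upper, colony_level=colony_level,
                          fixed={"others": 0.0})


# ---------------------------------------------------------------------------
# pseudo-residuals
# ---------------------------------------------------------------------------

def pseudo_residuals(fit: HMMFit, stack: BurstStack, eps: float = 1e-12) -> np.ndarray:
    """Forecast pseudo-residuals on the standard-normal scale, (B, Tmax).

    z_t = Phi^{-1}( P(X_t <= x_t | x_1..t-1) ), where the predictive CDF mixes
    the per-state gamma CDFs with the one-step-ahead predicted state
    probabilities from the normalised forward recursion.  Missing steps yield
    missing residuals while the forward weights still advance.
    """
    _check_signature(fit, stack)
    ll, filt, pred = forward_pass(fit.theta, stack, return_filter=True)
    if pred is None:
        raise RuntimeError("forward pass failed at the fitted parameters")
    B, T = stack.steps.shape
    u = np.full((B, T), np.nan)
    obs = np.isfinite(stack.steps)
    x = stack.steps[obs]
    cdf = np.stack([_gamma_cdf(x, fit.mu[s], fit.sigma[s]) for s in range(2)], axis=-1)
    u[obs] = (pred[obs] * cdf).sum(axis=-1)
    u = np.clip(u, eps, 1.0 - eps)
    z = np.full((B, T), np.nan)
    z[obs] = norm.ppf(u[obs])
    # mask padding beyond each burst's true length
    for b in range(B):
        z[b, stack.lengths[b]:] = np.nan
    return z


def residual_series(fit: HMMFit, bursts: pd.DataFrame) -> pd.DataFrame:
    """Pseudo-residuals as a long table aligned with the burst rows."""
    stack = stack_bursts(bursts, fit.spec)
    z = pseudo_residuals(fit, stack)
    out = bursts[["id", "burst", "timestamp", "step_m"]].copy()
    out["residual"] = np.nan
    grouped = bursts.groupby(["id", "burst"], sort=True).indices
    for b, key in enumerate(stack.burst_keys):
        idx = grouped[key]
        out.loc[idx, "residual"] = z[b, : len(idx)]
    return out


def residual_diagnostics(z: np.ndarray) -> dict:
    """KS distance from N(0,1), lag-1 autocorrelation, tail exceedance rate."""
    from scipy.stats import kstest
    zz = z[np.isfinite(z)]
    ks = kstest(zz, "norm").statistic
    # lag-1 autocorrelation within rows (bursts), skipping missing pairs
    num = den = 0.0
    zbar = zz.mean()
    for row in np.atleast_2d(z):
        a, b = row[:-1], row[1:]
        ok = np.isfinite(a) & np.isfinite(b)
        num += ((a[ok] - zbar) * (b[ok] - zbar)).sum()
    den = ((zz - zbar) ** 2).sum()
    return {"ks_distance": float(ks), "lag1_acf": float(num / den),
            "tail_fraction": float((np.abs(zz) > 1.96).mean()), "n": int(zz.size)}


# ---------------------------------------------------------------------------
# marginal fit
# ---------------------------------------------------------------------------

def marginal_fit(fit: HMMFit, stack: BurstStack, n_bins: int = 50) -> dict:
    """Empirical vs model-implied marginal step distribution.

    The model marginal is the two-component gamma mixture weighted by the
    stationary active/inactive probabilities averaged over all observed
    covariate rows; discrepancy is the total variation distance on the shared
    binning.
    """
    obs = np.isfinite(stack.steps)
    x = stack.steps[obs]
    eta = stack.X @ fit.beta.T
    g12, g21 = expit(eta[..., 0]), expit(eta[..., 1])
    pi_active = (g12 / (g12 + g21))[obs]
    w = np.array([1.0 - pi_active.mean(), pi_active.mean()])

    edges = np.linspace(0.0, x.max(), n_bins + 1)
    emp, _ = np.histogram(x, bins=edges)
    emp = emp / emp.sum()
    cdf_hi = sum(w[s] * _gamma_cdf(edges[1:], fit.mu[s], fit.sigma[s]) for s in range(2))
    cdf_lo = sum(w[s] * _gamma_cdf(edges[:-1], fit.mu[s], fit.sigma[s]) for s in range(2))
    model = cdf_hi - cdf_lo
    model = model / model.sum()
    tv = 0.5 * float(np.abs(emp - model).sum())
    return {"edges": edges, "empirical": emp, "model": model,
            "tv_distance": tv, "weights": w}
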