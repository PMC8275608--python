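"""Two-state gamma hidden Markov model with covariate-dependent transitions.

Observed variable: step length (m) between consecutive regularised GPS fixes.
State-conditional emissions are gamma distributions in the mean/sd
parametrisation.  The off-diagonal transition probabilities of the 2x2 matrix
are logistic functions of a per-step design row:

    eta_12 = beta_1 . x_t        gamma_12 = 1 / (1 + exp(-eta_12))
    eta_21 = beta_2 . x_t        gamma_21 = 1 / (1 + exp(-eta_21))

(the row-wise multinomial logit with "stay" as reference, which reduces to the
logistic link for two states).  The model is fitted by direct numerical
maximisation of the scaled-forward log-likelihood over the unconstrained
working vector theta = (log mu, log sigma, vec beta).

Bursts — maximal gap-free runs of fixes — are treated as independent
realisations; each burst is initialised from the stationary distribution of
the transition matrix at its first step's covariates.  Missing steps
contribute a unit emission vector, so the transition structure still advances
across them.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, gammaln

from pupmove.design import DesignInfo, Term, build_design

N_STATES = 2


# ---------------------------------------------------------------------------
# emission / transition primitives
# ---------------------------------------------------------------------------

def gamma_logpdf(step, mu, sigma):
    """Log-density of the gamma distribution parametrised by mean and sd.

    Shape k = mu^2/sigma^2 and rate lam = mu/sigma^2, so
    log f(x) = k log lam - log Gamma(k) + (k-1) log x - lam x.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(mu <= 0) or np.any(sigma <= 0):
        raise ValueError("gamma mean and sd must be strictly positive")
    x = np.asarray(step, dtype=float)
    k = mu**2 / sigma**2
    lam = mu / sigma**2
    return k * np.log(lam) - gammaln(k) + (k - 1.0) * np.log(x) - lam * x


def transition_matrix(beta: np.ndarray, design_row: np.ndarray) -> np.ndarray:
    """2x2 row-stochastic transition matrix at one covariate configuration."""
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(design_row, dtype=float)
    if beta.shape != (2, x.shape[-1]):
        raise ValueError(f"beta shape {beta.shape} does not match design row length {x.shape[-1]}")
    g12 = expit(beta[0] @ x)
    g21 = expit(beta[1] @ x)
    return np.array([[1.0 - g12, g12], [g21, 1.0 - g21]])


def stationary_distribution(gamma_mat: np.ndarray) -> np.ndarray:
    """Stationary distribution pi = (g21, g12) / (g12 + g21) of a 2x2 chain."""
    g = np.asarray(gamma_mat, dtype=float)
    g12, g21 = g[0, 1], g[1, 0]
    denom = g12 + g21
    if denom <= 0:
        raise ValueError("chain is absorbing: gamma_12 + gamma_21 = 0")
    return np.array([g21 / denom, g12 / denom])


# ---------------------------------------------------------------------------
# model specification and data stacking
# ---------------------------------------------------------------------------

@dataclass
class HMMSpec:
    """Model definition: states, emission family, transition formula.

    Only the 2-state gamma emission model is a supported analysis path; the
    state count is kept as a field for structural extensibility.
    """

    terms: list[Term]
    harmonics: int = 1
    n_states: int = N_STATES

    def design(self, df: pd.DataFrame) -> tuple[np.ndarray, DesignInfo]:
        return build_design(df, self.terms, self.harmonics)

    def with_dropped(self, drop_main_of: list[str], drop_interaction_of: list[str]) -> "HMMSpec":
        """Reduced spec: remove whole terms and/or their colony interactions."""
        new_terms = []
        for t in self.terms:
            if t.name in drop_main_of:
                continue
            if t.name in drop_interaction_of:
                new_terms.append(Term(t.name, interact_colony=False))
            else:
                new_terms.append(t)
        return replace(self, terms=new_terms)


@dataclass
class BurstStack:
    """Bursts padded to a common length for vectorised recursion.

    steps[b, t] is NaN where the step is missing or padded; padding with
    missing steps is likelihood-neutral because a normalised forward vector
    advanced through a stochastic matrix with unit emissions contributes
    log 1 = 0.
    """

    steps: np.ndarray          # (B, Tmax)
    X: np.ndarray              # (B, Tmax, p)
    lengths: np.ndarray        # (B,) true burst lengths
    info: DesignInfo
    burst_keys: list[tuple]    # (id, burst_index) per row
    n_zero_offset: int = 0     # zero steps offset to half the min positive step

    @property
    def n_obs(self) -> int:
        return int(np.isfinite(self.steps).sum())

    def fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(np.ascontiguousarray(np.nan_to_num(self.steps)).tobytes())
        h.update(np.ascontiguousarray(self.X).tobytes())
        return h.hexdigest()[:16]


def stack_bursts(bursts: pd.DataFrame, spec: HMMSpec) -> BurstStack:
    """Stack a long-format burst table (one row per step) for fitting.

    Expects columns ``id``, ``burst``, ``step_m`` plus every covariate the spec
    references.  Steps equal to exactly zero are offset to half the smallest
    positive observed step (gamma density is degenerate at zero); the count is
    recorded.
    """
    required = {"id", "burst", "step_m"}
    missing = required - set(bursts.columns)
    if missing:
        raise KeyError(f"burst table lacks columns {sorted(missing)}")

    X_all, info = spec.design(bursts)
    steps_all = np.asarray(bursts["step_m"], dtype=float)

    pos = steps_all[np.isfinite(steps_all) & (steps_all > 0)]
    zero_mask = np.isfinite(steps_all) & (steps_all == 0.0)
    n_zero = int(zero_mask.sum())
    if n_zero:
        if pos.size == 0:
            raise ValueError("all finite steps are zero; gamma emissions undefined")
        steps_all = steps_all.copy()
        steps_all[zero_mask] = pos.min() / 2.0

    keys = list(bursts.groupby(["id", "burst"], sort=True).groups)
    grouped = bursts.groupby(["id", "burst"], sort=True).indices
    lengths = np.array([len(grouped[k]) for k in keys])
    B, Tmax, p = len(keys), int(lengths.max()), X_all.shape[1]

    steps = np.full((B, Tmax), np.nan)
    X = np.zeros((B, Tmax, p))
    X[:, :, 0] = 1.0  # keep padded transition rows valid (intercept only)
    for b, k in enumerate(keys):
        idx = grouped[k]
        steps[b, : len(idx)] = steps_all[idx]
        X[b, : len(idx)] = X_all[idx]
    return BurstStack(steps=steps, X=X, lengths=lengths, info=info,
                      burst_keys=keys, n_zero_offset=n_zero)


# ---------------------------------------------------------------------------
# working parameter vector
# ---------------------------------------------------------------------------

def pack_theta(mu: np.ndarray, sigma: np.ndarray, beta: np.ndarray) -> np.ndarray:
    return np.concatenate([np.log(mu), np.log(sigma), np.ravel(beta)])


def unpack_theta(theta: np.ndarray, p: int):
    theta = np.asarray(theta, dtype=float)
    if theta.size != 4 + 2 * p:
        raise ValueError("theta length does not match design width")
    mu = np.exp(theta[0:2])
    sigma = np.exp(theta[2:4])
    beta = theta[4:].reshape(2, p)
    return mu, sigma, beta


def _emission_logp(steps: np.ndarray, mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """(B, T, 2) log-densities; 0 (unit emission) where the step is missing."""
    obs = np.isfinite(steps)
    logp = np.zeros(steps.shape + (2,))
    x = steps[obs]
    for s in range(2):
        logp[obs, s] = gamma_logpdf(x, mu[s], sigma[s])
    return logp


def forward_pass(theta: np.ndarray, stack: BurstStack, return_filter: bool = False):
    """Scaled forward recursion over all bursts simultaneously.

    Returns the total log-likelihood; with ``return_filter`` also the
    normalised forward probabilities alpha[b, t, s] (filtered state
    distributions) and the one-step-ahead predicted state probabilities.
    """
    B, T = stack.steps.shape
    p = stack.X.shape[2]
    mu, sigma, beta = unpack_theta(theta, p)

    eta = stack.X @ beta.T                    # (B, T, 2): logits for 1->2, 2->1
    g12 = expit(eta[..., 0])
    g21 = expit(eta[..., 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        logp = _emission_logp(stack.steps, mu, sigma)
    pxt = np.exp(logp)                        # unit where missing

    denom = g12[:, 0] + g21[:, 0]
    if np.any(denom <= 0):
        return -np.inf if not return_filter else (-np.inf, None, None)
    alpha = np.empty((B, 2))
    alpha[:, 0] = g21[:, 0] / denom
    alpha[:, 1] = g12[:, 0] / denom

    ll = 0.0
    filt = np.empty((B, T, 2)) if return_filter else None
    pred = np.empty((B, T, 2)) if return_filter else None
    for t in range(T):
        if t > 0:
            # transition t-1 -> t parametrised by the origin step's covariates
            a12 = g12[:, t - 1]
            a21 = g21[:, t - 1]
            nxt0 = alpha[:, 0] * (1.0 - a12) + alpha[:, 1] * a21
            nxt1 = alpha[:, 0] * a12 + alpha[:, 1] * (1.0 - a21)
            alpha = np.column_stack([nxt0, nxt1])
        if return_filter:
            pred[:, t] = alpha
        alpha = alpha * pxt[:, t]
        c = alpha.sum(axis=1)
        if not np.all(np.isfinite(c)) or np.any(c <= 0):
            return -np.inf if not return_filter else (-np.inf, None, None)
        ll += np.log(c).sum()
        alpha = alpha / c[:, None]
        if return_filter:
            filt[:, t] = alpha
    if return_filter:
        return ll, filt, pred
    return ll


def forward_loglik(theta: np.ndarray, stack: BurstStack) -> float:
    """Total log-likelihood over individuals and bursts (optimizer-safe -inf)."""
    return forward_pass(theta, stack, return_filter=False)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class HMMFit:
    """Fitted model: working/natural parameters, likelihood, AIC, covariance."""

    spec: HMMSpec
    theta: np.ndarray
    mu: np.ndarray
    sigma: np.ndarray
    beta: np.ndarray
    loglik: float
    aic: float
    n_params: int
    n_obs: int
    covariance: np.ndarray | None
    covariance_ok: bool
    design_signature: str
    data_fingerprint: str
    restart_log: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta.tolist(),
            "mu": self.mu.tolist(),
            "sigma": self.sigma.tolist(),
            "beta": self.beta.tolist(),
            "loglik": self.loglik,
            "aic": self.aic,
            "n_params": self.n_params,
            "n_obs": self.n_obs,
            "covariance": None if self.covariance is None else self.covariance.tolist(),
            "covariance_ok": self.covariance_ok,
            "design_signature": self.design_signature,
            "data_fingerprint": self.data_fingerprint,
            "restart_log": self.restart_log,
        }


def load_fit(path, spec: HMMSpec) -> HMMFit:
    """Rehydrate a fit artifact written by ``HMMFit.to_dict`` (JSON file)."""
    import json

    with open(path) as fh:
        d = json.load(fh)
    cov = None if d["covariance"] is None else np.asarray(d["covariance"])
    return HMMFit(spec=spec, theta=np.asarray(d["theta"]), mu=np.asarray(d["mu"]),
                  sigma=np.asarray(d["sigma"]), beta=np.asarray(d["beta"]),
                  loglik=d["loglik"], aic=d["aic"], n_params=d["n_params"],
                  n_obs=d["n_obs"], covariance=cov, covariance_ok=d["covariance_ok"],
                  design_signature=d["design_signature"],
                  data_fingerprint=d.get("data_fingerprint", ""),
                  restart_log=d.get("restart_log", []))


def _relabel(theta: np.ndarray, p: int) -> np.ndarray:
    """Enforce the label convention mu_1 < mu_2 (state 1 = inactive).

    Swapping states swaps the emission parameters and exchanges the two
    off-diagonal logits (the 1->2 row becomes the 2->1 row).
    """
    mu, sigma, beta = unpack_theta(theta, p)
    if mu[0] <= mu[1]:
        return theta
    return pack_theta(mu[::-1], sigma[::-1], beta[::-1])


def _numerical_hessian(f, x0: np.ndarray, rel_step: float = 1e-4) -> np.ndarray:
    """Central finite-difference Hessian (symmetrised)."""
    n = x0.size
    h = rel_step * np.maximum(1.0, np.abs(x0))
    H = np.empty((n, n))
    f0 = f(x0)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x0.copy(); xp[i] += h[i]
                xm = x0.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2.0 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp = x0.copy(); xpp[[i, j]] += [h[i], h[j]]
                xpm = x0.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x0.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x0.copy(); xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4.0 * h[i] * h[j])
    return H


def _starting_values(stack: BurstStack, rng: np.random.Generator, perturb: bool):
    """Quantile-split emission starts; beta starts at zero (plus noise)."""
    obs = stack.steps[np.isfinite(stack.steps)]
    med = np.median(obs)
    lo, hi = obs[obs <= med], obs[obs > med]
    mu0 = np.array([lo.mean(), hi.mean()])
    sd0 = np.array([max(lo.std(), 1e-3 * mu0[0]), max(hi.std(), 1e-3 * mu0[1])])
    p = stack.X.shape[2]
    beta0 = np.zeros((2, p))
    beta0[:, 0] = -1.0  # mildly persistent states
    if perturb:
        mu0 = mu0 * np.exp(rng.normal(0.0, 0.2, 2))
        sd0 = sd0 * np.exp(rng.normal(0.0, 0.2, 2))
        beta0 = beta0 + rng.normal(0.0, 0.1, beta0.shape)
    return pack_theta(mu0, sd0, beta0)


def fit(
    spec: HMMSpec,
    bursts: pd.DataFrame | BurstStack,
    n_restarts: int = 10,
    seed: int | None = None,
    warm_start: np.ndarray | None = None,
    compute_covariance: bool = True,
    maxiter: int = 500,
) -> HMMFit:
    """Maximum-likelihood fit by quasi-Newton ascent over the working scale.

    Restarts draw perturbed starting values (the first restart is the
    deterministic quantile-split start; a supplied ``warm_start`` is used as an
    additional unperturbed start).  The best converged optimum is kept and
    relabelled so that mu_1 < mu_2.  The covariance of theta is the inverse of
    a central finite-difference observed information; if that matrix is not
    positive definite the fit is returned with the covariance flagged
    unavailable.
    """
    stack = bursts if isinstance(bursts, BurstStack) else stack_bursts(bursts, spec)
    obs = stack.steps[np.isfinite(stack.steps)]
    if np.unique(obs).size < 2:
        raise ValueError("need at least 2 distinct non-missing step values")
    rng = np.random.default_rng(seed)
    p = stack.X.shape[2]

    nll = lambda th: -forward_loglik(th, stack)
    starts = []
    if warm_start is not None:
        starts.append(np.asarray(warm_start, dtype=float))
    for r in range(n_restarts):
        starts.append(_starting_values(stack, rng, perturb=(r > 0 or warm_start is not None)))

    best, log = None, []
    for i, th0 in enumerate(starts):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            res = minimize(nll, th0, method="L-BFGS-B",
                           options={"maxiter": maxiter, "ftol": 1e-10, "gtol": 1e-6})
        entry = {"restart": i, "loglik": -float(res.fun), "converged": bool(res.success),
                 "nit": int(res.nit), "message": str(res.message)}
        log.append(entry)
        usable = np.isfinite(res.fun)
        if usable and (best is None or res.fun < best.fun):
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"all restarts failed to converge; trace: {log}")

    theta = _relabel(best.x, p)
    mu, sigma, beta = unpack_theta(theta, p)
    loglik = -float(best.fun)
    k = theta.size
    aic = -2.0 * loglik + 2.0 * k

    cov, cov_ok = None, False
    if compute_covariance:
        H = _numerical_hessian(nll, theta)
        try:
            cov = np.linalg.inv(H)
            cov = (cov + cov.T) / 2.0
            cov_ok = bool(np.all(np.linalg.eigvalsh(cov) > 0))
        except np.linalg.LinAlgError:
            cov, cov_ok = None, False
        if cov is not None and not cov_ok:
            cov = None

    return HMMFit(spec=spec, theta=theta, mu=mu, sigma=sigma, beta=beta,
                  loglik=loglik, aic=aic, n_params=k, n_obs=stack.n_obs,
                  covariance=cov, covariance_ok=cov_ok,
                  design_signature=stack.info.signature(),
                  data_fingerprint=stack.fingerprint(), restart_log=log)
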