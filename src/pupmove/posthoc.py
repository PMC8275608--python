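"""Post-hoc statistics on decoded behavioural states.

- Random-intercept logistic regression (binomial GLMM, one normal random
  intercept per pup) fitted by maximum likelihood with adaptive Gauss-Hermite
  quadrature: used for the maternal-attendance and survival analyses, where
  the response is the decoded state (0 = inactive, 1 = active) per hourly
  observation.
- Wilcoxon/Mann-Whitney rank-sum comparison of per-pup mean displacement from
  the natal colony between the two colonies.
- A dispersion check of Pearson residuals against a simulation envelope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial.hermite import hermgauss
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from scipy.stats import mannwhitneyu, norm

from pupmove.hmm import _numerical_hessian


@dataclass
class GlmmResult:
    """Random-intercept logistic regression fit."""

    slope: float
    slope_se: float
    z: float
    p: float
    intercept: float
    re_sd: float
    loglik: float
    n_obs: int
    n_groups: int

    @property
    def re_var(self) -> float:
        return self.re_sd**2


def _group_stats(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """Per-group successes/trials at each binary predictor level."""
    uniq, gidx = np.unique(groups, return_inverse=True)
    G = uniq.size
    n = np.zeros((G, 2))
    s = np.zeros((G, 2))
    xi = x.astype(int)
    np.add.at(n, (gidx, xi), 1.0)
    np.add.at(s, (gidx, xi), y.astype(float))
    return n, s, G


def _group_loglik(b, eta0, eta1, n, s):
    """(G, K) log-likelihood of each group at each random-intercept value b."""
    l0 = s[:, 0:1] * (eta0 + b) - n[:, 0:1] * np.logaddexp(0.0, eta0 + b)
    l1 = s[:, 1:2] * (eta1 + b) - n[:, 1:2] * np.logaddexp(0.0, eta1 + b)
    return l0 + l1


def _group_modes(eta0, eta1, n, s, sigma, n_iter: int = 30):
    """Newton mode and curvature of the per-group joint log-density in b."""
    G = n.shape[0]
    b = np.zeros((G, 1))
    for _ in range(n_iter):
        p0 = expit(eta0 + b)
        p1 = expit(eta1 + b)
        grad = (s[:, 0:1] - n[:, 0:1] * p0) + (s[:, 1:2] - n[:, 1:2] * p1) - b / sigma**2
        hess = -(n[:, 0:1] * p0 * (1 - p0) + n[:, 1:2] * p1 * (1 - p1)) - 1.0 / sigma**2
        step = grad / hess
        b = b - np.clip(step, -5.0, 5.0)
    return b, hess


def glmm_logistic(y, x, groups, n_quad: int = 15) -> GlmmResult:
    """Binomial GLMM with a single normal random intercept per group.

    The marginal likelihood integrates the per-group Bernoulli likelihood over
    the random intercept with adaptive Gauss-Hermite quadrature (``n_quad``
    nodes centred and scaled at each group's conditional mode; 1 node is the
    Laplace approximation).  Standard errors come from the observed
    information of (intercept, slope, log sd); the slope p-value is two-sided
    Wald.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    if not set(np.unique(x)) <= {0.0, 1.0}:
        raise ValueError("predictor must be binary 0/1")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    n, s, G = _group_stats(y, x, groups)
    if G < 2:
        raise ValueError("need at least 2 groups")
    for level in (0, 1):
        tot, suc = n[:, level].sum(), s[:, level].sum()
        if tot > 0 and (suc == 0 or suc == tot):
            raise ValueError(f"complete separation: predictor level {level} has a constant response")

    nodes, weights = hermgauss(n_quad)
    log_w = np.log(weights)

    def nll(params):
        b0, b1, log_sd = params
        sigma = np.exp(log_sd)
        eta0, eta1 = b0, b0 + b1
        bhat, hess = _group_modes(eta0, eta1, n, s, sigma)
        tau = 1.0 / np.sqrt(-hess)
        bk = bhat + np.sqrt(2.0) * tau * nodes[None, :]
        lg = _group_loglik(bk, eta0, eta1, n, s)
        log_phi = -0.5 * (bk / sigma) ** 2 - np.log(sigma) - 0.5 * np.log(2 * np.pi)
        log_int = logsumexp(log_w[None, :] + nodes[None, :] ** 2 + lg + log_phi, axis=1)
        ll = (np.log(np.sqrt(2.0) * tau[:, 0]) + log_int).sum()
        return -ll if np.isfinite(ll) else 1e12

    # moment-flavoured start: pooled logit of the mean, zero slope
    p_bar = np.clip(y.mean(), 1e-3, 1 - 1e-3)
    x0 = np.array([np.log(p_bar / (1 - p_bar)), 0.0, np.log(0.5)])
    res = minimize(nll, x0, method="L-BFGS-B",
                   bounds=[(-30, 30), (-30, 30), (-10.0, 5.0)],
                   options={"maxiter": 500, "ftol": 1e-12})
    b0, b1, log_sd = res.x
    H = _numerical_hessian(nll, res.x)
    try:
        cov = np.linalg.inv(H)
        se = float(np.sqrt(max(cov[1, 1], 0.0)))
    except np.linalg.LinAlgError:
        se = np.nan
    if not np.isfinite(se) or se <= 0:
        raise RuntimeError("standard error unavailable (singular information)")
    z = b1 / se
    p = 2.0 * norm.sf(abs(z))
    return GlmmResult(slope=float(b1), slope_se=se, z=float(z), p=float(p),
                      intercept=float(b0), re_sd=float(np.exp(log_sd)),
                      loglik=-float(res.fun), n_obs=int(y.size), n_groups=int(G))


# ---------------------------------------------------------------------------
# rank-sum comparison
# ---------------------------------------------------------------------------

@dataclass
class RankSumResult:
    statistic: float     # rank sum of the first sample (W)
    u: float             # Mann-Whitney U of the first sample
    p: float
    method: str


def rank_sum_test(sample_a, sample_b) -> RankSumResult:
    """Two-sided rank-sum test with midranks for ties.

    Exact enumeration when m*n <= 10,000 and the data are tie-free; otherwise
    the tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    method = "exact" if (a.size * b.size <= 10_000 and not has_ties) else "asymptotic"
    res = mannwhitneyu(a, b, alternative="two-sided", method=method,
                       use_continuity=True)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0
    return RankSumResult(statistic=w, u=float(res.statistic), p=float(res.pvalue),
                         method=method)


# ---------------------------------------------------------------------------
# response assembly and residual check
# ---------------------------------------------------------------------------

def _naive_day(s: pd.Series) -> pd.Series:
    """Calendar day as a timezone-naive instant (UTC for tz-aware input)."""
    s = pd.to_datetime(s)
    if s.dt.tz is not None:
        s = s.dt.tz_convert("UTC").dt.tz_localize(None)
    return s.dt.normalize()


def join_attendance(decoded: pd.DataFrame, attendance: pd.DataFrame) -> pd.DataFrame:
    """Attach the daily maternal-presence record to hourly decoded states.

    Attendance is daily, states hourly: every step on a calendar day inherits
    that day's value.  Predictor convention: 0 = mother present ashore,
    1 = absent at sea.  Rows without an attendance record are dropped.
    """
    d = decoded[decoded.observed].copy()
    d["date"] = _naive_day(d.timestamp)
    att = attendance.copy()
    att["date"] = _naive_day(att.date)
    merged = d.merge(att[["id", "date", "mother_present"]], on=["id", "date"], how="inner")
    merged["mother_absent"] = 1 - merged.mother_present.astype(int)
    merged["active"] = (merged.state == 2).astype(int)
    return merged


def survival_frame(decoded: pd.DataFrame, metadata: pd.DataFrame) -> pd.DataFrame:
    """Decoded observations with the pup's fate (0 = died, 1 = survived)."""
    d = decoded[decoded.observed].copy()
    fate = metadata.set_index("id").fate
    d["survived"] = d.id.map(lambda i: int(fate.loc[i] == "survived"))
    d["active"] = (d.state == 2).astype(int)
    return d


def dispersion_check(result: GlmmResult, y, x, groups, n_sims: int = 500,
                     seed: int | None = None) -> dict:
    """Pearson-residual dispersion ratio against a parametric simulation envelope.

    Fitted probabilities use each group's empirical-Bayes modal intercept;
    simulated datasets redraw intercepts and responses from the fitted model
    and recompute the ratio, giving a 95% envelope.  This is a lightweight
    dispersion diagnostic, not a full simulated-residual suite.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    groups = np.asarray(groups)
    n, s, G = _group_stats(y, x, groups)
    eta0, eta1 = result.intercept, result.intercept + result.slope

    def ratio(n_, s_):
        bhat, _ = _group_modes(eta0, eta1, n_, s_, max(result.re_sd, 1e-6))
        p = expit(np.array([eta0, eta1])[None, :] + bhat)  # (G, 2)
        with np.errstate(invalid="ignore", divide="ignore"):
            pear = (s_ - n_ * p) ** 2 / (n_ * p * (1 - p))
        df = n_.sum() - 3
        return np.nansum(np.where(n_ > 0, pear, 0.0)) / df

    observed = ratio(n, s)
    rng = np.random.default_rng(seed)
    sims = np.empty(n_sims)
    for i in range(n_sims):
        b = rng.normal(0.0, result.re_sd, (G, 1))
        p = expit(np.array([eta0, eta1])[None, :] + b)
        s_sim = rng.binomial(n.astype(int), p).astype(float)
        sims[i] = ratio(n, s_sim)
    lo, hi = np.percentile(sims, [2.5, 97.5])
    return {"dispersion": float(observed), "envelope": (float(lo), float(hi)),
            "within_envelope": bool(lo <= observed <= hi)}
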