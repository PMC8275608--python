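"""Shared fixtures and independent brute-force oracles.

The oracles enumerate state paths explicitly and are deliberately written
against the raw formulas (logistic link, gamma density, stationary initial
law) rather than any package recursion, so they stay independent of the code
paths they check.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

from pupmove.design import Term
from pupmove.hmm import HMMSpec


def gamma_pdf(x, mu, sigma):
    return gamma_dist.pdf(x, a=mu**2 / sigma**2, scale=sigma**2 / mu)


def path_logprob(path, steps, X, mu, sigma, beta):
    """Joint log-probability of one 0/1 state path (origin-row transitions)."""
    g12 = expit(X @ beta[0])
    g21 = expit(X @ beta[1])
    pi0 = np.array([g21[0], g12[0]]) / (g12[0] + g21[0])
    lp = np.log(pi0[path[0]])
    for t in range(1, len(path)):
        G = np.array([[1 - g12[t - 1], g12[t - 1]], [g21[t - 1], 1 - g21[t - 1]]])
        lp += np.log(G[path[t - 1], path[t]])
    for t, s in enumerate(path):
        if np.isfinite(steps[t]):  # missing steps contribute a unit emission
            lp += np.log(gamma_pdf(steps[t], mu[s], sigma[s]))
    return lp


def brute_force_loglik(steps, X, mu, sigma, beta):
    """log sum over all 2^T paths of path probability x emission product."""
    T = len(steps)
    total = -np.inf
    for path in itertools.product([0, 1], repeat=T):
        total = np.logaddexp(total, path_logprob(path, steps, X, mu, sigma, beta))
    return total


def brute_force_viterbi(steps, X, mu, sigma, beta):
    """Exhaustive argmax path (1/2 labels); ties go to the lexically smaller path."""
    T = len(steps)
    best, best_lp = None, -np.inf
    for path in itertools.product([0, 1], repeat=T):
        lp = path_logprob(path, steps, X, mu, sigma, beta)
        if lp > best_lp:
            best, best_lp = path, lp
    return np.asarray(best) + 1, best_lp


def make_burst_frame(steps, covariates=None, pup="a", burst=1):
    """Long-format burst table around a given step series."""
    T = len(steps)
    df = pd.DataFrame({"id": pup, "burst": burst, "step_m": np.asarray(steps, float)})
    df["colony"] = 0.0
    df["age"] = np.linspace(-1, 1, T)
    df["hour"] = np.arange(T) % 24.0
    if covariates:
        for k, v in covariates.items():
            df[k] = v
    return df


@pytest.fixture
def tiny_spec():
    return HMMSpec([Term("colony"), Term("age"), Term("hour")])


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
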