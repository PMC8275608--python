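"""Viterbi decoding, occupancy, pseudo-residuals, marginal fit."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import gamma as gamma_dist
from scipy.stats import norm

from pupmove.decoding import (decode_table, marginal_fit, occupancy_curve,
                              occupancy_fraction, pseudo_residuals,
                              residual_diagnostics, viterbi, viterbi_path_logprob)
from pupmove.hmm import HMMFit, HMMSpec, pack_theta, stack_bursts
from pupmove.design import Term

from conftest import brute_force_viterbi, make_burst_frame


def fit_from_truth(spec, stack, mu, sigma, beta):
    theta = pack_theta(mu, sigma, beta)
    return HMMFit(spec=spec, theta=theta, mu=np.asarray(mu, float),
                  sigma=np.asarray(sigma, float), beta=np.asarray(beta, float),
                  loglik=0.0, aic=0.0, n_params=theta.size, n_obs=stack.n_obs,
                  covariance=None, covariance_ok=False,
                  design_signature=stack.info.signature(), data_fingerprint="t")


@pytest.fixture
def small_model(tiny_spec, rng):
    steps = rng.gamma(2.0, 12.0, 9)
    df = make_burst_frame(steps)
    stack = stack_bursts(df, tiny_spec)
    mu = np.array([10.0, 40.0])
    sigma = np.array([8.0, 30.0])
    beta = rng.normal(0, 0.6, (2, stack.X.shape[2]))
    return df, stack, mu, sigma, beta


class TestViterbi:
    def test_matches_exhaustive_argmax(self, tiny_spec, small_model):
        df, stack, mu, sigma, beta = small_model
        f = fit_from_truth(tiny_spec, stack, mu, sigma, beta)
        path = viterbi(f, stack)[0]
        oracle_path, oracle_lp = brute_force_viterbi(stack.steps[0], stack.X[0],
                                                     mu, sigma, beta)
        assert np.array_equal(path, oracle_path)
        assert viterbi_path_logprob(f, stack, [path]) == pytest.approx(oracle_lp, abs=1e-10)

    def test_matches_exhaustive_with_missing(self, tiny_spec, small_model, rng):
        df, _, mu, sigma, beta = small_model
        df = df.copy()
        df.loc[3, "step_m"] = np.nan
        stack = stack_bursts(df, tiny_spec)
        f = fit_from_truth(tiny_spec, stack, mu, sigma, beta)
        path = viterbi(f, stack)[0]
        oracle_path, _ = brute_force_viterbi(stack.steps[0], stack.X[0], mu, sigma, beta)
        assert np.array_equal(path, oracle_path)

    def test_dominant_emissions_all_state_one(self, tiny_spec, rng):
        steps = np.full(12, 5.0) + rng.normal(0, 0.1, 12)
        df = make_burst_frame(steps)
        stack = stack_bursts(df, tiny_spec)
        f = fit_from_truth(tiny_spec, stack, [5.0, 500.0], [1.0, 50.0],
                           np.zeros((2, stack.X.shape[2])))
        assert np.all(viterbi(f, stack)[0] == 1)

    def test_optimality_beats_true_path(self, tiny_spec, rng):
        # decoded path log-probability >= any other path's, incl. the truth
        from pupmove.design import build_design
        from pupmove.simulate import simulate_state_sequence, simulate_steps
        df = make_burst_frame(np.ones(200))
        X, _ = build_design(df, tiny_spec.terms, tiny_spec.harmonics)
        beta = rng.normal(0, 0.4, (2, X.shape[1]))
        states = simulate_state_sequence(beta, X, rng=rng)
        df["step_m"] = simulate_steps(states, (22.5, 75.8), (22.5, 75.8), rng)
        stack = stack_bursts(df, tiny_spec)
        f = fit_from_truth(tiny_spec, stack, [22.5, 75.8], [22.5, 75.8], beta)
        decoded = viterbi(f, stack)
        assert viterbi_path_logprob(f, stack, decoded) >= \
            viterbi_path_logprob(f, stack, [states]) - 1e-9

    def test_signature_mismatch_rejected(self, tiny_spec, small_model):
        df, stack, mu, sigma, beta = small_model
        other = HMMSpec([Term("colony"), Term("age")])
        stack2 = stack_bursts(df, other)
        f = fit_from_truth(tiny_spec, stack, mu, sigma, beta)
        with pytest.raises(ValueError, match="signature"):
            viterbi(f, stack2)


class TestOccupancyFraction:
    def _decoded(self, states_by_pup):
        rows = []
        for pid, s in states_by_pup.items():
            rows.append(pd.DataFrame({"id": pid, "state": s, "observed": True}))
        return pd.concat(rows, ignore_index=True)

    def test_all_active(self):
        out = occupancy_fraction(self._decoded({"a": [2, 2, 2]}))
        assert out["mean_active"] == 1.0

    def test_unweighted_mean_across_pups(self):
        d = self._decoded({"a": [1, 1, 1, 1, 2, 2, 2, 2, 2, 2],
                           "b": [1, 1, 1, 1, 1, 1, 2, 2, 2, 2]})
        out = occupancy_fraction(d)
        assert out["mean_inactive"] == pytest.approx(0.5)
        assert out["range_inactive"] == (0.4, 0.6)

    def test_pooled_variant(self):
        d = self._decoded({"a": [2] * 9, "b": [1]})
        assert occupancy_fraction(d, pooled=True)["mean_inactive"] == pytest.approx(0.1)
        assert occupancy_fraction(d)["mean_inactive"] == pytest.approx(0.5)


@pytest.fixture(scope="module")
def fitted():
    # cheap fit to exercise the curve machinery with a usable covariance
    from pupmove.harness import make_recovery_dataset
    from pupmove.hmm import fit
    data = make_recovery_dataset(n_pups=6, T=240, seed=5)
    return fit(data["spec"], data["bursts"], n_restarts=2, seed=8)


class TestOccupancyCurve:
    def test_null_covariate_flat_curve(self, tiny_spec, small_model):
        df, stack, mu, sigma, beta = small_model
        beta = beta.copy()
        cols = stack.info.columns
        for j, c in enumerate(cols):
            if "age" in c:
                beta[:, j] = 0.0
        f = fit_from_truth(tiny_spec, stack, mu, sigma, beta)
        curve = occupancy_curve(f, "age", np.linspace(-2, 2, 9))
        assert np.ptp(curve.point) < 1e-12
        assert not curve.has_band()

    def test_single_harmonic_single_peak(self, fitted):
        grid = np.linspace(0.0, 24.0, 241)
        curve = occupancy_curve(fitted, "hour", grid, n_draws=200, seed=0)
        interior = curve.point[1:-1]
        n_peaks = int(np.sum((interior > curve.point[:-2]) & (interior >= curve.point[2:])))
        assert n_peaks == 1
        assert np.all(curve.lower <= curve.point + 1e-12)
        assert np.all(curve.point <= curve.upper + 1e-12)

    def test_band_width_stabilises_with_draws(self, fitted):
        grid = np.array([0.0])
        w = {}
        for n in (1000, 10_000):
            c = occupancy_curve(fitted, "age", grid, n_draws=n, seed=42)
            w[n] = float(c.upper[0] - c.lower[0])
        assert abs(w[10_000] - w[1000]) / w[10_000] < 0.10

    def test_colony_stratified_levels_differ(self, fitted):
        g = np.linspace(-2, 2, 5)
        c0 = occupancy_curve(fitted, "age", g, n_draws=0, seed=0, colony_level=0.0)
        c1 = occupancy_curve(fitted, "age", g, n_draws=0, seed=0, colony_level=1.0)
        assert c0.colony_level != c1.colony_level
        assert c0.point.shape == c1.point.shape


class TestPseudoResiduals:
    def test_degenerate_single_state_is_probit_gamma(self, tiny_spec, rng):
        steps = rng.gamma(2.0, 10.0, 30)
        df = make_burst_frame(steps)
        stack = stack_bursts(df, tiny_spec)
        mu, sigma = np.array([20.0, 20.0]), np.array([14.0, 14.0])
        f = fit_from_truth(tiny_spec, stack, mu, sigma,
                           rng.normal(0, 0.3, (2, stack.X.shape[2])))
        z = pseudo_residuals(f, stack)[0]
        expected = norm.ppf(gamma_dist.cdf(stack.steps[0], a=(20.0 / 14.0) ** 2,
                                           scale=14.0**2 / 20.0))
        assert np.allclose(z, expected, atol=1e-10)

    def test_missing_steps_give_missing_residuals(self, tiny_spec, rng):
        steps = rng.gamma(2.0, 10.0, 20)
        steps[[4, 11]] = np.nan
        df = make_burst_frame(steps)
        stack = stack_bursts(df, tiny_spec)
        f = fit_from_truth(tiny_spec, stack, [10.0, 40.0], [8.0, 30.0],
                           rng.normal(0, 0.3, (2, stack.X.shape[2])))
        z = pseudo_residuals(f, stack)[0]
        assert np.isnan(z[[4, 11]]).all()
        assert np.isfinite(np.delete(z, [4, 11])).all()

    def test_calibrated_under_generating_model(self):
        from pupmove.harness import make_recovery_dataset
        data = make_recovery_dataset(n_pups=6, T=720, seed=77)
        stack = stack_bursts(data["bursts"], data["spec"])
        f = fit_from_truth(data["spec"], stack, data["mu"], data["sigma"], data["beta"])
        diag = residual_diagnostics(pseudo_residuals(f, stack))
        se = np.sqrt(0.05 * 0.95 / diag["n"])
        assert abs(diag["tail_fraction"] - 0.05) < 3 * se


class TestMarginalFit:
    def test_self_consistency_small_tv(self):
        from pupmove.harness import make_recovery_dataset
        data = make_recovery_dataset(n_pups=8, T=720, seed=3)
        stack = stack_bursts(data["bursts"], data["spec"])
        f = fit_from_truth(data["spec"], stack, data["mu"], data["sigma"], data["beta"])
        out = marginal_fit(f, stack)
        assert out["tv_distance"] < 0.05

    def test_coincident_states_collapse_to_component(self, tiny_spec, rng):
        steps = rng.gamma(2.0, 10.0, 100)
        stack = stack_bursts(make_burst_frame(steps), tiny_spec)
        f = fit_from_truth(tiny_spec, stack, [20.0, 20.0], [14.0, 14.0],
                           np.zeros((2, stack.X.shape[2])))
        out = marginal_fit(f, stack, n_bins=20)
        comp = gamma_dist.cdf(out["edges"][1:], a=(20 / 14) ** 2, scale=14**2 / 20) \
            - gamma_dist.cdf(out["edges"][:-1], a=(20 / 14) ** 2, scale=14**2 / 20)
        assert np.allclose(out["model"], comp / comp.sum(), atol=1e-12)

    def test_probabilities_normalised(self, tiny_spec, rng):
        steps = rng.gamma(2.0, 10.0, 200)
        stack = stack_bursts(make_burst_frame(steps), tiny_spec)
        f = fit_from_truth(tiny_spec, stack, [10.0, 40.0], [8.0, 30.0],
                           rng.normal(0, 0.3, (2, stack.X.shape[2])))
        out = marginal_fit(f, stack)
        assert out["empirical"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out["model"].sum() == pytest.approx(1.0, abs=1e-9)
        assert out["edges"][0] == 0.0


def test_decode_table_alignment(tiny_spec, rng):
    frames = [make_burst_frame(rng.gamma(2, 12, 30), pup=p) for p in "ab"]
    df = pd.concat(frames, ignore_index=True)
    from pupmove.hmm import fit
    f = fit(tiny_spec, df, n_restarts=1, seed=0, compute_covariance=False)
    out = decode_table(f, df)
    assert len(out) == len(df)
    assert set(out.state.unique()) <= {1, 2}
    assert out.observed.all()
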