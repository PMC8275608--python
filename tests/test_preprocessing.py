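"""Track regularisation, steps, censoring, bursts, SMI, covariates."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pupmove.preprocessing import (build_covariates, censor_steps, compute_steps,
                                   displacement_summaries, haversine_m,
                                   interpolate_weather, preprocess, regularize,
                                   scaled_mass_index, split_and_filter_bursts)


def fixes_frame(times, lats=None, lons=None, pup="a"):
    n = len(times)
    return pd.DataFrame({"id": pup, "timestamp": pd.to_datetime(times, utc=True),
                         "lat": -54.0 + np.zeros(n) if lats is None else lats,
                         "lon": -38.0 + np.zeros(n) if lons is None else lons})


class TestRegularize:
    def test_missing_hour_marked(self):
        t = ["2019-01-01 00:00", "2019-01-01 01:00", "2019-01-01 03:00"]
        g = regularize(fixes_frame(t))
        assert len(g) == 4
        assert list(g.observed) == [True, True, False, True]

    def test_jittered_fixes_snap_to_adjacent_hours(self):
        t = ["2019-01-01 00:02", "2019-01-01 00:58"]
        g = regularize(fixes_frame(t))
        assert list(g.timestamp.dt.strftime("%H:%M")) == ["00:00", "01:00"]
        assert g.observed.all()

    def test_contending_fixes_keep_nearest(self):
        t = ["2019-01-01 00:05", "2019-01-01 00:20", "2019-01-01 01:00"]
        with pytest.warns(UserWarning, match="contend"):
            g = regularize(fixes_frame(t, lats=np.array([-54.0, -54.5, -54.0])))
        assert len(g) == 2
        assert g.lat.iloc[0] == -54.0  # the :05 fix is nearer to 00:00 than :20

    def test_empty_input(self):
        assert len(regularize(fixes_frame([]))) == 0

    def test_idempotent_on_own_output(self):
        t = ["2019-01-01 00:00", "2019-01-01 02:00", "2019-01-01 03:00"]
        g1 = regularize(fixes_frame(t))
        obs = g1[g1.observed][["id", "timestamp", "lat", "lon"]]
        g2 = regularize(obs)
        pd.testing.assert_frame_equal(g1.reset_index(drop=True), g2)


class TestComputeSteps:
    def test_identical_fixes_zero(self):
        g = regularize(fixes_frame(["2019-01-01 00:00", "2019-01-01 01:00"]))
        assert compute_steps(g)[0] == pytest.approx(0.0)

    def test_latitude_millidegree(self):
        # 0.001 deg of latitude = R * dphi = 111.195 m on the mean sphere
        g = regularize(fixes_frame(["2019-01-01 00:00", "2019-01-01 01:00"],
                                   lats=np.array([-54.0, -53.999])))
        assert compute_steps(g)[0] == pytest.approx(111.195, abs=0.01)

    def test_missing_fix_propagates_to_both_steps(self):
        t = ["2019-01-01 00:00", "2019-01-01 02:00"]
        g = regularize(fixes_frame(t))
        steps = compute_steps(g)
        assert np.isnan(steps).all() and len(steps) == 2

    def test_haversine_symmetry(self):
        a = haversine_m(-54.0, -38.0, -54.01, -38.02)
        b = haversine_m(-54.01, -38.02, -54.0, -38.0)
        assert a == pytest.approx(b, rel=1e-12)


class TestCensorSteps:
    def test_threshold_application(self):
        out, n = censor_steps(np.array([100.0, 450.0, 399.0]))
        assert np.isnan(out[1]) and out[0] == 100.0 and out[2] == 399.0
        assert n == 1

    def test_identity_below_threshold(self):
        steps = np.array([0.0, 399.9, 400.0])
        out, n = censor_steps(steps)
        assert n == 0 and np.allclose(out, steps)

    def test_interval_scaling(self):
        # 5-minute data: the 400 m/h screen becomes 400/12 m per step
        out, n = censor_steps(np.array([30.0, 35.0]), interval=5)
        assert n == 1 and np.isnan(out[1]) and out[0] == 30.0

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2**31 - 1))
    def test_idempotent(self, seed):
        steps = np.random.default_rng(seed).gamma(1.0, 150.0, 200)
        once, n1 = censor_steps(steps)
        twice, n2 = censor_steps(once)
        assert n2 == 0
        assert np.array_equal(once, twice, equal_nan=True)


class TestBurstSplitting:
    def _track(self, hours_observed, start="2019-01-01"):
        t0 = pd.Timestamp(start, tz="UTC")
        times = [t0 + pd.Timedelta(hours=h) for h in hours_observed]
        return regularize(fixes_frame(times))

    def test_long_gap_splits(self):
        # 5-day track with a 6-h gap on day 2 -> 2 bursts
        hours = list(range(0, 50)) + list(range(56, 120))
        g = self._track(hours)
        bursts, acc = split_and_filter_bursts(g, np.full(len(g) - 1, 1.0))
        assert len(bursts) == 2
        assert [b.burst_index for b in bursts] == [1, 2]
        assert acc["kept"] + acc["dropped"] + acc["gap"] == acc["n_intervals"]

    def test_short_gap_retained_as_missing(self):
        hours = list(range(0, 48)) + list(range(51, 120))
        g = self._track(hours)
        bursts, _ = split_and_filter_bursts(g, np.full(len(g) - 1, 1.0))
        assert len(bursts) == 1
        assert not bursts[0].grid.observed.all()

    def test_exactly_four_hour_gap_not_split(self):
        hours = list(range(0, 50)) + list(range(54, 110))
        bursts, _ = split_and_filter_bursts(self._track(hours), np.full(109, 1.0))
        assert len(bursts) == 1

    def test_short_fragment_dropped(self):
        hours = list(range(0, 40)) + list(range(50, 120))
        g = self._track(hours)
        bursts, acc = split_and_filter_bursts(g, np.full(len(g) - 1, 1.0))
        assert len(bursts) == 1                     # the 40-h fragment is gone
        assert bursts[0].grid.timestamp.iloc[0].hour == 50 % 24
        assert acc["dropped"] == 39

    def test_span_is_first_to_last_instant(self):
        # 48 h span with interior missing rows still qualifies
        hours = [0, 1, 2] + list(range(5, 49))
        bursts, _ = split_and_filter_bursts(self._track(hours), np.full(48, 1.0))
        assert len(bursts) == 1


class TestWeatherInterpolation:
    def _series(self, vals):
        ts = pd.date_range("2019-01-01", periods=len(vals), freq="1h", tz="UTC")
        return pd.DataFrame({"timestamp": ts, "temp_c": vals,
                             "wind_speed": np.ones(len(vals))})

    def test_midpoint(self):
        out = interpolate_weather(self._series([1.0, np.nan, 3.0]))
        assert out.temp_c.tolist() == [1.0, 2.0, 3.0]

    def test_identity_when_complete(self):
        src = self._series([1.0, 2.0, 3.0])
        pd.testing.assert_frame_equal(interpolate_weather(src), src)

    def test_edges_filled_nearest(self):
        out = interpolate_weather(self._series([np.nan, 5.0, np.nan]))
        assert out.temp_c.tolist() == [5.0, 5.0, 5.0]

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            interpolate_weather(self._series([np.nan, np.nan]))


class TestScaledMassIndex:
    def test_reference_length_gives_mass(self):
        pop = pd.DataFrame({"mass_kg": [4.0, 5.0, 6.0], "length_cm": [55.0, 60.0, 65.0]})
        res = scaled_mass_index(pop)
        ind = pd.DataFrame({"mass_kg": [5.5], "length_cm": [res.l0]})
        out = scaled_mass_index(pop, ind)
        assert out.smi.iloc[0] == pytest.approx(5.5, abs=1e-12)

    def test_collinear_population_recovers_exponent(self):
        length = np.array([50.0, 55.0, 60.0, 65.0, 70.0])
        pop = pd.DataFrame({"mass_kg": 0.002 * length**2, "length_cm": length})
        res = scaled_mass_index(pop)
        assert res.b_sma == pytest.approx(2.0, abs=1e-10)

    def test_five_row_oracle(self):
        # independent arithmetic: OLS slope and Pearson r computed explicitly
        pop = pd.DataFrame({"mass_kg": [4.2, 5.1, 4.8, 6.3, 5.9],
                            "length_cm": [55.0, 61.0, 58.0, 67.0, 64.0]})
        ln_l, ln_m = np.log(pop.length_cm), np.log(pop.mass_kg)
        xc, yc = ln_l - ln_l.mean(), ln_m - ln_m.mean()
        slope = (xc * yc).sum() / (xc * xc).sum()
        r = (xc * yc).sum() / np.sqrt((xc * xc).sum() * (yc * yc).sum())
        b_sma = slope / r
        l0 = pop.length_cm.mean()
        expected = pop.mass_kg * (l0 / pop.length_cm) ** b_sma
        res = scaled_mass_index(pop)
        assert res.b_sma == pytest.approx(b_sma, abs=1e-12)
        assert np.allclose(res.smi, expected, atol=1e-12)

    def test_zero_length_variance_rejected(self):
        pop = pd.DataFrame({"mass_kg": [4.0, 5.0, 6.0], "length_cm": [60.0, 60.0, 60.0]})
        with pytest.raises(ValueError):
            scaled_mass_index(pop)


@pytest.fixture(scope="module")
def cohort():
    from pupmove.simulate import SimConfig, simulate_dataset
    cfg = SimConfig(n_individuals=2, seed=42)
    ds = simulate_dataset(cfg)
    res = preprocess(ds["fixes"], ds["weather"], ds["metadata"], ds["biometrics"])
    return cfg, ds, res


class TestPipeline:
    def test_reconciliation_balances(self, cohort):
        _, _, res = cohort
        rep = res["report"]
        assert rep["intervals_balanced"]
        assert rep["intervals"]["kept"] == rep["n_step_rows"]

    def test_standardised_columns(self, cohort):
        _, _, res = cohort
        b = res["bursts"]
        for c in ("age", "condition", "temp", "wind"):
            assert b[c].mean() == pytest.approx(0.0, abs=1e-10)
            assert b[c].std(ddof=0) == pytest.approx(1.0, abs=1e-10)

    def test_condition_uses_most_recent_measurement(self, cohort):
        _, _, res = cohort
        b = res["bursts"]
        # condition is piecewise constant: within any 10-day window a pup has one value
        one = b[b.id == b.id.iloc[0]]
        window = one[(one.age_raw >= 0) & (one.age_raw < 10)]
        assert window.condition_raw.nunique() == 1

    def test_binary_codings(self, cohort):
        cfg, ds, res = cohort
        b = res["bursts"]
        assert set(np.unique(b.sex)) <= {0.0, 1.0}
        meta = ds["metadata"].set_index("id")
        females = [i for i in b.id.unique() if meta.loc[i].sex == "F"]
        if females:
            assert (b[b.id.isin(females)].sex == 0.0).all()

    def test_missing_metadata_named_in_error(self, cohort):
        cfg, ds, res = cohort
        bad_meta = ds["metadata"][ds["metadata"].id != ds["metadata"].id.iloc[0]]
        with pytest.raises(KeyError, match=ds["metadata"].id.iloc[0]):
            preprocess(ds["fixes"], ds["weather"], bad_meta, ds["biometrics"])

    def test_rerun_on_scalers_is_stable(self, cohort):
        cfg, ds, res = cohort
        res2 = preprocess(ds["fixes"], ds["weather"], ds["metadata"], ds["biometrics"],
                          scalers=res["scalers"])
        pd.testing.assert_frame_equal(res["bursts"], res2["bursts"])


class TestDisplacement:
    def test_stationary_pup(self):
        t = pd.date_range("2019-01-01", periods=60, freq="1h", tz="UTC")
        fx = pd.DataFrame({"id": "a", "timestamp": t, "lat": -54.01, "lon": -38.055})
        g = regularize(fx)
        steps, _ = censor_steps(compute_steps(g))
        meta = pd.DataFrame({"id": ["a"], "sex": ["F"], "colony": ["FWB"], "year": [2019]})
        out = displacement_summaries(g, {"a": steps}, {"FWB": (-54.01, -38.055)}, meta)
        assert out["mean_step_m_overall"] == pytest.approx(0.0)
        assert out["mean_displacement_by_colony"]["FWB"] == pytest.approx(0.0)

    def test_unknown_colony_rejected(self):
        t = pd.date_range("2019-01-01", periods=3, freq="1h", tz="UTC")
        fx = pd.DataFrame({"id": "a", "timestamp": t, "lat": -54.0, "lon": -38.0})
        g = regularize(fx)
        meta = pd.DataFrame({"id": ["a"], "sex": ["F"], "colony": ["XXX"], "year": [2019]})
        with pytest.raises(KeyError):
            displacement_summaries(g, {"a": np.ones(2)}, {"FWB": (0, 0)}, meta)
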