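"""Synthetic central-place-explorer track generator with known ground truth.

Emulates the structure of hourly GPS deployments on fur seal pups at two
breeding colonies over two seasons: a two-state Markov switching process with
gamma step lengths, covariate-dependent transition logits (shared with the
fitting module, so generator truth and estimator target coincide), star-shaped
excursions around a per-pup home patch, staggered births, early mortality,
alternating maternal attendance bouts, missing fixes and implausible-speed
outliers.

Movement geometry: step lengths are drawn from the state-conditional gamma
distributions.  Inactive headings are isotropic; active headings persist
(previous heading plus small angular noise) blended with a home-attraction
component whose weight grows with distance from the home patch, so excursions
return and the step-length marginals remain exactly gamma.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pupmove.design import Term, build_design
from pupmove.hmm import stationary_distribution, transition_matrix

EARTH_RADIUS_M = 6_371_000.0

#: default transition formula of the generating model (matches the full
#: analysis model: every non-colony term interacts with colony)
DEFAULT_TERMS = [
    Term("colony"),
    Term("year"),
    Term("sex"),
    Term("age"),
    Term("condition"),
    Term("temp"),
    Term("wind"),
    Term("hour"),
]

#: standardisation constants used to place the generating coefficients on the
#: same scale the preprocessing applies to real data (mean, sd)
DEFAULT_SCALERS = {
    "age": (25.0, 15.0),
    "condition": (9.0, 2.0),
    "temp": (3.8, 1.35),
    "wind": (6.0, 3.0),
}


def default_beta(columns: list[str]) -> np.ndarray:
    """Generating coefficients for the two transition logits.

    Chosen to reproduce the qualitative study findings: roughly two thirds of
    time inactive, a midday activity peak, an age-driven activity increase at
    the reference (low-density) colony that is absent at the other colony, a
    weaker second season, and null sex/condition/temperature/wind effects.
    """
    coef_12 = {
        "intercept": -2.0, "year": -0.4, "age": 0.35, "hour_cos1": -0.6,
        "year:colony": 0.3, "age:colony": -0.35,
    }
    coef_21 = {
        "intercept": -1.0, "age": -0.15, "hour_cos1": 0.3, "age:colony": 0.15,
    }
    beta = np.zeros((2, len(columns)))
    for j, c in enumerate(columns):
        beta[0, j] = coef_12.get(c, 0.0)
        beta[1, j] = coef_21.get(c, 0.0)
    return beta


@dataclass
class SimConfig:
    """Study-design parameters of the synthetic cohort.

    ``n_individuals`` is per colony per season.  Defaults mirror the study
    conditions: hourly sampling, deployments of 20-80 days, state mean step
    lengths 22.5 m and 75.8 m, seasonal temperature means 3.7/3.9 deg C with
    sd 1.3/1.4, ~20% early mortality.
    """

    n_individuals: int = 16
    colony_labels: tuple[str, str] = ("FWB", "SSB")   # first = reference
    season_labels: tuple[int, int] = (2019, 2020)     # first = reference
    sampling_interval: int = 60                        # minutes
    duration_days: tuple[int, int] = (20, 80)
    home_patch: dict = field(default_factory=lambda: {
        "FWB": (-54.010, -38.055), "SSB": (-54.0085, -38.049)})
    #: per-colony scatter of pup home patches around the colony reference (m);
    #: larger at the high-density colony, where suckling locations spread wider
    home_jitter_m: dict = field(default_factory=lambda: {"FWB": 60.0, "SSB": 160.0})
    emission_mu: tuple[float, float] = (22.5, 75.8)
    emission_sigma: tuple[float, float] = (22.5, 75.8)
    terms: list = field(default_factory=lambda: list(DEFAULT_TERMS))
    harmonics: int = 1
    beta: np.ndarray | None = None                     # truth coefficients
    scalers: dict = field(default_factory=lambda: dict(DEFAULT_SCALERS))
    temp_by_season: dict = field(default_factory=lambda: {
        2019: (3.7, 1.3), 2020: (3.9, 1.4)})
    wind_mean: float = 6.0
    wind_sd: float = 3.0
    missing_rate: float = 0.02
    outlier_rate: float = 0.004
    #: expected number of multi-hour signal-lapse gaps per tracking day; each
    #: gap removes a consecutive run of 5-12 fixes, long enough to split bursts
    gap_rate_per_day: float = 0.02
    mortality_rate: float = 0.2
    mortality_day_range: tuple[int, int] = (4, 41)
    attendance_ashore_mean: float = 2.0                # days
    attendance_atsea_mean: float = 5.0
    heading_sd: float = 0.45                           # rad, active persistence noise
    attraction_scale_m: float = 300.0                  # home pull saturates here
    seed: int = 0

    def __post_init__(self):
        mu, sd = np.asarray(self.emission_mu), np.asarray(self.emission_sigma)
        if np.any(mu <= 0) or np.any(sd <= 0):
            raise ValueError("gamma means/sds must be strictly positive")
        if not mu[1] > mu[0]:
            raise ValueError("active-state mean must exceed inactive-state mean")
        for r in (self.missing_rate, self.outlier_rate, self.mortality_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if (24 * 60) % self.sampling_interval != 0:
            raise ValueError("sampling_interval must divide 24 h")

    @property
    def n_pups(self) -> int:
        return self.n_individuals * len(self.colony_labels) * len(self.season_labels)

    def design_columns(self) -> list[str]:
        probe = pd.DataFrame({t.name: [0.0] for t in self.terms} | {"hour": [0.0]})
        _, info = build_design(probe, self.terms, self.harmonics)
        return info.columns

    def truth_beta(self) -> np.ndarray:
        if self.beta is not None:
            return np.asarray(self.beta, dtype=float)
        return default_beta(self.design_columns())


@dataclass
class SimTruth:
    """Ground truth of one simulated cohort."""

    config: SimConfig
    beta: np.ndarray
    states: dict = field(default_factory=dict)         # id -> int array (1/2)
    home: dict = field(default_factory=dict)           # id -> (lat, lon)
    fate: dict = field(default_factory=dict)           # id -> "survived"/"died"
    death_day: dict = field(default_factory=dict)
    degraded: dict = field(default_factory=dict)       # id -> {"missing": [...], "outliers": [...]}


def _rng(config: SimConfig, *key) -> np.random.Generator:
    # zlib.crc32 is a stable hash (builtin hash() is salted per process)
    parts = [config.seed % (2**31)] + [zlib.crc32(repr(k).encode()) for k in key]
    return np.random.default_rng(parts)


# ---------------------------------------------------------------------------
# roster, weather, covariates
# ---------------------------------------------------------------------------

def pup_roster(config: SimConfig) -> pd.DataFrame:
    """Individual metadata: id, sex, colony, year, birth/capture dates, fate."""
    rng = _rng(config, "roster")
    rows = []
    idx = 0
    for year in config.season_labels:
        for colony in config.colony_labels:
            for _ in range(config.n_individuals):
                pid = f"pup{idx:03d}"
                birth = pd.Timestamp(f"{year - 1}-12-01", tz="UTC") + pd.Timedelta(
                    days=int(rng.integers(0, 21)))
                capture = birth + pd.Timedelta(days=2)
                duration = int(rng.integers(config.duration_days[0], config.duration_days[1] + 1))
                died = bool(rng.random() < config.mortality_rate)
                lo, hi = config.mortality_day_range
                death_day = int(np.clip(np.round(rng.lognormal(np.log(15.0), 0.5)), lo, hi)) if died else None
                if died and death_day is not None:
                    duration = min(duration, death_day)
                lat0, lon0 = config.home_patch[colony]
                jit = config.home_jitter_m
                jit = jit[colony] if isinstance(jit, dict) else float(jit)
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, jit)
                home_lat = lat0 + (rad * np.sin(ang)) / EARTH_RADIUS_M * (180 / np.pi)
                home_lon = lon0 + (rad * np.cos(ang)) / (
                    EARTH_RADIUS_M * np.cos(np.deg2rad(lat0))) * (180 / np.pi)
                rows.append(dict(id=pid, sex=("F" if rng.random() < 0.5 else "M"),
                                 colony=colony, year=year, birth_date=birth,
                                 capture_date=capture, duration_days=duration,
                                 fate=("died" if died else "survived"),
                                 death_date=(capture + pd.Timedelta(days=death_day)) if died else pd.NaT,
                                 home_lat=home_lat, home_lon=home_lon))
                idx += 1
    return pd.DataFrame(rows)


def simulate_weather(config: SimConfig, year: int) -> pd.DataFrame:
    """Hourly island weather for one season (Dec 1 to Mar 31), AR(1) smooth."""
    rng = _rng(config, "weather", year)
    start = pd.Timestamp(f"{year - 1}-12-01", tz="UTC")
    end = pd.Timestamp(f"{year}-03-31 23:00", tz="UTC")
    ts = pd.date_range(start, end, freq="1h")
    n = len(ts)
    m, sd = config.temp_by_season[year]
    phi = 0.97
    innov_sd = sd * np.sqrt(1 - phi**2)
    temp = np.empty(n)
    temp[0] = m + rng.normal(0, sd)
    for t in range(1, n):
        temp[t] = m + phi * (temp[t - 1] - m) + rng.normal(0, innov_sd)
    wind = np.empty(n)
    wind[0] = config.wind_mean + rng.normal(0, config.wind_sd)
    innov_w = config.wind_sd * np.sqrt(1 - phi**2)
    for t in range(1, n):
        wind[t] = config.wind_mean + phi * (wind[t - 1] - config.wind_mean) + rng.normal(0, innov_w)
    wind = np.maximum(wind, 0.0)
    return pd.DataFrame({"timestamp": ts, "temp_c": temp, "wind_speed": wind})


def simulate_biometrics(config: SimConfig, roster: pd.DataFrame) -> pd.DataFrame:
    """Repeated mass/length every 10 days; ln-mass tracks 2 ln-length closely."""
    rng = _rng(config, "biometrics")
    rows = []
    for rec in roster.itertuples():
        l0 = rng.normal(62.0, 3.0)
        growth_l = rng.normal(0.25, 0.05)      # cm / day
        cond = rng.normal(0.0, 0.12)           # pup-level log condition offset
        for day in range(0, rec.duration_days + 1, 10):
            length = l0 + growth_l * day + rng.normal(0, 0.5)
            drift = cond + rng.normal(0, 0.05)
            mass = 1.45e-3 * length**2 * np.exp(drift)
            rows.append(dict(id=rec.id, date=(rec.capture_date + pd.Timedelta(days=day)).normalize(),
                             mass_kg=round(mass, 3), length_cm=round(length, 1)))
    return pd.DataFrame(rows)


def simulate_attendance(config: SimConfig, roster: pd.DataFrame) -> pd.DataFrame:
    """Daily maternal presence: alternating ashore / at-sea bouts."""
    rng = _rng(config, "attendance")
    rows = []
    for rec in roster.itertuples():
        day, present = 0, True
        while day <= rec.duration_days:
            mean = config.attendance_ashore_mean if present else config.attendance_atsea_mean
            bout = 1 + rng.poisson(max(mean - 1.0, 0.0))
            for d in range(day, min(day + bout, rec.duration_days + 1)):
                rows.append(dict(id=rec.id,
                                 date=(rec.capture_date + pd.Timedelta(days=d)).normalize(),
                                 mother_present=int(present)))
            day += bout
            present = not present
    return pd.DataFrame(rows)


def simulate_covariates(config: SimConfig, pup_index: int,
                        roster: pd.DataFrame | None = None,
                        weather: dict | None = None,
                        biometrics: pd.DataFrame | None = None) -> pd.DataFrame:
    """Hourly covariate grid over one pup's deployment.

    Columns: timestamp, hour, age (days since capture, constant within a day),
    condition (10-day piecewise-constant scaled mass), temp, wind (island
    series), sex / colony / year indicators (0 = reference).  Also carries the
    standardised versions (suffix ``_z``) using the config's scalers, which is
    the scale the generating coefficients live on.
    """
    roster = pup_roster(config) if roster is None else roster
    rec = roster.iloc[pup_index]
    if weather is None:
        weather = {y: simulate_weather(config, y) for y in config.season_labels}
    if biometrics is None:
        biometrics = simulate_biometrics(config, roster)

    step = pd.Timedelta(minutes=config.sampling_interval)
    ts = pd.date_range(rec.capture_date, rec.capture_date + pd.Timedelta(days=rec.duration_days),
                       freq=step, inclusive="left")
    df = pd.DataFrame({"timestamp": ts})
    df["hour"] = df.timestamp.dt.hour + df.timestamp.dt.minute / 60.0
    df["age"] = ((df.timestamp - rec.capture_date) / pd.Timedelta(days=1)).astype(int)

    w = weather[rec.year].set_index("timestamp")
    hourly = df.timestamp.dt.floor("1h")
    df["temp"] = w.temp_c.reindex(hourly).to_numpy()
    df["wind"] = w.wind_speed.reindex(hourly).to_numpy()

    bio = biometrics[biometrics.id == rec.id].sort_values("date")
    l0_pop = biometrics.length_cm.mean()
    smi = bio.mass_kg * (l0_pop / bio.length_cm) ** 2.0   # true exponent 2 by construction
    meas_day = ((bio.date - rec.capture_date.normalize()) / pd.Timedelta(days=1)).astype(int).to_numpy()
    idx = np.clip(np.searchsorted(meas_day, df.age.to_numpy(), side="right") - 1, 0, len(bio) - 1)
    df["condition"] = smi.to_numpy()[idx]

    df["sex"] = float(rec.sex == "M")
    df["colony"] = float(rec.colony != config.colony_labels[0])
    df["year"] = float(rec.year != config.season_labels[0])
    for name, (m, s) in config.scalers.items():
        df[name + "_z"] = (df[name] - m) / s
    return df


def standardized_view(cov: pd.DataFrame, scalers: dict) -> pd.DataFrame:
    """Covariate table with metric columns replaced by their standardised form."""
    out = cov.copy()
    for name in scalers:
        out[name] = out[name + "_z"]
    return out


# ---------------------------------------------------------------------------
# state sequence and positions
# ---------------------------------------------------------------------------

def simulate_state_sequence(beta: np.ndarray, design: np.ndarray,
                            seed=None, rng: np.random.Generator | None = None) -> np.ndarray:
    """Markov chain with time-varying 2x2 transition matrices.

    ``design`` is the (T, p) design matrix; the transition into step t is
    parametrised by row t-1 (origin convention).  The initial state is drawn
    from the stationary distribution at the first row.  Returns labels 1/2.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    X = np.asarray(design, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (2, X.shape[1]):
        raise ValueError(f"beta shape {beta.shape} incompatible with design width {X.shape[1]}")
    from scipy.special import expit
    eta = X @ beta.T
    g12, g21 = expit(eta[:, 0]), expit(eta[:, 1])
    T = X.shape[0]
    states = np.empty(T, dtype=int)
    pi0 = stationary_distribution(np.array([[1 - g12[0], g12[0]], [g21[0], 1 - g21[0]]]))
    u = rng.random(T)
    states[0] = 1 if u[0] < pi0[0] else 2
    for t in range(1, T):
        p_switch = g12[t - 1] if states[t - 1] == 1 else g21[t - 1]
        states[t] = (3 - states[t - 1]) if u[t] < p_switch else states[t - 1]
    return states


def simulate_steps(states: np.ndarray, emission_mu, emission_sigma,
                   rng: np.random.Generator) -> np.ndarray:
    """Gamma step lengths conditional on the state labels (1/2)."""
    mu = np.asarray(emission_mu, float)[states - 1]
    sd = np.asarray(emission_sigma, float)[states - 1]
    shape = mu**2 / sd**2
    scale = sd**2 / mu
    return rng.gamma(shape, scale)


def simulate_positions(states: np.ndarray, emission_mu, emission_sigma,
                       home_patch: tuple[float, float], seed=None,
                       rng: np.random.Generator | None = None,
                       heading_sd: float = 0.45,
                       attraction_scale_m: float = 300.0,
                       steps: np.ndarray | None = None) -> pd.DataFrame:
    """Lat/lon fixes realising the state sequence as central-place exploration.

    The track starts at the home patch.  Step t moves from fix t to fix t+1,
    so a T-step state sequence yields T+1 fixes.  Displacements in metres are
    inverted to degrees with the local-scale equirectangular approximation.
    """
    rng = np.random.default_rng(seed) if rng is None else rng
    states = np.asarray(states, dtype=int)
    T = states.size
    if steps is None:
        steps = simulate_steps(states, emission_mu, emission_sigma, rng)
    lat0, lon0 = home_patch
    x = np.zeros(T + 1)
    y = np.zeros(T + 1)
    heading = rng.uniform(0, 2 * np.pi)
    for t in range(T):
        if states[t] == 1:
            heading = rng.uniform(0, 2 * np.pi)
        else:
            persist = heading + rng.normal(0.0, heading_sd)
            dist = np.hypot(x[t], y[t])
            w = min(1.0, dist / attraction_scale_m)
            to_home = np.arctan2(-y[t], -x[t]) + rng.normal(0.0, 0.3)
            vx = (1 - w) * np.cos(persist) + w * np.cos(to_home)
            vy = (1 - w) * np.sin(persist) + w * np.sin(to_home)
            heading = np.arctan2(vy, vx)
        x[t + 1] = x[t] + steps[t] * np.cos(heading)
        y[t + 1] = y[t] + steps[t] * np.sin(heading)
    lat = lat0 + (y / EARTH_RADIUS_M) * (180.0 / np.pi)
    lon = lon0 + (x / (EARTH_RADIUS_M * np.cos(np.deg2rad(lat0)))) * (180.0 / np.pi)
    return pd.DataFrame({"lat": lat, "lon": lon})


def inject_missing_and_outliers(track: pd.DataFrame, missing_rate: float,
                                outlier_rate: float, seed=None,
                                rng: np.random.Generator | None = None,
                                displacement_m: tuple[float, float] = (1200.0, 2500.0)):
    """Degrade a fix table: delete fixes, displace others beyond plausibility.

    Displacing a fix (rather than editing a step) guarantees that the steps
    recomputed from the degraded geometry exceed the 400 m/h screen, so the
    censoring filter is exercised end-to-end.  Returns (degraded_track, truth)
    where truth records the 0-based row positions deleted and displaced.
    """
    if not (0 <= missing_rate <= 1 and 0 <= outlier_rate <= 1):
        raise ValueError("rates must be in [0, 1]")
    rng = np.random.default_rng(seed) if rng is None else rng
    n = len(track)
    keep = rng.random(n) >= missing_rate
    degraded = track.loc[keep].copy()
    surviving = np.flatnonzero(keep)
    out_mask = rng.random(len(degraded)) < outlier_rate
    # displaced fixes are kept >= 2 rows apart so the steps flanking each one
    # are anchored at true positions and must exceed the plausibility screen
    chosen = np.flatnonzero(out_mask)
    last = -10
    for i in chosen:
        if i - last < 2:
            out_mask[i] = False
        else:
            last = i
    lat = degraded["lat"].to_numpy().copy()
    lon = degraded["lon"].to_numpy().copy()
    for i in np.flatnonzero(out_mask):
        d = rng.uniform(*displacement_m)
        ang = rng.uniform(0, 2 * np.pi)
        lat[i] += (d * np.sin(ang) / EARTH_RADIUS_M) * (180.0 / np.pi)
        lon[i] += (d * np.cos(ang) / (EARTH_RADIUS_M * np.cos(np.deg2rad(lat[i])))) * (180.0 / np.pi)
    degraded["lat"] = lat
    degraded["lon"] = lon
    truth = {"missing": np.flatnonzero(~keep).tolist(),
             "outliers": surviving[out_mask].tolist()}
    return degraded.reset_index(drop=True), truth


def _inject_gaps(track: pd.DataFrame, gap_rate_per_day: float, duration_days: int,
                 rng: np.random.Generator):
    """Remove consecutive runs of fixes emulating multi-hour signal lapses."""
    n_gaps = rng.poisson(gap_rate_per_day * duration_days)
    removed: list[int] = []
    if n_gaps == 0 or len(track) < 30:
        return track, removed
    keep = np.ones(len(track), dtype=bool)
    for _ in range(n_gaps):
        length = int(rng.integers(5, 13))
        start = int(rng.integers(1, len(track) - length))
        keep[start:start + length] = False
    removed = np.flatnonzero(~keep).tolist()
    return track.loc[keep].reset_index(drop=True), removed


# ---------------------------------------------------------------------------
# cohort orchestration and serialisation
# ---------------------------------------------------------------------------

def simulate_dataset(config: SimConfig) -> dict:
    """Simulate the full cohort.

    Returns a dict with keys ``fixes``, ``weather``, ``metadata``,
    ``biometrics``, ``attendance`` (DataFrames) and ``truth`` (SimTruth).
    Mortality truncation is applied before degradation, so the truth states
    always refer to the retained, pre-degradation track.
    """
    roster = pup_roster(config)
    weather = {y: simulate_weather(config, y) for y in config.season_labels}
    biometrics = simulate_biometrics(config, roster)
    attendance = simulate_attendance(config, roster)
    beta = config.truth_beta()
    truth = SimTruth(config=config, beta=beta)

    fixes_frames = []
    for i, rec in enumerate(roster.itertuples()):
        cov = simulate_covariates(config, i, roster, weather, biometrics)
        design_df = standardized_view(cov, config.scalers)
        X, _ = build_design(design_df, config.terms, config.harmonics)
        rng = _rng(config, "track", rec.id)
        states = simulate_state_sequence(beta, X, rng=rng)
        pos = simulate_positions(states, config.emission_mu, config.emission_sigma,
                                 (rec.home_lat, rec.home_lon), rng=rng,
                                 heading_sd=config.heading_sd,
                                 attraction_scale_m=config.attraction_scale_m)
        step_td = pd.Timedelta(minutes=config.sampling_interval)
        ts = pd.date_range(cov.timestamp.iloc[0], periods=len(pos), freq=step_td)
        track = pd.DataFrame({"id": rec.id, "timestamp": ts,
                              "lat": pos.lat, "lon": pos.lon})
        degraded, deg_truth = inject_missing_and_outliers(
            track, config.missing_rate, config.outlier_rate, rng=rng)
        degraded, gap_rows = _inject_gaps(degraded, config.gap_rate_per_day,
                                          rec.duration_days, rng)
        deg_truth["gaps"] = gap_rows
        fixes_frames.append(degraded)
        truth.states[rec.id] = states
        truth.home[rec.id] = (rec.home_lat, rec.home_lon)
        truth.fate[rec.id] = rec.fate
        if rec.fate == "died":
            truth.death_day[rec.id] = rec.duration_days
        truth.degraded[rec.id] = deg_truth

    fixes = pd.concat(fixes_frames, ignore_index=True)
    weather_df = pd.concat(weather.values(), ignore_index=True)
    metadata = roster[["id", "sex", "colony", "year", "birth_date", "fate", "death_date"]].copy()
    return {"fixes": fixes, "weather": weather_df, "metadata": metadata,
            "biometrics": biometrics, "attendance": attendance, "truth": truth}


def write_dataset(dataset: dict, out_dir) -> None:
    """Write the cohort as CSV files plus a JSON truth record."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fmt = "%Y-%m-%dT%H:%M:%SZ"
    fixes = dataset["fixes"].copy()
    fixes["timestamp"] = fixes.timestamp.dt.strftime(fmt)
    fixes.to_csv(out / "fixes.csv", index=False, float_format="%.17g")
    weather = dataset["weather"].copy()
    weather["timestamp"] = weather.timestamp.dt.strftime(fmt)
    weather.to_csv(out / "weather.csv", index=False, float_format="%.6f")
    meta = dataset["metadata"].copy()
    meta["birth_date"] = meta.birth_date.dt.strftime("%Y-%m-%d")
    meta["death_date"] = meta.death_date.dt.strftime("%Y-%m-%d")
    meta.to_csv(out / "metadata.csv", index=False)
    bio = dataset["biometrics"].copy()
    bio["date"] = bio.date.dt.strftime("%Y-%m-%d")
    bio.to_csv(out / "biometrics.csv", index=False)
    att = dataset["attendance"].copy()
    att["date"] = att.date.dt.strftime("%Y-%m-%d")
    att.to_csv(out / "attendance.csv", index=False)
    truth = dataset["truth"]
    with open(out / "truth.json", "w") as fh:
        json.dump({
            "beta": truth.beta.tolist(),
            "design_columns": truth.config.design_columns(),
            "emission_mu": list(truth.config.emission_mu),
            "emission_sigma": list(truth.config.emission_sigma),
            "scalers": {k: list(v) for k, v in truth.config.scalers.items()},
            "states": {k: v.tolist() for k, v in truth.states.items()},
            "home": {k: list(v) for k, v in truth.home.items()},
            "fate": truth.fate,
            "death_day": truth.death_day,
            "degraded": truth.degraded,
            "seed": truth.config.seed,
        }, fh)


def read_dataset(in_dir) -> dict:
    """Re-read a written cohort (timestamps parsed back to UTC instants)."""
    p = Path(in_dir)
    fixes = pd.read_csv(p / "fixes.csv", parse_dates=["timestamp"])
    weather = pd.read_csv(p / "weather.csv", parse_dates=["timestamp"])
    metadata = pd.read_csv(p / "metadata.csv", parse_dates=["birth_date", "death_date"])
    biometrics = pd.read_csv(p / "biometrics.csv", parse_dates=["date"])
    attendance = pd.read_csv(p / "attendance.csv", parse_dates=["date"])
    with open(p / "truth.json") as fh:
        truth = json.load(fh)
    return {"fixes": fixes, "weather": weather, "metadata": metadata,
            "biometrics": biometrics, "attendance": attendance, "truth": truth}
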