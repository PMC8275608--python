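"""GPS track preprocessing: regular grids, steps, censoring, bursts, covariates.

Pipeline order is fixed: regularise fixes onto the nominal sampling grid,
compute great-circle step lengths, censor implausible speeds (> 400 m/h by
default), split tracks at observation gaps exceeding four hours, drop bursts
spanning less than 48 h, then join and standardise covariates per step.
Every interval of the raw grid is accounted for in a reconciliation report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_M = 6_371_000.0

#: metric covariates standardised to pooled mean 0 / sd 1
METRIC_COVARIATES = ("age", "condition", "temp", "wind")


def haversine_m(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in metres on the WGS-84 mean-radius sphere."""
    p1, p2 = np.deg2rad(lat1), np.deg2rad(lat2)
    dphi = p2 - p1
    dlam = np.deg2rad(lon2) - np.deg2rad(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


# ---------------------------------------------------------------------------
# regularisation and steps
# ---------------------------------------------------------------------------

def regularize(fixes: pd.DataFrame, interval: int = 60) -> pd.DataFrame:
    """Snap fixes of one or more individuals onto the nominal sampling grid.

    Every grid instant between a pup's first and last (rounded) fix appears
    exactly once; fixes snap to the nearest grid instant (within interval/2 by
    construction of rounding); when two fixes contend for one instant the
    nearer wins and a warning is logged.  Unmatched instants have NaN
    coordinates.
    """
    if len(fixes) == 0:
        return pd.DataFrame(columns=["id", "timestamp", "lat", "lon", "observed"])
    freq = pd.Timedelta(minutes=interval)
    out = []
    for pid, grp in fixes.groupby("id", sort=True):
        grp = grp.sort_values("timestamp")
        snapped = grp.timestamp.dt.round(freq)
        offset = (grp.timestamp - snapped).abs()
        sub = pd.DataFrame({"snapped": snapped, "offset": offset,
                            "lat": grp.lat.to_numpy(), "lon": grp.lon.to_numpy()})
        dup = sub.duplicated("snapped", keep=False)
        if dup.any():
            warnings.warn(f"{pid}: {int(dup.sum())} fixes contend for shared grid instants; keeping nearest")
            sub = sub.sort_values(["snapped", "offset"]).drop_duplicates("snapped", keep="first")
        grid = pd.date_range(sub.snapped.iloc[0], sub.snapped.iloc[-1], freq=freq)
        g = sub.set_index("snapped").reindex(grid)
        out.append(pd.DataFrame({"id": pid, "timestamp": grid,
                                 "lat": g.lat.to_numpy(), "lon": g.lon.to_numpy(),
                                 "observed": np.isfinite(g.lat.to_numpy())}))
    return pd.concat(out, ignore_index=True)


def compute_steps(gridded: pd.DataFrame) -> np.ndarray:
    """Step lengths (m) between consecutive grid instants of one individual.

    Index t holds the distance from fix t to fix t+1; NaN when either end is
    missing; length is ``len(gridded) - 1``.
    """
    if gridded.id.nunique() > 1:
        raise ValueError("compute_steps expects a single individual's gridded track")
    lat = gridded.lat.to_numpy()
    lon = gridded.lon.to_numpy()
    with np.errstate(invalid="ignore"):
        d = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    return d


def censor_steps(steps: np.ndarray, threshold_m_per_h: float = 400.0,
                 interval: int = 60) -> tuple[np.ndarray, int]:
    """Set steps implying speeds above the threshold to missing.

    The threshold is specified in m/h and scaled to the sampling interval, so
    400 m/h becomes 400 m per step for hourly data and 400/12 m for 5-minute
    data.  Returns the censored series and the replacement count.
    """
    if threshold_m_per_h <= 0:
        raise ValueError("threshold must be positive")
    thr = threshold_m_per_h * interval / 60.0
    out = np.asarray(steps, dtype=float).copy()
    mask = np.isfinite(out) & (out > thr)
    out[mask] = np.nan
    return out, int(mask.sum())


@dataclass
class TrackBurst:
    """A maximal gap-free (<= 4 h) run of regularised fixes for one pup."""

    id: str
    burst_index: int
    grid: pd.DataFrame          # rows of the regularised track
    steps: np.ndarray           # len(grid) - 1, censored, NaN = missing
    start_row: int              # row offset into the pup's full grid


def split_and_filter_bursts(gridded: pd.DataFrame, steps: np.ndarray,
                            max_gap_h: float = 4.0, min_span_h: float = 48.0,
                            interval: int = 60):
    """Split one pup's gridded track at long observation gaps; drop short bursts.

    A cut happens wherever more than ``max_gap_h`` of consecutive grid time
    lacks a fix.  A burst's span is measured first-to-last grid instant and
    must be at least ``min_span_h``.  Returns (bursts, accounting) where
    accounting labels every raw grid interval as ``kept`` / ``dropped`` /
    ``gap`` for the reconciliation report.
    """
    if gridded.id.nunique() > 1:
        raise ValueError("split_and_filter_bursts expects a single individual")
    obs = gridded.observed.to_numpy()
    n = len(gridded)
    max_gap_rows = int(round(max_gap_h * 60.0 / interval))

    # segments of rows between gaps of > max_gap_rows consecutive missing rows
    segments = []
    seg_start, run_missing, last_obs = None, 0, None
    for i in range(n):
        if obs[i]:
            if seg_start is None:
                seg_start = i
            elif run_missing > max_gap_rows:
                segments.append((seg_start, last_obs))
                seg_start = i
            run_missing, last_obs = 0, i
        else:
            run_missing += 1
    if seg_start is not None:
        segments.append((seg_start, last_obs))

    span_td = pd.Timedelta(hours=min_span_h)
    ts = gridded.timestamp
    interval_label = np.full(n - 1 if n else 0, "gap", dtype=object)
    bursts = []
    k = 0
    pid = gridded.id.iloc[0]
    for a, b in segments:
        kept = (ts.iloc[b] - ts.iloc[a]) >= span_td
        interval_label[a:b] = "kept" if kept else "dropped"
        if kept:
            k += 1
            bursts.append(TrackBurst(id=pid, burst_index=k,
                                     grid=gridded.iloc[a:b + 1].reset_index(drop=True),
                                     steps=steps[a:b], start_row=a))
    accounting = {"n_intervals": int(max(n - 1, 0)),
                  "kept": int((interval_label == "kept").sum()),
                  "dropped": int((interval_label == "dropped").sum()),
                  "gap": int((interval_label == "gap").sum())}
    return bursts, accounting


# ---------------------------------------------------------------------------
# auxiliary tables
# ---------------------------------------------------------------------------

def interpolate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Fill missing weather values: linear interpolation in time for interior
    gaps, nearest-value fill at the edges (where interpolation is undefined)."""
    out = weather.sort_values("timestamp").reset_index(drop=True).copy()
    for col in out.columns:
        if col == "timestamp":
            continue
        s = out[col]
        if s.notna().sum() == 0:
            raise ValueError(f"weather column {col!r} is entirely missing")
        s = s.interpolate(method="linear", limit_area="inside")
        out[col] = s.ffill().bfill()
    return out


@dataclass
class SMIResult:
    """Scaled-mass-index computation: SMI_i = M_i * (L0 / L_i) ** b_SMA."""

    smi: pd.Series
    b_sma: float
    l0: float


def scaled_mass_index(population: pd.DataFrame,
                      individuals: pd.DataFrame | None = None) -> SMIResult:
    """Body condition as scaled mass.

    The standardised-major-axis exponent b_SMA is the OLS slope of ln mass on
    ln length divided by their Pearson correlation, estimated on the
    population table; L0 is the arithmetic mean length.  ``individuals``
    (defaulting to the population itself) receives the SMI values.
    """
    if len(population) < 3:
        raise ValueError("population table needs at least 3 records")
    m = population.mass_kg.to_numpy(dtype=float)
    l = population.length_cm.to_numpy(dtype=float)
    if np.any(m <= 0) or np.any(l <= 0):
        raise ValueError("masses and lengths must be strictly positive")
    ln_m, ln_l = np.log(m), np.log(l)
    if np.isclose(ln_l.var(), 0.0):
        raise ValueError("zero variance in length: SMA slope undefined")
    slope = np.cov(ln_l, ln_m, ddof=1)[0, 1] / np.var(ln_l, ddof=1)
    r = np.corrcoef(ln_l, ln_m)[0, 1]
    b_sma = slope / r
    l0 = float(l.mean())
    target = population if individuals is None else individuals
    smi = target.mass_kg * (l0 / target.length_cm) ** b_sma
    return SMIResult(smi=smi, b_sma=float(b_sma), l0=l0)


# ---------------------------------------------------------------------------
# covariate assembly
# ---------------------------------------------------------------------------

def _naive_days(s: pd.Series) -> pd.Series:
    """Calendar days as timezone-naive instants (UTC for tz-aware input)."""
    s = pd.to_datetime(s)
    if s.dt.tz is not None:
        s = s.dt.tz_convert("UTC").dt.tz_localize(None)
    return s.dt.normalize()

def build_covariates(bursts: list[TrackBurst], weather: pd.DataFrame,
                     metadata: pd.DataFrame, biometrics: pd.DataFrame,
                     colony_reference: str | None = None,
                     scalers: dict | None = None) -> tuple[pd.DataFrame, dict]:
    """Per-step covariate table across all bursts, standardised for fitting.

    One row per step: id, burst, timestamp, step_m, hour, then sex / colony /
    year indicators (0 = reference: female, the reference colony, the first
    season) and the metric covariates age (whole days since the pup's first
    fix), condition (most recent scaled mass index), temp and wind (hourly
    island series, gap-filled).  Metric covariates are standardised with
    pooled mean/sd over all step rows unless explicit ``scalers``
    {name: (mean, sd)} are supplied; the constants used are returned for
    reuse by downstream stages.
    """
    meta = metadata.set_index("id")
    weather = interpolate_weather(weather).set_index("timestamp")
    smi_res = scaled_mass_index(biometrics)
    bio = biometrics.copy()
    bio["smi"] = smi_res.smi

    if colony_reference is None:
        colony_reference = str(meta.colony.iloc[0])
    year_reference = int(meta.year.min())

    first_fix = {}
    for b in bursts:
        t0 = b.grid.timestamp.iloc[0]
        first_fix[b.id] = min(first_fix.get(b.id, t0), t0)

    rows = []
    for b in bursts:
        if b.id not in meta.index:
            raise KeyError(f"individual {b.id!r} missing from metadata")
        rec = meta.loc[b.id]
        g = b.grid.iloc[:-1]  # one covariate row per step (origin fix)
        ts = g.timestamp
        df = pd.DataFrame({"id": b.id, "burst": b.burst_index,
                           "timestamp": ts.to_numpy(), "step_m": b.steps})
        df["hour"] = ts.dt.hour.to_numpy() + ts.dt.minute.to_numpy() / 60.0
        df["age"] = ((ts - first_fix[b.id]) / pd.Timedelta(days=1)).astype(int).to_numpy()
        hourly = ts.dt.floor("1h")
        df["temp"] = weather.temp_c.reindex(hourly).to_numpy()
        df["wind"] = weather.wind_speed.reindex(hourly).to_numpy()
        if df.temp.isna().any() or df.wind.isna().any():
            raise ValueError(f"weather series does not cover burst {b.id}/{b.burst_index}")
        pb = bio[bio.id == b.id].sort_values("date")
        if len(pb) == 0:
            raise KeyError(f"individual {b.id!r} missing from biometrics")
        days = _naive_days(pb.date).to_numpy()
        idx = np.clip(np.searchsorted(days, _naive_days(ts).to_numpy(), side="right") - 1,
                      0, len(pb) - 1)
        df["condition"] = pb.smi.to_numpy()[idx]
        df["sex"] = float(rec.sex == "M")
        df["colony"] = float(str(rec.colony) != colony_reference)
        df["year"] = float(int(rec.year) != year_reference)
        rows.append(df)
    table = pd.concat(rows, ignore_index=True)

    used = {}
    for name in METRIC_COVARIATES:
        if scalers is not None and name in scalers:
            m, s = scalers[name]
        else:
            m, s = float(table[name].mean()), float(table[name].std(ddof=0))
        if s == 0:
            raise ValueError(f"covariate {name!r} has zero variance")
        table[name + "_raw"] = table[name]
        table[name] = (table[name] - m) / s
        used[name] = (float(m), float(s))
    return table, used


# ---------------------------------------------------------------------------
# displacement summaries
# ---------------------------------------------------------------------------

def displacement_summaries(gridded: pd.DataFrame, steps_by_id: dict,
                           reference_points: dict, metadata: pd.DataFrame) -> dict:
    """Per-pup mean hourly distance and mean displacement from the natal colony.

    ``steps_by_id`` maps pup id to its (censored) step series; displacement is
    the per-fix haversine distance to the pup's colony reference, averaged per
    pup and per colony.
    """
    meta = metadata.set_index("id")
    per_pup = []
    for pid, grp in gridded.groupby("id", sort=True):
        colony = str(meta.loc[pid].colony)
        if colony not in reference_points:
            raise KeyError(f"no reference point for colony {colony!r}")
        rlat, rlon = reference_points[colony]
        obs = grp[grp.observed]
        disp = haversine_m(obs.lat.to_numpy(), obs.lon.to_numpy(), rlat, rlon)
        steps = np.asarray(steps_by_id[pid], dtype=float)
        steps = steps[np.isfinite(steps)]
        per_pup.append(dict(id=pid, colony=colony,
                            mean_step_m=float(steps.mean()) if steps.size else np.nan,
                            mean_displacement_m=float(disp.mean())))
    tab = pd.DataFrame(per_pup)
    by_colony = tab.groupby("colony").mean_displacement_m.agg(["mean", "count"])
    return {
        "per_pup": tab,
        "mean_step_m_overall": float(np.nanmean(tab.mean_step_m)),
        "mean_displacement_by_colony": {c: float(v) for c, v in by_colony["mean"].items()},
    }


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def preprocess(fixes: pd.DataFrame, weather: pd.DataFrame, metadata: pd.DataFrame,
               biometrics: pd.DataFrame, interval: int = 60,
               threshold_m_per_h: float = 400.0, max_gap_h: float = 4.0,
               min_span_h: float = 48.0, colony_reference: str | None = None,
               scalers: dict | None = None) -> dict:
    """Full pipeline: regularise -> steps -> censor -> split/filter -> covariates.

    Returns ``bursts`` (long per-step table), ``burst_objects``, ``scalers``,
    ``gridded``, ``steps_by_id`` and a reconciliation ``report`` in which kept
    + dropped + gap intervals balance the raw grid exactly.
    """
    gridded = regularize(fixes, interval)
    all_bursts: list[TrackBurst] = []
    steps_by_id = {}
    n_censored = 0
    acc_total = {"n_intervals": 0, "kept": 0, "dropped": 0, "gap": 0}
    n_bursts_dropped = 0
    for pid, grp in gridded.groupby("id", sort=True):
        grp = grp.reset_index(drop=True)
        steps = compute_steps(grp)
        steps, c = censor_steps(steps, threshold_m_per_h, interval)
        n_censored += c
        bursts, acc = split_and_filter_bursts(grp, steps, max_gap_h, min_span_h, interval)
        steps_by_id[pid] = steps
        all_bursts.extend(bursts)
        for k in acc_total:
            acc_total[k] += acc[k]
        # count dropped fragments: contiguous dropped segments
        n_bursts_dropped += _count_dropped_segments(grp, max_gap_h, min_span_h, interval) - len(bursts)
    table, used_scalers = build_covariates(all_bursts, weather, metadata, biometrics,
                                           colony_reference, scalers)
    report = {
        "n_raw_fixes": int(len(fixes)),
        "n_grid_rows": int(len(gridded)),
        "n_missing_rows": int((~gridded.observed).sum()),
        "n_censored_steps": int(n_censored),
        "n_bursts_kept": len(all_bursts),
        "n_bursts_dropped": int(n_bursts_dropped),
        "intervals": acc_total,
        "intervals_balanced": acc_total["kept"] + acc_total["dropped"] + acc_total["gap"]
        == acc_total["n_intervals"],
        "n_step_rows": int(len(table)),
        "n_observed_steps": int(table.step_m.notna().sum()),
        "scalers": used_scalers,
    }
    return {"bursts": table, "burst_objects": all_bursts, "gridded": gridded,
            "steps_by_id": steps_by_id, "scalers": used_scalers, "report": report}


def _count_dropped_segments(grp: pd.DataFrame, max_gap_h, min_span_h, interval) -> int:
    """Number of all segments (kept or not), to derive the dropped count."""
    bursts, acc = split_and_filter_bursts(grp, np.full(max(len(grp) - 1, 0), np.nan),
                                          max_gap_h, 0.0, interval)
    return len(bursts)
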