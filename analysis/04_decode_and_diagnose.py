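#!/usr/bin/env python
"""Decode behavioural states and check model fit.

Viterbi-decodes the fitted HMM, summarises time spent inactive/active per pup,
computes state-occupancy curves (age and hour of day, per colony) with 95%
Monte-Carlo bands, and runs the fit diagnostics: forecast pseudo-residuals
(normality, autocorrelation, tail calibration) and the empirical-vs-model
marginal step distribution.  Writes decoded.csv (scratch/), the summary and
curves (results/), and diagnostic plots (scratch/figures/).
"""

import argparse
import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pupmove.decoding import (decode_table, marginal_fit, occupancy_curve,
                              occupancy_fraction, residual_diagnostics,
                              residual_series, pseudo_residuals)
from pupmove.hmm import HMMSpec, load_fit, stack_bursts


def _full_terms():
    from pupmove.design import Term
    return [Term("colony"), Term("year"), Term("sex"), Term("age"),
            Term("condition"), Term("temp"), Term("wind"), Term("hour")]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bursts", type=str, default="scratch/bursts.csv")
    ap.add_argument("--fit", type=str, default="results/hmm_fit.json")
    ap.add_argument("--draws", type=int, default=1000)
    ap.add_argument("--seed", type=int, default=9)
    ap.add_argument("--out", type=str, default="results")
    args = ap.parse_args()

    bursts = pd.read_csv(args.bursts, parse_dates=["timestamp"])
    spec = HMMSpec(_full_terms())
    f = load_fit(args.fit, spec)
    stack = stack_bursts(bursts, spec)

    decoded = decode_table(f, bursts)
    decoded.to_csv("scratch/decoded.csv", index=False)
    frac = occupancy_fraction(decoded)
    lo, hi = frac["range_inactive"]
    print(f"time inactive: mean {100 * frac['mean_inactive']:.1f}% "
          f"(range {100 * lo:.1f}-{100 * hi:.1f}%) across "
          f"{decoded.id.nunique()} pups")

    curves = {}
    for cov in ("age", "hour"):
        grid = np.linspace(0, 24, 49) if cov == "hour" else np.linspace(-2, 2, 41)
        for colony in (0.0, 1.0):
            c = occupancy_curve(f, cov, grid, n_draws=args.draws,
                                seed=args.seed, colony_level=colony)
            key = f"{cov}_colony{int(colony)}"
            curves[key] = {"grid": c.grid.tolist(), "point": c.point.tolist(),
                           "lower": None if c.lower is None else c.lower.tolist(),
                           "upper": None if c.upper is None else c.upper.tolist()}
            print(f"occupancy({cov}, colony={int(colony)}): active prob "
                  f"{c.point.min():.2f}-{c.point.max():.2f}")

    z = pseudo_residuals(f, stack)
    diag = residual_diagnostics(z)
    mfit = marginal_fit(f, stack)
    print(f"pseudo-residuals: KS {diag['ks_distance']:.4f}, lag-1 ACF "
          f"{diag['lag1_acf']:.4f}, |z|>1.96 fraction {diag['tail_fraction']:.3f}")
    print(f"marginal fit: total variation distance {mfit['tv_distance']:.4f}")

    out = Path(args.out); out.mkdir(parents=True, exist_ok=True)
    with open(out / "decoding_summary.json", "w") as fh:
        json.dump({
            "mean_inactive_pct": 100 * frac["mean_inactive"],
            "range_inactive_pct": [100 * lo, 100 * hi],
            "per_pup_inactive": {k: float(v) for k, v in frac["per_pup_inactive"].items()},
            "residuals": diag,
            "marginal_tv_distance": mfit["tv_distance"],
        }, fh, indent=2)
    with open(out / "curves.json", "w") as fh:
        json.dump(curves, fh)
    residual_series(f, bursts).to_csv("scratch/residuals.csv", index=False)

    figdir = Path("scratch/figures"); figdir.mkdir(parents=True, exist_ok=True)
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy.stats import norm
        zz = z[np.isfinite(z)]
        fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
        axes[0].hist(zz, bins=60, density=True)
        xs = np.linspace(-4, 4, 200)
        axes[0].plot(xs, norm.pdf(xs))
        axes[0].set_title("pseudo-residuals")
        from scipy.stats import probplot
        probplot(zz, plot=axes[1])
        mids = 0.5 * (mfit["edges"][1:] + mfit["edges"][:-1])
        axes[2].step(mids, mfit["empirical"], where="mid", label="empirical")
        axes[2].step(mids, mfit["model"], where="mid", label="model")
        axes[2].legend(); axes[2].set_title("marginal step distribution")
        fig.tight_layout()
        fig.savefig(figdir / "diagnostics.png", dpi=120)
        print(f"plots -> {figdir}/diagnostics.png")
    except Exception as e:  # plotting is best-effort
        print(f"plotting skipped: {e}")


if __name__ == "__main__":
    main()
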