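#!/usr/bin/env python
"""Rank covariates by the AIC cost of excluding them.

For each covariate of the full model, refits the HMM twice — once without its
colony-interaction columns, once without all of its terms — and reports
delta AIC = AIC(reduced) - AIC(full).  Covariates whose largest delta AIC
reaches the threshold (default 40) are flagged relevant.  The ladder only
reports; inference stays with the full model.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from pupmove.design import Term
from pupmove.hmm import HMMSpec, load_fit, stack_bursts
from pupmove.selection import exclusion_ladder

FULL_TERMS = [Term("colony"), Term("year"), Term("sex"), Term("age"),
              Term("condition"), Term("temp"), Term("wind"), Term("hour")]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--bursts", type=str, default="scratch/bursts.csv")
    ap.add_argument("--fit", type=str, default="results/hmm_fit.json",
                    help="full-model fit artifact to warm-start from")
    ap.add_argument("--threshold", type=float, default=40.0)
    ap.add_argument("--restarts", type=int, default=1)
    ap.add_argument("--seed", type=int, default=13)
    ap.add_argument("--out", type=str, default="results/selection.csv")
    args = ap.parse_args()

    bursts = pd.read_csv(args.bursts, parse_dates=["timestamp"])
    spec = HMMSpec(FULL_TERMS)
    full_fit = None
    if args.fit and Path(args.fit).exists():
        full_fit = load_fit(args.fit, spec)
        if full_fit.design_signature != stack_bursts(bursts, spec).info.signature():
            print("fit artifact does not match the burst design; refitting")
            full_fit = None

    res = exclusion_ladder(spec, bursts, threshold=args.threshold,
                           n_restarts=args.restarts, seed=args.seed,
                           full_fit=full_fit)
    t = res["table"]
    t.to_csv(args.out, index=False)
    print(t.to_string(index=False,
                      formatters={"aic": "{:.1f}".format, "delta_aic": "{:.1f}".format}))
    flagged = t[t.relevant == True].covariate.unique()  # noqa: E712
    print(f"relevant (delta AIC >= {args.threshold:g}): {', '.join(flagged) or 'none'}")


if __name__ == "__main__":
    main()
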