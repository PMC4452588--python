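#!/usr/bin/env python
"""Shear sweep at delta_a = 13: is bonding time correlated with shear rate?

Binding close to the wall is diffusion-dominated for few-nanometre particles;
the sweep reports a Spearman rank correlation of bonding time against the
physical shear rate (0..2000 /s) — non-significance is the expected outcome.
"""

import argparse
import json

from nanodpd.experiments import SweepSpec, run_sweep, summarize_sweep


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--preset", default="desk", choices=["full", "desk", "mini"])
    ap.add_argument("--replicates", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/shear")
    args = ap.parse_args()

    spec = SweepSpec(family="shear",
                     conditions=(0, 400, 800, 1200, 1600, 2000),
                     replicates=args.replicates, preset=args.preset,
                     master_seed=args.seed)
    df = run_sweep(spec, args.out)
    summary = summarize_sweep(spec, df, args.out)
    print(json.dumps(summary, indent=1))
    sp = summary.get("spearman_bonding_time_vs_rate")
    if sp:
        verdict = ("no detectable shear dependence" if not
                   sp["significant_at_0.05"] else
                   "bonding time varies with shear rate")
        print(f"Spearman rho={sp['rho']:.3f}, p={sp['p_value']:.3f}: {verdict}")


if __name__ == "__main__":
    main()
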