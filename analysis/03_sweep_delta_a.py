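#!/usr/bin/env python
"""Binding-strength sweep: bonding time vs delta_a (strong regime) and
attachment probability (weak regime).

The strong regime (13..25) should show mean bonding time falling roughly
linearly with delta_a; the weak regime (5..11) is reported as attachment
fractions.  Weak-regime probabilities are only meaningful at the full-scale
preset (long runs); at the desk preset they underestimate attachment.
"""

import argparse
import json

from nanodpd.experiments import SweepSpec, run_sweep, summarize_sweep


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--preset", default="desk", choices=["full", "desk", "mini"])
    ap.add_argument("--replicates", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--weak", action="store_true",
                    help="sweep the weak regime (5..11) instead of 13..25")
    ap.add_argument("--out", default=None)
    args = ap.parse_args()

    conditions = (5, 7, 9, 11) if args.weak else (13, 15, 17, 19, 21, 23, 25)
    out = args.out or ("results/delta_a_weak" if args.weak
                       else "results/delta_a")
    spec = SweepSpec(family="delta_a", conditions=conditions,
                     replicates=args.replicates, preset=args.preset,
                     master_seed=args.seed)
    df = run_sweep(spec, out)
    summary = summarize_sweep(spec, df, out)
    print(json.dumps(summary, indent=1))
    means = {c: v.get("mean_bonding_time") for c, v in
             summary["conditions"].items()}
    print("mean bonding time by delta_a:", means)


if __name__ == "__main__":
    main()
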