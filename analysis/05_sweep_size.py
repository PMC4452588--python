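#!/usr/bin/env python
"""Size sweep at delta_a = 20: bonding time for 2, 4 and 6 nm spheres.

Larger particles average their thermal kicks over more solvent contacts, move
more smoothly, and carry more ligands, so both the mean and the spread of the
bonding time should fall with diameter.
"""

import argparse
import json

from nanodpd.experiments import SweepSpec, run_sweep, summarize_sweep


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--preset", default="desk", choices=["full", "desk", "mini"])
    ap.add_argument("--replicates", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/size")
    args = ap.parse_args()

    spec = SweepSpec(family="size", conditions=(2.0, 4.0, 6.0),
                     replicates=args.replicates, preset=args.preset,
                     master_seed=args.seed)
    df = run_sweep(spec, args.out)
    summary = summarize_sweep(spec, df, args.out)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
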