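#!/usr/bin/env python
"""Shape sweep at delta_a = 20 and constant volume: sphere vs nanorods.

Rods with aspect ratios 5, 10 and 15 share the 2-unit sphere's volume and
ligand count; their longer reach and tumbling should let them contact the
wall sooner, so bonding time should fall as the aspect ratio grows.
"""

import argparse
import json

from nanodpd.experiments import SweepSpec, run_sweep, summarize_sweep


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--preset", default="desk", choices=["full", "desk", "mini"])
    ap.add_argument("--replicates", type=int, default=10)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", default="results/shape")
    args = ap.parse_args()

    spec = SweepSpec(family="shape", conditions=("sphere", 5, 10, 15),
                     replicates=args.replicates, preset=args.preset,
                     master_seed=args.seed)
    df = run_sweep(spec, args.out)
    summary = summarize_sweep(spec, df, args.out)
    print(json.dumps(summary, indent=1))


if __name__ == "__main__":
    main()
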