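#!/usr/bin/env python
"""Validate the solvent model: thermostat, momentum conservation, shear profile.

Three quick checks on pure-fluid systems: (1) equilibrium kinetic temperature
against kT = 1; (2) total-momentum drift in a fully periodic box; (3) the
steady velocity profile under SLLOD shear against the imposed gradient.
"""

import argparse
import json
from pathlib import Path

import numpy as np

from nanodpd import make_fluid_box, mini_preset
from nanodpd.engine import build_system, run


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results/fluid"))
    args = ap.parse_args()
    out = {}

    state = make_fluid_box(edge=8.0, rho=3.0, seed=args.seed)
    p0 = state.vel.sum(axis=0)
    traj = run(state, 8000, stride=100, seed=args.seed)
    out["kinetic_temperature"] = float(traj.kin_temp[40:].mean())
    out["momentum_drift_per_bead"] = float(
        np.abs(state.vel.sum(axis=0) - p0).max() / state.n_beads)

    # canonical homogeneous shear: periodic box with Lees-Edwards images
    state = make_fluid_box(edge=5.0, rho=3.0, seed=args.seed + 1)
    traj = run(state, 20000, stride=20000, seed=args.seed + 1,
               shear_rate=0.1, profile_bins=5, profile_start=4000)
    z = traj.meta["profile_z"]
    v = traj.meta["velocity_profile"]
    out["imposed_shear_rate"] = 0.1
    out["periodic_profile_slope"] = float(np.polyfit(z - z[0], v, 1)[0])

    # walled channel (production geometry): linear but wall-limited gradient
    cfg = mini_preset(delta_a=0.0, seed=args.seed)
    sheared = build_system(cfg)
    traj = run(sheared, 10000, stride=1000, seed=args.seed,
               shear_rate=0.1, profile_bins=8)
    z = traj.meta["profile_z"]
    v = traj.meta["velocity_profile"]
    out["walled_profile_slope"] = float(np.polyfit(z - z[0], v, 1)[0])

    args.out.mkdir(parents=True, exist_ok=True)
    (args.out / "validation.json").write_text(json.dumps(out, indent=1))
    print(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
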