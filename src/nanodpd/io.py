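"""Plain-text persistence: extended XYZ export and per-frame scalar CSVs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .builder import Species, SystemState
from .engine import Trajectory


def write_xyz(path, positions: np.ndarray, species: np.ndarray,
              box, comment: str = "", append: bool = False) -> None:
    """One extended-XYZ frame: species label + coordinates per bead."""
    mode = "a" if append else "w"
    lx, ly, lz = box
    with open(path, mode) as fh:
        fh.write(f"{len(positions)}\n")
        fh.write(
            f'Lattice="{lx} 0 0 0 {ly} 0 0 0 {lz}" '
            f'Properties=species:S:1:pos:R:3 {comment}\n'
        )
        for s, (x, y, z) in zip(species, positions):
            fh.write(f"{Species(int(s)).name} {x:.6f} {y:.6f} {z:.6f}\n")


def write_state_xyz(path, state: SystemState, comment: str = "") -> None:
    write_xyz(path, state.pos, state.species, state.box, comment)


def write_trajectory(outdir, traj: Trajectory, stem: str = "traj") -> Path:
    """Persist a trajectory: scalar CSV, JSON metadata, optional XYZ frames."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({
        "time": traj.times,
        "com_x": traj.com[:, 0], "com_y": traj.com[:, 1], "com_z": traj.com[:, 2],
        "contacts": traj.contacts,
        "kin_temp": traj.kin_temp,
    })
    csv_path = outdir / f"{stem}_scalars.csv"
    df.to_csv(csv_path, index=False)
    meta = {k: v for k, v in traj.meta.items()
            if not isinstance(v, np.ndarray)}
    meta["box"] = list(map(float, traj.box))
    (outdir / f"{stem}_meta.json").write_text(json.dumps(meta, indent=1))
    if traj.full_positions is not None and traj.species is not None:
        xyz = outdir / f"{stem}.xyz"
        for k, frame in enumerate(traj.full_positions):
            write_xyz(xyz, frame, traj.species, traj.box,
                      comment=f"frame={k}", append=k > 0)
    return csv_path


def read_trajectory(outdir, stem: str = "traj") -> Trajectory:
    """Rehydrate the scalar portion of a stored trajectory."""
    outdir = Path(outdir)
    df = pd.read_csv(outdir / f"{stem}_scalars.csv")
    meta = json.loads((outdir / f"{stem}_meta.json").read_text())
    box = np.array(meta.pop("box"))
    quat = np.zeros((len(df), 4))
    quat[:, 0] = 1.0
    return Trajectory(
        times=df["time"].to_numpy(),
        com=df[["com_x", "com_y", "com_z"]].to_numpy(),
        quat=quat,
        contacts=df["contacts"].to_numpy(np.int64),
        kin_temp=df["kin_temp"].to_numpy(),
        box=box, meta=meta,
    )
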