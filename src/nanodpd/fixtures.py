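"""Deterministic toy systems and scripted trajectories with known ground truth.

These stand-ins exercise every builder/engine/observable operation without a
full production run: an analytic two-bead system for the pair-force law, a
fully periodic pure-solvent box for thermostat and momentum checks, and
scripted trajectories whose MSD and binding time are known in closed form.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .builder import (
    InteractionMatrix,
    Species,
    SystemState,
    build_interaction_matrix,
)
from .engine import Trajectory


def _empty_bonds():
    return (np.zeros((0, 2), np.int64), np.zeros(0), np.zeros(0))


def make_two_bead_system(
    species_pair: tuple[Species, Species] = (Species.WM, Species.WM),
    separation: float = 0.5,
    delta_a: float = 20.0,
    box_edge: float = 6.0,
    gamma: float = 3.0,
    kT: float = 1.0,
) -> SystemState:
    """Two stationary beads at a given separation in an empty periodic box."""
    if separation <= 0:
        raise ValueError("separation must be positive")
    half = box_edge / 2.0
    pos = np.array([
        [half - separation / 2.0, half, half],
        [half + separation / 2.0, half, half],
    ])
    bonds, bk, br = _empty_bonds()
    return SystemState(
        pos=pos, vel=np.zeros((2, 3)),
        species=np.array(species_pair, dtype=np.int8),
        n_immobile=0, core_start=2,
        bonds=bonds, bond_k=bk, bond_r0=br,
        box=np.full(3, float(box_edge)), z_lo=0.0, z_hi=box_edge,
        periodic_z=True, matrix=build_interaction_matrix(delta_a),
        gamma=gamma, kT=kT,
    )


def make_fluid_box(
    edge: float = 10.0,
    rho: float = 3.0,
    seed: int = 0,
    matrix: InteractionMatrix | None = None,
    gamma: float = 3.0,
    kT: float = 1.0,
    dt: float = 0.02,
) -> SystemState:
    """Fully periodic pure-solvent box at density rho, Maxwell-Boltzmann
    velocities with zero net momentum; deterministic given (edge, rho, seed)."""
    if edge <= 0 or rho <= 0:
        raise ValueError("edge and density must be positive")
    n = int(round(rho * edge**3))
    rng = np.random.default_rng(seed)
    pos = rng.random((n, 3)) * edge
    vel = rng.normal(0.0, np.sqrt(kT), (n, 3))
    vel -= vel.mean(axis=0)
    bonds, bk, br = _empty_bonds()
    return SystemState(
        pos=pos, vel=vel,
        species=np.full(n, Species.WM, dtype=np.int8),
        n_immobile=0, core_start=n,
        bonds=bonds, bond_k=bk, bond_r0=br,
        box=np.full(3, float(edge)), z_lo=0.0, z_hi=float(edge),
        periodic_z=True,
        matrix=matrix or build_interaction_matrix(0.0),
        gamma=gamma, kT=kT, dt=dt,
    )


@dataclass(frozen=True)
class ScriptedTrajectory:
    """Parameters of a trajectory with analytically known MSD / binding time.

    ``motion``: "static", "drift" (constant velocity), or "walk" (seeded
    Gaussian random walk with per-axis step standard deviation ``step_sd``).
    ``attach_time``: from this time onward the contact count equals
    ``contacts_after`` (before it, ``contacts_before``).
    """

    motion: str = "static"
    n_frames: int = 201
    frame_dt: float = 1.0
    velocity: tuple[float, float, float] = (1.0, 0.0, 0.0)
    step_sd: float = 0.1
    seed: int = 0
    attach_time: float | None = None
    contacts_before: int = 0
    contacts_after: int = 3


def make_scripted_trajectory(spec: ScriptedTrajectory) -> Trajectory:
    """Materialise a ScriptedTrajectory as a Trajectory object."""
    t = np.arange(spec.n_frames) * spec.frame_dt
    if spec.motion == "static":
        com = np.zeros((spec.n_frames, 3))
    elif spec.motion == "drift":
        com = t[:, None] * np.asarray(spec.velocity, dtype=float)[None, :]
    elif spec.motion == "walk":
        rng = np.random.default_rng(spec.seed)
        steps = rng.normal(0.0, spec.step_sd, (spec.n_frames - 1, 3))
        com = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
    else:
        raise ValueError(f"unknown motion law {spec.motion!r}")
    contacts = np.full(spec.n_frames, spec.contacts_before, np.int64)
    if spec.attach_time is not None:
        contacts[t >= spec.attach_time] = spec.contacts_after
    quat = np.zeros((spec.n_frames, 4))
    quat[:, 0] = 1.0
    return Trajectory(
        times=t, com=com, quat=quat, contacts=contacts,
        kin_temp=np.ones(spec.n_frames), box=np.full(3, np.inf),
        meta={"scripted": True, "motion": spec.motion, "seed": spec.seed},
    )
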