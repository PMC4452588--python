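"""DPD time integration: pair forces, velocity-Verlet stepping, SLLOD shear.

The force on bead i from bead j within the cutoff is

    f_ij = [ a_ij (r_c - r) - gamma w_D (e . v_ij) + sigma w_R zeta / sqrt(dt) ] e

with ``e`` the unit vector from j to i, ``w_D = (w_R)^2 = (r_c - r)^2`` and the
noise amplitude tied to the friction by the fluctuation--dissipation relation
``sigma^2 = 2 gamma k_bT``.  Bonded beads additionally feel the harmonic
spring ``-K (r - r_s) e``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import kernels
from .builder import (
    BoxSpec,
    SystemState,
    assemble_system,
    build_interaction_matrix,
    build_nanorod,
    build_spherical_np,
)
from .config import RunConfig

__all__ = [
    "sigma_from_gamma", "pair_force", "bond_force", "compute_forces",
    "step", "run", "run_simulation", "Trajectory", "InstabilityError",
]


class InstabilityError(RuntimeError):
    """A bead moved more than r_c in a single step."""


def sigma_from_gamma(gamma: float, kT: float) -> float:
    """Noise amplitude from the fluctuation-dissipation relation, sqrt(2 gamma kT)."""
    if gamma < 0 or kT < 0:
        raise ValueError("gamma and kT must be non-negative")
    return math.sqrt(2.0 * gamma * kT)


def pair_force(r_i, r_j, v_i, v_j, a_ij: float, gamma: float = 3.0,
               sigma: float = 0.0, zeta: float = 0.0, dt: float = 0.02):
    """DPD pair force on bead i (conservative + dissipative + random terms).

    ``zeta`` is the symmetric per-pair noise draw; pass the same value for
    (i, j) and (j, i) to get an exact Newton's-third-law pair.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    d = r_i - r_j
    r = float(np.linalg.norm(d))
    if r < 1.0e-12:
        raise ValueError("coincident beads: force direction undefined")
    if r >= 1.0:
        return np.zeros(3)
    e = d / r
    w = 1.0 - r
    vij = np.asarray(v_i, dtype=float) - np.asarray(v_j, dtype=float)
    f = a_ij * w - gamma * w * w * float(e @ vij)
    if sigma > 0.0:
        f += sigma * w * zeta / math.sqrt(dt)
    return f * e


def bond_force(r_i, r_j, K: float = 100.0, r_s: float = 0.5):
    """Harmonic spring force on bead i; zero at separation r_s."""
    d = np.asarray(r_i, dtype=float) - np.asarray(r_j, dtype=float)
    r = float(np.linalg.norm(d))
    if r < 1.0e-12:
        raise ValueError("coincident bonded beads")
    return (-K * (r - r_s) / r) * d


def _noise_kind(name: str) -> int:
    return {"none": kernels.NOISE_NONE, "uniform": kernels.NOISE_UNIFORM,
            "gaussian": kernels.NOISE_GAUSSIAN}[name]


def compute_forces(state: SystemState, seed: int = 0,
                   noise: str = "none") -> np.ndarray:
    """Per-bead force array for the current state (cell-list accumulation).

    With ``noise="none"`` (default) only conservative, dissipative and bonded
    terms enter, so the result is deterministic; otherwise the random force is
    included using ``seed``.
    """
    n = state.n_beads
    lx, ly, lz = state.box
    ncells = max(1, int(lx)) * max(1, int(ly)) * max(1, int(lz))
    cell_start = np.zeros(ncells, np.int64)
    cell_count = np.zeros(ncells, np.int64)
    cell_of = np.empty(n, np.int64)
    order = np.empty(n, np.int64)
    pos_c = np.empty((n, 3))
    vel_c = np.empty((n, 3))
    spec_c = np.empty(n, np.int8)
    mob_c = np.empty(n, np.uint8)
    forces_c = np.empty((n, 3))
    forces = np.zeros((n, 3))
    nk = _noise_kind(noise)
    sigma = state.sigma if nk != kernels.NOISE_NONE else 0.0
    gamma_wall = state.gamma * state.wall_gamma_mult
    sigma_wall = (math.sqrt(2.0 * gamma_wall * state.kT)
                  if sigma > 0.0 else 0.0)
    kernels.seeded_forces(
        int(seed), state.pos, state.vel, state.species, state.matrix.a,
        state.gamma, sigma, gamma_wall, sigma_wall,
        1.0 / math.sqrt(state.dt), nk,
        state.bonds, state.bond_k, state.bond_r0,
        float(lx), float(ly), float(lz), state.periodic_z, state.n_immobile,
        cell_start, cell_count, cell_of, order,
        pos_c, vel_c, spec_c, mob_c, forces_c, forces,
    )
    return forces


@dataclass
class Trajectory:
    """Frames saved at a fixed stride: NP centre of mass, orientation,
    functional-end/wall contact count and kinetic temperature, plus optional
    full bead positions for XYZ export."""

    times: np.ndarray        # (F,)
    com: np.ndarray          # (F, 3) unwrapped
    quat: np.ndarray         # (F, 4)
    contacts: np.ndarray     # (F,) int
    kin_temp: np.ndarray     # (F,)
    box: np.ndarray
    meta: dict = field(default_factory=dict)
    full_positions: np.ndarray | None = None   # (Ff, N, 3)
    species: np.ndarray | None = None

    def __post_init__(self):
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.times)


def run(state: SystemState, steps: int, *, stride: int = 25,
        shear_rate: float = 0.0, seed: int = 0, noise: str = "uniform",
        thermostat: bool = True, full_every: int = 0,
        profile_bins: int = 0, profile_start: int | None = None,
        body_force=(0.0, 0.0, 0.0), stop_when_bound=None,
        meta: dict | None = None):
    """Integrate ``state`` in place for ``steps`` and return its Trajectory.

    ``shear_rate`` is the reduced SLLOD rate (gradient of streaming x-velocity
    along z).  ``thermostat=False`` switches off dissipative and random forces
    (useful for ballistic checks).  With ``profile_bins > 0`` the binned mean
    laboratory x-velocity over z is accumulated from step ``profile_start``
    onward and returned in the trajectory metadata.

    ``body_force`` applies a constant external force to the rigid body
    (ballistic checks).  ``stop_when_bound`` may be a BindingCriterion: the
    run then ends as soon as the criterion is irrevocably satisfied, which
    shortens bound replicates without changing their adjudication.
    """
    if steps < 0 or stride <= 0:
        raise ValueError("steps must be >= 0 and stride positive")
    n = state.n_beads
    nf = steps // stride + 1
    frame_t = np.zeros(nf)
    frame_com = np.zeros((nf, 3))
    frame_quat = np.zeros((nf, 4))
    frame_contacts = np.zeros(nf, np.int64)
    frame_kint = np.zeros(nf)
    fe_idx = np.flatnonzero(state.species == 0).astype(np.int64)  # Species.FE
    n_full = (steps // (stride * full_every) + 1) if full_every > 0 else 0
    frames_full = np.zeros((max(n_full, 1), n if full_every > 0 else 1, 3))
    prof_sum = np.zeros(profile_bins)
    prof_cnt = np.zeros(profile_bins, np.int64)
    if profile_start is None:
        profile_start = steps // 2

    nk = _noise_kind(noise)
    sigma = sigma_from_gamma(state.gamma, state.kT) if thermostat else 0.0
    gamma = state.gamma if thermostat else 0.0
    if nk == kernels.NOISE_NONE:
        sigma = 0.0
    gamma_wall = gamma * state.wall_gamma_mult
    sigma_wall = sigma * math.sqrt(state.wall_gamma_mult)
    inertia_inv = (state.body_inertia_inv() if state.n_core
                   else np.eye(3))
    contact_range = float(meta.get("contact_range", 1.0)) if meta else 1.0
    if stop_when_bound is not None:
        contact_range = stop_when_bound.contact_range
        stop_min_contacts = stop_when_bound.min_contacts
        stop_dwell = stop_when_bound.dwell
    else:
        stop_min_contacts = 0
        stop_dwell = 0.0
    out_info = np.zeros(2, np.int64)

    status = kernels.run_kernel(
        state.pos, state.vel, state.species, state.matrix.a,
        gamma, sigma, gamma_wall, sigma_wall, state.dt, nk,
        state.bonds, state.bond_k, state.bond_r0,
        state.n_immobile, state.core_start,
        state.body_ref, state.body_com, state.body_quat,
        state.body_vel, state.body_angmom, inertia_inv,
        float(max(state.n_core, 1)),
        float(state.box[0]), float(state.box[1]), float(state.box[2]),
        state.periodic_z, state.z_lo, state.z_hi,
        float(shear_rate), int(steps), int(stride), int(seed) % (2**31 - 1),
        fe_idx, contact_range,
        frame_t, frame_com, frame_quat, frame_contacts, frame_kint,
        int(full_every), frames_full,
        int(profile_start), prof_sum, prof_cnt,
        np.asarray(body_force, dtype=float), int(stop_min_contacts),
        float(stop_dwell), out_info,
    )
    if status == kernels.STATUS_UNSTABLE:
        raise InstabilityError(
            f"bead displacement exceeded r_c in one step (dt={state.dt}, "
            f"shear={shear_rate}); system diverged"
        )

    nf_used = int(out_info[0])
    info = dict(meta or {})
    info.update(seed=int(seed), shear_rate=float(shear_rate),
                steps=int(steps), stride=int(stride),
                stopped_early=nf_used < nf)
    if profile_bins > 0:
        with np.errstate(invalid="ignore"):
            info["velocity_profile"] = prof_sum / np.maximum(prof_cnt, 1)
        info["profile_z"] = (state.z_lo + (np.arange(profile_bins) + 0.5)
                             * (state.z_hi - state.z_lo) / profile_bins)
    return Trajectory(
        times=frame_t[:nf_used], com=frame_com[:nf_used],
        quat=frame_quat[:nf_used], contacts=frame_contacts[:nf_used],
        kin_temp=frame_kint[:nf_used],
        box=state.box.copy(), meta=info,
        full_positions=(frames_full[:int(out_info[1])]
                        if full_every > 0 else None),
        species=state.species.copy() if full_every > 0 else None,
    )


def step(state: SystemState, n: int = 1, **kw) -> Trajectory:
    """Advance ``state`` by ``n`` velocity-Verlet steps (thin wrapper on run)."""
    return run(state, n, stride=max(n, 1), **kw)


def build_system(config: RunConfig) -> SystemState:
    """Construct the SystemState a config describes (seeded, deterministic)."""
    box = BoxSpec(dimensions=tuple(config.box), rho=config.rho,
                  wall_thickness=config.wall_thickness)
    matrix = build_interaction_matrix(config.delta_a)
    if config.shape == "sphere":
        template = build_spherical_np(config.diameter, n_chains=config.n_chains,
                                      rho=config.rho)
    elif config.shape == "rod":
        template = build_nanorod(config.aspect_ratio, config.diameter,
                                 n_chains=config.n_chains or 8, rho=config.rho)
    else:
        raise ValueError(f"unknown shape {config.shape!r}")
    np_pos = None
    if config.np_z is not None:
        np_pos = (config.box[0] / 2.0, config.box[1] / 2.0, config.np_z)
    return assemble_system(
        box, template, matrix, np_position=np_pos,
        gamma=config.gamma, kT=config.kT, dt=config.dt, seed=config.seed,
        wall_gamma_mult=config.wall_gamma_mult,
    )


def run_simulation(config: RunConfig, stop_when_bound: bool = False) -> Trajectory:
    """Build the configured system and integrate it; fully reproducible.

    The master seed drives both system assembly and the thermal noise stream;
    frames carry the config hash so every result row is traceable.
    """
    state = build_system(config)
    ss = np.random.SeedSequence([int(config.seed), 0xD9D])
    noise_seed = int(ss.generate_state(1, np.uint32)[0]) % (2**31 - 1)
    meta = {
        "config_hash": config.hash(),
        "delta_a": config.delta_a,
        "shape": config.shape,
        "diameter": config.diameter,
        "aspect_ratio": config.aspect_ratio,
        "shear_physical": config.shear_physical,
        "contact_range": config.criterion.contact_range,
    }
    return run(
        state, config.steps, stride=config.stride,
        shear_rate=config.shear_reduced, seed=noise_seed,
        noise=config.noise, full_every=config.save_full_every,
        stop_when_bound=config.criterion if stop_when_bound else None,
        meta=meta,
    )
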