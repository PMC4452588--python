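"""Shared fixtures and the independent all-pairs force oracle."""

from __future__ import annotations

import numpy as np
import pytest

from nanodpd import build_interaction_matrix, desk_preset, mini_preset


def brute_force_oracle(state) -> np.ndarray:
    """Independent numpy all-pairs evaluation of conservative + dissipative +
    bonded forces (no noise).  Minimum image in periodic directions; pairs of
    two immobile beads are skipped, mirroring the production convention that
    wall beads exert but never receive resolved forces."""
    pos, vel, L = state.pos, state.vel, state.box
    n = len(pos)
    d = pos[:, None, :] - pos[None, :, :]
    axes = (0, 1, 2) if state.periodic_z else (0, 1)
    for ax in axes:
        d[..., ax] -= L[ax] * np.round(d[..., ax] / L[ax])
    r = np.sqrt(np.sum(d * d, axis=-1))
    mask = (r < 1.0) & (r > 1.0e-12)
    imm = np.arange(n) < state.n_immobile
    mask &= ~(imm[:, None] & imm[None, :])
    rsafe = np.where(r > 0, r, 1.0)
    e = d / rsafe[..., None]
    w = np.where(mask, 1.0 - r, 0.0)
    a = state.matrix.a[state.species[:, None], state.species[None, :]]
    dv = vel[:, None, :] - vel[None, :, :]
    rdotv = np.einsum("ijk,ijk->ij", e, dv)
    f = a * w - state.gamma * w * w * rdotv
    forces = np.sum(np.where(mask, f, 0.0)[..., None] * e, axis=1)

    for (i, j), K, r0 in zip(state.bonds, state.bond_k, state.bond_r0):
        dd = pos[i] - pos[j]
        for ax in axes:
            dd[ax] -= L[ax] * np.round(dd[ax] / L[ax])
        rij = np.linalg.norm(dd)
        fb = -K * (rij - r0) / rij * dd
        forces[i] += fb
        forces[j] -= fb
    return forces


@pytest.fixture(scope="session")
def desk_system():
    """One assembled desk-scale system, shared across read-only tests."""
    from nanodpd.engine import build_system

    return build_system(desk_preset(delta_a=20.0, seed=7))


@pytest.fixture(scope="session")
def matrix20():
    return build_interaction_matrix(20.0)


@pytest.fixture(scope="session")
def mini_cfg():
    return mini_preset(delta_a=20.0, seed=11)
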