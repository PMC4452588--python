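"""Construct DPD simulation systems: box, walls, fluid, and grafted nanoparticles.

Everything is expressed in reduced DPD units (cutoff ``r_c``, bead mass ``m``
and thermal energy ``k_bT`` all equal 1).  The physical mapping used throughout
the package is ``r_c = 1 nm``, so a 2-unit sphere models a 2-nm nanoparticle.

The model has exactly six bead species:

=====  =============================================
FE     functional end of a ligand (binding tip)
HL     ligand head bead (hydrophobic)
TL     ligand tail bead (hydrophilic, grafted end)
NP     nanoparticle core bead (rigid)
VS     vascular-surface (receptor wall) bead, immobile
WM     water molecule (solvent)
=====  =============================================

The ligand--wall affinity is controlled by a single binding factor ``delta_a``:
the FE--VS repulsion is ``25 - delta_a`` while every other pair keeps its
default soft repulsion (25 between like beads, 45 between hydrophobic and
hydrophilic species).  Larger ``delta_a`` means the functional end prefers the
receptor surface over solvent, i.e. stronger effective binding.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

R_C = 1.0  # interaction cutoff; the unit of length

GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


class Species(enum.IntEnum):
    FE = 0
    HL = 1
    TL = 2
    NP = 3
    VS = 4
    WM = 5


N_SPECIES = 6

#: Default repulsion between any pair of beads (k_bT / r_c).
A_DEFAULT = 25.0
#: Repulsion between hydrophobic (HL) and hydrophilic beads.
A_PHOBIC_PHILIC = 45.0


# --------------------------------------------------------------------------
# interaction matrix
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionMatrix:
    """Symmetric per-species-pair repulsion factors ``a_ij``.

    ``a[FE, VS] = 25 - delta_a``; all diagonal entries are 25; HL against any
    non-HL species is 45; every remaining pair is 25.
    """

    a: np.ndarray
    delta_a: float

    def __post_init__(self):
        a = np.asarray(self.a, dtype=float)
        if a.shape != (N_SPECIES, N_SPECIES):
            raise ValueError("interaction matrix must be 6x6")
        if not np.allclose(a, a.T):
            raise ValueError("interaction matrix must be symmetric")
        if (a < 0).any():
            raise ValueError("repulsion factors must be non-negative")
        object.__setattr__(self, "a", a)


def build_interaction_matrix(delta_a: float) -> InteractionMatrix:
    """Return the six-species repulsion matrix for binding factor ``delta_a``.

    Parameters
    ----------
    delta_a:
        Binding factor in ``[0, 25]``; the FE--VS repulsion is
        ``25 - delta_a``, so ``delta_a = 25`` removes ligand--receptor
        repulsion entirely (strongest binding) and ``delta_a = 0`` leaves the
        matrix with no bias toward the wall.
    """
    if not 0.0 <= delta_a <= 25.0:
        raise ValueError(
            f"delta_a={delta_a} outside [0, 25]: would give a negative "
            "ligand-receptor repulsion factor"
        )
    a = np.full((N_SPECIES, N_SPECIES), A_DEFAULT)
    hl = Species.HL
    for s in Species:
        if s != hl:
            a[hl, s] = a[s, hl] = A_PHOBIC_PHILIC
    a[Species.FE, Species.VS] = a[Species.VS, Species.FE] = A_DEFAULT - delta_a
    return InteractionMatrix(a=a, delta_a=float(delta_a))


# --------------------------------------------------------------------------
# geometry specs
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxSpec:
    """Simulation box: periodic in x and y, bounded by walls in z."""

    dimensions: tuple[float, float, float] = (22.0, 22.0, 22.0)
    rho: float = 3.0           # bead number density (beads / r_c^3)
    wall_thickness: float = 1.0

    def __post_init__(self):
        if any(d <= 0 for d in self.dimensions):
            raise ValueError("box dimensions must be positive")
        if self.rho < 0:
            raise ValueError("density must be non-negative")

    @property
    def volume(self) -> float:
        lx, ly, lz = self.dimensions
        return lx * ly * lz


@dataclass(frozen=True)
class LigandChainSpec:
    """A grafted ligand: ten beads, 7 hydrophilic tail + 2 head + 1 functional end.

    The tail (TL) end is permanently attached to the nanoparticle; the single
    FE bead at the tip is the only species that feels the ``delta_a``
    attraction to the receptor wall.
    """

    n_beads: int = 10
    spring_constant: float = 100.0
    bond_length: float = 0.5   # natural spring length r_s, in r_c

    @property
    def composition(self) -> list[Species]:
        """Ordered species from graft point to tip: 7 TL, 2 HL, 1 FE."""
        return [Species.TL] * 7 + [Species.HL] * 2 + [Species.FE]

    def __post_init__(self):
        if self.n_beads != 10:
            raise ValueError("ligand chains have exactly ten beads")
        if self.spring_constant <= 0 or self.bond_length <= 0:
            raise ValueError("spring constant and bond length must be positive")


@dataclass(frozen=True)
class RigidBodyTemplate:
    """Bead layout of a rigid nanoparticle (sphere or spherocylinder rod).

    Core bead coordinates are in the body frame (centre of mass at the
    origin).  ``graft_sites`` and ``graft_normals`` give where ligand chains
    attach on the surface and the outward direction each chain initially
    extends along.
    """

    core_positions: np.ndarray          # (n_core, 3)
    shape: str                          # "sphere" | "rod"
    volume: float                       # analytic body volume, r_c^3
    long_axis: float
    short_axis: float
    graft_sites: np.ndarray             # (n_chains, 3)
    graft_normals: np.ndarray           # (n_chains, 3) unit vectors
    chain_spec: LigandChainSpec

    @property
    def aspect_ratio(self) -> float:
        return self.long_axis / self.short_axis

    @property
    def n_core(self) -> int:
        return len(self.core_positions)

    @property
    def n_chains(self) -> int:
        return len(self.graft_sites)


MIN_CORE_SPACING = 0.4   # r_c; minimum spacing between core beads
MIN_GRAFT_SPACING = 0.45  # r_c; below this the surface cannot hold the chains


def _fibonacci_sphere(n: int, radius: float = 1.0) -> np.ndarray:
    """Deterministic near-uniform points on a sphere (Fibonacci spiral)."""
    if n == 1:
        return np.array([[0.0, 0.0, radius]])
    k = np.arange(n)
    z = 1.0 - 2.0 * (k + 0.5) / n
    phi = k * GOLDEN_ANGLE
    s = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    return radius * np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def build_spherical_np(
    diameter: float,
    chain_spec: LigandChainSpec | None = None,
    n_chains: int | None = None,
    rho: float = 3.0,
) -> RigidBodyTemplate:
    """Rigid spherical nanoparticle with radially grafted ligand chains.

    Core beads are laid out as a centre bead plus concentric Fibonacci shells
    so the total count matches the global bead density ``rho``; graft sites
    are a separate Fibonacci layout on the surface, one ten-bead chain each.

    ``n_chains`` defaults to 8 for the 2-unit reference sphere, scaled with
    surface area for other diameters.
    """
    if diameter <= 0:
        raise ValueError("diameter must be positive")
    chain_spec = chain_spec or LigandChainSpec()
    r = diameter / 2.0
    if n_chains is None:
        n_chains = max(1, round(8 * (diameter / 2.0) ** 2))
    if n_chains < 1:
        raise ValueError("need at least one grafted chain")

    volume = 4.0 / 3.0 * math.pi * r**3
    n_core = max(1, round(rho * volume))
    # concentric shells: counts proportional to shell area
    n_shells = max(1, round(r / 0.7))
    radii = r * (np.arange(1, n_shells + 1) / n_shells)
    weights = radii**2
    counts = np.maximum(1, np.round((n_core - 1) * weights / weights.sum()).astype(int))
    beads = [np.zeros((1, 3))]
    for rad, cnt in zip(radii, counts):
        beads.append(_fibonacci_sphere(int(cnt), rad))
    core = np.vstack(beads)

    sites = _fibonacci_sphere(n_chains, r)
    normals = sites / np.linalg.norm(sites, axis=1, keepdims=True)
    _check_graft_spacing(sites)
    return RigidBodyTemplate(
        core_positions=core,
        shape="sphere",
        volume=volume,
        long_axis=diameter,
        short_axis=diameter,
        graft_sites=sites,
        graft_normals=normals,
        chain_spec=chain_spec,
    )


def _check_graft_spacing(sites: np.ndarray) -> None:
    if len(sites) < 2:
        return
    d = np.linalg.norm(sites[:, None, :] - sites[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < MIN_GRAFT_SPACING:
        raise ValueError(
            f"graft sites closer than {MIN_GRAFT_SPACING} r_c: surface cannot "
            f"hold {len(sites)} chains"
        )


def build_nanorod(
    aspect_ratio: float,
    reference_diameter: float = 2.0,
    chain_spec: LigandChainSpec | None = None,
    n_chains: int = 8,
    rho: float = 3.0,
) -> RigidBodyTemplate:
    """Rigid spherocylinder with the same volume as the reference sphere.

    The rod radius ``a`` solves ``V = pi a^2 L + (4/3) pi a^3`` with
    ``L = 2a(aspect_ratio - 1)``, so long axis / short axis equals
    ``aspect_ratio`` exactly and the volume matches the reference sphere's.
    The chain count defaults to the reference sphere's 8 chains (equal drug
    load, equal ligand number).
    """
    if aspect_ratio < 1.0:
        raise ValueError("aspect ratio must be >= 1")
    chain_spec = chain_spec or LigandChainSpec()
    v_ref = 4.0 / 3.0 * math.pi * (reference_diameter / 2.0) ** 3
    if aspect_ratio == 1.0:
        return build_spherical_np(reference_diameter, chain_spec, n_chains, rho)
    a = (v_ref / (math.pi * (2.0 * (aspect_ratio - 1.0) + 4.0 / 3.0))) ** (1.0 / 3.0)
    if a < MIN_CORE_SPACING / 2.0:
        raise ValueError(
            f"aspect ratio {aspect_ratio} gives rod radius {a:.3f} r_c, too "
            "thin to place beads"
        )
    cyl_len = 2.0 * a * (aspect_ratio - 1.0)   # straight section, cap centres
    half = cyl_len / 2.0

    n_core = max(2, round(rho * v_ref))
    spacing = cyl_len / (n_core - 1) if n_core > 1 else 0.0
    if spacing < MIN_CORE_SPACING:
        n_core = int(cyl_len / MIN_CORE_SPACING) + 1
        spacing = cyl_len / (n_core - 1)
    xs = np.linspace(-half, half, n_core)
    core = np.column_stack([xs, np.zeros(n_core), np.zeros(n_core)])

    sites, normals = _spherocylinder_surface(n_chains, a, half)
    _check_graft_spacing(sites)
    return RigidBodyTemplate(
        core_positions=core,
        shape="rod",
        volume=v_ref,
        long_axis=cyl_len + 2.0 * a,
        short_axis=2.0 * a,
        graft_sites=sites,
        graft_normals=normals,
        chain_spec=chain_spec,
    )


def _spherocylinder_surface(n: int, a: float, half: float):
    """Near-uniform graft sites on a spherocylinder of radius a, cap centres at +-half."""
    area_cyl = 2.0 * math.pi * a * (2.0 * half)
    area_caps = 4.0 * math.pi * a**2
    n_cyl = int(round(n * area_cyl / (area_cyl + area_caps)))
    n_caps = n - n_cyl
    pts, nrm = [], []
    # golden-angle helix along the straight section
    for k in range(n_cyl):
        x = -half + (k + 0.5) / n_cyl * 2.0 * half
        phi = k * GOLDEN_ANGLE
        nv = np.array([0.0, math.cos(phi), math.sin(phi)])
        pts.append(np.array([x, 0.0, 0.0]) + a * nv)
        nrm.append(nv)
    # hemispherical caps, alternating ends
    cap_pts = _fibonacci_sphere(max(n_caps, 1), a)
    for k in range(n_caps):
        p = cap_pts[k].copy()
        end = 1.0 if k % 2 == 0 else -1.0
        p[0] = abs(p[0]) * end  # fold onto the outward hemisphere
        centre = np.array([end * half, 0.0, 0.0])
        nv = p / np.linalg.norm(p)
        pts.append(centre + p)
        nrm.append(nv)
    return np.array(pts), np.array(nrm)


# --------------------------------------------------------------------------
# walls and fluid
# --------------------------------------------------------------------------

def _wall_lattice(box: BoxSpec, z_levels: np.ndarray) -> np.ndarray:
    """Square-lattice layers (staggered) at the given z levels."""
    lx, ly, _ = box.dimensions
    nx, ny = max(1, round(lx)), max(1, round(ly))
    xs = (np.arange(nx) + 0.5) * lx / nx
    ys = (np.arange(ny) + 0.5) * ly / ny
    layers = []
    for i, z in enumerate(z_levels):
        off = 0.5 * lx / nx if i % 2 else 0.0
        gx, gy = np.meshgrid((xs + off) % lx, ys, indexing="ij")
        layer = np.column_stack([gx.ravel(), gy.ravel(), np.full(gx.size, z)])
        layers.append(layer)
    return np.vstack(layers)


def _wall_levels(thickness: float, rho: float, area_sites: int, area: float) -> np.ndarray:
    total = rho * area * thickness
    n_layers = max(1, round(total / area_sites))
    if n_layers == 1:
        return np.array([thickness])
    return thickness * np.arange(n_layers) / (n_layers - 1)


def build_wall(box: BoxSpec) -> np.ndarray:
    """Receptor (VS) wall slab on the bottom z-face; beads are immobile.

    Layers span ``[0, wall_thickness]`` so the topmost receptor layer sits at
    the bounce-back plane where ligands make contact.  For the 22-box at
    density 3 this emits exactly 22*22*3 = 1452 beads.
    """
    if box.rho <= 0:
        raise ValueError("wall density must be positive: the wall must exist")
    lx, ly, _ = box.dimensions
    nx, ny = max(1, round(lx)), max(1, round(ly))
    levels = _wall_levels(box.wall_thickness, box.rho, nx * ny, lx * ly)
    return _wall_lattice(box, levels)


def build_top_wall(box: BoxSpec) -> np.ndarray:
    """Frozen-solvent slab closing the top z-face (chemically neutral)."""
    lx, ly, lz = box.dimensions
    nx, ny = max(1, round(lx)), max(1, round(ly))
    levels = _wall_levels(box.wall_thickness, box.rho, nx * ny, lx * ly)
    return _wall_lattice(box, lz - levels)


EXCLUSION_RADIUS = 0.5  # r_c; no fluid bead within this of any existing bead


def fill_fluid(
    box: BoxSpec,
    excluded: np.ndarray,
    *,
    z_range: tuple[float, float] | None = None,
    seed: int = 0,
    exclusion_radius: float = EXCLUSION_RADIUS,
) -> np.ndarray:
    """Place solvent (WM) beads uniformly at density rho in the free volume.

    The free volume is the box between ``z_range`` planes minus a sphere of
    ``exclusion_radius`` around every existing bead (walls, nanoparticle core,
    ligands); it is measured on a deterministic 0.25 r_c grid, so the emitted
    count ``round(rho * V_free)`` does not depend on the seed.
    """
    lx, ly, lz = box.dimensions
    z0, z1 = z_range if z_range is not None else (0.0, lz)
    if z1 <= z0:
        raise ValueError("free volume is empty")
    excluded = np.asarray(excluded, dtype=float).reshape(-1, 3)
    tree = cKDTree(excluded) if len(excluded) else None

    h = 0.25
    nx, ny, nz = (max(1, int(round(L / h))) for L in (lx, ly, z1 - z0))
    gx = (np.arange(nx) + 0.5) * lx / nx
    gy = (np.arange(ny) + 0.5) * ly / ny
    gz = z0 + (np.arange(nz) + 0.5) * (z1 - z0) / nz
    pts = np.stack(np.meshgrid(gx, gy, gz, indexing="ij"), axis=-1).reshape(-1, 3)
    if tree is not None:
        d, _ = tree.query(pts, k=1, distance_upper_bound=exclusion_radius)
        frac_free = np.mean(np.isinf(d))
    else:
        frac_free = 1.0
    v_free = frac_free * lx * ly * (z1 - z0)
    if v_free <= 0:
        raise ValueError("free volume is empty after exclusions")
    n_target = int(round(box.rho * v_free))

    rng = np.random.default_rng(seed)
    out = np.empty((n_target, 3))
    filled = 0
    while filled < n_target:
        batch = max(1024, 2 * (n_target - filled))
        cand = rng.random((batch, 3))
        cand[:, 0] *= lx
        cand[:, 1] *= ly
        cand[:, 2] = z0 + cand[:, 2] * (z1 - z0)
        if tree is not None:
            d, _ = tree.query(cand, k=1, distance_upper_bound=exclusion_radius)
            cand = cand[np.isinf(d)]
        take = min(len(cand), n_target - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


# --------------------------------------------------------------------------
# assembled system
# --------------------------------------------------------------------------

@dataclass
class SystemState:
    """Complete particle state plus box, boundary and interaction description.

    Bead ordering is [immobile wall beads | fluid | ligand chains | rigid
    core]; ``n_immobile`` and ``core_start`` delimit the blocks.  Velocities
    are peculiar (streaming component excluded) when shear is applied.
    """

    pos: np.ndarray                 # (N, 3)
    vel: np.ndarray                 # (N, 3)
    species: np.ndarray             # (N,) int8
    n_immobile: int
    core_start: int                 # index of first rigid core bead (== N if no body)
    bonds: np.ndarray               # (B, 2) int64
    bond_k: np.ndarray              # (B,)
    bond_r0: np.ndarray             # (B,)
    box: np.ndarray                 # (3,)
    z_lo: float                     # bottom bounce-back plane
    z_hi: float                     # top bounce-back plane
    periodic_z: bool
    matrix: InteractionMatrix
    gamma: float = 3.0
    kT: float = 1.0
    dt: float = 0.02
    #: friction multiplier for fluid-wall bead pairs (no-slip enforcement);
    #: the paired noise amplitude scales as sqrt of this, preserving the
    #: per-pair fluctuation-dissipation balance
    wall_gamma_mult: float = 1.0
    # rigid-body state (world frame); meaningful only if core_start < N
    body_ref: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    body_com: np.ndarray = field(default_factory=lambda: np.zeros(3))
    body_quat: np.ndarray = field(default_factory=lambda: np.array([1.0, 0, 0, 0]))
    body_vel: np.ndarray = field(default_factory=lambda: np.zeros(3))
    body_angmom: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @property
    def n_beads(self) -> int:
        return len(self.pos)

    @property
    def n_core(self) -> int:
        return self.n_beads - self.core_start

    @property
    def sigma(self) -> float:
        """Noise amplitude from the fluctuation-dissipation relation."""
        return math.sqrt(2.0 * self.gamma * self.kT)

    @property
    def body_mass(self) -> float:
        return float(self.n_core)   # unit bead mass

    def body_inertia_inv(self) -> np.ndarray:
        """Inverse body-frame inertia tensor; beads carry a 0.1 m r_c^2 self term."""
        ref = self.body_ref
        eye = np.eye(3)
        inertia = 0.1 * len(ref) * eye.copy()
        for r in ref:
            inertia += (r @ r) * eye - np.outer(r, r)
        return np.linalg.inv(inertia)

    def copy(self) -> "SystemState":
        return replace(
            self,
            pos=self.pos.copy(), vel=self.vel.copy(), species=self.species.copy(),
            bonds=self.bonds.copy(), bond_k=self.bond_k.copy(),
            bond_r0=self.bond_r0.copy(), box=self.box.copy(),
            body_ref=self.body_ref.copy(), body_com=self.body_com.copy(),
            body_quat=self.body_quat.copy(), body_vel=self.body_vel.copy(),
            body_angmom=self.body_angmom.copy(),
        )


def _chain_beads(template: RigidBodyTemplate, com: np.ndarray):
    """Initial ligand bead positions/species/bonds for every grafted chain.

    Chains extend radially outward from each graft site at a compressed
    spacing (0.35 r_c) so even long chains start inside the box; they relax to
    the 0.5 r_c natural bond length within a few tens of steps.
    """
    spec = template.chain_spec
    comp = spec.composition
    pos, species, bonds = [], [], []
    spacing = 0.35
    for site, normal in zip(template.graft_sites, template.graft_normals):
        first = len(pos)
        for j in range(spec.n_beads):
            pos.append(com + site + normal * (spacing * (j + 1)))
            species.append(int(comp[j]))
            if j > 0:
                bonds.append((first + j - 1, first + j))
    return np.array(pos), np.array(species, dtype=np.int8), bonds


def assemble_system(
    box: BoxSpec,
    template: RigidBodyTemplate,
    matrix: InteractionMatrix,
    *,
    np_position: tuple[float, float, float] | None = None,
    orientation: np.ndarray | None = None,
    gamma: float = 3.0,
    kT: float = 1.0,
    dt: float = 0.02,
    seed: int = 0,
    wall_gamma_mult: float = 1.0,
) -> SystemState:
    """Build the closed system: walls, fluid, one grafted nanoparticle.

    The nanoparticle is placed at the box centre by default, with
    Maxwell--Boltzmann initial velocities at ``kT`` and zero net momentum.
    Raises if the rigid core overlaps the wall slabs.
    """
    lx, ly, lz = box.dimensions
    z_lo = box.wall_thickness
    z_hi = lz - box.wall_thickness
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0xB11D]))

    wall_bot = build_wall(box)
    wall_top = build_top_wall(box)
    n_immobile = len(wall_bot) + len(wall_top)

    com = np.array(np_position) if np_position is not None else np.array(
        [lx / 2.0, ly / 2.0, lz / 2.0]
    )
    ref = template.core_positions - template.core_positions.mean(axis=0)
    if orientation is not None:
        ref = ref @ orientation.T
        graft_rot = orientation
    else:
        graft_rot = np.eye(3)
    core = com + ref
    if core[:, 2].min() < z_lo or core[:, 2].max() > z_hi:
        raise ValueError("nanoparticle core overlaps a wall slab")

    tpl = replace(
        template,
        graft_sites=template.graft_sites @ graft_rot.T,
        graft_normals=template.graft_normals @ graft_rot.T,
    )
    lig_pos, lig_species, lig_bonds = _chain_beads(tpl, com)
    # keep initial chain beads out of the wall slabs; they relax afterwards
    lig_pos[:, 2] = np.clip(lig_pos[:, 2], z_lo + 0.2, z_hi - 0.2)
    lig_pos[:, 0] %= lx
    lig_pos[:, 1] %= ly

    excluded = np.vstack([wall_bot, wall_top, core, lig_pos])
    fluid = fill_fluid(
        box, excluded, z_range=(z_lo, z_hi), seed=int(rng.integers(2**31 - 1))
    )

    n_lig = len(lig_pos)
    n_fluid = len(fluid)
    pos = np.vstack([wall_bot, wall_top, fluid, lig_pos, core])
    species = np.concatenate([
        np.full(len(wall_bot), Species.VS, dtype=np.int8),
        np.full(len(wall_top), Species.WM, dtype=np.int8),
        np.full(n_fluid, Species.WM, dtype=np.int8),
        lig_species,
        np.full(len(core), Species.NP, dtype=np.int8),
    ])
    core_start = n_immobile + n_fluid + n_lig

    # bonds: intra-chain springs + anchor each chain's first bead to the
    # nearest rigid core bead
    spec = template.chain_spec
    bonds = []
    for i, j in lig_bonds:
        bonds.append((n_immobile + n_fluid + i, n_immobile + n_fluid + j))
    tree = cKDTree(core)
    for c in range(tpl.n_chains):
        first = n_immobile + n_fluid + c * spec.n_beads
        _, anchor = tree.query(com + tpl.graft_sites[c])
        bonds.append((core_start + int(anchor), first))
    bonds = np.array(bonds, dtype=np.int64).reshape(-1, 2)
    bond_k = np.full(len(bonds), spec.spring_constant)
    bond_r0 = np.full(len(bonds), spec.bond_length)

    # Maxwell-Boltzmann velocities for mobile degrees of freedom
    vel = np.zeros_like(pos)
    n_flex = n_fluid + n_lig
    vel[n_immobile:core_start] = rng.normal(0.0, math.sqrt(kT), (n_flex, 3))
    body_vel = rng.normal(0.0, math.sqrt(kT / max(len(core), 1)), 3)
    # zero total momentum over mobile dof
    ptot = vel[n_immobile:core_start].sum(axis=0) + body_vel * len(core)
    mtot = n_flex + len(core)
    vel[n_immobile:core_start] -= ptot / mtot
    body_vel = body_vel - ptot / mtot

    return SystemState(
        pos=pos, vel=vel, species=species,
        n_immobile=n_immobile, core_start=core_start,
        bonds=bonds, bond_k=bond_k, bond_r0=bond_r0,
        box=np.array([lx, ly, lz]), z_lo=z_lo, z_hi=z_hi, periodic_z=False,
        matrix=matrix, gamma=gamma, kT=kT, dt=dt,
        wall_gamma_mult=wall_gamma_mult,
        body_ref=ref, body_com=com.astype(float),
        body_quat=np.array([1.0, 0.0, 0.0, 0.0]),
        body_vel=body_vel, body_angmom=np.zeros(3),
    )
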