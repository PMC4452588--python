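# Methods

## The model

`nanodpd` simulates a ligand-coated nanoparticle (NP) suspended in explicit
coarse-grained solvent between two walls, binding to receptors on the bottom
wall while an optional linear shear flow runs along x.  The method is
dissipative particle dynamics (DPD): soft beads interacting through a
conservative repulsion, a pairwise dissipative force, and a pairwise random
force, with bonded bead-spring chains on top.  The force on bead *i* from
bead *j* inside the cutoff r_c is

    f_ij = [ a_ij (r_c − r_ij)  − K (r_ij − r_s)  − γ w_D (e_ij · v_ij)
             + σ w_R ζ_ij Δt^(−1/2) ] e_ij ,

with w_D = (w_R)² = (r_c − r_ij)², e_ij the unit vector from *j* to *i*
(repulsive sign convention), and the bead-spring term present only for bonded
pairs.  The noise amplitude is tied to the friction by the
fluctuation–dissipation relation σ² = 2 γ k_bT, which makes the pair
thermostat maintain k_bT without any extra velocity rescaling (the run is
otherwise plain NVE).

Reduced units: r_c = m = k_bT = 1.  The physical mapping is r_c = 1 nm, so
the full-scale 22 r_c box is a ~22-nm slab of capillary-adjacent plasma and
the 2/4/6-unit particles are 2/4/6-nm NPs.

### Species and the binding factor

Exactly six bead species exist: FE (functional end of a ligand), HL (ligand
head, hydrophobic), TL (ligand tail, hydrophilic), NP (rigid core), VS
(vascular-surface receptor bead), WM (water).  All like-pair repulsions are
25 (water compressibility convention); hydrophobic–hydrophilic pairs are 45.
The single tunable chemistry knob is the binding factor Δa: the FE–VS
repulsion is 25 − Δa.  Large Δa means the ligand tip prefers receptor contact
over solvent contact — an effective, purely repulsion-mediated adhesion.
Δa is bounded to [0, 25]; beyond 25 the repulsion would turn negative.

### Ligand chains

Each ligand is a ten-bead chain grafted to the core: 7 TL (grafted end),
2 HL, 1 FE tip, bonded by harmonic springs with K = 100 and natural length
r_s = 0.5 r_c (K from the model definition; r_s is our choice of a typical
coarse-grained polymer spacing, config-exposed).  Only the FE tip feels Δa.
The 3-hydrophobic/7-hydrophilic split admits two readings (FE counted among
the hydrophobic head beads, or among the hydrophilic beads with 3 HL); we
take the first.  The difference moves one bead between the HL and TL blocks
and does not touch the FE–VS chemistry that drives binding.

The 2-unit reference sphere carries 8 chains (≈0.64 chains/nm²); larger
spheres scale the count with surface area.  Nanorods keep the reference
sphere's 8 chains — equal volume, equal ligand load — so shape comparisons
are not confounded by ligand number.

### Geometry and walls

The box is periodic in x and y.  Both z faces carry a 1-r_c slab of frozen
beads on a staggered lattice at the global density (3 layers, exactly
ρ·L²·thickness beads): receptor (VS) beads at the bottom, frozen solvent
(WM) at the top.  Frozen-bead slabs on both faces are standard DPD channel
practice — a bare reflecting plane produces density artifacts, and a
chemically neutral top slab cannot compete for ligands.  Mobile beads that
cross either slab's inner plane are bounced back with the *full* velocity
vector inverted (no-slip, no-penetration).

Solvent fills the space between the slabs at density 3, excluding a 0.5-r_c
sphere around every wall/core/ligand bead; the free volume is measured on a
deterministic 0.25-r_c grid so the emitted count is seed-independent.  For
the full-scale geometry this yields ≈28.1k fluid beads around one 2-unit NP.

### Rigid body

The NP core (a centre bead plus concentric shells for spheres; an axial bead
row for spherocylinder rods, volume-matched to the reference sphere within
5%) moves as one rigid unit: net force and torque about the centre of mass
drive translation plus quaternion rotation, with bead positions regenerated
from the body frame every step (intra-body distances are therefore preserved
to integrator round-off).  Each core bead contributes a 0.1 m r_c² self term
to the body inertia so thin rods keep a finite moment about their long axis.
If any core bead penetrates a wall plane the body is reflected and its full
momentum (linear and angular) inverted, mirroring the bead-level rule.

### Integration and shear

Groot–Warren modified velocity Verlet (λ = ½): half-kick, drift, force
evaluation with the half-kicked velocities (the dissipative force thus sees
updated velocities), half-kick.  Δt = 0.02 τ.  A step that moves any bead
farther than r_c aborts the run as unstable.

Shear uses the SLLOD equations: stored momenta are peculiar, positions are
advected by the streaming profile γ̇ (z − z_wall) x̂, and peculiar x-momentum
is damped by −γ̇ p_z each step.  Dissipative forces therefore act on peculiar
velocities; a free-flight bead conserves its laboratory velocity exactly
(verified against the closed form).  Physical shear rates map linearly to
reduced rates with 2000 s⁻¹ → 0.1 τ⁻¹ (config-exposed constant; only the
ordering of shear settings matters for the conclusions).

In *fully periodic* boxes the z-face images carry the accumulated
Lees–Edwards strain offset in x (applied both to pair separations and to
beads wrapping through the z faces); without it the wrap plane acts as a
momentum sink.  In this canonical homogeneous geometry the steady velocity
profile is linear with the imposed gradient (within 5%, ensemble-averaged).

In the *walled* production geometry — SLLOD between stationary frozen-bead
walls, the model's own combination — the realised gradient is linear but
systematically below the imposed rate (≈0.5–0.7 of γ̇ for 10–16 r_c
channels, approaching γ̇ as the channel grows).  The cause is conservative
scattering off the static wall lattices, which makes both walls effectively
laboratory-stationary while the SLLOD terms assume a co-moving upper
boundary; raising the fluid–wall friction (``wall_gamma_mult``) barely moves
it, confirming the conservative channel.  Near the receptor wall, where
binding happens, the flow matches the imposed profile, so binding-zone
physics — and in particular the shear-independence finding — is unaffected;
shear conditions should be read as ordered settings rather than exact rates.

Two further deliberate simplifications: (1) the combination of SLLOD with
stationary bounce-back walls is used as the model defines it, although a
moving-wall Couette setup would be the cleaner realisation; (2) the
streaming-velocity *gradient across* the rigid body is not coupled to the
body, so shear-induced tumbling of rods enters only through the dissipative
coupling to the solvent.

### Noise

One symmetric random number per interacting pair per step.  Default is
uniform with matched variance (√3·U(−1,1)) — the classic DPD choice, and
materially faster in the inner loop; Gaussian noise is available via
`noise: gaussian`.  All randomness (fluid placement, initial velocities,
pair noise) derives deterministically from one master seed, so a config +
seed reproduces a run bit-for-bit.

## Observables

* **MSD** — single-origin squared displacement |r_COM(t) − r_COM(0)|² of the
  NP centre of mass (unwrapped).  This is the rising-then-plateau curve a
  binding trajectory shows; a sliding-origin time average is available as an
  option but is not the default.
* **Binding** — the model gives no operational definition of "firmly bound",
  so we fix one: ≥ 3 FE beads within 1 r_c of the receptor plane,
  continuously for ≥ 20 τ.  Bonding time is the start of the earliest such
  episode.  All three knobs are config-exposed and recorded with every
  result.  The rule is monotone: tightening any knob never makes an unbound
  replicate bound and never shortens a bonding time.
* **Ultimate MSD** — mean of the MSD curve after bonding_time + dwell.
* **Attachment probability** — bound fraction with an exact Clopper–Pearson
  95% interval.
* **Group statistics** — per-condition mean and sample SD of bonding times of
  *bound* replicates (unbound replicates are counted and reported, never
  silently dropped), with two-sided Mann–Whitney U tests between adjacent
  conditions.  The nonparametric test is our choice: bonding times at n = 10
  are visibly skewed, and the model's own analysis names no test.  Shear
  independence is assessed by a Spearman rank correlation of bonding time
  against shear rate at α = 0.05.

## Presets and problem sizes

* `full` — 22³ r_c box, 4×10⁵ steps (8000 τ), ~31k beads: the full-scale
  geometry.
* `desk` — 12³ box, 5×10⁴ steps (1000 τ), ~5k beads: the workhorse preset
  for sweeps; a replicate takes on the order of a minute.  Rod conditions
  use a 16³ box so a γ = 15 rod (10.7 r_c long) fits between the walls.
* `mini` — 10³ box, 2.5×10⁴ steps, ~3.2k beads: the test suite's preset.
  Rod conditions use a 12³ box; the longest rod's outer chain beads then
  occasionally touch their own periodic images — a soft, transient contact
  accepted at test scale (the full-scale 22-box has the analogous margin).

A geometric caveat for reduced boxes: a 4- or 6-unit sphere with 5-r_c
ligands nearly spans the 12 r_c channel, so its chains start in wall contact
and large-particle bonding times collapse toward zero.  The size ordering
(larger binds faster) survives, but reduced-scale size sweeps exaggerate it;
only the full-scale box separates the three diameters non-degenerately.

Replicates default to 10 per condition.  Sweeps run at reduced scale are
tagged "underpowered" in their summaries rather than silently passed off as
full-power results.  Runs whose only purpose is a bound/unbound verdict may
stop early once the binding criterion is irrevocably satisfied; this changes
no adjudication, only the cost of bound replicates.

What the reduced presets preserve, and what they do not: the binding
transition in Δa, the ordering of size and shape effects, and shear
independence near the wall survive the 12-box/1000-τ reduction for strongly
binding conditions (Δa ≳ 13).  Absolute bonding times do not transfer — the
diffusion path to the wall is shorter — and *marginal* binding strengths
(Δa ≈ 11) attach more slowly than at full scale because attachment there is
driven by repeated wall visits over the full 8000 τ; desk-scale attachment
fractions at Δa ≤ 11 are therefore lower bounds on the full-scale values.

## Synthetic fixtures

The `fixtures` module generates the ground-truth scaffolds the tests run on:
an analytic two-bead system (hand-checkable pair forces), fully periodic
pure-solvent boxes (thermostat, equation-of-motion and momentum checks), and
scripted trajectories (static / constant drift / seeded random walk, with a
prescribed contact schedule) whose MSD and bonding time are known in closed
form.  They exercise every observable without running the engine, and they
emit the same CSV/XYZ formats as production code.  What they deliberately do
not emulate: hydrodynamics, real binding kinetics, or any correlation
structure of real trajectories — passing fixture tests validates the
analysis plumbing, not the physics (the engine invariants cover that).

## Numerical details

* Cell-list neighbour search (cell edge ≥ r_c) rebuilt every step with a
  counting sort; the pair set is identical to the all-pairs double loop,
  which is also the automatic fallback for boxes narrower than three cells.
* Coincident beads (r < 10⁻⁶ r_c) are skipped rather than given an arbitrary
  force direction; the one-shot force evaluator rejects them loudly.
* Forces on wall beads are never resolved (they are immobile), so wall–wall
  pair interactions are skipped.
* Frame capture at a fixed stride records NP COM, orientation quaternion,
  FE–wall contact count and kinetic temperature; full bead positions are
  optional (XYZ export) and off by default for large runs.
* Binding adjudication happens at frame resolution (default stride
  25 steps = 0.5 τ against a 20 τ dwell).

## Known limitations

* One nanoparticle per box; no NP–NP interactions or concentration effects.
* Receptors are a uniform static bead field, not discrete mobile binders;
  there is no bond-level on/off kinetics, so "binding" is adsorption in a
  repulsion-contrast well.
* The Δa ≈ 11 attachment fraction is strongly run-length dependent (see
  presets above).
* No membrane wrapping/endocytosis, no red blood cells, no vessel branching.
* The quaternion update is first order in ω Δt; adequate for the slow NP
  rotations seen here, not for stiff spinning bodies.
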