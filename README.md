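# nanodpd

Dissipative particle dynamics (DPD) simulations of ligand-coated
nanoparticles binding to a receptor-coated vascular wall under shear flow.

Targeted drug carriers are a few nanometres across: whether they attach to a
diseased vessel wall is decided by Brownian motion, ligand–receptor
chemistry, particle size and shape, and (possibly) the local blood shear.
`nanodpd` builds a coarse-grained model of this process — a rigid
nanoparticle carrying ten-bead ligand chains, explicit solvent at density 3,
a frozen receptor wall, SLLOD-imposed shear — integrates it with a
Groot–Warren DPD scheme, and measures binding statistics: bonding time,
attachment probability, mean-square displacement (MSD) and its post-binding
plateau.  It is aimed at people studying nanoparticle margination and
adhesion at the mesoscale.

## The model in brief

Beads interact within a cutoff r_c through

    f_ij = [ a_ij (r_c − r_ij) − K (r_ij − r_s) − γ w_D (ê·v_ij)
             + σ w_R ζ_ij Δt^(−1/2) ] ê,      w_D = (w_R)² = (r_c − r_ij)²,

with σ² = 2γk_bT (fluctuation–dissipation), the bead-spring term only on
bonded pairs, and reduced units r_c = m = k_bT = 1 (r_c ≙ 1 nm).  Six
species exist — ligand functional end (FE), ligand head (HL), ligand tail
(TL), nanoparticle core (NP), vascular surface (VS), water (WM) — and one
knob controls chemistry: the binding factor Δa sets the FE–VS repulsion to
25 − Δa, so Δa = 25 removes ligand–receptor repulsion entirely (strong
binding) while Δa = 0 leaves no bias toward the wall.  A replicate counts as
*bound* once ≥ 3 FE beads stay within 1 r_c of the receptor plane for 20 τ.

See `docs/methods.md` for the full model description, parameter defaults and
known limitations.

## Worked example

```python
import nanodpd as nd
from nanodpd.observables import detect_binding

# a solvent pair at half the cutoff: conservative force a_ij (1 - r) = 12.5
pair = nd.make_two_bead_system((nd.Species.WM, nd.Species.WM), separation=0.5)
print(abs(nd.compute_forces(pair)[0]).max())        # 12.5

# one reduced-geometry binding run: 12^3 box, strong binding, 1000/s shear
cfg = nd.desk_preset(delta_a=20.0, seed=3)
traj = nd.run_simulation(cfg)
event = detect_binding(traj, cfg.criterion)
print(event.bound, event.bonding_time, round(event.ultimate_msd, 1))
# True 70.0 653.4
```

The particle diffused for ~70 τ before three ligand tips gripped the
receptor plane and stayed; after binding its squared displacement fluctuates
around the plateau value printed last (dominated by the x-drift accumulated
on the way down, plus tethered wobble).

The four study sweeps are packaged as numbered drivers:

```
python analysis/01_build_system.py            # full-scale system census + XYZ
python analysis/02_validate_fluid.py          # thermostat / momentum / shear profile
python analysis/03_sweep_delta_a.py --preset desk --replicates 10
python analysis/04_sweep_shear.py   --preset desk --replicates 10
python analysis/05_sweep_size.py    --preset desk --replicates 10
python analysis/06_sweep_shape.py   --preset desk --replicates 10
```

Each writes a tidy `events.csv` (condition, seed, bound, bonding_time,
ultimate_msd, config hash) and a `summary.json` with per-condition means,
SDs, attachment probabilities with exact 95% intervals, Mann–Whitney
pairwise tests, and — for the shear family — the Spearman rank correlation
of bonding time against shear rate.  Sweeps are resumable: re-running
completes only missing replicates.  The same machinery is available from the
CLI (`nanodpd experiment run --family size --preset desk`).

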