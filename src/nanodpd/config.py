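"""Run configuration: one document describing a complete, reproducible run.

A config captures box geometry, binding factor, nanoparticle size/shape,
shear setting, run length and the master seed; serialises to/from YAML.  The
physical mapping is r_c = 1 nm and physical shear rates (s^-1) map linearly
onto reduced rates with 2000 s^-1 -> 0.1 tau^-1.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

SCHEMA_VERSION = 1

#: reduced shear rate (tau^-1) per physical s^-1; 2000 s^-1 -> 0.1 tau^-1
SHEAR_MAP = 0.1 / 2000.0


@dataclass(frozen=True)
class BindingCriterion:
    """Operational definition of 'firmly bound'.

    A replicate is bound once at least ``min_contacts`` functional-end beads
    sit within ``contact_range`` of the receptor plane continuously for at
    least ``dwell`` reduced time units.
    """

    contact_range: float = 1.0   # r_c from the wall-slab top plane
    min_contacts: int = 3
    dwell: float = 20.0          # tau

    def __post_init__(self):
        if self.contact_range <= 0 or self.min_contacts <= 0 or self.dwell <= 0:
            raise ValueError("binding criterion fields must be positive")


@dataclass(frozen=True)
class RunConfig:
    box: tuple[float, float, float] = (22.0, 22.0, 22.0)
    rho: float = 3.0
    wall_thickness: float = 1.0
    delta_a: float = 20.0
    shape: str = "sphere"            # "sphere" | "rod"
    diameter: float = 2.0            # sphere diameter / rod reference diameter
    aspect_ratio: float = 1.0
    n_chains: int | None = None      # None -> 8 area-scaled default
    shear_physical: float = 1000.0   # s^-1
    steps: int = 400_000
    stride: int = 100                # frames every `stride` steps
    dt: float = 0.02
    gamma: float = 3.0
    kT: float = 1.0
    #: fluid-wall friction multiplier enforcing no-slip at the frozen walls
    wall_gamma_mult: float = 1.0
    noise: str = "uniform"           # "uniform" | "gaussian"
    seed: int = 0
    criterion: BindingCriterion = field(default_factory=BindingCriterion)
    np_z: float | None = None        # initial NP height; None -> box centre
    save_full_every: int = 0         # extra stride multiplier for full frames

    @property
    def shear_reduced(self) -> float:
        return self.shear_physical * SHEAR_MAP

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema_version", None)
        crit = d.pop("criterion", None)
        if isinstance(crit, dict):
            d["criterion"] = BindingCriterion(**crit)
        elif crit is not None:
            d["criterion"] = crit
        if isinstance(d.get("box"), list):
            d["box"] = tuple(d["box"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha1(payload.encode()).hexdigest()[:12]

    def replace(self, **kw) -> "RunConfig":
        return dataclasses.replace(self, **kw)


def _preset(defaults: dict, kw: dict) -> RunConfig:
    merged = {**defaults, **kw}
    return RunConfig(**merged)


def full_preset(**kw) -> RunConfig:
    """The full-scale geometry: 22^3 box, 4e5 steps."""
    return _preset(dict(box=(22.0, 22.0, 22.0), steps=400_000, stride=100), kw)


def desk_preset(**kw) -> RunConfig:
    """Reduced geometry preserving the binding physics: 12^3 box, 5e4 steps.

    Rod shapes get a larger default box (16 r_c) from the experiments layer so
    high-aspect rods fit between the walls.
    """
    return _preset(dict(box=(12.0, 12.0, 12.0), steps=50_000, stride=25), kw)


def mini_preset(**kw) -> RunConfig:
    """Smallest box that still shows the binding transition; used by fast tests."""
    return _preset(dict(box=(10.0, 10.0, 10.0), steps=25_000, stride=25), kw)
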