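"""The four sweeps: binding factor, shear rate, particle size, particle shape.

Each sweep runs seeded replicate simulations per condition, adjudicates
binding, and emits a tidy events CSV plus a JSON summary.  Sweeps are
resumable: rerunning with the same output directory completes only the
missing (condition, seed) cells, and every row is traceable to its condition,
replicate seed and config hash.
"""

from __future__ import annotations

import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import RunConfig, desk_preset, full_preset, mini_preset
from .engine import run_simulation
from .observables import (
    BindingEvent,
    attachment_probability,
    detect_binding,
    sort_ascending_report,
    summarize_bonding_times,
)

PRESETS = {"full": full_preset, "desk": desk_preset, "mini": mini_preset}

#: Desk/mini boxes for rod sweeps are widened so high-aspect rods fit
#: between the walls (a gamma=15 rod is ~10.7 r_c long).
ROD_BOX = {"desk": (16.0, 16.0, 16.0), "mini": (14.0, 14.0, 14.0)}

# replicate counts are evaluated against this before trends are trusted
FULL_POWER_REPLICATES = 10


@dataclass(frozen=True)
class SweepSpec:
    """One sweep family: condition values, replicate count, base preset."""

    family: str                      # delta_a | shear | size | shape
    conditions: tuple
    replicates: int = 10
    preset: str = "desk"
    master_seed: int = 0
    overrides: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not self.conditions:
            raise ValueError("conditions must be non-empty")
        if self.family not in {"delta_a", "shear", "size", "shape"}:
            raise ValueError(f"unknown sweep family {self.family!r}")


def _condition_config(spec: SweepSpec, value) -> RunConfig:
    kw = dict(spec.overrides)
    base = PRESETS[spec.preset]
    if spec.family == "delta_a":
        kw.setdefault("delta_a", float(value))
    elif spec.family == "shear":
        kw.setdefault("delta_a", 13.0)
        kw["shear_physical"] = float(value)
        kw["delta_a"] = kw.get("delta_a", 13.0)
    elif spec.family == "size":
        kw.setdefault("delta_a", 20.0)
        kw["diameter"] = float(value)
    elif spec.family == "shape":
        kw.setdefault("delta_a", 20.0)
        if value == "sphere" or value == 1 or value == 1.0:
            kw["shape"] = "sphere"
            kw["aspect_ratio"] = 1.0
        else:
            kw["shape"] = "rod"
            kw["aspect_ratio"] = float(value)
        if "box" not in kw and spec.preset in ROD_BOX:
            kw["box"] = ROD_BOX[spec.preset]
    return base(**kw)


def _replicate_seed(spec: SweepSpec, value, rep: int) -> int:
    tag = zlib.crc32(str(value).encode())
    ss = np.random.SeedSequence([int(spec.master_seed), tag, rep])
    return int(ss.generate_state(1, np.uint32)[0]) % (2**31 - 1)


def run_sweep(spec: SweepSpec, outdir) -> pd.DataFrame:
    """Run (or resume) a sweep; returns the tidy events table.

    Columns: condition, seed, bound, bonding_time, ultimate_msd, config_hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    events_path = outdir / "events.csv"
    done = set()
    rows = []
    if events_path.exists():
        existing = pd.read_csv(events_path)
        rows = existing.to_dict("records")
        done = {(str(r["condition"]), int(r["seed"])) for r in rows}

    for value in spec.conditions:
        cfg0 = _condition_config(spec, value)
        for rep in range(spec.replicates):
            seed = _replicate_seed(spec, value, rep)
            key = (str(value), seed)
            if key in done:
                continue
            cfg = cfg0.replace(seed=seed)
            traj = run_simulation(cfg)
            ev = detect_binding(traj, cfg.criterion, seed=seed, condition=value)
            rows.append({
                "condition": value,
                "seed": seed,
                "bound": ev.bound,
                "bonding_time": ev.bonding_time,
                "ultimate_msd": ev.ultimate_msd,
                "config_hash": cfg.hash(),
            })
            pd.DataFrame(rows).to_csv(events_path, index=False)
    df = pd.DataFrame(rows)
    # normalise dtypes so fresh and resumed (CSV round-tripped) tables agree
    df["bonding_time"] = pd.to_numeric(df["bonding_time"], errors="coerce")
    df["ultimate_msd"] = pd.to_numeric(df["ultimate_msd"], errors="coerce")
    df["bound"] = df["bound"].astype(bool)
    df.to_csv(events_path, index=False)
    return df


def _events_from_table(df: pd.DataFrame) -> dict:
    groups: dict = {}
    for _, r in df.iterrows():
        bt = r["bonding_time"]
        bound = bool(r["bound"]) and not (isinstance(bt, float) and math.isnan(bt))
        ev = BindingEvent(
            bound=bound,
            bonding_time=float(bt) if bound else None,
            ultimate_msd=(float(r["ultimate_msd"])
                          if bound and not pd.isna(r["ultimate_msd"]) else None),
            seed=int(r["seed"]), condition=r["condition"],
        )
        groups.setdefault(r["condition"], []).append(ev)
    return groups


def _power_note(spec: SweepSpec) -> str:
    if spec.replicates < FULL_POWER_REPLICATES or spec.preset != "full":
        return (f"underpowered: {spec.replicates} replicates at "
                f"{spec.preset} scale")
    return "full power"


def summarize_sweep(spec: SweepSpec, df: pd.DataFrame, outdir) -> dict:
    """Condition-level summary JSON for a completed sweep."""
    outdir = Path(outdir)
    groups = _events_from_table(df)
    summary: dict = {
        "family": spec.family,
        "preset": spec.preset,
        "replicates": spec.replicates,
        "power": _power_note(spec),
        "conditions": {},
    }
    any_bound = any(e.bound for evs in groups.values() for e in evs)
    for value, evs in groups.items():
        p, ci = attachment_probability(evs)
        entry = {"n": len(evs), "attachment_probability": p,
                 "attachment_ci95": list(ci)}
        times = [e.bonding_time for e in evs if e.bound]
        if times:
            entry["mean_bonding_time"] = float(np.mean(times))
            entry["sd_bonding_time"] = (float(np.std(times, ddof=1))
                                        if len(times) > 1 else None)
        summary["conditions"][str(value)] = entry

    bound_groups = {v: evs for v, evs in groups.items()
                    if any(e.bound for e in evs)}
    if bound_groups:
        table = summarize_bonding_times(bound_groups)
        summary["pairwise_mwu"] = table.attrs["pairwise_mwu"].to_dict("records")
        sort_ascending_report(bound_groups).to_csv(
            outdir / "sorted_bonding_times.csv", index=False)

    if spec.family == "shear" and any_bound:
        sub = df[df["bound"] == True]  # noqa: E712
        if sub["condition"].nunique() >= 3:
            rho, p = stats.spearmanr(sub["condition"].astype(float),
                                     sub["bonding_time"].astype(float))
            summary["spearman_bonding_time_vs_rate"] = {
                "rho": float(rho), "p_value": float(p),
                "significant_at_0.05": bool(p < 0.05),
            }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    return summary


def sweep_delta_a(spec: SweepSpec | None = None, outdir="results/delta_a",
                  **kw) -> dict:
    """Binding-strength sweep: weak regime reports attachment probability,
    strong regime reports bonding times."""
    spec = spec or SweepSpec(family="delta_a",
                             conditions=(13, 15, 17, 19, 21, 23, 25), **kw)
    df = run_sweep(spec, outdir)
    return summarize_sweep(spec, df, outdir)


def sweep_shear(spec: SweepSpec | None = None, outdir="results/shear",
                **kw) -> dict:
    """Shear sweep at delta_a = 13; reports the rank correlation of bonding
    time against shear rate (the shear-independence check)."""
    spec = spec or SweepSpec(family="shear",
                             conditions=(0, 400, 800, 1200, 1600, 2000), **kw)
    df = run_sweep(spec, outdir)
    return summarize_sweep(spec, df, outdir)


def sweep_size(spec: SweepSpec | None = None, outdir="results/size",
               **kw) -> dict:
    """Diameter sweep {2, 4, 6} at delta_a = 20."""
    spec = spec or SweepSpec(family="size", conditions=(2.0, 4.0, 6.0), **kw)
    df = run_sweep(spec, outdir)
    return summarize_sweep(spec, df, outdir)


def sweep_shape(spec: SweepSpec | None = None, outdir="results/shape",
                **kw) -> dict:
    """Equal-volume shape sweep {sphere, rod gamma=5, 10, 15} at delta_a = 20."""
    spec = spec or SweepSpec(family="shape",
                             conditions=("sphere", 5, 10, 15), **kw)
    df = run_sweep(spec, outdir)
    return summarize_sweep(spec, df, outdir)
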