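"""Trajectory analysis: MSD, binding detection, attachment probability, group stats.

Binding is adjudicated operationally: a replicate is *bound* once at least
``min_contacts`` functional-end beads sit within ``contact_range`` of the
receptor plane continuously for at least ``dwell`` reduced time; the bonding
time is the start of the earliest such episode.  The ultimate MSD is the mean
of the displacement-squared curve after the particle has settled
(``bonding_time + dwell`` onward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import BindingCriterion
from .engine import Trajectory

__all__ = [
    "BindingCriterion", "BindingEvent", "msd", "detect_binding",
    "attachment_probability", "summarize_bonding_times",
    "sort_ascending_report",
]


@dataclass(frozen=True)
class BindingEvent:
    """Outcome of one replicate: bound or not, bonding time, plateau MSD."""

    bound: bool
    bonding_time: float | None = None
    ultimate_msd: float | None = None
    seed: int | None = None
    condition: object = None

    def __post_init__(self):
        if self.bound != (self.bonding_time is not None):
            raise ValueError("bonding_time must be present iff bound")


def msd(traj: Trajectory, reference_time: float = 0.0,
        average_origins: bool = False) -> pd.Series:
    """Squared displacement of the NP centre of mass versus time.

    By default this is the single-origin curve ``|r(t) - r(t0)|^2`` (the
    rising-then-plateau curve characteristic of a binding trajectory).  With
    ``average_origins=True`` a sliding-origin time average is returned
    instead, indexed by lag time.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames to compute an MSD")
    r = traj.com
    t = traj.times
    if average_origins:
        n = len(t)
        lags = np.arange(n)
        out = np.zeros(n)
        for k in range(n):
            d = r[k:] - r[: n - k]
            out[k] = np.mean(np.sum(d * d, axis=1))
        return pd.Series(out, index=lags * (t[1] - t[0]), name="msd")
    i0 = int(np.searchsorted(t, reference_time))
    i0 = min(i0, len(t) - 1)
    d = r - r[i0]
    return pd.Series(np.sum(d * d, axis=1), index=t, name="msd")


def detect_binding(traj: Trajectory,
                   criterion: BindingCriterion | None = None,
                   seed: int | None = None,
                   condition=None) -> BindingEvent:
    """Apply the binding criterion to a trajectory's contact-count record.

    The stored contact counts were taken against the trajectory's own
    ``contact_range`` (recorded in ``traj.meta``); only ``min_contacts`` and
    ``dwell`` are re-adjudicated here.
    """
    criterion = criterion or BindingCriterion()
    t = traj.times
    if len(t) == 0:
        raise ValueError("empty trajectory")
    ok = traj.contacts >= criterion.min_contacts

    bonding_time = None
    start = None
    for k in range(len(t) + 1):
        inside = k < len(t) and ok[k]
        if inside and start is None:
            start = k
        elif not inside and start is not None:
            if t[k - 1] - t[start] >= criterion.dwell:
                bonding_time = float(t[start])
                break
            start = None
    if bonding_time is None:
        return BindingEvent(bound=False, seed=seed, condition=condition)

    settle = bonding_time + criterion.dwell
    curve = msd(traj)
    tail = curve[curve.index >= settle]
    ultimate = float(tail.mean()) if len(tail) else None
    return BindingEvent(bound=True, bonding_time=bonding_time,
                        ultimate_msd=ultimate, seed=seed, condition=condition)


def attachment_probability(events: list[BindingEvent],
                           conf: float = 0.95):
    """Fraction of bound replicates with an exact Clopper--Pearson interval.

    Returns ``(p_hat, (lo, hi))``.
    """
    if not events:
        raise ValueError("no events")
    n = len(events)
    k = sum(e.bound for e in events)
    p = k / n
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else stats.beta.ppf(alpha / 2.0, k, n - k + 1)
    hi = 1.0 if k == n else stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k)
    return p, (float(lo), float(hi))


def summarize_bonding_times(groups: dict) -> pd.DataFrame:
    """Per-condition mean/SD of bonding times plus adjacent-pair Mann-Whitney U.

    ``groups`` maps condition label -> list of BindingEvents.  Unbound
    replicates are counted (``n_unbound``) but never enter the statistics; a
    group with no bound replicate is flagged ``no_bonding`` and excluded from
    the pairwise tests.
    """
    rows = []
    labels = list(groups)
    bound_times = {}
    for lab in labels:
        evs = groups[lab]
        if not evs:
            raise ValueError(f"group {lab!r} is empty")
        times = np.array([e.bonding_time for e in evs if e.bound], dtype=float)
        bound_times[lab] = times
        rows.append({
            "condition": lab,
            "n": len(evs),
            "n_bound": len(times),
            "n_unbound": len(evs) - len(times),
            "mean_bonding_time": times.mean() if len(times) else np.nan,
            "sd_bonding_time": times.std(ddof=1) if len(times) > 1 else np.nan,
            "no_bonding": len(times) == 0,
        })
    df = pd.DataFrame(rows).set_index("condition")

    pvals = []
    tested = [lab for lab in labels if len(bound_times[lab]) > 0]
    for a, b in zip(tested[:-1], tested[1:]):
        ta, tb = bound_times[a], bound_times[b]
        if len(ta) and len(tb):
            if np.array_equal(np.sort(ta), np.sort(tb)):
                p = 1.0   # identical samples carry no evidence
            else:
                p = float(stats.mannwhitneyu(ta, tb,
                                             alternative="two-sided").pvalue)
            pvals.append({"a": a, "b": b, "p_value": p})
    df.attrs["pairwise_mwu"] = pd.DataFrame(pvals)
    return df


def sort_ascending_report(groups: dict) -> pd.DataFrame:
    """Bonding times of bound replicates per group, sorted ascending.

    Tidy long format (condition, rank, bonding_time) for ordered-replicate
    comparison plots and CSV export.
    """
    rows = []
    for lab, evs in groups.items():
        times = sorted(e.bonding_time for e in evs if e.bound)
        if not times:
            raise ValueError(f"group {lab!r} has no bound replicate")
        for rank, bt in enumerate(times):
            rows.append({"condition": lab, "rank": rank, "bonding_time": bt})
    return pd.DataFrame(rows)
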