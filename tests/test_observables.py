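"""Observable-layer tests: MSD closed forms, binding adjudication, statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nanodpd import (
    BindingCriterion,
    BindingEvent,
    ScriptedTrajectory,
    attachment_probability,
    detect_binding,
    make_scripted_trajectory,
    msd,
    sort_ascending_report,
    summarize_bonding_times,
)


class TestMsd:
    def test_static_particle_is_zero(self):
        traj = make_scripted_trajectory(ScriptedTrajectory(motion="static"))
        assert (msd(traj) == 0).all()

    def test_pure_drift_is_quadratic(self):
        v = (0.3, -0.4, 1.2)
        traj = make_scripted_trajectory(
            ScriptedTrajectory(motion="drift", velocity=v))
        t = traj.times
        expected = (0.3**2 + 0.4**2 + 1.2**2) * t**2
        assert np.allclose(msd(traj).to_numpy(), expected)

    def test_msd_at_origin_vanishes_and_nonnegative(self):
        traj = make_scripted_trajectory(
            ScriptedTrajectory(motion="walk", step_sd=0.2, seed=5))
        curve = msd(traj)
        assert curve.iloc[0] == 0.0
        assert (curve >= 0).all()

    def test_random_walk_ensemble_slope(self):
        """For a 3-D Gaussian walk with per-axis step variance s^2 the
        expected MSD after k steps is 3 s^2 k."""
        s = 0.3
        n_frames, n_walks = 101, 400
        acc = np.zeros(n_frames)
        for k in range(n_walks):
            traj = make_scripted_trajectory(
                ScriptedTrajectory(motion="walk", step_sd=s,
                                   n_frames=n_frames, seed=k))
            acc += msd(traj).to_numpy()
        mean_curve = acc / n_walks
        ks = np.arange(n_frames)
        slope = np.sum(ks * mean_curve) / np.sum(ks * ks)
        assert slope == pytest.approx(3 * s**2, rel=0.1)

    def test_sliding_origin_average_of_drift(self):
        traj = make_scripted_trajectory(
            ScriptedTrajectory(motion="drift", velocity=(1.0, 0, 0)))
        curve = msd(traj, average_origins=True)
        lags = curve.index.to_numpy()
        assert np.allclose(curve.to_numpy(), lags**2)

    def test_single_frame_rejected(self):
        traj = make_scripted_trajectory(ScriptedTrajectory(n_frames=1))
        with pytest.raises(ValueError):
            msd(traj)


class TestDetectBinding:
    def test_attach_at_time(self):
        traj = make_scripted_trajectory(
            ScriptedTrajectory(motion="static", attach_time=100.0))
        ev = detect_binding(traj, BindingCriterion(dwell=20.0))
        assert ev.bound
        assert ev.bonding_time == pytest.approx(100.0)
        assert ev.ultimate_msd == pytest.approx(0.0)

    def test_no_contacts_never_binds(self):
        traj = make_scripted_trajectory(ScriptedTrajectory(motion="walk"))
        ev = detect_binding(traj)
        assert not ev.bound
        assert ev.bonding_time is None

    def test_short_spike_below_dwell_ignored(self):
        traj = make_scripted_trajectory(
            ScriptedTrajectory(motion="static", attach_time=50.0))
        # truncate so the contact episode lasts only 2 frames (2 time units)
        traj.contacts[traj.times > 52.0] = 0
        ev = detect_binding(traj, BindingCriterion(dwell=20.0))
        assert not ev.bound

    def test_min_contacts_threshold(self):
        traj = make_scripted_trajectory(
            ScriptedTrajectory(motion="static", attach_time=10.0,
                               contacts_after=2))
        assert not detect_binding(traj, BindingCriterion(min_contacts=3)).bound
        assert detect_binding(traj, BindingCriterion(min_contacts=2)).bound

    @given(
        contacts=st.lists(st.integers(min_value=0, max_value=5),
                          min_size=30, max_size=120),
        min_contacts=st.integers(min_value=1, max_value=4),
        dwell=st.integers(min_value=2, max_value=30),
    )
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_monotone_in_criterion_strictness(self, contacts, min_contacts,
                                              dwell):
        """Tightening the criterion never decreases bonding time and never
        converts an unbound trajectory into a bound one."""
        traj = make_scripted_trajectory(
            ScriptedTrajectory(motion="static", n_frames=len(contacts)))
        traj.contacts[:] = contacts
        loose = detect_binding(traj, BindingCriterion(
            min_contacts=min_contacts, dwell=float(dwell)))
        for tighter in (
            BindingCriterion(min_contacts=min_contacts + 1, dwell=float(dwell)),
            BindingCriterion(min_contacts=min_contacts, dwell=float(dwell + 7)),
        ):
            tight = detect_binding(traj, tighter)
            if tight.bound:
                assert loose.bound
                assert tight.bonding_time >= loose.bonding_time

    def test_empty_trajectory_rejected(self):
        traj = make_scripted_trajectory(ScriptedTrajectory(n_frames=2))
        traj.times = traj.times[:0]
        traj.contacts = traj.contacts[:0]
        with pytest.raises(ValueError):
            detect_binding(traj)


class TestAttachmentProbability:
    @staticmethod
    def _events(k, n):
        return ([BindingEvent(bound=True, bonding_time=1.0)] * k
                + [BindingEvent(bound=False)] * (n - k))

    @pytest.mark.parametrize("k,n,expected", [(7, 10, 0.7), (0, 10, 0.0),
                                              (10, 10, 1.0)])
    def test_point_estimates(self, k, n, expected):
        p, (lo, hi) = attachment_probability(self._events(k, n))
        assert p == pytest.approx(expected)
        assert lo <= p <= hi
        assert 0.0 <= lo <= hi <= 1.0

    def test_clopper_pearson_matches_beta_quantiles(self):
        p, (lo, hi) = attachment_probability(self._events(3, 10))
        assert lo == pytest.approx(stats.beta.ppf(0.025, 3, 8))
        assert hi == pytest.approx(stats.beta.ppf(0.975, 4, 7))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            attachment_probability([])


def _exact_mwu_two_sided(x, y):
    """Enumeration oracle: exact two-sided Mann-Whitney p for tiny samples."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        r = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2
        us.append(r)
    us = np.array(us)
    mu = us.mean()
    p = np.mean(np.abs(us - mu) >= abs(u_obs - mu) - 1e-12)
    return p


class TestGroupStatistics:
    def test_mean_and_sd(self):
        evs = [BindingEvent(bound=True, bonding_time=t) for t in (10, 20, 30)]
        df = summarize_bonding_times({"a": evs})
        assert df.loc["a", "mean_bonding_time"] == pytest.approx(20.0)
        assert df.loc["a", "sd_bonding_time"] == pytest.approx(10.0)

    def test_identical_groups_not_significant(self):
        evs = [BindingEvent(bound=True, bonding_time=t) for t in (5, 6, 7, 8)]
        df = summarize_bonding_times({"a": evs, "b": list(evs)})
        assert df.attrs["pairwise_mwu"]["p_value"].iloc[0] == pytest.approx(1.0)

    def test_separated_groups_significant_and_match_enumeration(self):
        x = np.arange(1.0, 11.0)
        y = np.arange(101.0, 111.0)
        ga = [BindingEvent(bound=True, bonding_time=t) for t in x]
        gb = [BindingEvent(bound=True, bonding_time=t) for t in y]
        df = summarize_bonding_times({"a": ga, "b": gb})
        p = df.attrs["pairwise_mwu"]["p_value"].iloc[0]
        assert p < 0.05
        x3, y3 = np.array([1.0, 2, 3]), np.array([11.0, 12, 13])
        p_scipy = stats.mannwhitneyu(x3, y3, alternative="two-sided",
                                     method="exact").pvalue
        assert p_scipy == pytest.approx(_exact_mwu_two_sided(x3, y3))

    def test_unbound_reported_not_dropped(self):
        evs = [BindingEvent(bound=True, bonding_time=4.0), BindingEvent(bound=False)]
        df = summarize_bonding_times({"a": evs})
        assert df.loc["a", "n_unbound"] == 1
        assert df.loc["a", "n_bound"] == 1

    def test_all_unbound_group_flagged(self):
        df = summarize_bonding_times({
            "a": [BindingEvent(bound=False)],
            "b": [BindingEvent(bound=True, bonding_time=2.0)],
        })
        assert bool(df.loc["a", "no_bonding"])
        assert len(df.attrs["pairwise_mwu"]) == 0


class TestSortedReport:
    def test_sorted_and_permutation(self):
        evs = [BindingEvent(bound=True, bonding_time=t) for t in (30, 10, 20)]
        out = sort_ascending_report({"g": evs})
        assert list(out["bonding_time"]) == [10, 20, 30]
        assert sorted(out["bonding_time"]) == sorted(
            e.bonding_time for e in evs)

    def test_singleton_unchanged(self):
        out = sort_ascending_report(
            {"g": [BindingEvent(bound=True, bonding_time=7.0)]})
        assert len(out) == 1 and out["bonding_time"].iloc[0] == 7.0


class TestBindingEventInvariant:
    def test_bonding_time_iff_bound(self):
        with pytest.raises(ValueError):
            BindingEvent(bound=True, bonding_time=None)
        with pytest.raises(ValueError):
            BindingEvent(bound=False, bonding_time=3.0)
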