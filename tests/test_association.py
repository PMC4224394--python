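"""Object-based colocalization and association/dwell analysis."""

import numpy as np
import pandas as pd
import pytest

import septrack as st
from septrack.association import AssociationEvent
from septrack.exceptions import ConfigurationError, InputError
from septrack.tracking import Track


def pts(xy, frame=None):
    df = pd.DataFrame(xy, columns=["x_px", "y_px"])
    if frame is not None:
        df.insert(0, "frame", frame)
    return df


def _track(xs, ys, start=0, tid=0):
    n = len(xs)
    return Track(
        track_id=tid,
        frames=np.arange(start, start + n),
        x=np.asarray(xs, float),
        y=np.asarray(ys, float),
        intensity=np.full(n, 100.0),
    )


def _refs(rows):
    return pd.DataFrame(rows, columns=["frame", "ref_id", "x_px", "y_px"])


class TestColocFraction:
    def test_identical_sets_fully_colocalized(self):
        a = pts([(1, 1), (5, 9), (20, 3)])
        assert st.object_coloc_fraction(a, a.copy(), 0.5) == 1.0

    def test_disjoint_sets_zero(self):
        a = pts([(0, 0), (1, 1)])
        b = pts([(30, 30), (40, 40)])
        assert st.object_coloc_fraction(a, b, 3.0) == 0.0

    def test_empty_a_is_missing(self):
        assert np.isnan(st.object_coloc_fraction(pts([]), pts([(1, 1)]), 3.0))

    def test_negative_radius_rejected(self):
        with pytest.raises(ConfigurationError):
            st.object_coloc_fraction(pts([(0, 0)]), pts([(0, 0)]), -1.0)

    def test_asymmetry(self):
        a = pts([(0.0, 0.0)])
        b = pts([(1.0, 0.0), (50.0, 50.0)])
        assert st.object_coloc_fraction(a, b, 3.0) == 1.0
        assert st.object_coloc_fraction(b, a, 3.0) == 0.5

    def test_generator_fraction_recovered_from_positions(self, control_run):
        """Configured colocalization recovered by the measurement operator
        on ground-truth positions, within binomial 3-sigma."""
        cfg, _, result = control_run
        truth = result.truth
        tr = truth.tracks
        refs_by_frame = {f: g for f, g in truth.ref_positions.groupby("frame")}
        hits = total = 0
        for f, grp in tr.groupby("frame"):
            rg = refs_by_frame.get(f)
            frac = st.object_coloc_fraction(grp, rg, cfg.ref_channel.radius_px)
            hits += frac * len(grp)
            total += len(grp)
        p = cfg.ref_channel.coloc_fraction
        assert total >= 5000
        assert abs(hits / total - p) <= 3 * np.sqrt(p * (1 - p) / total)


class TestColocTimeCourse:
    def test_identical_channels_flat_at_one(self):
        rows = [(f, x, 2.0) for f in range(12) for x in (1.0, 8.0)]
        a = pd.DataFrame(rows, columns=["frame", "x_px", "y_px"])
        tc = st.coloc_time_course(a, a.copy(), radius_px=1.0, bin_frames=3)
        assert (tc.fraction == 1.0).all()
        assert (tc.n_objects == 6).all()

    def test_zero_radius_with_noise_is_zero(self, rng):
        a = pd.DataFrame(
            {"frame": np.repeat(np.arange(20), 3), "x_px": rng.uniform(0, 50, 60),
             "y_px": rng.uniform(0, 50, 60)}
        )
        b = a.copy()
        b["x_px"] += rng.normal(0, 0.1, len(b))
        tc = st.coloc_time_course(a, b, radius_px=0.0)
        assert tc.fraction.fillna(0).sum() == 0.0

    def test_empty_series(self):
        empty = pd.DataFrame(columns=["frame", "x_px", "y_px"])
        assert len(st.coloc_time_course(empty, empty, 3.0)) == 0


class TestAssociationRuns:
    def test_full_overlap_is_one_censored_event(self):
        t = _track(np.full(10, 5.0), np.full(10, 5.0))
        refs = _refs([(f, 0, 5.5, 5.0) for f in range(10)])
        events = st.association_runs(t, refs, radius_px=3.0, frame_interval_ms=154.0)
        assert len(events) == 1
        e = events[0]
        assert e.dwell_s == pytest.approx(1.54)
        assert e.censored_start and e.censored_end and e.censored

    def test_one_frame_break_with_zero_gap_splits(self):
        xs = np.full(9, 5.0)
        xs[4] = 20.0  # leaves the radius for one frame
        t = _track(xs, np.full(9, 5.0))
        refs = _refs([(f, 0, 5.0, 5.0) for f in range(9)])
        events = st.association_runs(t, refs, radius_px=3.0, frame_interval_ms=154.0,
                                     max_gap_frames=0)
        assert len(events) == 2

    def test_one_frame_break_with_gap_one_merges(self):
        xs = np.full(9, 5.0)
        xs[4] = 20.0
        t = _track(xs, np.full(9, 5.0))
        refs = _refs([(f, 0, 5.0, 5.0) for f in range(9)])
        events = st.association_runs(t, refs, radius_px=3.0, frame_interval_ms=154.0,
                                     max_gap_frames=1)
        assert len(events) == 1
        assert events[0].n_gap_frames == 1

    def test_sticky_assignment_keeps_current_ref(self):
        # two refs both within radius; the track starts nearer ref 0 and
        # drifts toward ref 1 while staying in range of ref 0
        t = _track([4.0, 4.5, 5.0, 5.5, 6.0], np.zeros(5))
        refs = _refs(
            [(f, 0, 4.0, 0.0) for f in range(5)] + [(f, 1, 6.5, 0.0) for f in range(5)]
        )
        events = st.association_runs(t, refs, radius_px=3.0, frame_interval_ms=100.0)
        assert len(events) == 1
        assert events[0].ref_id == 0

    def test_frame_bookkeeping_conservation(self, control_run):
        cfg, _, result = control_run
        for track in result.tracks[:20]:
            events = st.association_runs(
                track, result.refs, radius_px=3.0,
                frame_interval_ms=cfg.frame_interval_ms, max_gap_frames=1,
            )
            in_events = sum(e.n_frames - e.n_gap_frames for e in events)
            gaps = sum(e.n_gap_frames for e in events)
            assert in_events + gaps <= len(track)


class TestDwellStats:
    @staticmethod
    def _event(dwell_s, censored=False, n_frames=10):
        return AssociationEvent(
            track_id=0, ref_id=0, start_frame=100, end_frame=100 + n_frames - 1,
            dwell_s=dwell_s, censored_start=censored, censored_end=False,
        )

    def test_mean_of_uncensored_events(self):
        stats = st.dwell_stats([self._event(2.0), self._event(4.0)])
        assert stats.mean_s == pytest.approx(3.0)
        assert stats.n == 2

    def test_all_censored_with_exclude_raises(self):
        with pytest.raises(InputError):
            st.dwell_stats([self._event(2.0, censored=True)])

    def test_censored_included_on_request(self):
        stats = st.dwell_stats(
            [self._event(2.0, censored=True), self._event(4.0)], censoring="include"
        )
        assert stats.n == 2

    def test_empty_input_raises(self):
        with pytest.raises(InputError):
            st.dwell_stats([])

    def test_min_frames_drops_short_passes(self):
        events = [self._event(60.0, n_frames=120), self._event(0.5, n_frames=1)]
        stats = st.dwell_stats(events, min_frames=3)
        assert stats.n == 1
        assert stats.mean_s == pytest.approx(60.0)

    def test_frame_unit_invariance(self):
        """Dwells expressed in frames do not depend on the frame interval."""
        t = _track(np.full(8, 5.0), np.full(8, 5.0))
        refs = _refs([(f, 0, 5.0, 5.0) for f in range(8)])
        for dt in (154.0, 475.0):
            (e,) = st.association_runs(t, refs, radius_px=3.0, frame_interval_ms=dt)
            assert e.n_frames == 8
            assert e.dwell_s == pytest.approx(8 * dt / 1000.0)
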