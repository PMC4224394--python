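"""Frame linking, track assembly and the track-length filter."""

import itertools

import numpy as np
import pandas as pd
import pytest

import septrack as st
from septrack.exceptions import ConfigurationError, InputError
from septrack.tracking import LinkParams, Track


def dets(rows):
    """Detection table from (frame, x, y, intensity) tuples."""
    return pd.DataFrame(rows, columns=["frame", "x_px", "y_px", "intensity"])


def brute_force_assignment(a, b, params):
    """Enumerate every gate-feasible one-to-one partial assignment and
    return (max cardinality, min total cost at that cardinality)."""
    ax = a[["x_px", "y_px"]].to_numpy()
    bx = b[["x_px", "y_px"]].to_numpy()
    ia, ib = a.intensity.to_numpy(), b.intensity.to_numpy()
    scale = params.intensity_scale
    feasible = {}
    for i in range(len(a)):
        for j in range(len(b)):
            d = np.hypot(*(ax[i] - bx[j]))
            if d <= params.gate_radius_px:
                feasible[(i, j)] = (
                    params.w_dist * d / params.gate_radius_px
                    + params.w_int * abs(ia[i] - ib[j]) / scale
                )
    best = (0, 0.0)
    cols = list(range(len(b)))
    for k in range(min(len(a), len(b)), -1, -1):
        found = False
        best_cost = np.inf
        for rows in itertools.combinations(range(len(a)), k):
            for perm in itertools.permutations(cols, k):
                pairs = list(zip(rows, perm))
                if all(p in feasible for p in pairs):
                    found = True
                    best_cost = min(best_cost, sum(feasible[p] for p in pairs))
        if found:
            return k, best_cost
    return best


def link_cardinality_cost(a, b, params):
    links = st.link_frames(a, b, params)
    ax = a[["x_px", "y_px"]].to_numpy()
    bx = b[["x_px", "y_px"]].to_numpy()
    cost = sum(
        params.w_dist * np.hypot(*(ax[i] - bx[j])) / params.gate_radius_px
        + params.w_int
        * abs(a.intensity.iloc[i] - b.intensity.iloc[j])
        / params.intensity_scale
        for i, j in links
    )
    return len(links), cost


class TestLinkFrames:
    def test_single_pair_within_gate_links(self):
        a = dets([(0, 10, 10, 100)])
        b = dets([(1, 12, 11, 100)])
        assert st.link_frames(a, b) == [(0, 0)]

    def test_crossing_spots_follow_intensity_identity(self):
        """Two detections swap positions; with the intensity term active
        the cheaper assignment (enumerated by hand) keeps identities."""
        a = dets([(0, 10, 10, 100), (0, 13, 10, 200)])
        b = dets([(1, 13, 10, 100), (1, 10, 10, 200)])
        # identity-preserving: dist 3+3 -> cost 2*3/5 = 1.2, no dI term
        # proximity-preserving: dist 0, dI 100+100 -> 0.5*200/scale
        # at scale 50 that is 2.0 > 1.2, so identities must be kept
        params = LinkParams(gate_radius_px=5.0, w_dist=1.0, w_int=0.5, intensity_scale=50.0)
        assert sorted(st.link_frames(a, b, params)) == [(0, 0), (1, 1)]
        # at scale 1000 the intensity term is negligible and proximity wins
        weak = LinkParams(gate_radius_px=5.0, w_dist=1.0, w_int=0.5, intensity_scale=1000.0)
        assert sorted(st.link_frames(a, b, weak)) == [(0, 1), (1, 0)]

    def test_beyond_gate_is_death_plus_birth(self):
        a = dets([(0, 10, 10, 100)])
        b = dets([(1, 30, 30, 100)])
        assert st.link_frames(a, b, LinkParams(gate_radius_px=5.0)) == []

    def test_empty_inputs(self):
        a = dets([])
        b = dets([(1, 5, 5, 50)])
        assert st.link_frames(a, a) == []
        assert st.link_frames(a, b) == []

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, m = rng.integers(0, 7, size=2)
        params = LinkParams(gate_radius_px=6.0, w_dist=1.0, w_int=0.5, intensity_scale=100.0)
        a = dets([(0, *rng.uniform(0, 20, 2), rng.uniform(50, 300)) for _ in range(n)])
        b = dets([(1, *rng.uniform(0, 20, 2), rng.uniform(50, 300)) for _ in range(m)])
        bk, bc = brute_force_assignment(a, b, params)
        lk, lc = link_cardinality_cost(a, b, params)
        assert lk == bk
        assert lc == pytest.approx(bc, abs=1e-9)


class TestBuildTracks:
    def test_stationary_detection_yields_single_track(self):
        d = dets([(f, 10.0, 10.0, 100.0) for f in range(10)])
        tracks = st.build_tracks(d)
        assert len(tracks) == 1
        assert len(tracks[0]) == 10

    def test_missing_frame_splits_never_bridged(self):
        d = dets([(f, 10.0, 10.0, 100.0) for f in range(10) if f != 5])
        tracks = st.build_tracks(d)
        lengths = sorted(len(t) for t in tracks)
        assert lengths == [4, 5]
        spans = sorted((t.start_frame, t.end_frame) for t in tracks)
        assert spans == [(0, 4), (6, 9)]

    def test_detection_conservation(self):
        rng = np.random.default_rng(3)
        rows = []
        for f in range(20):
            for _ in range(rng.integers(1, 5)):
                rows.append((f, *rng.uniform(0, 40, 2), rng.uniform(50, 150)))
        d = dets(rows)
        tracks = st.build_tracks(d)
        in_tracks = sum(len(t) for t in tracks)
        assert in_tracks <= len(d)  # remainder are discarded singletons
        # every tracked detection is one of the inputs, used exactly once
        used = set()
        key = {(f, round(x, 9), round(y, 9)) for f, x, y in zip(d.frame, d.x_px, d.y_px)}
        for t in tracks:
            for f, x, y in zip(t.frames, t.x, t.y):
                k = (f, round(x, 9), round(y, 9))
                assert k in key and k not in used
                used.add(k)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(4)
        rows = []
        for f in range(15):
            for _ in range(4):
                rows.append((f, *rng.uniform(0, 50, 2), rng.uniform(50, 150)))
        d = dets(rows)
        shuffled = d.sample(frac=1.0, random_state=7).reset_index(drop=True)
        t1 = {
            tuple(zip(t.frames, np.round(t.x, 9), np.round(t.y, 9)))
            for t in st.build_tracks(d)
        }
        t2 = {
            tuple(zip(t.frames, np.round(t.x, 9), np.round(t.y, 9)))
            for t in st.build_tracks(shuffled)
        }
        assert t1 == t2

    def test_non_integer_frames_rejected(self):
        d = dets([(0.5, 1.0, 1.0, 10.0)])
        with pytest.raises(InputError):
            st.build_tracks(d)


class TestFilterTracks:
    @staticmethod
    def _track(n):
        return Track(
            track_id=0,
            frames=np.arange(n),
            x=np.zeros(n),
            y=np.zeros(n),
            intensity=np.ones(n),
        )

    def test_five_frame_track_removed(self):
        assert st.filter_tracks([self._track(5)], min_frames=6) == []

    def test_six_frame_track_retained(self):
        assert len(st.filter_tracks([self._track(6)], min_frames=6)) == 1

    def test_empty_input(self):
        assert st.filter_tracks([], min_frames=6) == []

    def test_min_frames_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            st.filter_tracks([self._track(6)], min_frames=1)
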