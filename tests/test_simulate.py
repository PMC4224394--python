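"""Synthetic-movie generator: filament field, motion model, rendering."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

import septrack as st
from septrack.exceptions import ConfigurationError


class TestFilamentField:
    def test_zero_filaments_gives_empty_field(self):
        cfg = st.SimConfig(n_filaments=0, seed=1)
        field = st.make_filament_field(cfg)
        assert field.filaments == ()

    def test_deterministic_for_fixed_seed(self):
        cfg = st.SimConfig(n_filaments=5, seed=9)
        f1 = st.make_filament_field(cfg)
        f2 = st.make_filament_field(cfg)
        assert len(f1.filaments) == len(f2.filaments)
        for a, b in zip(f1.filaments, f2.filaments):
            assert np.array_equal(a, b)

    def test_polylines_clipped_to_field(self):
        cfg = st.SimConfig(field_size_px=(128, 128), n_filaments=5, seed=3)
        field = st.make_filament_field(cfg)
        assert len(field.filaments) == 5
        for poly in field.filaments:
            assert poly.shape[0] >= 2
            assert np.all(poly >= 0.0) and np.all(poly < 128.0)


class TestSimulateTracks:
    def test_motile_only_mean_step_length(self):
        """With binding made negligible, the mean true step equals the
        configured speed converted to px/frame (1000*0.154/143 px)."""
        cfg = st.SimConfig(
            n_frames=400,
            n_objects=10,
            motile_speed_um_s=1.0,
            pixel_size_nm=143.0,
            frame_interval_ms=154.0,
            bound_dwell_s=1e-6,
            free_dwell_s=1e9,
            seed=4,
        )
        truth = st.simulate_tracks(cfg)
        xy = truth.tracks[["x_px", "y_px"]].to_numpy().reshape(10, 400, 2)
        steps = np.hypot(*(np.diff(xy, axis=1).transpose(2, 0, 1)))
        motile = truth.tracks.state.to_numpy().reshape(10, 400)[:, :-1] == "motile"
        assert motile.mean() > 0.999
        # steps folded at the reflective boundary shorten the chord, so the
        # exact arithmetic value holds for interior steps
        interior = (
            (xy[:, :-1] > 2).all(axis=2)
            & (xy[:, 1:] > 2).all(axis=2)
            & (xy[:, :-1] < 125).all(axis=2)
            & (xy[:, 1:] < 125).all(axis=2)
        )
        sel = motile & interior
        assert sel.sum() > 1000
        assert steps[sel].mean() == pytest.approx(1000 * 0.154 / 143.0, rel=1e-6)

    def test_bound_only_steps_stay_within_jitter(self):
        cfg = st.SimConfig(
            n_frames=300,
            n_objects=8,
            bound_dwell_s=1e9,
            free_dwell_s=1e-6,
            localization_jitter_px=0.3,
            seed=5,
        )
        truth = st.simulate_tracks(cfg)
        xy = truth.tracks[["x_px", "y_px"]].to_numpy().reshape(8, 300, 2)
        steps = np.hypot(*(np.diff(xy, axis=1).transpose(2, 0, 1)))
        # steps are differences of two independent jitters: sd = sqrt(2)*0.3
        assert np.quantile(steps, 0.999) <= 4 * 0.3 * np.sqrt(2)

    def test_completed_bound_dwell_matches_exponential_mean(self):
        """Law of large numbers on completed sojourns, in an acquisition
        long relative to the dwell so truncation bias is negligible."""
        cfg = st.control_config(
            seed=6, n_frames=6000, n_objects=10, bound_dwell_s=20.0
        )
        truth = st.simulate_tracks(cfg)
        bi = truth.bound_intervals
        dur = (bi.end_frame - bi.start_frame + 1) * cfg.frame_interval_s
        completed = dur[bi.completed]
        assert len(completed) > 200
        assert completed.mean() == pytest.approx(20.0, rel=0.15)

    def test_association_intervals_within_bounds_and_disjoint(self, control_run):
        cfg, _, result = control_run
        ti = result.truth.association_intervals
        assert (ti.start_frame <= ti.end_frame).all()
        assert (ti.start_frame >= 0).all() and (ti.end_frame < cfg.n_frames).all()
        for _, grp in ti.groupby("object_id"):
            grp = grp.sort_values("start_frame")
            assert (grp.start_frame.to_numpy()[1:] > grp.end_frame.to_numpy()[:-1]).all()

    def test_coloc_fraction_recovered_within_binomial_error(self):
        cfg = st.control_config(seed=11)  # 12 objects x 600 frames > 5000
        truth = st.simulate_tracks(cfg)
        ti = truth.association_intervals
        n = cfg.n_objects * cfg.n_frames
        covered = (ti.end_frame - ti.start_frame + 1).sum() / n
        target = cfg.ref_channel.coloc_fraction
        assert abs(covered - target) <= 3 * np.sqrt(target * (1 - target) / n)

    def test_invalid_motion_config_rejected(self):
        with pytest.raises(ConfigurationError):
            st.SimConfig(motile_speed_um_s=0.0)
        with pytest.raises(ConfigurationError):
            st.SimConfig(bound_dwell_s=-1.0)
        with pytest.raises(ConfigurationError):
            st.SimConfig(n_frames=1)


class TestRenderMovie:
    def test_zero_objects_background_only(self):
        cfg = st.SimConfig(n_frames=10, n_objects=0, background=50.0, seed=7)
        movie, _ = st.simulate_movie(cfg)
        coat = movie.channel("coat")
        se = np.sqrt(50.0 / coat[0].size)
        assert abs(coat[0].mean() - 50.0) < 3 * se

    def test_bleach_constant_recovered_by_exponential_fit(self):
        cfg = st.SimConfig(
            n_frames=300,
            n_objects=5,
            bleach_tau_frames=200.0,
            read_noise_sd=0.0,
            seed=8,
        )
        movie, _ = st.simulate_movie(cfg)
        means = movie.channel("coat").mean(axis=(1, 2))
        t = np.arange(len(means))
        popt, _ = curve_fit(
            lambda t, a, tau: a * np.exp(-t / tau), t, means, p0=(means[0], 150.0)
        )
        assert popt[1] == pytest.approx(200.0, rel=0.10)

    def test_fixed_seed_bit_identical(self):
        cfg = st.control_config(seed=5, n_frames=30)
        m1, t1 = st.simulate_movie(cfg)
        m2, t2 = st.simulate_movie(cfg)
        assert np.array_equal(m1.data, m2.data)
        assert t1.tracks.equals(t2.tracks)
        assert t1.association_intervals.equals(t2.association_intervals)

    def test_transient_mode_peaks_in_configured_window(self):
        """With a ramp-up/ramp-down association profile, the ground-truth
        colocalization time course peaks inside the high-probability window."""
        n = 1200
        profile = np.zeros(n)
        profile[n // 3 : 2 * n // 3] = 0.9
        profile[: n // 3] = 0.1
        profile[2 * n // 3 :] = 0.1
        cfg = st.control_config(
            seed=13, n_frames=n, n_objects=12, coloc_profile=tuple(profile)
        )
        truth = st.simulate_tracks(cfg)
        ti = truth.association_intervals
        per_frame = np.zeros(n)
        for iv in ti.itertuples():
            per_frame[iv.start_frame : iv.end_frame + 1] += 1
        thirds = per_frame.reshape(3, n // 3).sum(axis=1)
        assert thirds[1] > thirds[0] and thirds[1] > thirds[2]
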