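"""Descriptor-panel tests: speed traces, thresholds, episodes, summaries."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vialtrack.kinematics import (
    KinematicsError,
    VialKinetics,
    average_replicates,
    compute_speed_trace,
    percent_in_motion,
    segment_walk_episodes,
    summarize_vial,
)
from vialtrack.synthetic_arena import straight_track
from vialtrack.tracking import Track

FPS = 30.0


def track_from_speeds(raw_speeds_mm_s, fps=FPS):
    """Build a straight-line track whose raw per-frame speeds are given."""
    steps = np.asarray(raw_speeds_mm_s, dtype=float) / fps
    y = np.concatenate(([0.0], np.cumsum(steps)))
    n = len(y)
    return Track(0, 0, np.arange(n), np.arange(n) / fps,
                 np.zeros(n), y, np.zeros(n, dtype=bool))


class TestSpeedTrace:
    def test_constant_advance(self):
        tr = track_from_speeds([3.0] * 30)
        trace = compute_speed_trace(tr, FPS, window_frames=1)
        np.testing.assert_allclose(trace.speed_mm_s, 3.0)

    def test_stationary_all_zero(self):
        tr = track_from_speeds([0.0] * 30)
        trace = compute_speed_trace(tr, FPS)
        np.testing.assert_array_equal(trace.speed_mm_s, 0.0)

    def test_sawtooth_smoothing_matches_hand_average(self):
        rng = np.random.default_rng(4)
        raw = np.where(np.arange(40) % 2 == 0, 3.0, 1.0) + rng.uniform(0, 0.1, 40)
        tr = track_from_speeds(raw)
        trace = compute_speed_trace(tr, FPS, window_frames=5)
        # independent hand computation of the truncated moving average
        expected = np.array([
            trace.raw_speed_mm_s[max(i - 2, 0):min(i + 3, 40)].mean()
            for i in range(40)
        ])
        np.testing.assert_allclose(trace.speed_mm_s, expected, atol=1e-9)

    def test_even_window_rejected(self):
        with pytest.raises(KinematicsError, match="odd"):
            compute_speed_trace(track_from_speeds([1.0] * 5), FPS, window_frames=4)

    def test_short_track_rejected(self):
        tr = Track(0, 0, np.array([0]), np.array([0.0]), np.array([0.0]),
                   np.array([0.0]), np.array([False]))
        with pytest.raises(KinematicsError, match=">= 2"):
            compute_speed_trace(tr, FPS)

    def test_gapped_track_rejected(self):
        tr = Track(0, 0, np.array([0, 2, 3]), np.zeros(3), np.zeros(3),
                   np.zeros(3), np.zeros(3, dtype=bool))
        with pytest.raises(KinematicsError, match="spacing"):
            compute_speed_trace(tr, FPS)


class TestPercentInMotion:
    def trace(self, speeds):
        return compute_speed_trace(track_from_speeds(speeds), FPS, window_frames=1)

    def test_always_moving(self):
        assert percent_in_motion([self.trace([5.0] * 30)], 2.5) == 100.0

    def test_exactly_at_cutoff_is_not_motion(self):
        # "faster than" is strict: sitting on the cutoff counts as no motion
        assert percent_in_motion([self.trace([2.5] * 30)], 2.5) == 0.0

    def test_half_and_half(self):
        assert percent_in_motion([self.trace([5.0] * 15 + [1.0] * 15)], 2.5) == 50.0

    def test_negative_cutoff_rejected(self):
        with pytest.raises(KinematicsError):
            percent_in_motion([self.trace([1.0] * 5)], -1.0)

    def test_monotone_in_cutoff(self):
        rng = np.random.default_rng(9)
        tr = self.trace(rng.uniform(0, 8, 100))
        values = [percent_in_motion([tr], c) for c in np.linspace(0, 8, 20)]
        assert all(a >= b for a, b in zip(values, values[1:]))


class TestSegmentEpisodes:
    def trace(self, speeds):
        return compute_speed_trace(track_from_speeds(speeds), FPS, window_frames=1)

    def test_full_recording_single_episode(self):
        eps = segment_walk_episodes(self.trace([5.0] * 300), 2.0, 0.0)
        assert len(eps) == 1
        assert eps[0].duration_s == pytest.approx(10.0)
        assert eps[0].path_length_mm == pytest.approx(50.0)

    def test_slow_trace_no_episodes(self):
        assert segment_walk_episodes(self.trace([1.0] * 300), 2.0, 0.0) == []

    def test_run_length_enumeration(self):
        eps = segment_walk_episodes(self.trace([3, 3, 1, 3, 3]), 2.0, 0.0)
        assert [(e.start_frame, e.end_frame) for e in eps] == [(0, 1), (3, 4)]
        for e in eps:
            assert e.duration_s == pytest.approx(2 / FPS)
            assert e.path_length_mm == pytest.approx(2 * 3.0 / FPS)

    def test_exactly_at_threshold_counts_as_walking(self):
        # "below 2 mm/s" is excluded, so 2.0 itself walks (non-strict >=)
        eps = segment_walk_episodes(self.trace([2.0] * 30), 2.0, 0.0)
        assert len(eps) == 1

    def test_min_episode_filter(self):
        speeds = [3, 3, 3, 3, 3, 3, 0, 3, 3]  # 6-frame and 2-frame runs
        eps = segment_walk_episodes(self.trace(speeds), 2.0, min_episode_s=5 / FPS)
        assert len(eps) == 1 and eps[0].start_frame == 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(KinematicsError):
            segment_walk_episodes(self.trace([1.0] * 5), -2.0, 0.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        tr = self.trace(rng.uniform(0, 8, 200))
        prev_dur, prev_n = np.inf, np.inf
        for thr in np.linspace(0.5, 6.0, 12):
            eps = segment_walk_episodes(tr, thr, 0.0)
            dur = sum(e.duration_s for e in eps)
            assert dur <= prev_dur + 1e-12
            prev_dur = dur


class TestSummarizeVial:
    def test_single_fly_closed_form(self):
        tr = straight_track(5.0, duration_s=10.0, fps=FPS)
        kin = summarize_vial([tr], fly_count=1, fps=FPS)
        assert kin.mean_velocity_mm_s == pytest.approx(5.0)
        assert kin.max_velocity_mm_s == pytest.approx(5.0)
        assert kin.total_walking_duration_s == pytest.approx(10.0)
        assert kin.total_walking_distance_mm == pytest.approx(50.0)
        assert kin.percent_time_in_motion == pytest.approx(100.0)
        assert kin.n_trajectories == 1
        assert kin.mean_trajectory_length_mm == pytest.approx(50.0)
        assert kin.mean_trajectory_length_per_episode_mm == pytest.approx(50.0)

    def test_all_stationary_zeros(self):
        tr = track_from_speeds([0.0] * 60)
        kin = summarize_vial([tr], fly_count=5, fps=FPS)
        assert kin.fly_count == 5
        for f in ("mean_velocity_mm_s", "max_velocity_mm_s",
                  "total_walking_duration_s", "total_walking_distance_mm",
                  "percent_time_in_motion", "mean_trajectory_length_mm",
                  "mean_trajectory_length_per_episode_mm", "n_trajectories"):
            assert getattr(kin, f) == 0.0

    def test_zero_fly_count_with_tracks_rejected(self):
        tr = track_from_speeds([1.0] * 30)
        with pytest.raises(KinematicsError, match="fly_count"):
            summarize_vial([tr], fly_count=0, fps=FPS)

    def test_conservation_identities(self, pipeline):
        for vial in range(4):
            tracks = [t for t in pipeline.tracks if t.vial_id == vial]
            kin = summarize_vial(tracks, pipeline.counts[vial], pipeline.config.fps)
            if kin.n_trajectories > 0:
                assert kin.n_trajectories * kin.mean_trajectory_length_per_episode_mm \
                    == pytest.approx(kin.total_walking_distance_mm, rel=1e-9)
            assert kin.fly_count * kin.mean_trajectory_length_mm \
                == pytest.approx(kin.total_walking_distance_mm, rel=1e-9)

    @given(st.floats(min_value=0.1, max_value=10.0))
    @settings(max_examples=30, deadline=None)
    def test_threshold_boundary_behavior(self, v):
        tr = straight_track(v, duration_s=2.0, fps=FPS)
        kin = summarize_vial([tr], fly_count=1, fps=FPS,
                             params={"min_episode_s": 0.0})
        if v <= 2.5:
            assert kin.percent_time_in_motion == 0.0
        else:
            assert kin.percent_time_in_motion == 100.0
        if v >= 2.0:
            assert kin.total_walking_duration_s > 0.0
        else:
            assert kin.total_walking_duration_s == 0.0


class TestAverageReplicates:
    def kin(self, vial=0, mean=4.0, fly_count=10):
        return VialKinetics(
            vial_id=vial, fly_count=fly_count, mean_velocity_mm_s=mean,
            max_velocity_mm_s=2 * mean, total_walking_duration_s=5.0,
            total_walking_distance_mm=100.0, percent_time_in_motion=50.0,
            mean_trajectory_length_mm=10.0,
            mean_trajectory_length_per_episode_mm=5.0,
            n_trajectories=20.0, n_trajectories_per_fly=2.0,
        )

    def test_identical_replicates(self):
        a = self.kin()
        assert average_replicates(a, self.kin()) == a

    def test_mean_of_velocities(self):
        avg = average_replicates(self.kin(mean=4.0), self.kin(mean=6.0))
        assert avg.mean_velocity_mm_s == 5.0

    def test_commutative(self):
        a, b = self.kin(mean=3.3), self.kin(mean=7.7)
        assert average_replicates(a, b) == average_replicates(b, a)

    def test_fly_count_min_and_flag(self):
        avg = average_replicates(self.kin(fly_count=10), self.kin(fly_count=9))
        assert avg.fly_count == 9
        assert avg.fly_count_mismatch

    def test_vial_mismatch_rejected(self):
        with pytest.raises(KinematicsError, match="vial"):
            average_replicates(self.kin(vial=0), self.kin(vial=1))


def test_noisy_render_descriptors_within_ten_percent():
    """Recovery with default rendering noise stays within 10%."""
    from conftest import truth_as_track
    from vialtrack import detection, tracking
    from vialtrack.kinematics import DESCRIPTOR_FIELDS
    from vialtrack.synthetic_arena import (
        SimulationConfig, render_frames, simulate_cohort)

    cfg = SimulationConfig(n_vials=2, flies_per_vial=10, duration_s=10.0,
                           min_separation_mm=2.5, noise_sd=3.0, seed=21)
    truth = simulate_cohort(cfg)
    frames = render_frames(truth, cfg)
    bg = detection.estimate_background(frames, quantile=0.75)
    regions = [detection.calibrate(r, cfg.tube_length_mm, cfg.tube_width_mm)
               for r in detection.segment_vials(bg, cfg.n_vials)]
    dets = detection.detect_sequence(frames, regions, background=bg)
    tracks = tracking.build_tracks(dets, fps=cfg.fps)
    for vial in range(cfg.n_vials):
        count = detection.count_flies(dets, vial)
        tracked = summarize_vial([t for t in tracks if t.vial_id == vial],
                                 count, cfg.fps)
        reference = summarize_vial(
            [truth_as_track(t) for t in truth if t.vial_id == vial],
            cfg.flies_per_vial, cfg.fps)
        for name in DESCRIPTOR_FIELDS:
            assert getattr(tracked, name) == pytest.approx(
                getattr(reference, name), rel=0.10, abs=1e-9), (vial, name)


def test_tracked_descriptors_match_ground_truth(pipeline):
    """Parameter recovery: descriptors from the tracked noise-free video
    stay within 5% of descriptors computed on the exact trajectories."""
    from conftest import truth_as_track
    from vialtrack.kinematics import DESCRIPTOR_FIELDS

    for vial in range(4):
        tracked = summarize_vial(
            [t for t in pipeline.tracks if t.vial_id == vial],
            pipeline.counts[vial], pipeline.config.fps)
        truth = summarize_vial(
            [truth_as_track(t) for t in pipeline.truth if t.vial_id == vial],
            pipeline.config.flies_per_vial, pipeline.config.fps)
        for name in DESCRIPTOR_FIELDS:
            ref = getattr(truth, name)
            got = getattr(tracked, name)
            assert got == pytest.approx(ref, rel=0.05, abs=1e-9), name
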