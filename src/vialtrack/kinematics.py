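"""Kinetic descriptor panel: speed traces, walking episodes, vial summaries.

Two thresholds drive the panel: speeds below 2.0 mm/s are not progressive
movement (walking-episode membership, non-strict >=), and "time in motion"
counts frames strictly faster than the 2.5 mm/s cutoff. Vial totals are
normalized by the detector-derived fly count so vials with different
survivor numbers stay comparable.

Threshold comparisons use a 1e-9 mm/s guard band so that trajectories
constructed to sit exactly on a threshold classify by the stated convention
rather than by floating-point rounding of position differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from vialtrack.tracking import Track

#: numeric guard band for threshold comparisons, mm/s
SPEED_TOL = 1e-9

DEFAULT_PARAMS = {
    "walk_threshold_mm_s": 2.0,
    "motion_cutoff_mm_s": 2.5,
    "min_episode_s": 0.2,
    "smoothing_window_frames": 5,
}


class KinematicsError(ValueError):
    """Invalid trace, threshold, or summary input."""


@dataclass
class SpeedTrace:
    """Per-frame speeds of one track. ``frames[i]`` indexes the interval
    from point i to i+1; ``speed_mm_s`` is the (optionally smoothed) trace
    used for classification, ``raw_speed_mm_s`` the unsmoothed one used for
    path lengths."""

    frames: np.ndarray
    speed_mm_s: np.ndarray
    raw_speed_mm_s: np.ndarray
    fps: float
    smoothed: bool
    window_frames: int


@dataclass
class WalkEpisode:
    """A maximal run of frames at or above the walking threshold."""

    start_frame: int
    end_frame: int  # inclusive
    duration_s: float
    path_length_mm: float


@dataclass
class VialKinetics:
    """The descriptor panel for one recording of one vial.

    ``n_trajectories`` is the raw episode count (so that
    n_trajectories x mean_trajectory_length_per_episode_mm =
    fly_count x mean_trajectory_length_mm = total_walking_distance_mm);
    ``n_trajectories_per_fly`` is the count-normalized figure.
    ``total_walking_duration_s`` is per fly. It is a float after replicate
    averaging, hence the numeric type.
    """

    vial_id: int
    fly_count: int
    mean_velocity_mm_s: float
    max_velocity_mm_s: float
    total_walking_duration_s: float
    total_walking_distance_mm: float
    percent_time_in_motion: float
    mean_trajectory_length_mm: float
    mean_trajectory_length_per_episode_mm: float
    n_trajectories: float
    n_trajectories_per_fly: float
    fly_count_mismatch: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_time_in_motion <= 100.0:
            raise KinematicsError(
                f"percent_time_in_motion out of [0, 100]: {self.percent_time_in_motion}")


DESCRIPTOR_FIELDS = [
    "mean_velocity_mm_s", "max_velocity_mm_s", "total_walking_duration_s",
    "total_walking_distance_mm", "percent_time_in_motion",
    "mean_trajectory_length_mm", "mean_trajectory_length_per_episode_mm",
    "n_trajectories", "n_trajectories_per_fly",
]


def _moving_average(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with the window truncated at the ends."""
    n = len(values)
    half = window // 2
    csum = np.concatenate(([0.0], np.cumsum(values)))
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_speed_trace(track: Track, fps: float,
                        window_frames: int = 5) -> SpeedTrace:
    """Per-frame speed ``|p_{i+1} - p_i| * fps`` smoothed by a centered
    moving average of ``window_frames`` (odd; 1 disables smoothing)."""
    if window_frames < 1 or window_frames % 2 == 0:
        raise KinematicsError(
            f"window_frames must be a positive odd count, got {window_frames}")
    if fps <= 0:
        raise KinematicsError(f"fps must be > 0, got {fps}")
    if len(track) < 2:
        raise KinematicsError("speed trace needs a track with >= 2 points")
    if np.any(np.diff(track.frames) != 1):
        raise KinematicsError(
            f"track (vial {track.vial_id}, fly {track.fly_id}) has non-uniform "
            "frame spacing; interpolate gaps before computing speeds")
    raw = np.hypot(np.diff(track.x_mm), np.diff(track.y_mm)) * fps
    smoothed = _moving_average(raw, window_frames) if window_frames > 1 else raw.copy()
    return SpeedTrace(
        frames=track.frames[:-1].copy(),
        speed_mm_s=smoothed, raw_speed_mm_s=raw, fps=fps,
        smoothed=window_frames > 1, window_frames=window_frames,
    )


def percent_in_motion(traces: Sequence[SpeedTrace],
                      cutoff_mm_s: float = 2.5) -> float:
    """Percent of pooled frames whose speed is strictly above the cutoff."""
    if cutoff_mm_s < 0:
        raise KinematicsError(f"cutoff_mm_s must be >= 0, got {cutoff_mm_s}")
    if not traces:
        raise KinematicsError("percent_in_motion needs at least one trace")
    total = sum(len(tr.speed_mm_s) for tr in traces)
    if total == 0:
        return 0.0
    moving = sum(int(np.sum(tr.speed_mm_s > cutoff_mm_s + SPEED_TOL)) for tr in traces)
    return 100.0 * moving / total


def segment_walk_episodes(trace: SpeedTrace, walk_threshold_mm_s: float = 2.0,
                          min_episode_s: float = 0.2) -> list[WalkEpisode]:
    """Maximal runs of consecutive frames with speed >= the walking
    threshold; runs shorter than ``min_episode_s`` are discarded. Path
    length sums the raw per-frame displacements inside the run."""
    if walk_threshold_mm_s < 0:
        raise KinematicsError(
            f"walk_threshold_mm_s must be >= 0, got {walk_threshold_mm_s}")
    walking = trace.speed_mm_s >= walk_threshold_mm_s - SPEED_TOL
    if not walking.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], walking.view(np.int8), [0]))))
    episodes = []
    min_frames = min_episode_s * trace.fps
    for i0, i1 in zip(edges[0::2], edges[1::2]):  # [i0, i1) run in trace indices
        n_frames = i1 - i0
        if n_frames < min_frames:
            continue
        episodes.append(WalkEpisode(
            start_frame=int(trace.frames[i0]),
            end_frame=int(trace.frames[i1 - 1]),
            duration_s=n_frames / trace.fps,
            path_length_mm=float(np.sum(trace.raw_speed_mm_s[i0:i1]) / trace.fps),
        ))
    return episodes


def summarize_vial(tracks: Sequence[Track], fly_count: int, fps: float,
                   params: Mapping | None = None,
                   vial_id: int | None = None) -> VialKinetics:
    """Descriptor panel for one vial recording, normalized by fly count.

    Mean/max velocity are pooled over all per-frame speeds of all tracks
    (robust to identity switches, which only re-partition the pool).
    Walking duration, trajectory length, and trajectory count are divided
    by the detector-derived fly count where the panel is per-fly.
    """
    p = {**DEFAULT_PARAMS, **(params or {})}
    if fly_count < 1:
        if any(len(t) for t in tracks):
            raise KinematicsError("fly_count must be >= 1 when tracks are present")
        fly_count = max(fly_count, 0)
    if vial_id is None:
        vial_id = tracks[0].vial_id if tracks else 0

    traces = [compute_speed_trace(t, fps, p["smoothing_window_frames"])
              for t in tracks if len(t) >= 2]
    episodes: list[WalkEpisode] = []
    for tr in traces:
        episodes.extend(segment_walk_episodes(
            tr, p["walk_threshold_mm_s"], p["min_episode_s"]))

    pooled = np.concatenate([tr.speed_mm_s for tr in traces]) \
        if traces else np.empty(0)
    mean_v = float(pooled.mean()) if pooled.size else 0.0
    max_v = float(pooled.max()) if pooled.size else 0.0
    pct = percent_in_motion(traces, p["motion_cutoff_mm_s"]) if traces else 0.0

    total_dist = float(sum(e.path_length_mm for e in episodes))
    total_dur = float(sum(e.duration_s for e in episodes))
    n_epi = len(episodes)
    denom = max(fly_count, 1)
    return VialKinetics(
        vial_id=vial_id, fly_count=fly_count,
        mean_velocity_mm_s=mean_v, max_velocity_mm_s=max_v,
        total_walking_duration_s=total_dur / denom,
        total_walking_distance_mm=total_dist,
        percent_time_in_motion=pct,
        mean_trajectory_length_mm=total_dist / denom,
        mean_trajectory_length_per_episode_mm=total_dist / n_epi if n_epi else 0.0,
        n_trajectories=float(n_epi),
        n_trajectories_per_fly=n_epi / denom,
    )


def average_replicates(a: VialKinetics, b: VialKinetics) -> VialKinetics:
    """Field-wise mean of two back-to-back recordings of the same vial.

    The fly count is the smaller of the two (a fly lost between replicates
    should not inflate normalization); unequal counts set
    ``fly_count_mismatch``.
    """
    if a.vial_id != b.vial_id:
        raise KinematicsError(
            f"cannot average replicates of different vials ({a.vial_id} vs {b.vial_id})")
    averaged = {f: (getattr(a, f) + getattr(b, f)) / 2.0 for f in DESCRIPTOR_FIELDS}
    return replace(
        a, fly_count=min(a.fly_count, b.fly_count),
        fly_count_mismatch=a.fly_count != b.fly_count,
        **averaged,
    )
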