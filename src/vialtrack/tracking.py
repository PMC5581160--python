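"""Fly tracking mode: links per-frame detections into per-fly tracks.

Frame-to-frame association is a gated minimum-total-distance assignment
solved exactly (Hungarian method). Prediction is constant-position: at
30 fps a fly moves little relative to inter-fly spacing, so the last known
position is the best cheap predictor; the documented cost is identity
swaps during close crossings, which the identity-agnostic descriptors
tolerate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from vialtrack.detection import Detection

DEFAULT_PARAMS = {
    "gate_mm_per_s": 60.0,   # ~10x the largest plausible mean speed
    "max_gap_frames": 3,
    "min_track_frames": 15,  # 0.5 s at 30 fps
}

_BIG = 1e9  # cost barring over-gate pairings in the assignment matrix


class TrackingError(ValueError):
    """Invalid assignment or track-building input."""


@dataclass
class Track:
    """One fly's path: frame indices, timestamps, mm coordinates, and a
    per-point flag marking gap-filled (linearly interpolated) positions."""

    vial_id: int
    fly_id: int
    frames: np.ndarray
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    interpolated: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=int)
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_mm = np.asarray(self.x_mm, dtype=float)
        self.y_mm = np.asarray(self.y_mm, dtype=float)
        self.interpolated = np.asarray(self.interpolated, dtype=bool)
        if np.any(np.diff(self.frames) <= 0):
            raise TrackingError(
                f"track (vial {self.vial_id}, fly {self.fly_id}) has "
                "non-increasing frame indices")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_mm, self.y_mm])


def assign(predicted: np.ndarray, observed: np.ndarray, gate_mm: float
           ) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Gated minimum-total-Euclidean-distance matching.

    Returns (matched pairs as (prediction index, observation index),
    unmatched prediction indices, unmatched observation indices). Solved
    optimally; no matched pair exceeds ``gate_mm``.
    """
    if gate_mm < 0:
        raise TrackingError(f"gate_mm must be >= 0, got {gate_mm}")
    predicted = np.atleast_2d(np.asarray(predicted, dtype=float)) \
        if len(predicted) else np.empty((0, 2))
    observed = np.atleast_2d(np.asarray(observed, dtype=float)) \
        if len(observed) else np.empty((0, 2))
    n_p, n_o = len(predicted), len(observed)
    if n_p == 0 or n_o == 0:
        return [], list(range(n_p)), list(range(n_o))
    dist = np.hypot(
        predicted[:, 0:1] - observed[:, 0][None, :],
        predicted[:, 1:2] - observed[:, 1][None, :],
    )
    cost = np.where(dist <= gate_mm, dist, _BIG)
    rows, cols = linear_sum_assignment(cost)
    pairs = [(int(r), int(c)) for r, c in zip(rows, cols) if dist[r, c] <= gate_mm]
    matched_p = {r for r, _ in pairs}
    matched_o = {c for _, c in pairs}
    return (pairs,
            [i for i in range(n_p) if i not in matched_p],
            [j for j in range(n_o) if j not in matched_o])


class _LiveTrack:
    __slots__ = ("frames", "xs", "ys", "interp", "misses")

    def __init__(self, frame: int, x: float, y: float):
        self.frames = [frame]
        self.xs = [x]
        self.ys = [y]
        self.interp = [False]
        self.misses = 0

    def extend(self, frame: int, x: float, y: float) -> None:
        """Append a matched detection, linearly interpolating any gap."""
        gap = frame - self.frames[-1]
        x0, y0 = self.xs[-1], self.ys[-1]
        for k in range(1, gap):
            frac = k / gap
            self.frames.append(self.frames[-1] + 1)
            self.xs.append(x0 + frac * (x - x0))
            self.ys.append(y0 + frac * (y - y0))
            self.interp.append(True)
        self.frames.append(frame)
        self.xs.append(x)
        self.ys.append(y)
        self.interp.append(False)
        self.misses = 0


def build_tracks(detections_by_frame: Mapping[int, Sequence[Detection]],
                 fps: float, params: Mapping | None = None,
                 vial_id: int | None = None) -> list[Track]:
    """Link one vial's detections into tracks frame by frame.

    Each live track is predicted at its last position and matched to the
    frame's detections via `assign` with gate ``gate_mm_per_s / fps``.
    Unmatched detections open new tracks; tracks unmatched for more than
    ``max_gap_frames`` are closed; gaps up to that length are filled by
    linear interpolation; tracks shorter than ``min_track_frames`` are
    discarded.
    """
    p = {**DEFAULT_PARAMS, **(params or {})}
    if fps <= 0:
        raise TrackingError(f"fps must be > 0, got {fps}")
    frames_order = sorted(detections_by_frame)
    gate_mm = p["gate_mm_per_s"] / fps

    if vial_id is None:
        vials = sorted({d.vial_id
                        for dets in detections_by_frame.values() for d in dets})
        if len(vials) > 1:
            out: list[Track] = []
            for v in vials:
                out.extend(build_tracks(detections_by_frame, fps, p, vial_id=v))
            return out
        vial_id = vials[0] if vials else 0

    live: list[_LiveTrack] = []
    closed: list[_LiveTrack] = []
    for frame in frames_order:
        dets = [d for d in detections_by_frame[frame] if d.vial_id == vial_id]
        preds = np.array([[t.xs[-1], t.ys[-1]] for t in live]) \
            if live else np.empty((0, 2))
        obs = np.array([[d.cx_mm, d.cy_mm] for d in dets]) \
            if dets else np.empty((0, 2))
        # the effective gate grows with the number of frames missed
        pairs, un_p, un_o = [], list(range(len(live))), list(range(len(dets)))
        if len(live) and len(dets):
            # per-track gate: allow gate_mm per elapsed frame since last hit
            gates = np.array([gate_mm * max(frame - t.frames[-1], 1) for t in live])
            dist = np.hypot(preds[:, 0:1] - obs[:, 0][None, :],
                            preds[:, 1:2] - obs[:, 1][None, :])
            cost = np.where(dist <= gates[:, None], dist, _BIG)
            rows, cols = linear_sum_assignment(cost)
            pairs = [(int(r), int(c)) for r, c in zip(rows, cols)
                     if dist[r, c] <= gates[r]]
            matched_p = {r for r, _ in pairs}
            matched_o = {c for _, c in pairs}
            un_p = [i for i in range(len(live)) if i not in matched_p]
            un_o = [j for j in range(len(dets)) if j not in matched_o]
        for r, c in pairs:
            live[r].extend(frame, dets[c].cx_mm, dets[c].cy_mm)
        survivors = []
        for i, t in enumerate(live):
            if i in {r for r, _ in pairs}:
                survivors.append(t)
                continue
            t.misses += 1
            if t.misses > p["max_gap_frames"]:
                closed.append(t)
            else:
                survivors.append(t)
        live = survivors
        for j in un_o:
            live.append(_LiveTrack(frame, dets[j].cx_mm, dets[j].cy_mm))
    closed.extend(live)

    tracks = []
    fly_id = 0
    for t in sorted(closed, key=lambda t: (t.frames[0], t.xs[0], t.ys[0])):
        if len(t.frames) < p["min_track_frames"]:
            continue
        frames_arr = np.array(t.frames)
        tracks.append(Track(
            vial_id=vial_id, fly_id=fly_id,
            frames=frames_arr, t_s=frames_arr / fps,
            x_mm=np.array(t.xs), y_mm=np.array(t.ys),
            interpolated=np.array(t.interp),
        ))
        fly_id += 1
    return tracks
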