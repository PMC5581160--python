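"""Synthetic multi-vial arena: ground-truth trajectories and rendered video.

Fly motion is a two-state (pause/walk) Markov chain sampled at frame
resolution. While walking a fly advances by an episode-constant speed along
a slowly reorienting heading, plus a constant upward drift modelling the
post-startle climb; while paused it does not move. Trajectories are
rendered as dark soft-edged discs on bright vertical tube strips in a
640x480 frame, so the detection/tracking/kinematics stack can be validated
against exact ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from typing import Sequence

import numpy as np

from vialtrack.video_io import FrameSequence

FRAME_WIDTH_PX = 640
FRAME_HEIGHT_PX = 480
#: vertical margin above/below each tube strip, px
STRIP_MARGIN_PX = 15
#: intensity of the area outside the tube strips
OUTSIDE_LEVEL = 120


class SimulationError(ValueError):
    """Invalid simulation configuration; message names the offending field."""


@dataclass
class SimulationConfig:
    """Parameters of the stochastic walking model and the renderer.

    Protocol constants default to the published recording geometry: four
    75 x 13 mm vials, 10 flies each, 10 s at 30 frames/s. Motion-model
    parameters (transition probabilities, speeds, drift) are free knobs.
    ``min_separation_mm > 0`` rejection-samples initial positions and
    cancels steps that would bring two flies closer than the bound, keeping
    per-frame detection counts unambiguous.
    """

    n_vials: int = 4
    flies_per_vial: int = 10
    duration_s: float = 10.0
    fps: float = 30.0
    tube_length_mm: float = 75.0
    tube_width_mm: float = 13.0
    # mean pause 4 frames, mean walk 20 frames: long sits that would bleed
    # into a temporal-median background are vanishingly rare
    p_start_walk: float = 0.25
    p_stop_walk: float = 0.05
    walk_speed_mean_mm_s: float = 6.0
    walk_speed_sd_mm_s: float = 1.5
    heading_persistence: float = 0.8
    geotaxis_drift_mm_s: float = 0.5
    blob_radius_px: int = 3
    background_level: int = 200
    fly_level: int = 40
    noise_sd: float = 3.0
    min_separation_mm: float = 0.0
    wall_margin_mm: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_start_walk", "p_stop_walk", "heading_persistence"):
            v = getattr(self, name)
            if not (math.isfinite(v) and 0.0 <= v <= 1.0):
                raise SimulationError(f"{name} must be in [0, 1], got {v}")
        for name in ("duration_s", "fps", "tube_length_mm", "tube_width_mm",
                     "walk_speed_mean_mm_s"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise SimulationError(f"{name} must be finite and > 0, got {v}")
        for name in ("walk_speed_sd_mm_s", "geotaxis_drift_mm_s", "noise_sd",
                     "min_separation_mm", "wall_margin_mm"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise SimulationError(f"{name} must be finite and >= 0, got {v}")
        for name in ("n_vials", "flies_per_vial", "blob_radius_px"):
            v = getattr(self, name)
            if int(v) != v or (v < 1 and name != "flies_per_vial") or v < 0:
                raise SimulationError(f"{name} must be a non-negative integer, got {v}")
        for name in ("background_level", "fly_level"):
            v = getattr(self, name)
            if int(v) != v or not (0 <= v <= 255):
                raise SimulationError(f"{name} must be an integer in [0, 255], got {v}")
        if 2 * self.wall_margin_mm >= min(self.tube_width_mm, self.tube_length_mm):
            raise SimulationError(
                "wall_margin_mm too large for the tube cross-section")
        if self.fly_level >= self.background_level:
            raise SimulationError(
                "fly_level must be below background_level (dark flies on a "
                f"bright background), got {self.fly_level} >= {self.background_level}"
            )

    @classmethod
    def from_mapping(cls, mapping: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise SimulationError(f"unknown simulation field(s): {sorted(unknown)}")
        return cls(**mapping)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fps))


@dataclass
class GroundTruthTrack:
    """One fly's exact trajectory: positions at frame resolution plus the
    walk/pause flag for the step leaving each position."""

    vial_id: int
    fly_id: int
    t_s: np.ndarray
    x_mm: np.ndarray
    y_mm: np.ndarray
    walking: np.ndarray  # bool, same length as positions

    def __len__(self) -> int:
        return len(self.t_s)


def _reflect(value: float, lo: float, hi: float) -> float:
    """Fold a coordinate back into [lo, hi] by reflection at the walls."""
    span = hi - lo
    if span <= 0:
        return lo
    v = (value - lo) % (2.0 * span)
    if v > span:
        v = 2.0 * span - v
    return lo + v


def _draw_episode_speed(rng: np.random.Generator, mean: float, sd: float) -> float:
    """Truncated-normal (at 0) episode speed via rejection; falls back to a
    small positive value if the positive tail is unreachable."""
    if sd == 0:
        return max(mean, 0.0)
    for _ in range(1000):
        v = rng.normal(mean, sd)
        if v > 0:
            return v
    return 1e-6


def _sample_initial_positions(rng: np.random.Generator, n: int, width: float,
                              length: float, min_sep: float,
                              margin: float = 0.0) -> np.ndarray:
    pos = np.empty((n, 2))
    for i in range(n):
        for attempt in range(10000):
            cand = np.array([rng.uniform(margin, width - margin),
                             rng.uniform(margin, length - margin)])
            if min_sep <= 0 or i == 0 or \
                    np.min(np.hypot(*(pos[:i] - cand).T)) >= min_sep:
                pos[i] = cand
                break
        else:
            raise SimulationError(
                f"min_separation_mm={min_sep} infeasible for {n} flies in a "
                f"{width} x {length} mm tube"
            )
    return pos


def simulate_cohort(config: SimulationConfig) -> list[GroundTruthTrack]:
    """Simulate every fly in every vial; returns one track per fly.

    Each track has ``duration_s * fps + 1`` positions. Dynamics per frame:
    the pause/walk state flips with ``p_start_walk`` / ``p_stop_walk``; a
    walking fly steps by (episode speed)/fps along a heading blended from
    the previous heading and a fresh uniform one by ``heading_persistence``,
    plus ``geotaxis_drift_mm_s``/fps upward; walls reflect. Deterministic
    for a given config (seed included).
    """
    rng = np.random.default_rng(config.seed)
    n_steps = config.n_frames
    dt = 1.0 / config.fps
    t = np.arange(n_steps + 1) * dt
    p_sum = config.p_start_walk + config.p_stop_walk
    p_walk_init = config.p_start_walk / p_sum if p_sum > 0 else 0.0

    tracks: list[GroundTruthTrack] = []
    for vial in range(config.n_vials):
        n = config.flies_per_vial
        pos = _sample_initial_positions(
            rng, n, config.tube_width_mm, config.tube_length_mm,
            config.min_separation_mm, config.wall_margin_mm)
        walking = rng.random(n) < p_walk_init
        speeds = np.zeros(n)
        headings = np.zeros((n, 2))
        for i in np.flatnonzero(walking):
            speeds[i] = _draw_episode_speed(
                rng, config.walk_speed_mean_mm_s, config.walk_speed_sd_mm_s)
            ang = rng.uniform(0, 2 * np.pi)
            headings[i] = (np.cos(ang), np.sin(ang))

        xs = np.empty((n, n_steps + 1))
        ys = np.empty((n, n_steps + 1))
        walk_flags = np.empty((n, n_steps + 1), dtype=bool)
        xs[:, 0], ys[:, 0] = pos[:, 0], pos[:, 1]

        for step in range(n_steps):
            for i in range(n):
                if walking[i]:
                    if rng.random() < config.p_stop_walk:
                        walking[i] = False
                else:
                    if rng.random() < config.p_start_walk:
                        walking[i] = True
                        speeds[i] = _draw_episode_speed(
                            rng, config.walk_speed_mean_mm_s,
                            config.walk_speed_sd_mm_s)
                        ang = rng.uniform(0, 2 * np.pi)
                        headings[i] = (np.cos(ang), np.sin(ang))
                walk_flags[i, step] = walking[i]
                if not walking[i]:
                    xs[i, step + 1] = xs[i, step]
                    ys[i, step + 1] = ys[i, step]
                    continue
                ang = rng.uniform(0, 2 * np.pi)
                fresh = np.array([np.cos(ang), np.sin(ang)])
                blended = (config.heading_persistence * headings[i]
                           + (1.0 - config.heading_persistence) * fresh)
                norm = np.hypot(*blended)
                if norm > 1e-12:
                    headings[i] = blended / norm
                dx = speeds[i] * dt * headings[i][0]
                dy = speeds[i] * dt * headings[i][1] + config.geotaxis_drift_mm_s * dt
                m = config.wall_margin_mm  # fly body keeps its centre off the wall
                rx, ry = xs[i, step] + dx, ys[i, step] + dy
                nx = _reflect(rx, m, config.tube_width_mm - m)
                ny = _reflect(ry, m, config.tube_length_mm - m)
                # a wall bounce flips the matching heading component, so a
                # persistent heading does not grind along the wall
                if not m <= rx <= config.tube_width_mm - m:
                    headings[i][0] = -headings[i][0]
                if not m <= ry <= config.tube_length_mm - m:
                    headings[i][1] = -headings[i][1]
                if config.min_separation_mm > 0 and n > 1:
                    others = [j for j in range(n) if j != i]
                    ox = np.array([xs[j, step + 1] if j < i else xs[j, step]
                                   for j in others])
                    oy = np.array([ys[j, step + 1] if j < i else ys[j, step]
                                   for j in others])
                    if np.min(np.hypot(ox - nx, oy - ny)) < config.min_separation_mm:
                        # bounce off the neighbour rather than pinning in
                        # place (a pinned fly would bleed into the temporal-
                        # median background model)
                        headings[i] = -headings[i]
                        dx = speeds[i] * dt * headings[i][0]
                        dy = (speeds[i] * dt * headings[i][1]
                              + config.geotaxis_drift_mm_s * dt)
                        nx = _reflect(xs[i, step] + dx, m, config.tube_width_mm - m)
                        ny = _reflect(ys[i, step] + dy, m, config.tube_length_mm - m)
                        if np.min(np.hypot(ox - nx, oy - ny)) < config.min_separation_mm:
                            nx, ny = xs[i, step], ys[i, step]  # stay this frame
                xs[i, step + 1] = nx
                ys[i, step + 1] = ny
        walk_flags[:, n_steps] = walk_flags[:, n_steps - 1] if n_steps else False

        for i in range(n):
            tracks.append(GroundTruthTrack(
                vial_id=vial, fly_id=i, t_s=t.copy(),
                x_mm=xs[i], y_mm=ys[i], walking=walk_flags[i],
            ))
    return tracks


# ---------------------------------------------------------------------------
# rendering


def vial_layout(config: SimulationConfig) -> list[dict]:
    """Pixel geometry of each tube strip in the 640x480 frame.

    Strips are evenly spaced horizontally; the tube length spans the strip
    height, which fixes the (isotropic) mm-per-pixel scale.
    """
    strip_h = FRAME_HEIGHT_PX - 2 * STRIP_MARGIN_PX
    mm_per_px = config.tube_length_mm / strip_h
    strip_w = int(round(config.tube_width_mm / mm_per_px))
    layout = []
    for i in range(config.n_vials):
        cx = (i + 1) * FRAME_WIDTH_PX / (config.n_vials + 1)
        x_min = int(round(cx - strip_w / 2))
        layout.append({
            "vial_id": i,
            "x_min_px": x_min,
            "x_max_px": x_min + strip_w,
            "y_min_px": STRIP_MARGIN_PX,
            "y_max_px": STRIP_MARGIN_PX + strip_h,
            "mm_per_px": mm_per_px,
        })
    for a, b in zip(layout, layout[1:]):
        if a["x_max_px"] > b["x_min_px"]:
            raise SimulationError(
                "tube strips overlap horizontally; reduce n_vials or tube_width_mm")
    return layout


def project_mm_to_px(x_mm: float, y_mm: float, region: dict) -> tuple[float, float]:
    """Map vial coordinates (x across tube, y above tube bottom) to pixel
    (col, row); row increases downward so the tube bottom is ``y_max_px``."""
    s = region["mm_per_px"]
    return (region["x_min_px"] + x_mm / s, region["y_max_px"] - y_mm / s)


def render_frames(tracks: Sequence[GroundTruthTrack],
                  config: SimulationConfig) -> FrameSequence:
    """Render ground-truth tracks to a grayscale frame sequence.

    Flies are soft-edged discs (coverage-weighted blend toward
    ``fly_level``) so intensity-weighted centroids recover sub-pixel
    positions. Additive Gaussian noise of sd ``noise_sd`` is applied last
    and clipped to [0, 255]. Deterministic given (tracks, config).
    """
    layout = vial_layout(config)
    n_frames = 1 + max((len(tr) for tr in tracks), default=config.n_frames + 1) - 1
    eps = 1e-9
    for tr in tracks:
        if tr.vial_id >= config.n_vials:
            raise SimulationError(f"track vial_id {tr.vial_id} outside layout")
        if (np.any(tr.x_mm < -eps) or np.any(tr.x_mm > config.tube_width_mm + eps)
                or np.any(tr.y_mm < -eps) or np.any(tr.y_mm > config.tube_length_mm + eps)):
            raise SimulationError(
                f"track (vial {tr.vial_id}, fly {tr.fly_id}) leaves the tube bounds")

    canvas = np.full((FRAME_HEIGHT_PX, FRAME_WIDTH_PX), OUTSIDE_LEVEL, dtype=np.float64)
    for reg in layout:
        canvas[reg["y_min_px"]:reg["y_max_px"],
               reg["x_min_px"]:reg["x_max_px"]] = config.background_level

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0xF1]))
    r = float(config.blob_radius_px)
    pad = int(math.ceil(r)) + 1
    frames = np.empty((n_frames, FRAME_HEIGHT_PX, FRAME_WIDTH_PX), dtype=np.uint8)

    for f in range(n_frames):
        img = canvas.copy()
        cov = np.zeros_like(img)
        for tr in tracks:
            if f >= len(tr):
                continue
            reg = layout[tr.vial_id]
            col, row = project_mm_to_px(tr.x_mm[f], tr.y_mm[f], reg)
            c0, c1 = int(math.floor(col)) - pad, int(math.floor(col)) + pad + 1
            r0, r1 = int(math.floor(row)) - pad, int(math.floor(row)) + pad + 1
            c0, r0 = max(c0, 0), max(r0, 0)
            c1, r1 = min(c1, FRAME_WIDTH_PX), min(r1, FRAME_HEIGHT_PX)
            if c0 >= c1 or r0 >= r1:
                continue
            cc, rr = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
            dist = np.hypot(cc - col, rr - row)
            local = np.clip(r + 0.5 - dist, 0.0, 1.0)
            cov[r0:r1, c0:c1] = np.maximum(cov[r0:r1, c0:c1], local)
        img = (1.0 - cov) * img + cov * config.fly_level
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        frames[f] = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    meta = {
        "layout": layout,
        "seed": config.seed,
        "tube_length_mm": config.tube_length_mm,
        "tube_width_mm": config.tube_width_mm,
        "n_vials": config.n_vials,
    }
    return FrameSequence(frames=frames, fps=config.fps, source="synthetic", meta=meta)


def straight_track(speed_mm_s: float, duration_s: float = 10.0, fps: float = 30.0,
                   vial_id: int = 0, fly_id: int = 0, x_mm: float = 6.5,
                   y0_mm: float = 0.0):
    """A noiseless constant-speed straight-line Track moving upward.

    Convenience input for descriptor threshold sweeps; positions are not
    bounded by the tube (pure kinematic input, never rendered).
    """
    from vialtrack.tracking import Track

    n = int(round(duration_s * fps))
    frames = np.arange(n + 1)
    step = speed_mm_s / fps
    return Track(
        vial_id=vial_id, fly_id=fly_id, frames=frames,
        t_s=frames / fps,
        x_mm=np.full(n + 1, x_mm),
        y_mm=y0_mm + frames * step,
        interpolated=np.zeros(n + 1, dtype=bool),
    )
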