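"""Frame-sequence, trajectory-table, and configuration I/O.

Owns every on-disk format: PNG frame directories with a JSON sidecar,
AVI/MP4 containers (read-only), trajectory and detection CSV tables, and
YAML/JSON configuration files. All tables are comma-separated UTF-8 with a
mandatory header and '.' decimal separator.

Pixel convention: origin at top-left, row index increases downward.
Conversion to "height above tube bottom" happens in detection's
calibration, never here. Time is stored both as integer frame index and
seconds; the frame index is authoritative.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

SIDECAR_NAME = "sequence.json"

TRACK_COLUMNS = ["vial_id", "fly_id", "frame", "t_s", "x_mm", "y_mm", "interpolated"]
GROUND_TRUTH_COLUMNS = ["vial_id", "fly_id", "frame", "t_s", "x_mm", "y_mm", "walking"]
DETECTION_COLUMNS = ["frame", "vial_id", "cx_mm", "cy_mm", "area_px", "peak_contrast"]


class VideoIOError(ValueError):
    """Malformed frame sequence, sidecar, or container."""


class TrackParseError(ValueError):
    """Malformed trajectory/detection CSV; carries the offending column or line."""


class ConfigError(ValueError):
    """Unknown key, wrong type, or out-of-range value in a configuration file."""


@dataclass
class FrameSequence:
    """Ordered grayscale frames with acquisition metadata.

    ``frames`` is a (n_frames, height, width) uint8 array; ``fps`` the
    acquisition rate; ``source`` a provenance string (path or "synthetic").
    """

    frames: np.ndarray
    fps: float
    source: str = "memory"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise VideoIOError(
                f"frames must be a 3-D (n, h, w) array, got shape {self.frames.shape}"
            )
        if self.frames.dtype != np.uint8:
            raise VideoIOError(f"frames must be uint8, got {self.frames.dtype}")
        if not (math.isfinite(self.fps) and self.fps > 0):
            raise VideoIOError(f"fps must be finite and > 0, got {self.fps}")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])

    @property
    def height_px(self) -> int:
        return int(self.frames.shape[1])

    @property
    def width_px(self) -> int:
        return int(self.frames.shape[2])

    def __len__(self) -> int:
        return self.n_frames


def _to_grayscale(img: np.ndarray) -> np.ndarray:
    """Collapse an RGB(A) frame to 8-bit luminance; pass grayscale through."""
    if img.ndim == 2:
        return img.astype(np.uint8, copy=False)
    if img.ndim == 3 and img.shape[2] in (3, 4):
        rgb = img[..., :3].astype(np.float64)
        lum = 0.2126 * rgb[..., 0] + 0.7152 * rgb[..., 1] + 0.0722 * rgb[..., 2]
        return np.clip(np.rint(lum), 0, 255).astype(np.uint8)
    raise VideoIOError(f"cannot interpret frame of shape {img.shape} as an image")


def write_frame_sequence(seq: FrameSequence, path: str | Path) -> Path:
    """Write ``seq`` as zero-padded PNG frames plus a JSON sidecar.

    Returns the directory path. The sidecar records fps, pixel dimensions,
    frame count, and any metadata (vial layout, seed) stored in ``seq.meta``.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    width = max(6, len(str(seq.n_frames)))
    for i, frame in enumerate(seq.frames):
        iio.imwrite(out / f"frame_{i:0{width}d}.png", frame)
    sidecar = {
        "fps": seq.fps,
        "width_px": seq.width_px,
        "height_px": seq.height_px,
        "n_frames": seq.n_frames,
        "source": seq.source,
        **seq.meta,
    }
    (out / SIDECAR_NAME).write_text(json.dumps(sidecar, indent=2, sort_keys=True))
    return out


def read_frame_sequence(path: str | Path, fps_override: float | None = None) -> FrameSequence:
    """Read a PNG frame directory (with sidecar) or an AVI/MP4 container.

    PNG frames are taken in lexicographic order. ``fps`` comes from the
    sidecar or container metadata unless ``fps_override`` is given; a
    directory without a sidecar requires the override.
    """
    p = Path(path)
    if not p.exists():
        raise VideoIOError(f"no such frame source: {p}")
    if p.is_dir():
        return _read_frame_dir(p, fps_override)
    return _read_container(p, fps_override)


def _read_frame_dir(p: Path, fps_override: float | None) -> FrameSequence:
    frame_paths = sorted(q for q in p.iterdir() if q.suffix.lower() == ".png")
    if not frame_paths:
        raise VideoIOError(f"no PNG frames found in {p}")
    meta: dict = {}
    sidecar = p / SIDECAR_NAME
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    fps = fps_override if fps_override is not None else meta.get("fps")
    if fps is None:
        raise VideoIOError(
            f"{p} has no {SIDECAR_NAME} sidecar and no fps_override was given"
        )
    frames = []
    shape = None
    for q in frame_paths:
        img = _to_grayscale(iio.imread(q))
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise VideoIOError(
                f"frame dimension mismatch in {p}: {q.name} is {img.shape}, "
                f"expected {shape}"
            )
        frames.append(img)
    extra = {k: v for k, v in meta.items() if k not in
             {"fps", "width_px", "height_px", "n_frames", "source"}}
    return FrameSequence(
        frames=np.stack(frames), fps=float(fps),
        source=meta.get("source", str(p)), meta=extra,
    )


def _read_container(p: Path, fps_override: float | None) -> FrameSequence:
    try:
        raw = iio.imread(p, index=None)
    except Exception as exc:  # plugin/codec availability varies
        raise VideoIOError(f"cannot decode video container {p}: {exc}") from exc
    fps = fps_override
    if fps is None:
        try:
            fps = iio.immeta(p).get("fps")
        except Exception:
            fps = None
    if fps is None:
        raise VideoIOError(f"container {p} reports no frame rate; pass fps_override")
    frames = np.stack([_to_grayscale(f) for f in np.asarray(raw)])
    return FrameSequence(frames=frames, fps=float(fps), source=str(p))


# ---------------------------------------------------------------------------
# trajectory tables


def _validate_table(df: pd.DataFrame, expected: Sequence[str], path: Path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise TrackParseError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in expected]
    if extra:
        raise TrackParseError(f"{path}: unexpected column(s) {extra}")
    for col in ("t_s", "x_mm", "y_mm", "cx_mm", "cy_mm"):
        if col in df.columns and len(df):
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            if bad.any():
                line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
                raise TrackParseError(
                    f"{path}: non-numeric value in column '{col}' at line {line}"
                )
            if vals.isna().any():
                line = int(np.flatnonzero(vals.isna().to_numpy())[0]) + 2
                raise TrackParseError(
                    f"{path}: empty value in column '{col}' at line {line}"
                )


def write_tracks(tracks: Sequence, path: str | Path) -> Path:
    """Write Track objects to CSV (header always present, one row per point)."""
    rows = []
    for tr in tracks:
        for i in range(len(tr.frames)):
            rows.append((
                tr.vial_id, tr.fly_id, int(tr.frames[i]), float(tr.t_s[i]),
                float(tr.x_mm[i]), float(tr.y_mm[i]), int(tr.interpolated[i]),
            ))
    df = pd.DataFrame(rows, columns=TRACK_COLUMNS)
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format="%.6f")
    return out


def read_tracks(path: str | Path) -> list:
    """Read a tracks CSV back into Track objects (grouped by vial, fly)."""
    from vialtrack.tracking import Track  # late import to avoid a cycle

    p = Path(path)
    try:
        df = pd.read_csv(p, dtype={"vial_id": "Int64", "fly_id": "Int64"})
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise TrackParseError(f"{p}: cannot parse CSV: {exc}") from exc
    _validate_table(df, TRACK_COLUMNS, p)
    tracks = []
    for (vial_id, fly_id), g in df.groupby(["vial_id", "fly_id"], sort=True):
        g = g.sort_values("frame")
        tracks.append(Track(
            vial_id=int(vial_id), fly_id=int(fly_id),
            frames=g["frame"].to_numpy(dtype=int),
            t_s=g["t_s"].to_numpy(dtype=float),
            x_mm=g["x_mm"].to_numpy(dtype=float),
            y_mm=g["y_mm"].to_numpy(dtype=float),
            interpolated=g["interpolated"].to_numpy(dtype=bool),
        ))
    return tracks


def write_ground_truth(tracks: Sequence, path: str | Path) -> Path:
    """Write simulator GroundTruthTrack objects to CSV."""
    rows = []
    for tr in tracks:
        for i in range(len(tr.t_s)):
            rows.append((
                tr.vial_id, tr.fly_id, i, float(tr.t_s[i]),
                float(tr.x_mm[i]), float(tr.y_mm[i]), int(tr.walking[i]),
            ))
    df = pd.DataFrame(rows, columns=GROUND_TRUTH_COLUMNS)
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format="%.6f")
    return out


def write_detections(detections_by_frame: Mapping[int, Sequence], path: str | Path) -> Path:
    """Write per-frame Detection lists to CSV ordered by frame then vial."""
    rows = []
    for frame in sorted(detections_by_frame):
        for d in detections_by_frame[frame]:
            rows.append((d.frame, d.vial_id, d.cx_mm, d.cy_mm, d.area_px, d.peak_contrast))
    df = pd.DataFrame(rows, columns=DETECTION_COLUMNS)
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False, float_format="%.6f")
    return out


def read_detections(path: str | Path) -> dict[int, list]:
    """Read a detections CSV into {frame: [Detection, ...]}."""
    from vialtrack.detection import Detection

    p = Path(path)
    df = pd.read_csv(p)
    _validate_table(df, DETECTION_COLUMNS, p)
    out: dict[int, list] = {}
    for row in df.itertuples(index=False):
        det = Detection(
            frame=int(row.frame), vial_id=int(row.vial_id),
            cx_mm=float(row.cx_mm), cy_mm=float(row.cy_mm),
            area_px=int(row.area_px), peak_contrast=float(row.peak_contrast),
        )
        out.setdefault(det.frame, []).append(det)
    return out


KINETICS_COLUMNS = [
    "vial_id", "fly_count", "mean_velocity_mm_s", "max_velocity_mm_s",
    "total_walking_duration_s", "total_walking_distance_mm",
    "percent_time_in_motion", "mean_trajectory_length_mm",
    "mean_trajectory_length_per_episode_mm", "n_trajectories",
    "n_trajectories_per_fly", "fly_count_mismatch",
]


def write_kinetics(kinetics: Sequence, path: str | Path) -> Path:
    """Write VialKinetics rows to CSV, one row per vial per recording."""
    rows = [[getattr(k, c) for c in KINETICS_COLUMNS] for k in kinetics]
    df = pd.DataFrame(rows, columns=KINETICS_COLUMNS)
    out = Path(path)
    out.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(out, index=False)
    return out


def read_kinetics(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    df = pd.read_csv(p)
    missing = [c for c in KINETICS_COLUMNS if c not in df.columns]
    if missing:
        raise TrackParseError(f"{p}: missing column(s) {missing}")
    return df


# ---------------------------------------------------------------------------
# configuration

#: Default analysis configuration. Thresholds follow the published protocol
#: (2.0 mm/s walking threshold, 2.5 mm/s motion cutoff, 30 fps, 4 vials,
#: 75 x 13 mm tubes); the rest are tool defaults, all overridable.
CONFIG_DEFAULTS: dict[str, Any] = {
    "fps": 30.0,
    "n_vials": 4,
    "tube_length_mm": 75.0,
    "tube_width_mm": 13.0,
    "walk_threshold_mm_s": 2.0,
    "motion_cutoff_mm_s": 2.5,
    "min_episode_s": 0.2,
    "smoothing_window_frames": 5,
    "contrast_min": 25.0,
    "area_min": 4,
    "area_max": 400,
    "background_max_samples": 25,
    "background_quantile": 0.75,
    "gate_mm_per_s": 60.0,
    "max_gap_frames": 3,
    "min_track_frames": 15,
    "seed": 0,
    "simulation": {},
}

_POSITIVE_KEYS = {
    "fps", "n_vials", "tube_length_mm", "tube_width_mm",
    "smoothing_window_frames", "contrast_min", "area_min", "area_max",
    "gate_mm_per_s", "min_track_frames",
}
_NONNEGATIVE_KEYS = {
    "walk_threshold_mm_s", "motion_cutoff_mm_s", "min_episode_s",
    "max_gap_frames",
}
_INT_KEYS = {
    "n_vials", "smoothing_window_frames", "area_min", "area_max",
    "background_max_samples", "max_gap_frames", "min_track_frames", "seed",
}


def load_config(path: str | Path | None = None,
                overrides: Mapping[str, Any] | None = None) -> dict[str, Any]:
    """Load and validate a YAML/JSON configuration, filling defaults.

    An empty or absent file yields the full default configuration. Unknown
    keys are rejected. ``overrides`` (e.g. from CLI flags) are applied after
    the file and validated identically.
    """
    cfg = dict(CONFIG_DEFAULTS)
    cfg["simulation"] = {}
    loaded: dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) if text.strip() else {}
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        loaded = data
    for source in (loaded, overrides or {}):
        for key, value in source.items():
            if key not in CONFIG_DEFAULTS:
                raise ConfigError(f"unknown configuration key: {key!r}")
            if key == "simulation":
                if not isinstance(value, Mapping):
                    raise ConfigError("'simulation' must be a mapping")
                cfg["simulation"] = {**cfg["simulation"], **value}
                continue
            cfg[key] = _coerce(key, value)
    _validate_config(cfg)
    return cfg


def _coerce(key: str, value: Any) -> Any:
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"configuration key {key!r} must be numeric, got {value!r}")
    if key in _INT_KEYS:
        if float(value) != int(value):
            raise ConfigError(f"configuration key {key!r} must be an integer, got {value!r}")
        return int(value)
    return float(value)


def _validate_config(cfg: Mapping[str, Any]) -> None:
    for key in _POSITIVE_KEYS:
        if not (math.isfinite(cfg[key]) and cfg[key] > 0):
            raise ConfigError(f"configuration key {key!r} must be > 0, got {cfg[key]}")
    for key in _NONNEGATIVE_KEYS:
        if not (math.isfinite(cfg[key]) and cfg[key] >= 0):
            raise ConfigError(f"configuration key {key!r} must be >= 0, got {cfg[key]}")
    if cfg["smoothing_window_frames"] % 2 != 1:
        raise ConfigError("smoothing_window_frames must be odd")
    if cfg["area_max"] < cfg["area_min"]:
        raise ConfigError("area_max must be >= area_min")
    if cfg["background_max_samples"] < 2:
        raise ConfigError("background_max_samples must be >= 2")
    if not 0.0 <= cfg["background_quantile"] <= 1.0:
        raise ConfigError("background_quantile must be in [0, 1]")
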