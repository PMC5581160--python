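"""Fly detector mode: background model, vial segmentation, blob detection.

Flies are dark blobs on brightly backlit tubes, so detection is signed
background subtraction (background - frame) followed by connected-component
analysis inside each calibrated vial region. The background is a temporal
median, robust to moving flies without needing an empty-vial shot.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from vialtrack.video_io import FrameSequence

#: default blob-detection parameters, sized to the synthetic renderer's discs
DEFAULT_PARAMS = {"contrast_min": 25.0, "area_min": 4, "area_max": 400}

_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


class DetectionError(ValueError):
    """Background, segmentation, or calibration failure."""


@dataclass
class VialRegion:
    """Axis-aligned pixel ROI of one vial; ``[x_min_px, x_max_px)`` columns
    by ``[y_min_px, y_max_px)`` rows. ``mm_per_px`` is set by `calibrate`."""

    vial_id: int
    x_min_px: int
    x_max_px: int
    y_min_px: int
    y_max_px: int
    mm_per_px: float | None = None

    def __post_init__(self) -> None:
        if self.x_max_px <= self.x_min_px or self.y_max_px <= self.y_min_px:
            raise DetectionError(f"empty vial region: {self}")
        if self.mm_per_px is not None and self.mm_per_px <= 0:
            raise DetectionError(f"mm_per_px must be > 0, got {self.mm_per_px}")

    @property
    def width_px(self) -> int:
        return self.x_max_px - self.x_min_px

    @property
    def height_px(self) -> int:
        return self.y_max_px - self.y_min_px


@dataclass
class Detection:
    """One fly candidate in one frame, in vial coordinates (mm): x across
    the tube, y measured upward from the tube bottom."""

    frame: int
    vial_id: int
    cx_mm: float
    cy_mm: float
    area_px: int
    peak_contrast: float


def estimate_background(frames: FrameSequence, max_samples: int = 25,
                        quantile: float = 0.5) -> np.ndarray:
    """Per-pixel temporal median (default) over up to ``max_samples`` evenly
    spaced frames. Requires at least 2 frames (a single frame has no
    temporal signal to separate flies from background).

    Because flies are dark on a bright background, a quantile above 0.5
    tolerates flies dwelling on a pixel for up to ``quantile`` of the
    samples (at the cost of a small positive noise bias); the full
    pipeline uses 0.75 for this reason.
    """
    if len(frames) < 2:
        raise DetectionError("background estimation needs at least 2 frames")
    if max_samples < 2:
        raise DetectionError("max_samples must be >= 2")
    if not 0.0 <= quantile <= 1.0:
        raise DetectionError(f"quantile must be in [0, 1], got {quantile}")
    n = len(frames)
    idx = np.unique(np.linspace(0, n - 1, min(max_samples, n)).round().astype(int))
    sample = frames.frames[idx].astype(np.float64)
    if quantile == 0.5:
        return np.median(sample, axis=0)
    return np.quantile(sample, quantile, axis=0)


def _otsu_threshold(values: np.ndarray, nbins: int = 256) -> float:
    """Otsu's between-class-variance maximizing split of a 1-D sample."""
    values = np.asarray(values, dtype=np.float64).ravel()
    lo, hi = values.min(), values.max()
    if hi <= lo:
        return lo
    hist, edges = np.histogram(values, bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2
    w = hist.astype(np.float64)
    total = w.sum()
    omega = np.cumsum(w) / total
    mu = np.cumsum(w * centers) / total
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b[~np.isfinite(sigma_b)] = -1.0
    return float(centers[int(np.argmax(sigma_b))])


def segment_vials(background: np.ndarray, n_expected: int) -> list[VialRegion]:
    """Locate ``n_expected`` bright vertical tube strips in the background.

    Column bands whose mean intensity exceeds the global Otsu split are the
    candidates; the ``n_expected`` widest are kept, each extended vertically
    by thresholding its row profile with the same split. Regions are
    ordered left to right and numbered 0..n-1.
    """
    if n_expected < 1:
        raise DetectionError("n_expected must be >= 1")
    bg = np.asarray(background, dtype=np.float64)
    col_profile = bg.mean(axis=0)
    thr = _otsu_threshold(bg)
    bright = col_profile > thr
    # contiguous runs of bright columns
    edges = np.flatnonzero(np.diff(np.concatenate(([0], bright.view(np.int8), [0]))))
    bands = list(zip(edges[0::2], edges[1::2]))  # [start, stop) pairs
    if len(bands) < n_expected:
        raise DetectionError(
            f"expected {n_expected} vial band(s), found {len(bands)}")
    bands = sorted(bands, key=lambda b: b[1] - b[0], reverse=True)[:n_expected]
    bands.sort(key=lambda b: b[0])

    regions = []
    for vial_id, (c0, c1) in enumerate(bands):
        row_profile = bg[:, c0:c1].mean(axis=1)
        rows = np.flatnonzero(row_profile > thr)
        if rows.size == 0:
            raise DetectionError(f"band {vial_id} has no bright rows")
        regions.append(VialRegion(
            vial_id=vial_id, x_min_px=int(c0), x_max_px=int(c1),
            y_min_px=int(rows[0]), y_max_px=int(rows[-1]) + 1,
        ))
    return regions


def calibrate(region: VialRegion, tube_length_mm: float = 75.0,
              tube_width_mm: float | None = 13.0) -> VialRegion:
    """Set the isotropic mm-per-pixel scale from the tube length spanning
    the region height. The tube width is only a consistency check (10%
    tolerance, warning not error)."""
    if tube_length_mm <= 0:
        raise DetectionError("tube_length_mm must be > 0")
    height = region.y_max_px - region.y_min_px
    if height <= 0:
        raise DetectionError("cannot calibrate a zero-height region")
    mm_per_px = tube_length_mm / height
    if tube_width_mm is not None:
        implied_width = region.width_px * mm_per_px
        if abs(implied_width - tube_width_mm) > 0.1 * tube_width_mm:
            warnings.warn(
                f"vial {region.vial_id}: implied tube width {implied_width:.1f} mm "
                f"deviates >10% from expected {tube_width_mm} mm",
                stacklevel=2,
            )
    return VialRegion(
        vial_id=region.vial_id,
        x_min_px=region.x_min_px, x_max_px=region.x_max_px,
        y_min_px=region.y_min_px, y_max_px=region.y_max_px,
        mm_per_px=mm_per_px,
    )


def detect_flies(frame: np.ndarray, background: np.ndarray,
                 regions: Sequence[VialRegion],
                 params: Mapping | None = None,
                 frame_index: int = 0) -> list[Detection]:
    """Detect dark blobs in one frame within each calibrated region.

    Pixels with (background - frame) > ``contrast_min`` form the mask;
    8-connected components with area in [area_min, area_max] become
    detections. Centroids are intensity-weighted by the contrast image and
    converted to mm with y measured upward from the region bottom.
    """
    p = {**DEFAULT_PARAMS, **(params or {})}
    diff = np.asarray(background, dtype=np.float64) - np.asarray(frame, dtype=np.float64)
    detections: list[Detection] = []
    for reg in regions:
        if reg.mm_per_px is None:
            raise DetectionError(f"vial {reg.vial_id} region is not calibrated")
        sub = diff[reg.y_min_px:reg.y_max_px, reg.x_min_px:reg.x_max_px]
        mask = sub > p["contrast_min"]
        labels, n_comp = ndimage.label(mask, structure=_EIGHT_CONNECTED)
        if n_comp == 0:
            continue
        areas = ndimage.sum_labels(np.ones_like(sub), labels, index=range(1, n_comp + 1))
        for comp, area in zip(range(1, n_comp + 1), areas):
            if not (p["area_min"] <= area <= p["area_max"]):
                continue
            comp_mask = labels == comp
            weights = sub * comp_mask
            total = weights.sum()
            rows, cols = np.nonzero(comp_mask)
            cy_px = float((rows * weights[rows, cols]).sum() / total)
            cx_px = float((cols * weights[rows, cols]).sum() / total)
            peak = float(sub[comp_mask].max())
            detections.append(Detection(
                frame=frame_index, vial_id=reg.vial_id,
                cx_mm=cx_px * reg.mm_per_px,
                cy_mm=(reg.height_px - cy_px) * reg.mm_per_px,
                area_px=int(area), peak_contrast=peak,
            ))
    return detections


def detect_sequence(frames: FrameSequence, regions: Sequence[VialRegion],
                    params: Mapping | None = None,
                    background: np.ndarray | None = None,
                    max_samples: int = 25) -> dict[int, list[Detection]]:
    """Run `detect_flies` over a whole recording; returns {frame: detections}."""
    if background is None:
        background = estimate_background(frames, max_samples=max_samples)
    return {
        i: detect_flies(frames.frames[i], background, regions, params, frame_index=i)
        for i in range(len(frames))
    }


def count_flies(detections_by_frame: Mapping[int, Sequence[Detection]],
                vial_id: int) -> int:
    """Modal per-frame detection count for one vial over a recording.

    Ties break toward the larger count: occlusion merges blobs, so
    undercounts are likelier than overcounts. Empty input counts 0 flies.
    """
    per_frame = [
        sum(1 for d in dets if d.vial_id == vial_id)
        for dets in detections_by_frame.values()
    ]
    if not per_frame:
        return 0
    counts = Counter(per_frame)
    best = max(counts.values())
    return max(c for c, k in counts.items() if k == best)
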