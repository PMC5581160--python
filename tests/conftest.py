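"""Shared fixtures: one default synthetic cohort rendered and pushed through
the full detection/tracking pipeline at session scope, reused by detection,
tracking, kinematics, and acceptance tests."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from vialtrack import detection, tracking
from vialtrack.synthetic_arena import (
    SimulationConfig,
    render_frames,
    simulate_cohort,
)
from vialtrack.tracking import Track


@pytest.fixture(scope="session")
def default_sim_config() -> SimulationConfig:
    """Noise-free default recording: 4 vials, 10 flies, 10 s at 30 fps, with
    rejection-sampled separation so detection counts are unambiguous."""
    return SimulationConfig(seed=7, min_separation_mm=2.5, noise_sd=0.0)


@pytest.fixture(scope="session")
def cohort_truth(default_sim_config):
    return simulate_cohort(default_sim_config)


@pytest.fixture(scope="session")
def rendered(cohort_truth, default_sim_config):
    return render_frames(cohort_truth, default_sim_config)


@dataclass
class PipelineResult:
    config: SimulationConfig
    truth: list
    frames: object
    background: np.ndarray
    regions: list
    detections: dict
    counts: dict
    tracks: list


@pytest.fixture(scope="session")
def pipeline(default_sim_config, cohort_truth, rendered) -> PipelineResult:
    """Full detect -> track run on the default noise-free render."""
    background = detection.estimate_background(rendered, quantile=0.75)
    regions = [
        detection.calibrate(r, default_sim_config.tube_length_mm,
                            default_sim_config.tube_width_mm)
        for r in detection.segment_vials(background, default_sim_config.n_vials)
    ]
    dets = detection.detect_sequence(rendered, regions, background=background)
    counts = {r.vial_id: detection.count_flies(dets, r.vial_id) for r in regions}
    tracks = tracking.build_tracks(dets, fps=default_sim_config.fps)
    return PipelineResult(
        config=default_sim_config, truth=cohort_truth, frames=rendered,
        background=background, regions=regions, detections=dets,
        counts=counts, tracks=tracks,
    )


def truth_as_track(tr) -> Track:
    """Adapt a GroundTruthTrack to the Track interface for kinematics."""
    n = len(tr.t_s)
    return Track(
        vial_id=tr.vial_id, fly_id=tr.fly_id, frames=np.arange(n),
        t_s=tr.t_s, x_mm=tr.x_mm, y_mm=tr.y_mm,
        interpolated=np.zeros(n, dtype=bool),
    )
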