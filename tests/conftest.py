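"""Shared fixtures and the independent brute-force TTF oracle.

The oracle deliberately avoids the package's track/event machinery: it
filters detections by class and confidence, takes the earliest in-segment
detection frame as t1, and scans every (gaze sample x box) pair in time
order for t2. Tests compare the pipeline against it on randomly generated
sessions.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from ttfix.simulate import SessionSpec
from ttfix.types import PipelineConfig, SessionBundle


@pytest.fixture
def config() -> PipelineConfig:
    return PipelineConfig()


def brute_force_ttf(session: SessionBundle, config: PipelineConfig):
    """Reference TTF: flat scans only, no tracking/interpolation.

    Returns (t1, t2, flags) with the same flag vocabulary as compute_ttf.
    Valid only for sessions whose detections have no intra-track frame gaps
    (the synthetic generator produces contiguous tracks).
    """
    seg = session.segment
    assert seg is not None
    geom = session.geometry
    dets = [
        d
        for d in session.detections
        if d.class_label == config.person_class and d.confidence >= config.min_confidence
    ]
    in_seg = [d for d in dets if seg.contains(d.frame_index * 1000.0 / geom.fps)]
    if not in_seg:
        return None, None, {"no_hazard_onset"}
    t1 = min(d.frame_index for d in in_seg) * 1000.0 / geom.fps
    t2 = None
    for s in session.gaze:
        if not s.valid or s.t_ms < t1 or s.t_ms >= seg.end_ms:
            continue
        frame = math.floor(s.t_ms * geom.fps / 1000.0)
        for d in dets:
            if d.frame_index != frame:
                continue
            b = d.box
            if (
                b.x_min_px <= s.x_px <= b.x_min_px + b.width_px
                and b.y_min_px <= s.y_px <= b.y_min_px + b.height_px
            ):
                t2 = s.t_ms
                break
        if t2 is not None:
            break
    if t2 is None:
        return t1, None, {"miss"}
    ttf = t2 - t1
    flags = set()
    if ttf == 0:
        flags.add("anticipatory")
    elif ttf < config.ttf_min_saccade_ms:
        flags.add("sub_saccade")
    return t1, t2, flags


def random_session_spec(rng: np.random.Generator, duration_ms: float = 3000.0) -> SessionSpec:
    """A randomized but well-formed synthetic session specification."""
    entry = int(rng.integers(0, 60))
    latency = float(rng.integers(0, 40)) * 20.0  # 0 .. 780 ms on the sample grid
    return SessionSpec(
        seed=int(rng.integers(0, 2**31 - 1)),
        duration_ms=duration_ms,
        hazard_entry_frame=entry,
        box_entry_xy=(float(rng.uniform(500, 800)), float(rng.uniform(100, 400))),
        box_velocity_px=(float(rng.uniform(-2.5, 0.0)), float(rng.uniform(-0.5, 0.5))),
        box_size_px=(float(rng.uniform(25, 60)), float(rng.uniform(40, 90))),
        gaze_latency_ms=latency,
        gaze_noise_px=float(rng.uniform(0.0, 5.0)),
        missing_fraction=float(rng.uniform(0.0, 0.3)),
        fixation_xy=(float(rng.uniform(50, 250)), float(rng.uniform(50, 250))),
        stop_sign_times_ms=(400.0,),
        brake_delay_ms=(float(rng.integers(25, 100)) * 20.0,),
    )
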