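"""End-to-end session processing: corrections -> tracks -> TTF -> features -> QC.

``run_pipeline`` never raises on a quality-control failure: a session that
cannot yield a feature gets the corresponding flag on its record instead,
so batch processing over a cohort always produces one row per subject.
"""

from __future__ import annotations

from .features import (
    FeatureUnavailable,
    average_prt,
    distance_at_onset,
    gaze_near,
    initial_gaze_distance,
    perception_response_time,
    speed_at_onset,
    stop_sign_triggers,
    time_to_collision,
)
from .gaze_events import (
    apply_corrections,
    build_tracks,
    compute_ttf,
    detect_segment,
    interpolate_boxes,
    NoHazardOnset,
)
from .io import time_to_frame
from .screening import qc_session
from .types import (
    FLAG_IGD_UNAVAILABLE,
    FLAG_PRT_MISSING,
    FLAG_SPEED_UNAVAILABLE,
    FLAG_TTC_UNDEFINED,
    Detection,
    FeatureRecord,
    PipelineConfig,
    SessionBundle,
    TTFResult,
)

__all__ = ["run_pipeline"]


class ConfigurationError(ValueError):
    """A required stream or setting is missing."""


def _onset_box(session: SessionBundle, config: PipelineConfig, t1_ms: float):
    """Box of the earliest-starting hazard track at the onset frame."""
    frame = time_to_frame(t1_ms, session.geometry)
    tracks = build_tracks(session.detections, config)
    tracks = [interpolate_boxes(t, config.max_box_gap_frames) for t in tracks]
    for track in tracks:
        box = track.box_at(frame)
        if box is not None:
            return box
    return None


def run_pipeline(
    session: SessionBundle,
    config: PipelineConfig | None = None,
    corrections: list[tuple[str, Detection]] | None = None,
) -> tuple[FeatureRecord, TTFResult, "QCReport"]:
    """Process one session into a feature record.

    Order of operations: manual corrections are applied to the raw
    detections first; tracks are assembled and interpolated; hazard onset
    t1 and first gaze-on-target t2 give the TTF; the simulator log supplies
    speed and distance at onset (hence TTC) and the brake responses to the
    stop-sign triggers (hence PRT, averaged over the valid repetitions);
    session QC runs last and its failures are recorded as flags.
    """
    config = config or PipelineConfig()
    if not session.detections and not session.gaze:
        raise ConfigurationError("session has neither detections nor gaze")
    if corrections:
        session.detections = apply_corrections(session.detections, corrections)

    if session.segment is None:
        try:
            session.segment = detect_segment(session.detections, session.geometry, config)
        except NoHazardOnset:
            pass

    ttf = compute_ttf(session, config)
    record = FeatureRecord(subject_id=session.subject_id, fitness=session.fitness)
    record.flags |= set(ttf.flags)
    record.ttf_ms = ttf.ttf_ms

    if ttf.t1_ms is not None:
        t1 = ttf.t1_ms
        try:
            record.speed_kmh = speed_at_onset(session.simlog, t1)
        except FeatureUnavailable:
            record.flags.add(FLAG_SPEED_UNAVAILABLE)
        try:
            distance = distance_at_onset(session.simlog, t1)
            record.ttc_s = time_to_collision(distance, record.speed_kmh or 0.0)
        except FeatureUnavailable:
            record.flags.add(FLAG_TTC_UNDEFINED)

        box = _onset_box(session, config, t1)
        sample = gaze_near(session.gaze, t1, config.igd_search_window_ms)
        if box is not None and sample is not None:
            record.igd_deg = initial_gaze_distance(
                sample, box, config.resolve_deg_per_px(session.geometry)
            )
        else:
            record.flags.add(FLAG_IGD_UNAVAILABLE)

    triggers = stop_sign_triggers(session.simlog)
    prts = []
    for i, trig in enumerate(triggers):
        nxt = triggers[i + 1] if i + 1 < len(triggers) else None
        prts.append(perception_response_time(session.simlog, trig, config, nxt))
    record.prt_ms = average_prt(prts, config)
    if record.prt_ms is None:
        record.flags.add(FLAG_PRT_MISSING)

    qc = qc_session(session, config, ttf)
    for name in qc.failures:
        if name in ("frozen_gaze", "missing_gaze", "recording_pause"):
            record.flags.add(f"qc_{name}")  # event flags are already on the record
    return record, ttf, qc
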