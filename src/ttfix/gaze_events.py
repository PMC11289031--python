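"""Hazard-onset and gaze-on-target event detection.

The time to fixate (TTF) is the interval between t1, the first frame in
which a pedestrian is detected inside the scene segment, and t2, the first
valid gaze sample from t1 onward that lands inside any pedestrian bounding
box of its frame. Gaze already on the target at onset is anticipatory
(TTF = 0); a TTF shorter than the minimum physiological saccade latency is
flagged sub-saccade but kept; gaze that never enters a box before the
segment ends is a miss.
"""

from __future__ import annotations

from dataclasses import replace

from .io import frame_start_ms, time_to_frame
from .types import (
    FLAG_ANTICIPATORY,
    FLAG_MISS,
    FLAG_NO_ONSET,
    FLAG_SUB_SACCADE,
    BoundingBox,
    Detection,
    DetectionSource,
    DetectionTrack,
    FrameGeometry,
    GazeSample,
    PipelineConfig,
    SceneSegment,
    SessionBundle,
    TTFResult,
)

__all__ = [
    "NoHazardOnset",
    "apply_corrections",
    "build_tracks",
    "interpolate_boxes",
    "point_in_box",
    "hazard_onset",
    "first_gaze_on_target",
    "compute_ttf",
    "detect_segment",
]


class NoHazardOnset(Exception):
    """No qualifying pedestrian detection inside the scene segment."""


def apply_corrections(
    detections: list[Detection],
    corrections: list[tuple[str, Detection]],
) -> list[Detection]:
    """Apply manual corrections (replace / add / delete) in file order.

    ``replace`` and ``delete`` match on (frame, track_id); deleting a
    non-existent entry is ignored. Applied corrections carry
    ``source=correction``.
    """
    out = list(detections)
    for action, det in corrections:
        key = (det.frame_index, det.track_id)
        if action == "add":
            out.append(replace(det, source=DetectionSource.CORRECTION))
        elif action == "replace":
            out = [d for d in out if (d.frame_index, d.track_id) != key]
            out.append(replace(det, source=DetectionSource.CORRECTION))
        elif action == "delete":
            out = [d for d in out if (d.frame_index, d.track_id) != key]
        else:  # pragma: no cover - reader validates actions
            raise ValueError(f"unknown correction action {action!r}")
    out.sort(key=lambda d: (d.frame_index, d.track_id if d.track_id is not None else -1))
    return out


def _qualifies(d: Detection, config: PipelineConfig) -> bool:
    return d.class_label == config.person_class and d.confidence >= config.min_confidence


def build_tracks(detections: list[Detection], config: PipelineConfig) -> list[DetectionTrack]:
    """Group person-class detections above the confidence floor into tracks.

    Detections carrying a track_id are grouped by it; trackless detections
    are linked greedily to the nearest open track by IoU between consecutive
    frames (threshold ``iou_link_threshold``), opening a new track when no
    match exists.
    """
    persons = sorted(
        (d for d in detections if _qualifies(d, config)),
        key=lambda d: d.frame_index,
    )
    by_id: dict[int, list[Detection]] = {}
    trackless: list[Detection] = []
    for d in persons:
        if d.track_id is not None:
            by_id.setdefault(d.track_id, []).append(d)
        else:
            trackless.append(d)

    tracks = [DetectionTrack(track_id=tid, detections=dets) for tid, dets in sorted(by_id.items())]

    # Greedy IoU linking for trackless detections.
    next_id = max(by_id.keys(), default=-1) + 1
    open_tracks: list[list[Detection]] = []
    for d in trackless:
        best: list[Detection] | None = None
        best_iou = config.iou_link_threshold
        for t in open_tracks:
            last = t[-1]
            if last.frame_index >= d.frame_index:
                continue
            if d.frame_index - last.frame_index > 1:
                continue
            iou = last.box.iou(d.box)
            if iou >= best_iou:
                best_iou = iou
                best = t
        if best is None:
            open_tracks.append([d])
        else:
            best.append(d)
    for dets in open_tracks:
        tracks.append(
            DetectionTrack(
                track_id=next_id,
                detections=[replace(d, track_id=next_id) for d in dets],
            )
        )
        next_id += 1
    return tracks


def interpolate_boxes(track: DetectionTrack, max_gap_frames: int) -> DetectionTrack:
    """Fill frame gaps of at most ``max_gap_frames`` by per-coordinate linear
    interpolation of (x_min, y_min, width, height); wider gaps stay open."""
    if not track.detections:
        return track
    dets = list(track.detections)
    filled: list[Detection] = [dets[0]]
    for prev, nxt in zip(dets, dets[1:]):
        gap = nxt.frame_index - prev.frame_index - 1
        if 0 < gap <= max_gap_frames:
            for k in range(1, gap + 1):
                frac = k / (gap + 1)
                b0, b1 = prev.box, nxt.box
                box = BoundingBox(
                    x_min_px=b0.x_min_px + frac * (b1.x_min_px - b0.x_min_px),
                    y_min_px=b0.y_min_px + frac * (b1.y_min_px - b0.y_min_px),
                    width_px=b0.width_px + frac * (b1.width_px - b0.width_px),
                    height_px=b0.height_px + frac * (b1.height_px - b0.height_px),
                )
                filled.append(
                    Detection(
                        frame_index=prev.frame_index + k,
                        class_label=prev.class_label,
                        confidence=min(prev.confidence, nxt.confidence),
                        box=box,
                        track_id=track.track_id,
                        source=DetectionSource.INTERPOLATED,
                    )
                )
        filled.append(nxt)
    return DetectionTrack(track_id=track.track_id, detections=filled)


def point_in_box(x_px: float, y_px: float, box: BoundingBox) -> bool:
    """Closed-rectangle hit test: a gaze point on the edge counts as inside."""
    return (
        box.x_min_px <= x_px <= box.x_min_px + box.width_px
        and box.y_min_px <= y_px <= box.y_min_px + box.height_px
    )


def hazard_onset(
    tracks: list[DetectionTrack],
    segment: SceneSegment,
    geometry: FrameGeometry,
    config: PipelineConfig,
) -> float:
    """t1: start time of the earliest detection frame inside the segment.

    Interpolated boxes do not define the onset (they are inferred, not
    observed); when several tracks start on the same frame, t1 is simply that
    frame's start time.
    """
    candidate: int | None = None
    for track in tracks:
        for d in track.detections:
            if d.source is DetectionSource.INTERPOLATED:
                continue
            t = frame_start_ms(d.frame_index, geometry)
            if segment.contains(t) and (candidate is None or d.frame_index < candidate):
                candidate = d.frame_index
                break  # frames increase within a track
    if candidate is None:
        raise NoHazardOnset("no qualifying person detection inside the segment")
    return frame_start_ms(candidate, geometry)


def first_gaze_on_target(
    gaze: list[GazeSample],
    tracks: list[DetectionTrack],
    t1_ms: float,
    segment: SceneSegment,
    geometry: FrameGeometry,
) -> float | None:
    """t2: timestamp of the first valid gaze sample at or after t1 whose point
    lies inside any track's box on the sample's frame; interpolated boxes
    count. Returns None (miss) when no such sample exists before segment end.
    """
    boxes_by_frame: dict[int, list[BoundingBox]] = {}
    for track in tracks:
        for d in track.detections:
            boxes_by_frame.setdefault(d.frame_index, []).append(d.box)
    for s in gaze:
        if s.t_ms < t1_ms or not s.valid:
            continue
        if s.t_ms >= segment.end_ms:
            break
        frame = time_to_frame(s.t_ms, geometry)
        for box in boxes_by_frame.get(frame, ()):
            if point_in_box(s.x_px, s.y_px, box):
                return s.t_ms
    return None


def detect_segment(
    detections: list[Detection],
    geometry: FrameGeometry,
    config: PipelineConfig,
) -> SceneSegment:
    """Fallback scene segment when none is configured: from the first
    qualifying detection's frame to just past the last detection's frame."""
    frames = [d.frame_index for d in detections if _qualifies(d, config)]
    if not frames:
        raise NoHazardOnset("no qualifying detections to derive a segment from")
    return SceneSegment(
        start_ms=frame_start_ms(min(frames), geometry),
        end_ms=frame_start_ms(max(frames) + 1, geometry),
    )


def compute_ttf(session: SessionBundle, config: PipelineConfig) -> TTFResult:
    """Full TTF computation for one session: corrections are assumed already
    applied to ``session.detections``; builds tracks, interpolates, finds t1
    and t2 and returns TTF with event flags."""
    segment = session.segment
    if segment is None:
        segment = detect_segment(session.detections, session.geometry, config)
    tracks = build_tracks(session.detections, config)
    tracks = [interpolate_boxes(t, config.max_box_gap_frames) for t in tracks]
    try:
        t1 = hazard_onset(tracks, segment, session.geometry, config)
    except NoHazardOnset:
        return TTFResult(t1_ms=None, t2_ms=None, ttf_ms=None, flags=frozenset({FLAG_NO_ONSET}))
    t2 = first_gaze_on_target(session.gaze, tracks, t1, segment, session.geometry)
    if t2 is None:
        return TTFResult(t1_ms=t1, t2_ms=None, ttf_ms=None, flags=frozenset({FLAG_MISS}))
    ttf = t2 - t1
    flags: set[str] = set()
    if ttf == 0:
        flags.add(FLAG_ANTICIPATORY)
    elif ttf < config.ttf_min_saccade_ms:
        flags.add(FLAG_SUB_SACCADE)
    return TTFResult(t1_ms=t1, t2_ms=t2, ttf_ms=ttf, flags=frozenset(flags))
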