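"""CSV readers/writers for the pipeline's file dialects and time-frame alignment.

Dialects (all plain CSV with a header row):

* gaze:        ``t_ms,x_px,y_px,valid``           (valid in {0,1})
* detections:  ``frame,track_id,class,conf,x,y,w,h``  (x,y = top-left, px)
* corrections: detections dialect plus ``action`` in {replace, add, delete}
* simlog:      ``t_ms,speed_kmh,distance_m,brake_N,stop_sign``
* features:    ``subject_id,fitness,ttf_ms,speed_kmh,igd_deg,ttc_s,prt_ms,flags``
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable

import pandas as pd

from .types import (
    BoundingBox,
    Detection,
    DetectionSource,
    FeatureRecord,
    Fitness,
    FrameGeometry,
    GazeSample,
    SimulatorSample,
)

__all__ = [
    "FormatError",
    "read_gaze_csv",
    "write_gaze_csv",
    "read_detections_csv",
    "write_detections_csv",
    "read_corrections_csv",
    "read_simlog_csv",
    "write_simlog_csv",
    "read_features_csv",
    "write_features_csv",
    "time_to_frame",
    "frame_start_ms",
]

GAZE_COLUMNS = ["t_ms", "x_px", "y_px", "valid"]
DETECTION_COLUMNS = ["frame", "track_id", "class", "conf", "x", "y", "w", "h"]
CORRECTION_COLUMNS = DETECTION_COLUMNS + ["action"]
SIMLOG_COLUMNS = ["t_ms", "speed_kmh", "distance_m", "brake_N", "stop_sign"]
FEATURE_COLUMNS = [
    "subject_id",
    "fitness",
    "ttf_ms",
    "speed_kmh",
    "igd_deg",
    "ttc_s",
    "prt_ms",
    "flags",
]

CORRECTION_ACTIONS = frozenset({"replace", "add", "delete"})


class FormatError(ValueError):
    """Raised when a CSV file violates its dialect or an invariant."""


def _require_columns(df: pd.DataFrame, expected: list[str], path: Path) -> None:
    missing = [c for c in expected if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {missing}; expected header {expected}")


def read_gaze_csv(path: str | Path, geometry: FrameGeometry | None = None) -> list[GazeSample]:
    """Read a gaze trace; rows with valid=0 are retained but flagged.

    Timestamps must be strictly increasing; duplicates are a format error
    naming the offending row.
    """
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, GAZE_COLUMNS, path)
    samples: list[GazeSample] = []
    prev_t = -math.inf
    for i, row in enumerate(df.itertuples(index=False)):
        t = float(row.t_ms)
        valid = bool(int(row.valid))
        if t == prev_t:
            raise FormatError(f"{path}: duplicate timestamp {t} at row {i}")
        if t < prev_t:
            raise FormatError(f"{path}: non-increasing timestamp {t} at row {i}")
        prev_t = t
        if valid and (not _is_number(row.x_px) or not _is_number(row.y_px)):
            raise FormatError(f"{path}: non-numeric coordinate on valid row {i}")
        x = float(row.x_px) if _is_number(row.x_px) else math.nan
        y = float(row.y_px) if _is_number(row.y_px) else math.nan
        samples.append(GazeSample(t_ms=t, x_px=x, y_px=y, valid=valid))
    return samples


def _is_number(v: object) -> bool:
    try:
        return not math.isnan(float(v))  # type: ignore[arg-type]
    except (TypeError, ValueError):
        return False


def write_gaze_csv(samples: Iterable[GazeSample], path: str | Path) -> None:
    df = pd.DataFrame(
        [{"t_ms": s.t_ms, "x_px": s.x_px, "y_px": s.y_px, "valid": int(s.valid)} for s in samples],
        columns=GAZE_COLUMNS,
    )
    df.to_csv(path, index=False)


def _detection_from_row(
    row: tuple, path: Path, i: int, source: DetectionSource
) -> Detection:
    # row follows DETECTION_COLUMNS order ("class" is a keyword, so no
    # attribute access through itertuples here).
    frame, track_id, class_label, conf, x, y, w, h = row[:8]
    w, h = float(w), float(h)
    if w <= 0 or h <= 0:
        raise FormatError(f"{path}: non-positive box size ({w} x {h}) at row {i}")
    track = int(track_id) if _is_number(track_id) and int(track_id) >= 0 else None
    return Detection(
        frame_index=int(frame),
        class_label=str(class_label),
        confidence=float(conf),
        box=BoundingBox(float(x), float(y), w, h),
        track_id=track,
        source=source,
    )


def read_detections_csv(path: str | Path) -> list[Detection]:
    """Read a MOT-like detections table (one bounding box per row)."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, DETECTION_COLUMNS, path)
    rows = df[DETECTION_COLUMNS].itertuples(index=False, name=None)
    return [
        _detection_from_row(row, path, i, DetectionSource.DETECTOR)
        for i, row in enumerate(rows)
    ]


def write_detections_csv(detections: Iterable[Detection], path: str | Path) -> None:
    rows = []
    for d in detections:
        rows.append(
            {
                "frame": d.frame_index,
                "track_id": d.track_id if d.track_id is not None else -1,
                "class": d.class_label,
                "conf": d.confidence,
                "x": d.box.x_min_px,
                "y": d.box.y_min_px,
                "w": d.box.width_px,
                "h": d.box.height_px,
            }
        )
    pd.DataFrame(rows, columns=DETECTION_COLUMNS).to_csv(path, index=False)


def read_corrections_csv(path: str | Path) -> list[tuple[str, Detection]]:
    """Read manual corrections: (action, detection) pairs in file order."""
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, CORRECTION_COLUMNS, path)
    out: list[tuple[str, Detection]] = []
    rows = df[CORRECTION_COLUMNS].itertuples(index=False, name=None)
    for i, row in enumerate(rows):
        action = str(row[8]).strip().lower()
        if action not in CORRECTION_ACTIONS:
            raise FormatError(f"{path}: unknown action {action!r} at row {i}")
        out.append((action, _detection_from_row(row, path, i, DetectionSource.CORRECTION)))
    return out


def read_simlog_csv(path: str | Path) -> list[SimulatorSample]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, SIMLOG_COLUMNS, path)
    samples: list[SimulatorSample] = []
    prev_t = -math.inf
    for i, row in enumerate(df.itertuples(index=False)):
        t = float(row.t_ms)
        if t <= prev_t:
            raise FormatError(f"{path}: non-increasing timestamp {t} at row {i}")
        prev_t = t
        samples.append(
            SimulatorSample(
                t_ms=t,
                speed_kmh=float(row.speed_kmh),
                distance_m=float(row.distance_m),
                brake_force_N=float(row.brake_N),
                stop_sign_active=bool(int(row.stop_sign)),
            )
        )
    return samples


def write_simlog_csv(samples: Iterable[SimulatorSample], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "t_ms": s.t_ms,
                "speed_kmh": s.speed_kmh,
                "distance_m": s.distance_m,
                "brake_N": s.brake_force_N,
                "stop_sign": int(s.stop_sign_active),
            }
            for s in samples
        ],
        columns=SIMLOG_COLUMNS,
    )
    df.to_csv(path, index=False)


def _fmt_opt(v: float | None) -> str:
    return "" if v is None else repr(float(v))


def write_features_csv(records: Iterable[FeatureRecord], path: str | Path) -> None:
    """Write one row per subject; flags serialise ';'-separated, sorted."""
    rows = []
    for r in records:
        rows.append(
            {
                "subject_id": r.subject_id,
                "fitness": r.fitness.value if r.fitness is not None else "",
                "ttf_ms": _fmt_opt(r.ttf_ms),
                "speed_kmh": _fmt_opt(r.speed_kmh),
                "igd_deg": _fmt_opt(r.igd_deg),
                "ttc_s": _fmt_opt(r.ttc_s),
                "prt_ms": _fmt_opt(r.prt_ms),
                "flags": ";".join(sorted(r.flags)),
            }
        )
    pd.DataFrame(rows, columns=FEATURE_COLUMNS).to_csv(path, index=False)


def read_features_csv(path: str | Path) -> list[FeatureRecord]:
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, FEATURE_COLUMNS, path)
    records: list[FeatureRecord] = []
    for i, row in enumerate(df.itertuples(index=False)):
        fit_raw = row.fitness.strip()
        if fit_raw:
            try:
                fitness = Fitness(fit_raw)
            except ValueError as exc:
                raise FormatError(f"{path}: unknown fitness label {fit_raw!r} at row {i}") from exc
        else:
            fitness = None
        records.append(
            FeatureRecord(
                subject_id=str(row.subject_id),
                fitness=fitness,
                ttf_ms=float(row.ttf_ms) if row.ttf_ms else None,
                speed_kmh=float(row.speed_kmh) if row.speed_kmh else None,
                igd_deg=float(row.igd_deg) if row.igd_deg else None,
                ttc_s=float(row.ttc_s) if row.ttc_s else None,
                prt_ms=float(row.prt_ms) if row.prt_ms else None,
                flags=set(row.flags.split(";")) if row.flags else set(),
            )
        )
    return records


def time_to_frame(t_ms: float, geometry: FrameGeometry) -> int:
    """Map a timestamp to the video frame whose half-open interval
    [i/fps, (i+1)/fps) contains it: ``floor(t_ms * fps / 1000)``."""
    if t_ms < 0:
        raise ValueError("t_ms must be >= 0")
    return int(math.floor(t_ms * geometry.fps / 1000.0))


def frame_start_ms(frame_index: int, geometry: FrameGeometry) -> float:
    """Time at which a frame starts, in ms."""
    return frame_index * 1000.0 / geometry.fps
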