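"""Domain types for the time-to-fixate pipeline.

The pipeline works on three time-synchronised streams recorded during a
driving-simulator hazard scene: per-frame object detections from the scene
camera, raw gaze samples from a head-mounted eye tracker, and the simulator
log (speed, distance to the pedestrians, brake force, stop-sign triggers).
All streams share one clock, expressed in milliseconds from recording start.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

__all__ = [
    "FrameGeometry",
    "BoundingBox",
    "DetectionSource",
    "Detection",
    "GazeSample",
    "SimulatorSample",
    "SceneSegment",
    "Fitness",
    "SessionBundle",
    "PipelineConfig",
    "DetectionTrack",
    "TTFResult",
    "FeatureRecord",
    "FLAG_ANTICIPATORY",
    "FLAG_SUB_SACCADE",
    "FLAG_MISS",
    "FLAG_NO_ONSET",
    "FLAG_TTF_OVER_MAX",
    "FLAG_TTF_IQR_OUTLIER",
    "FLAG_PRT_OUT_OF_RANGE",
    "FLAG_PRT_MISSING",
    "FLAG_IGD_UNAVAILABLE",
    "FLAG_TTC_UNDEFINED",
    "FLAG_SPEED_UNAVAILABLE",
]


# Event / screening flag tokens (serialised ';'-separated in the features CSV).
FLAG_ANTICIPATORY = "anticipatory"
FLAG_SUB_SACCADE = "sub_saccade"
FLAG_MISS = "miss"
FLAG_NO_ONSET = "no_hazard_onset"
FLAG_TTF_OVER_MAX = "ttf_over_max"
FLAG_TTF_IQR_OUTLIER = "ttf_iqr_outlier"
FLAG_PRT_OUT_OF_RANGE = "prt_out_of_range"
FLAG_PRT_MISSING = "prt_missing"
FLAG_IGD_UNAVAILABLE = "igd_unavailable"
FLAG_TTC_UNDEFINED = "ttc_undefined"
FLAG_SPEED_UNAVAILABLE = "speed_unavailable"


@dataclass(frozen=True)
class FrameGeometry:
    """Scene-camera geometry and sampling rates.

    The default matches a 960x540 scene video with gaze sampled at 50 Hz;
    ``fps`` is the video frame rate used for gaze-to-frame alignment and
    defaults to the gaze rate (one frame per gaze period).
    """

    width_px: int = 960
    height_px: int = 540
    fps: float = 50.0
    gaze_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("frame dimensions must be positive")
        if self.fps <= 0 or self.gaze_rate_hz <= 0:
            raise ValueError("sampling rates must be positive")

    @property
    def frame_period_ms(self) -> float:
        return 1000.0 / self.fps

    @property
    def gaze_period_ms(self) -> float:
        return 1000.0 / self.gaze_rate_hz


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned detection rectangle, pixel coordinates, origin top-left.

    Boxes may extend beyond the frame; clipping is a reader option.
    """

    x_min_px: float
    y_min_px: float
    width_px: float
    height_px: float

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("box width and height must be positive")

    @property
    def x_max_px(self) -> float:
        return self.x_min_px + self.width_px

    @property
    def y_max_px(self) -> float:
        return self.y_min_px + self.height_px

    @property
    def center(self) -> tuple[float, float]:
        return (self.x_min_px + self.width_px / 2.0, self.y_min_px + self.height_px / 2.0)

    def iou(self, other: "BoundingBox") -> float:
        """Intersection-over-union with another box."""
        ix = max(0.0, min(self.x_max_px, other.x_max_px) - max(self.x_min_px, other.x_min_px))
        iy = max(0.0, min(self.y_max_px, other.y_max_px) - max(self.y_min_px, other.y_min_px))
        inter = ix * iy
        union = self.width_px * self.height_px + other.width_px * other.height_px - inter
        return inter / union if union > 0 else 0.0


class DetectionSource(str, enum.Enum):
    DETECTOR = "detector"
    CORRECTION = "correction"
    INTERPOLATED = "interpolated"


@dataclass(frozen=True)
class Detection:
    """One per-frame detector output (or manual correction / interpolation)."""

    frame_index: int
    class_label: str
    confidence: float
    box: BoundingBox
    track_id: int | None = None
    source: DetectionSource = DetectionSource.DETECTOR

    def __post_init__(self) -> None:
        if self.frame_index < 0:
            raise ValueError("frame_index must be >= 0")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")


@dataclass(frozen=True)
class GazeSample:
    """One timestamped scene-camera gaze point; invalid samples carry no
    usable coordinates and are retained only for quality-control ratios."""

    t_ms: float
    x_px: float
    y_px: float
    valid: bool = True


@dataclass(frozen=True)
class SimulatorSample:
    """One simulator-log row: ego speed, distance to the pedestrians, brake
    pedal force and whether the stop-sign stimulus is on screen."""

    t_ms: float
    speed_kmh: float
    distance_m: float
    brake_force_N: float
    stop_sign_active: bool = False


@dataclass(frozen=True)
class SceneSegment:
    """Half-open time window [start_ms, end_ms) delimiting the hazard scene
    within the full recording."""

    start_ms: float
    end_ms: float

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("segment start must precede its end")

    def contains(self, t_ms: float) -> bool:
        return self.start_ms <= t_ms < self.end_ms


class Fitness(str, enum.Enum):
    """Fitness-to-drive label: conditionally fit = licensed only within 30 km
    of the patient's residence."""

    FIT = "fit"
    CONDITIONALLY_FIT = "conditionally_fit"
    UNFIT = "unfit"


@dataclass
class SessionBundle:
    """All streams of one subject's hazard scene, on a shared clock."""

    subject_id: str
    geometry: FrameGeometry
    detections: list[Detection]
    gaze: list[GazeSample]
    simlog: list[SimulatorSample]
    fitness: Fitness | None = None
    segment: SceneSegment | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable thresholds of the pipeline.

    ``deg_per_px`` converts pixel distances to visual angle; the default
    derives from an 82-degree horizontal scene-camera field of view over the
    frame width. ``brake_threshold_N`` is the pedal force defining a braking
    response; TTF validity, the PRT window and the 3-IQR outlier rule are the
    cohort screens applied downstream.
    """

    person_class: str = "person"
    min_confidence: float = 0.25
    horizontal_fov_deg: float = 82.0
    deg_per_px: float | None = None  # None -> horizontal_fov_deg / width_px
    ttf_valid_max_ms: float = 500.0
    ttf_min_saccade_ms: float = 120.0
    prt_valid_range_ms: tuple[float, float] = (500.0, 4000.0)
    brake_threshold_N: float = 75.0
    iqr_multiplier: float = 3.0
    tukey_conf: float = 0.95
    glm_alpha: float = 0.001
    max_box_gap_frames: int = 5
    iou_link_threshold: float = 0.3
    igd_search_window_ms: float = 100.0
    qc_missing_gaze_fraction: float = 0.5
    qc_pause_gap_periods: float = 3.0

    def __post_init__(self) -> None:
        lo, hi = self.prt_valid_range_ms
        if not 0 < lo < hi:
            raise ValueError("prt_valid_range_ms must be ordered and positive")
        for name in (
            "min_confidence",
            "horizontal_fov_deg",
            "ttf_valid_max_ms",
            "ttf_min_saccade_ms",
            "brake_threshold_N",
            "iqr_multiplier",
            "tukey_conf",
            "glm_alpha",
            "iou_link_threshold",
            "igd_search_window_ms",
            "qc_missing_gaze_fraction",
            "qc_pause_gap_periods",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_box_gap_frames < 0:
            raise ValueError("max_box_gap_frames must be >= 0")

    def resolve_deg_per_px(self, geometry: FrameGeometry) -> float:
        if self.deg_per_px is not None:
            return self.deg_per_px
        return self.horizontal_fov_deg / geometry.width_px


@dataclass
class DetectionTrack:
    """Frame-ordered detections of one tracked object; gaps are allowed until
    interpolation fills those no wider than ``max_box_gap_frames``."""

    track_id: int
    detections: list[Detection] = field(default_factory=list)

    def __post_init__(self) -> None:
        frames = [d.frame_index for d in self.detections]
        if frames != sorted(frames) or len(set(frames)) != len(frames):
            raise ValueError("track detections must have strictly increasing frames")

    def box_at(self, frame_index: int) -> BoundingBox | None:
        for d in self.detections:
            if d.frame_index == frame_index:
                return d.box
        return None


@dataclass(frozen=True)
class TTFResult:
    """Hazard onset t1, first gaze-on-target t2 and their difference.

    Flags are mutually exclusive: ``anticipatory`` iff TTF == 0 (gaze already
    on the target at onset), ``sub_saccade`` iff 0 < TTF < the minimum
    saccade latency, ``miss`` iff the gaze never enters a target box before
    the segment ends.
    """

    t1_ms: float | None
    t2_ms: float | None
    ttf_ms: float | None
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.ttf_ms is not None and self.ttf_ms < 0:
            raise ValueError("ttf_ms must be >= 0 when present")


@dataclass
class FeatureRecord:
    """One subject's extracted features and screening flags.

    ``ttf_ms`` time to fixate; ``speed_kmh`` ego speed at hazard onset;
    ``igd_deg`` initial gaze distance in visual degrees; ``ttc_s`` time to
    collision at onset; ``prt_ms`` mean perception response time over the
    valid stop-sign repetitions. Any field may be absent (None) with a
    corresponding flag.
    """

    subject_id: str
    fitness: Fitness | None = None
    ttf_ms: float | None = None
    speed_kmh: float | None = None
    igd_deg: float | None = None
    ttc_s: float | None = None
    prt_ms: float | None = None
    flags: set[str] = field(default_factory=set)

    def with_flags(self, *tokens: str) -> "FeatureRecord":
        return replace(self, flags=set(self.flags) | set(tokens))


def euclidean_px(x1: float, y1: float, x2: float, y2: float) -> float:
    """Plain Euclidean distance in pixels."""
    return math.hypot(x2 - x1, y2 - y1)
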