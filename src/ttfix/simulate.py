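"""Synthetic driving-simulator sessions and cohorts with known ground truth.

``generate_session`` emulates the hazard scene the pipeline is built for: a
pedestrian (person-class track) enters the frame at a configured video
frame and follows a linear trajectory; the driver's gaze holds a road-centre
fixation and then, after a configured latency (the ground-truth TTF), jumps
onto the pedestrian box centre with Gaussian noise and optional linear
slippage drift; the simulator log carries a speed/distance profile, stop-sign
triggers and step brake responses after configured delays. Everything is
deterministic given the seed.

``generate_cohort`` draws per-subject feature records whose per-group TTF
and PRT distributions follow configured means and standard deviations
(truncated normal inside the validity windows, so un-injected records
survive the screens) with lognormal speed/IGD/TTC covariates; outliers
beyond the TTF validity cap can be injected deliberately.

The gaze model is fixation -> single step into the box (no saccade
kinematics): the pipeline's gaze-in-box event needs timing realism, not
velocity realism.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import frame_start_ms
from .types import (
    BoundingBox,
    Detection,
    DetectionSource,
    FeatureRecord,
    Fitness,
    FrameGeometry,
    GazeSample,
    SceneSegment,
    SessionBundle,
    SimulatorSample,
)

__all__ = [
    "SessionSpec",
    "CohortSpec",
    "GroupSpec",
    "GroundTruth",
    "generate_session",
    "generate_cohort",
    "render_frames",
    "detect_frames",
    "render_session_video",
    "TABLE_GROUP_DEFAULTS",
]


@dataclass(frozen=True)
class SessionSpec:
    """Parameters of one synthetic hazard session."""

    seed: int = 0
    geometry: FrameGeometry = field(default_factory=FrameGeometry)
    duration_ms: float = 8000.0
    hazard_entry_frame: int = 100
    box_entry_xy: tuple[float, float] = (700.0, 280.0)
    box_velocity_px: tuple[float, float] = (-3.0, 0.0)  # px per frame
    box_size_px: tuple[float, float] = (36.0, 72.0)
    detector_confidence: float = 0.9
    gaze_latency_ms: float = 240.0  # ground-truth TTF
    gaze_noise_px: float = 2.0
    slippage_drift_px_per_s: float = 0.0
    missing_fraction: float = 0.0
    fixation_xy: tuple[float, float] = (300.0, 270.0)
    stop_sign_times_ms: tuple[float, ...] = (1000.0, 3600.0, 6200.0)
    brake_delay_ms: tuple[float, ...] = (700.0, 900.0, 1100.0)
    brake_force_N: float = 150.0
    speed_kmh: float = 30.0
    initial_distance_m: float = 60.0
    simlog_rate_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.gaze_latency_ms < 0:
            raise ValueError("gaze_latency_ms must be >= 0")
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ValueError("missing_fraction must lie in [0, 1)")
        if self.hazard_entry_frame < 0:
            raise ValueError("hazard_entry_frame must be >= 0")


@dataclass(frozen=True)
class GroundTruth:
    """Construction-time truth for one synthetic session."""

    t1_ms: float
    t2_ms: float | None
    ttf_ms: float | None
    prts_ms: tuple[float, ...]


def _box_at_frame(spec: SessionSpec, frame: int) -> BoundingBox:
    k = frame - spec.hazard_entry_frame
    x = spec.box_entry_xy[0] + k * spec.box_velocity_px[0]
    y = spec.box_entry_xy[1] + k * spec.box_velocity_px[1]
    return BoundingBox(x, y, spec.box_size_px[0], spec.box_size_px[1])


def _box_on_screen(box: BoundingBox, geom: FrameGeometry) -> bool:
    return (
        box.x_max_px > 0
        and box.x_min_px < geom.width_px
        and box.y_max_px > 0
        and box.y_min_px < geom.height_px
    )


def generate_session(
    spec: SessionSpec, subject_id: str = "synthetic", fitness: Fitness | None = None
) -> tuple[SessionBundle, GroundTruth]:
    """Build one session plus its ground truth; bit-reproducible per seed."""
    rng = np.random.default_rng(spec.seed)
    geom = spec.geometry
    n_frames = int(math.ceil(spec.duration_ms / geom.frame_period_ms))

    t1 = frame_start_ms(spec.hazard_entry_frame, geom)
    arrival = t1 + spec.gaze_latency_ms
    if t1 >= spec.duration_ms:
        raise ValueError("hazard entry lies beyond the session duration")

    detections: list[Detection] = []
    for frame in range(spec.hazard_entry_frame, n_frames):
        box = _box_at_frame(spec, frame)
        if not _box_on_screen(box, geom):
            break
        detections.append(
            Detection(
                frame_index=frame,
                class_label="person",
                confidence=spec.detector_confidence,
                box=box,
                track_id=1,
                source=DetectionSource.DETECTOR,
            )
        )
    if detections:
        last_t = frame_start_ms(detections[-1].frame_index, geom)
        if last_t < arrival and arrival < spec.duration_ms:
            raise ValueError("box trajectory leaves the frame before gaze arrival")

    period = geom.gaze_period_ms
    n_gaze = int(math.ceil(spec.duration_ms / period))
    gaze: list[GazeSample] = []
    gt_t2: float | None = None
    for i in range(n_gaze):
        t = i * period
        drift = spec.slippage_drift_px_per_s * t / 1000.0
        if t < arrival:
            x, y = spec.fixation_xy
        else:
            frame = min(int(t // geom.frame_period_ms), n_frames - 1)
            box = _box_at_frame(spec, max(frame, spec.hazard_entry_frame))
            x, y = box.center
        noise = rng.normal(0.0, spec.gaze_noise_px, size=2) if spec.gaze_noise_px > 0 else (0.0, 0.0)
        valid = bool(rng.random() >= spec.missing_fraction)
        gaze.append(
            GazeSample(
                t_ms=t,
                x_px=x + noise[0] + drift,
                y_px=y + noise[1] + drift,
                valid=valid,
            )
        )
        if gt_t2 is None and valid and t >= arrival:
            gt_t2 = t

    sim_period = 1000.0 / spec.simlog_rate_hz
    n_sim = int(math.ceil(spec.duration_ms / sim_period))
    speed_ms = spec.speed_kmh / 3.6
    prts: list[float] = []
    brake_windows: list[tuple[float, float]] = []
    triggers = spec.stop_sign_times_ms
    for i, (trig, delay) in enumerate(zip(triggers, spec.brake_delay_ms)):
        window = (trig + delay, trig + delay + 600.0)
        if i + 1 < len(triggers) and window[1] >= triggers[i + 1]:
            raise ValueError(
                f"brake window after trigger {i} reaches the next stop sign; "
                "shorten the delay or space the triggers"
            )
        brake_windows.append(window)
        prts.append(delay)
    simlog: list[SimulatorSample] = []
    for i in range(n_sim):
        t = i * sim_period
        braking = any(lo <= t <= hi for lo, hi in brake_windows)
        sign_on = any(trig <= t < trig + 500.0 for trig in spec.stop_sign_times_ms)
        simlog.append(
            SimulatorSample(
                t_ms=t,
                speed_kmh=spec.speed_kmh,
                distance_m=max(0.0, spec.initial_distance_m - speed_ms * t / 1000.0),
                brake_force_N=spec.brake_force_N if braking else 0.0,
                stop_sign_active=sign_on,
            )
        )

    session = SessionBundle(
        subject_id=subject_id,
        geometry=geom,
        detections=detections,
        gaze=gaze,
        simlog=simlog,
        fitness=fitness,
        segment=SceneSegment(0.0, spec.duration_ms),
    )
    truth = GroundTruth(
        t1_ms=t1,
        t2_ms=gt_t2,
        ttf_ms=None if gt_t2 is None else gt_t2 - t1,
        prts_ms=tuple(prts),
    )
    return session, truth


@dataclass(frozen=True)
class GroupSpec:
    """Per-group sampling parameters for a synthetic cohort."""

    n: int
    ttf_mean: float
    ttf_sd: float
    prt_mean: float
    prt_sd: float
    speed_mean: float = 19.5
    speed_sd: float = 10.5
    igd_mean: float = 5.0
    igd_sd: float = 4.0
    ttc_mean: float = 3.8
    ttc_sd: float = 3.5

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("each group needs n >= 2")


# Defaults emulating the three fitness-to-drive groups of the study cohort
# (TTF/PRT means and SDs in ms; speed km/h, IGD degrees, TTC seconds).
TABLE_GROUP_DEFAULTS: dict[Fitness, GroupSpec] = {
    Fitness.FIT: GroupSpec(
        n=20, ttf_mean=163, ttf_sd=47, prt_mean=1241, prt_sd=475,
        speed_mean=19.5, speed_sd=10.5, igd_mean=6.67, igd_sd=6.35,
        ttc_mean=3.3, ttc_sd=2.6,
    ),
    Fitness.CONDITIONALLY_FIT: GroupSpec(
        n=17, ttf_mean=293, ttf_sd=95, prt_mean=1215.98, prt_sd=358,
        speed_mean=19.1, speed_sd=11.4, igd_mean=3.90, igd_sd=2.20,
        ttc_mean=3.9, ttc_sd=3.5,
    ),
    Fitness.UNFIT: GroupSpec(
        n=19, ttf_mean=262, ttf_sd=99, prt_mean=1696, prt_sd=449,
        speed_mean=20.3, speed_sd=10.9, igd_mean=4.99, igd_sd=4.76,
        ttc_mean=4.2, ttc_sd=4.7,
    ),
}

TTF_BOUNDS_MS = (100.0, 500.0)
PRT_BOUNDS_MS = (500.0, 4000.0)


@dataclass(frozen=True)
class CohortSpec:
    seed: int = 0
    groups: dict[Fitness, GroupSpec] = field(
        default_factory=lambda: dict(TABLE_GROUP_DEFAULTS)
    )
    ttf_bounds_ms: tuple[float, float] = TTF_BOUNDS_MS
    prt_bounds_ms: tuple[float, float] = PRT_BOUNDS_MS
    outlier_count: int = 0
    outlier_range_ms: tuple[float, float] = (600.0, 1500.0)

    def __post_init__(self) -> None:
        for fitness, g in self.groups.items():
            if not self.ttf_bounds_ms[0] <= g.ttf_mean <= self.ttf_bounds_ms[1]:
                raise ValueError(
                    f"{fitness.value}: TTF mean {g.ttf_mean} outside truncation bounds"
                )
            if not self.prt_bounds_ms[0] <= g.prt_mean <= self.prt_bounds_ms[1]:
                raise ValueError(
                    f"{fitness.value}: PRT mean {g.prt_mean} outside truncation bounds"
                )


def _truncnorm(rng, mean: float, sd: float, lo: float, hi: float, n: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def _lognormal(rng, mean: float, sd: float, n: int) -> np.ndarray:
    # moment-matched lognormal (right-skewed, strictly positive)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=n)


def generate_cohort(spec: CohortSpec) -> list[FeatureRecord]:
    """Draw one synthetic cohort; deterministic given the seed."""
    rng = np.random.default_rng(spec.seed)
    records: list[FeatureRecord] = []
    idx = 0
    for fitness, g in spec.groups.items():
        ttf = _truncnorm(rng, g.ttf_mean, g.ttf_sd, *spec.ttf_bounds_ms, n=g.n)
        prt = _truncnorm(rng, g.prt_mean, g.prt_sd, *spec.prt_bounds_ms, n=g.n)
        speed = _lognormal(rng, g.speed_mean, g.speed_sd, g.n)
        igd = _lognormal(rng, g.igd_mean, g.igd_sd, g.n)
        ttc = _lognormal(rng, g.ttc_mean, g.ttc_sd, g.n)
        for j in range(g.n):
            records.append(
                FeatureRecord(
                    subject_id=f"S{idx:03d}",
                    fitness=fitness,
                    ttf_ms=float(ttf[j]),
                    speed_kmh=float(speed[j]),
                    igd_deg=float(igd[j]),
                    ttc_s=float(ttc[j]),
                    prt_ms=float(prt[j]),
                )
            )
            idx += 1
    if spec.outlier_count:
        if spec.outlier_count > len(records):
            raise ValueError("more injected outliers than records")
        chosen = rng.choice(len(records), size=spec.outlier_count, replace=False)
        lo, hi = spec.outlier_range_ms
        for i in chosen:
            records[int(i)].ttf_ms = float(rng.uniform(lo, hi))
    return records


# --- optional rendering path (exercises the detector-adapter contract) -----

_BOX_COLOR = (220, 30, 30)


def render_frames(session: SessionBundle) -> list[np.ndarray]:
    """Rasterise the session as RGB frames with a filled rectangle per box."""
    geom = session.geometry
    by_frame: dict[int, list[BoundingBox]] = {}
    for d in session.detections:
        by_frame.setdefault(d.frame_index, []).append(d.box)
    n_frames = max(by_frame, default=-1) + 1
    frames: list[np.ndarray] = []
    for f in range(n_frames):
        img = np.full((geom.height_px, geom.width_px, 3), 255, dtype=np.uint8)
        for box in by_frame.get(f, ()):
            y0 = max(0, int(round(box.y_min_px)))
            y1 = min(geom.height_px, int(round(box.y_max_px)))
            x0 = max(0, int(round(box.x_min_px)))
            x1 = min(geom.width_px, int(round(box.x_max_px)))
            if y1 > y0 and x1 > x0:
                img[y0:y1, x0:x1] = _BOX_COLOR
        frames.append(img)
    return frames


def detect_frames(frames: list[np.ndarray], confidence: float = 1.0) -> list[Detection]:
    """Trivial colour-threshold detector: the bounding box of the marked
    pixels in each frame (one box per frame)."""
    out: list[Detection] = []
    for f, img in enumerate(frames):
        mask = (img[:, :, 0] > 150) & (img[:, :, 1] < 100) & (img[:, :, 2] < 100)
        ys, xs = np.nonzero(mask)
        if ys.size == 0:
            continue
        x0, x1 = int(xs.min()), int(xs.max()) + 1
        y0, y1 = int(ys.min()), int(ys.max()) + 1
        out.append(
            Detection(
                frame_index=f,
                class_label="person",
                confidence=confidence,
                box=BoundingBox(float(x0), float(y0), float(x1 - x0), float(y1 - y0)),
                track_id=1,
            )
        )
    return out


def render_session_video(session: SessionBundle, path) -> int:
    """Write the rendered frames as a lossless PNG sequence under ``path``
    (a directory); returns the number of frames written."""
    import imageio.v3 as iio
    from pathlib import Path

    out_dir = Path(path)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = render_frames(session)
    for i, img in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{i:05d}.png", img)
    return len(frames)
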