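"""Auxiliary hazard-perception features: IGD, TTC, onset speed, PRT, and the
type-B timing uncertainty.

* IGD (initial gaze distance): Euclidean pixel distance from the gaze point
  at hazard onset to the centre of the pedestrian bounding box, rounded to
  the nearest integer pixel, then converted to visual degrees.
* TTC (time to collision): ego-vehicle distance to the pedestrians divided
  by ego speed, both read from the simulator log at hazard onset.
* PRT (perception response time): time from a stop-sign trigger until the
  brake pedal force first reaches the response threshold (75 N by default);
  repetitions outside the plausibility window are discarded before
  averaging.
"""

from __future__ import annotations

import math
from bisect import bisect_left
from dataclasses import dataclass

from .types import GazeSample, PipelineConfig, SimulatorSample, BoundingBox

__all__ = [
    "FeatureUnavailable",
    "UncertaintySpec",
    "initial_gaze_distance",
    "gaze_near",
    "time_to_collision",
    "speed_at_onset",
    "distance_at_onset",
    "perception_response_time",
    "stop_sign_triggers",
    "average_prt",
    "type_b_uncertainty",
]


class FeatureUnavailable(Exception):
    """A feature cannot be computed from the available streams."""


@dataclass(frozen=True)
class UncertaintySpec:
    """Timing resolution of the measurement chain (default: one 50 Hz video
    frame period, 20 ms)."""

    resolution_ms: float = 20.0

    def __post_init__(self) -> None:
        if self.resolution_ms < 0:
            raise ValueError("resolution_ms must be >= 0")


def gaze_near(
    gaze: list[GazeSample], t_ms: float, window_ms: float = 100.0
) -> GazeSample | None:
    """The valid gaze sample nearest in time to ``t_ms`` within ±window_ms;
    ties go to the earlier sample."""
    best: GazeSample | None = None
    best_dt = window_ms
    for s in gaze:
        if not s.valid:
            continue
        dt = abs(s.t_ms - t_ms)
        if dt < best_dt or (dt == best_dt and best is None):
            best = s
            best_dt = dt
    return best


def initial_gaze_distance(
    gaze_at_t1: GazeSample, box_at_t1: BoundingBox, deg_per_px: float
) -> float:
    """IGD in visual degrees: pixel distance from the gaze point to the box
    centre, rounded to the nearest integer pixel before angle conversion."""
    cx, cy = box_at_t1.center
    d_px = round(math.hypot(gaze_at_t1.x_px - cx, gaze_at_t1.y_px - cy))
    return d_px * deg_per_px


def time_to_collision(distance_m: float, speed_kmh: float) -> float:
    """TTC in seconds: distance over speed (km/h converted to m/s)."""
    if speed_kmh <= 0:
        raise FeatureUnavailable("TTC undefined at non-positive speed")
    return distance_m / (speed_kmh / 3.6)


def _nearest_sample(simlog: list[SimulatorSample], t_ms: float) -> SimulatorSample:
    if not simlog:
        raise FeatureUnavailable("empty simulator log")
    if not simlog[0].t_ms <= t_ms <= simlog[-1].t_ms:
        raise FeatureUnavailable(f"t={t_ms} ms outside simulator log span")
    times = [s.t_ms for s in simlog]
    i = bisect_left(times, t_ms)
    if i == 0:
        return simlog[0]
    if i < len(times) and times[i] == t_ms:
        return simlog[i]
    before = simlog[i - 1]
    after = simlog[i] if i < len(simlog) else before
    # ties -> earlier sample
    if t_ms - before.t_ms <= after.t_ms - t_ms:
        return before
    return after


def speed_at_onset(simlog: list[SimulatorSample], t1_ms: float) -> float:
    """Ego speed of the log sample nearest in time to hazard onset
    (ties break to the earlier sample)."""
    return _nearest_sample(simlog, t1_ms).speed_kmh


def distance_at_onset(simlog: list[SimulatorSample], t1_ms: float) -> float:
    """Distance to the pedestrians at hazard onset (same nearest-sample rule)."""
    return _nearest_sample(simlog, t1_ms).distance_m


def stop_sign_triggers(simlog: list[SimulatorSample]) -> list[float]:
    """Rising edges of the stop-sign stimulus in the simulator log."""
    triggers: list[float] = []
    prev = False
    for s in simlog:
        if s.stop_sign_active and not prev:
            triggers.append(s.t_ms)
        prev = s.stop_sign_active
    return triggers


def perception_response_time(
    simlog: list[SimulatorSample],
    trigger_t_ms: float,
    config: PipelineConfig,
    next_trigger_t_ms: float | None = None,
) -> float | None:
    """PRT for one stop-sign repetition: time from the trigger to the first
    sample strictly after it with brake force >= the threshold, searched up
    to the next trigger (or log end). A brake already above threshold at the
    trigger instant is not a response. Returns None on a miss."""
    end = next_trigger_t_ms if next_trigger_t_ms is not None else math.inf
    for s in simlog:
        if s.t_ms <= trigger_t_ms:
            continue
        if s.t_ms >= end:
            break
        if s.brake_force_N >= config.brake_threshold_N:
            return s.t_ms - trigger_t_ms
    return None


def average_prt(prts: list[float | None], config: PipelineConfig) -> float | None:
    """Mean of the PRT repetitions that fall inside the validity window
    (missing repetitions and out-of-range values are dropped); None when no
    repetition survives."""
    lo, hi = config.prt_valid_range_ms
    valid = [p for p in prts if p is not None and lo <= p <= hi]
    if not valid:
        return None
    return sum(valid) / len(valid)


def type_b_uncertainty(spec: UncertaintySpec) -> float:
    """Type-B standard uncertainty of an event time read off a clock with
    resolution r, assuming a uniform error over ±r/2: u = r / (2*sqrt(3))."""
    return spec.resolution_ms / (2.0 * math.sqrt(3.0))
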