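"""Session-level quality control and cohort-level validity/outlier screening.

Session QC reproduces the exclusion taxonomy of manual review: frozen gaze
(zero coordinate variance across the segment), excessive missing gaze data,
recording pauses, anticipatory perception, no hazard onset, and gaze misses.

Cohort screening applies two rules to time-to-fixate values: a pointwise
validity cap (a TTF at or above 500 ms counts as a miss — the driver
reacting too late or not at all) and a one-sided interquartile-range rule
(values more than three IQRs above the third quartile are outliers).
Perception response times are range-filtered per repetition before
averaging, then the same IQR rule applies to the averaged values. All flags
are computed in a single pass on the original cohort, never on an
already-filtered one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import average_prt
from .types import (
    FLAG_ANTICIPATORY,
    FLAG_MISS,
    FLAG_NO_ONSET,
    FLAG_PRT_MISSING,
    FLAG_PRT_OUT_OF_RANGE,
    FLAG_TTF_IQR_OUTLIER,
    FLAG_TTF_OVER_MAX,
    FeatureRecord,
    PipelineConfig,
    SessionBundle,
    TTFResult,
)

__all__ = ["QCReport", "qc_session", "screen_ttf", "screen_prt", "iqr_upper_fence"]


@dataclass
class QCReport:
    """Per-session QC outcome: check name -> (passed, measured quantity)."""

    subject_id: str
    checks: dict[str, tuple[bool, float | None]] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return all(ok for ok, _ in self.checks.values())

    @property
    def failures(self) -> list[str]:
        return [name for name, (ok, _) in self.checks.items() if not ok]

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "passed": self.passed,
            "checks": {
                name: {"pass": ok, "measured": measured}
                for name, (ok, measured) in self.checks.items()
            },
        }


def qc_session(
    session: SessionBundle,
    config: PipelineConfig,
    ttf: TTFResult | None = None,
) -> QCReport:
    """Session-level QC; event-flag checks are copied from the TTF result
    when one is supplied."""
    report = QCReport(subject_id=session.subject_id)
    seg = session.segment
    gaze = session.gaze
    if seg is not None:
        gaze = [s for s in gaze if seg.contains(s.t_ms)]

    valid = [s for s in gaze if s.valid]
    if valid:
        xs = np.array([s.x_px for s in valid])
        ys = np.array([s.y_px for s in valid])
        frozen = bool(np.var(xs) == 0.0 and np.var(ys) == 0.0) and len(valid) > 1
        report.checks["frozen_gaze"] = (not frozen, float(np.var(xs) + np.var(ys)))
    else:
        report.checks["frozen_gaze"] = (False, 0.0)

    missing_frac = 1.0 - len(valid) / len(gaze) if gaze else 1.0
    report.checks["missing_gaze"] = (
        missing_frac <= config.qc_missing_gaze_fraction,
        missing_frac,
    )

    max_gap_ms = config.qc_pause_gap_periods * session.geometry.gaze_period_ms
    gaps = [b.t_ms - a.t_ms for a, b in zip(gaze, gaze[1:])]
    worst = max(gaps) if gaps else 0.0
    report.checks["recording_pause"] = (worst <= max_gap_ms, worst)

    if ttf is not None:
        report.checks["anticipatory"] = (FLAG_ANTICIPATORY not in ttf.flags, None)
        report.checks["no_onset"] = (FLAG_NO_ONSET not in ttf.flags, None)
        report.checks["miss"] = (FLAG_MISS not in ttf.flags, None)
    return report


def iqr_upper_fence(values: np.ndarray, multiplier: float) -> float:
    """Q3 + multiplier * IQR, quartiles by linear interpolation between order
    statistics (the convention of common statistical environments)."""
    q1, q3 = np.quantile(values, [0.25, 0.75], method="linear")
    return float(q3 + multiplier * (q3 - q1))


def screen_ttf(cohort: list[FeatureRecord], config: PipelineConfig) -> list[FeatureRecord]:
    """Flag invalid and outlying TTFs on the pooled cohort, single-pass.

    A record gains ``ttf_over_max`` when its TTF reaches the validity cap
    and ``ttf_iqr_outlier`` when it exceeds the 3-IQR fence above Q3 of the
    pooled TTF sample. The removal set is the union of both flags; flagged
    values are retained in the returned records.
    """
    values = np.array([r.ttf_ms for r in cohort if r.ttf_ms is not None], dtype=float)
    fence = None
    if values.size >= 4:
        fence = iqr_upper_fence(values, config.iqr_multiplier)
    elif values.size > 0:
        warnings.warn(
            "fewer than 4 TTF values: IQR outlier rule skipped (quartiles unstable)",
            stacklevel=2,
        )
    out: list[FeatureRecord] = []
    for r in cohort:
        flags = set(r.flags)
        if r.ttf_ms is not None:
            if r.ttf_ms >= config.ttf_valid_max_ms:
                flags.add(FLAG_TTF_OVER_MAX)
            if fence is not None and r.ttf_ms > fence:
                flags.add(FLAG_TTF_IQR_OUTLIER)
        out.append(FeatureRecord(**{**r.__dict__, "flags": flags}))
    return out


def screen_prt(
    cohort: list[FeatureRecord],
    config: PipelineConfig,
    repetitions: dict[str, list[float | None]] | None = None,
) -> list[FeatureRecord]:
    """Screen PRTs: when per-repetition values are supplied, the validity
    window is applied per repetition and the mean of the survivors replaces
    ``prt_ms`` (absent if none survive); the IQR rule then flags outliers
    among the averaged PRTs."""
    out: list[FeatureRecord] = []
    for r in cohort:
        flags = set(r.flags)
        prt = r.prt_ms
        if repetitions is not None and r.subject_id in repetitions:
            reps = repetitions[r.subject_id]
            prt = average_prt(reps, config)
            if prt is None:
                flags.add(FLAG_PRT_MISSING)
            if any(
                p is not None
                and not (config.prt_valid_range_ms[0] <= p <= config.prt_valid_range_ms[1])
                for p in reps
            ):
                flags.add(FLAG_PRT_OUT_OF_RANGE)
        out.append(FeatureRecord(**{**r.__dict__, "prt_ms": prt, "flags": flags}))

    averaged = np.array([r.prt_ms for r in out if r.prt_ms is not None], dtype=float)
    if averaged.size >= 4:
        fence = iqr_upper_fence(averaged, config.iqr_multiplier)
        for i, r in enumerate(out):
            if r.prt_ms is not None and r.prt_ms > fence:
                out[i] = r.with_flags("prt_iqr_outlier")
    return out
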