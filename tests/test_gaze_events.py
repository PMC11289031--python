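"""Track assembly, hit testing, hazard onset / first-fixation events and TTF."""

from __future__ import annotations

import numpy as np
import pytest

from conftest import brute_force_ttf, random_session_spec
from ttfix.gaze_events import (
    NoHazardOnset,
    apply_corrections,
    build_tracks,
    compute_ttf,
    first_gaze_on_target,
    hazard_onset,
    interpolate_boxes,
    point_in_box,
)
from ttfix.simulate import SessionSpec, generate_session
from ttfix.types import (
    BoundingBox,
    Detection,
    DetectionSource,
    DetectionTrack,
    FrameGeometry,
    GazeSample,
    PipelineConfig,
    SceneSegment,
)


def det(frame, x=100.0, y=100.0, w=40.0, h=80.0, conf=0.9, cls="person", track=None):
    return Detection(frame, cls, conf, BoundingBox(x, y, w, h), track_id=track)


class TestCorrections:
    def test_empty_corrections_identity(self):
        dets = [det(0, track=1), det(1, track=1)]
        assert apply_corrections(dets, []) == dets

    def test_add_on_empty_frame(self):
        dets = [det(0, track=1)]
        out = apply_corrections(dets, [("add", det(5, track=2))])
        added = [d for d in out if d.frame_index == 5]
        assert len(added) == 1 and added[0].source is DetectionSource.CORRECTION

    def test_replace_and_delete(self):
        dets = [det(0, x=10, track=1), det(1, track=1)]
        out = apply_corrections(
            dets,
            [("replace", det(0, x=99, track=1)), ("delete", det(1, track=1))],
        )
        assert len(out) == 1
        assert out[0].box.x_min_px == 99 and out[0].source is DetectionSource.CORRECTION

    def test_delete_nonexistent_is_noop(self):
        dets = [det(0, track=1)]
        assert apply_corrections(dets, [("delete", det(7, track=9))]) == dets

    def test_random_script_matches_sequential_replay(self):
        """Random corrections vs a naive dict-based replay oracle."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            dets = [
                det(int(f), x=float(rng.uniform(0, 900)), track=int(t))
                for f, t in zip(rng.integers(0, 20, 15), rng.integers(1, 4, 15))
            ]
            # de-duplicate (frame, track) in the base set
            seen, base = set(), []
            for d in dets:
                if (d.frame_index, d.track_id) not in seen:
                    seen.add((d.frame_index, d.track_id))
                    base.append(d)
            script = []
            for _ in range(10):
                action = rng.choice(["add", "replace", "delete"])
                script.append((str(action), det(int(rng.integers(0, 20)),
                                                x=float(rng.uniform(0, 900)),
                                                track=int(rng.integers(1, 4)))))
            # oracle: dict keyed by (frame, track); add appends to a list
            state: dict = {}
            for d in base:
                state[(d.frame_index, d.track_id)] = [d]
            for action, d in script:
                key = (d.frame_index, d.track_id)
                if action == "add":
                    state.setdefault(key, []).append(d)
                elif action == "replace":
                    state[key] = [d]
                else:
                    state.pop(key, None)
            def key(d):
                return (d.frame_index, d.track_id, d.box.x_min_px, d.box.y_min_px)

            expected = sorted(key(d) for v in state.values() for d in v)
            got = apply_corrections(base, script)
            assert sorted(key(d) for d in got) == expected


class TestBuildTracks:
    def test_single_repeated_box_one_track(self, config):
        dets = [det(f, track=None) for f in range(10)]
        tracks = build_tracks(dets, config)
        assert len(tracks) == 1 and len(tracks[0].detections) == 10

    def test_disjoint_boxes_two_tracks(self, config):
        dets = []
        for f in range(5):
            dets.append(det(f, x=50.0))
            dets.append(det(f, x=700.0))
        tracks = build_tracks(dets, config)
        assert len(tracks) == 2
        assert all(len(t.detections) == 5 for t in tracks)

    def test_below_confidence_filtered(self, config):
        dets = [det(f, conf=0.1) for f in range(5)]
        assert build_tracks(dets, config) == []

    def test_track_id_grouping_preserved(self, config):
        dets = [det(f, track=7) for f in range(4)] + [det(f, x=600, track=8) for f in range(4)]
        tracks = build_tracks(dets, config)
        assert sorted(t.track_id for t in tracks) == [7, 8]


class TestInterpolation:
    def test_constant_gap_fill(self):
        track = DetectionTrack(1, [det(10, track=1), det(12, track=1)])
        out = interpolate_boxes(track, max_gap_frames=5)
        frames = [d.frame_index for d in out.detections]
        assert frames == [10, 11, 12]
        mid = out.detections[1]
        assert mid.box == det(10).box and mid.source is DetectionSource.INTERPOLATED

    def test_midpoint_interpolation(self):
        track = DetectionTrack(1, [det(0, x=100, track=1), det(2, x=110, track=1)])
        out = interpolate_boxes(track, max_gap_frames=5)
        assert out.detections[1].box.x_min_px == pytest.approx(105.0)

    def test_gap_beyond_max_left_open(self):
        track = DetectionTrack(1, [det(0, track=1), det(7, track=1)])
        out = interpolate_boxes(track, max_gap_frames=5)
        assert [d.frame_index for d in out.detections] == [0, 7]


class TestPointInBox:
    box = BoundingBox(100, 200, 40, 80)

    def test_center_inside(self):
        assert point_in_box(120, 240, self.box)

    def test_closed_corner(self):
        assert point_in_box(140, 280, self.box)
        assert point_in_box(100, 200, self.box)

    def test_just_outside(self):
        assert not point_in_box(141, 240, self.box)
        assert not point_in_box(120, 281, self.box)


class TestHazardOnset:
    geom = FrameGeometry()
    seg = SceneSegment(0.0, 5000.0)

    def test_first_frame_at_segment_start(self, config):
        tracks = [DetectionTrack(1, [det(0, track=1), det(1, track=1)])]
        assert hazard_onset(tracks, self.seg, self.geom, config) == 0.0

    def test_frame_37_gives_740_ms(self, config):
        tracks = [DetectionTrack(1, [det(37, track=1)])]
        assert hazard_onset(tracks, self.seg, self.geom, config) == 740.0

    def test_no_qualifying_detection_raises(self, config):
        with pytest.raises(NoHazardOnset):
            hazard_onset([], self.seg, self.geom, config)

    def test_raising_min_confidence_never_decreases_t1(self):
        rng = np.random.default_rng(4)
        dets = [
            det(int(f), conf=float(rng.uniform(0.2, 1.0)), track=1 + int(f) % 2)
            for f in sorted(rng.choice(100, size=30, replace=False))
        ]
        prev_t1 = -1.0
        for thr in (0.25, 0.4, 0.6, 0.8):
            cfg = PipelineConfig(min_confidence=thr)
            tracks = build_tracks(dets, cfg)
            try:
                t1 = hazard_onset(tracks, self.seg, self.geom, cfg)
            except NoHazardOnset:
                break
            assert t1 >= prev_t1
            prev_t1 = t1


class TestFirstGaze:
    geom = FrameGeometry()
    seg = SceneSegment(0.0, 5000.0)

    def _tracks(self):
        return [DetectionTrack(1, [det(f, track=1) for f in range(100, 150)])]

    def test_anticipatory_at_t1(self):
        gaze = [GazeSample(2000.0, 120.0, 140.0)]
        t2 = first_gaze_on_target(gaze, self._tracks(), 2000.0, self.seg, self.geom)
        assert t2 == 2000.0

    def test_entry_at_2240_found_by_scan(self):
        gaze = [GazeSample(t, 500.0, 400.0) for t in np.arange(0, 2240, 20.0)]
        gaze += [GazeSample(t, 120.0, 140.0) for t in np.arange(2240, 3000, 20.0)]
        t2 = first_gaze_on_target(gaze, self._tracks(), 2000.0, self.seg, self.geom)
        assert t2 == 2240.0

    def test_never_enters_is_miss(self):
        gaze = [GazeSample(t, 500.0, 400.0) for t in np.arange(0, 3000, 20.0)]
        assert first_gaze_on_target(gaze, self._tracks(), 2000.0, self.seg, self.geom) is None

    def test_invalid_samples_cannot_certify(self):
        gaze = [GazeSample(2000.0, 120.0, 140.0, valid=False),
                GazeSample(2020.0, 120.0, 140.0, valid=True)]
        t2 = first_gaze_on_target(gaze, self._tracks(), 2000.0, self.seg, self.geom)
        assert t2 == 2020.0


class TestComputeTTF:
    def test_clean_session_latency_240(self, config):
        session, truth = generate_session(SessionSpec(seed=1, gaze_noise_px=0.0))
        res = compute_ttf(session, config)
        assert res.t1_ms == truth.t1_ms == 2000.0
        assert res.ttf_ms == 240.0 and res.flags == frozenset()

    def test_anticipatory_zero_latency(self, config):
        session, _ = generate_session(SessionSpec(seed=2, gaze_latency_ms=0.0, gaze_noise_px=0.0))
        res = compute_ttf(session, config)
        assert res.ttf_ms == 0.0 and res.flags == frozenset({"anticipatory"})

    def test_sub_saccade_flagged_but_kept(self, config):
        session, _ = generate_session(SessionSpec(seed=3, gaze_latency_ms=60.0, gaze_noise_px=0.0))
        res = compute_ttf(session, config)
        assert res.ttf_ms == 60.0 and res.flags == frozenset({"sub_saccade"})

    def test_flags_mutually_exclusive_on_random_sessions(self, config):
        rng = np.random.default_rng(10)
        for _ in range(50):
            session, _ = generate_session(random_session_spec(rng))
            res = compute_ttf(session, config)
            assert len(res.flags & {"anticipatory", "sub_saccade", "miss"}) <= 1
            assert ("miss" in res.flags) == (res.t2_ms is None and res.t1_ms is not None)

    def test_matches_brute_force_oracle(self, config):
        """Pipeline equals the flat (gaze sample x box) scan on 200 random sessions."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            session, _ = generate_session(random_session_spec(rng))
            res = compute_ttf(session, config)
            t1, t2, flags = brute_force_ttf(session, config)
            assert res.t1_ms == t1
            assert res.t2_ms == t2
            assert set(res.flags) == flags

    def test_time_translation_invariance(self, config):
        """Shifting all streams by a constant leaves TTF unchanged."""
        from ttfix.types import SessionBundle

        session, _ = generate_session(SessionSpec(seed=12, gaze_noise_px=3.0))
        base = compute_ttf(session, config)
        shift = 40.0  # two frame periods, keeps gaze/frame alignment consistent
        shifted = SessionBundle(
            subject_id=session.subject_id,
            geometry=session.geometry,
            detections=[
                Detection(d.frame_index + 2, d.class_label, d.confidence, d.box,
                          d.track_id, d.source)
                for d in session.detections
            ],
            gaze=[GazeSample(s.t_ms + shift, s.x_px, s.y_px, s.valid) for s in session.gaze],
            simlog=session.simlog,
            segment=SceneSegment(session.segment.start_ms + shift,
                                 session.segment.end_ms + shift),
        )
        res = compute_ttf(shifted, config)
        assert res.ttf_ms == base.ttf_ms
        assert res.t1_ms == base.t1_ms + shift

    def test_detections_after_t2_do_not_matter(self, config):
        session, _ = generate_session(SessionSpec(seed=13, gaze_noise_px=0.0))
        base = compute_ttf(session, config)
        extra = det(int(base.t2_ms // 20) + 10, x=5.0, y=5.0, track=99)
        session.detections.append(extra)
        assert compute_ttf(session, config).ttf_ms == base.ttf_ms

    def test_no_person_detection_flags_no_onset(self, config):
        session, _ = generate_session(SessionSpec(seed=14))
        session.detections = []
        res = compute_ttf(session, config)
        assert res.flags == frozenset({"no_hazard_onset"}) and res.ttf_ms is None
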