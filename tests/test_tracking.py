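import numpy as np
import pytest

from rowcount import (
    BoundingBox,
    Detection,
    FrameDetections,
    SortTracker,
    TrackerConfig,
    TrackStatus,
    associate,
    final_count,
    iou,
)
from rowcount.tracking import _KalmanBox, _x_to_box

from .oracles import brute_force_best_assignment


def frame(i, boxes, size=(1920, 1080)):
    return FrameDetections(
        i, [Detection(i, BoundingBox(*b), 0.9) for b in boxes], size
    )


class TestIoU:
    def test_identity(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint(self):
        assert iou(BoundingBox(0, 0, 10, 10), BoundingBox(50, 50, 5, 5)) == 0.0

    def test_half_overlap(self):
        # intersection 50, union 150
        a = BoundingBox(0, 0, 10, 10)
        b = BoundingBox(5, 0, 10, 10)
        assert iou(a, b) == pytest.approx(1 / 3)


class TestKalmanPrediction:
    def test_zero_velocity_fixed_point(self):
        kf = _KalmanBox(BoundingBox(100, 100, 20, 20), q_scale=0.0, r_scale=1.0)
        box = kf.predict()
        assert box.center == (pytest.approx(110), pytest.approx(110))
        assert box.width == pytest.approx(20)

    def test_constant_velocity_closed_form(self):
        kf = _KalmanBox(BoundingBox(100, 100, 20, 20), q_scale=0.0, r_scale=1.0)
        kf.x[5] = 10.0  # dv: +10 px/frame downward
        for step in range(1, 6):
            box = kf.predict()
            assert box.center[1] == pytest.approx(110 + 10 * step)
            assert box.center[0] == pytest.approx(110)

    def test_nonpositive_area_clamped(self):
        kf = _KalmanBox(BoundingBox(0, 0, 4, 4), q_scale=0.0, r_scale=1.0)
        kf.x[6] = -100.0  # area shrinking faster than area itself
        with pytest.warns(UserWarning, match="area"):
            box = kf.predict()
        assert box.area > 0


class TestAssociate:
    def test_single_overlap_matches(self):
        tracks = [BoundingBox(0, 0, 10, 10)]
        dets = frame(1, [(1, 1, 10, 10)])
        matches, ut, ud = associate(tracks, dets, 0.3)
        assert matches == [(0, 0)] and not ut and not ud

    def test_below_threshold_unmatched(self):
        tracks = [BoundingBox(0, 0, 10, 10)]
        dets = frame(1, [(8, 8, 10, 10)])  # IoU ~ 0.02
        matches, ut, ud = associate(tracks, dets, 0.3)
        assert not matches and ut == [0] and ud == [0]

    def test_optimal_against_bruteforce(self, rng):
        for _ in range(30):
            nt, nd = rng.integers(1, 6), rng.integers(1, 6)
            tracks = [
                BoundingBox(x, y, 10 + s, 10 + s)
                for x, y, s in rng.uniform(0, 40, size=(nt, 3))
            ]
            dets = frame(
                1,
                [
                    (x, y, 10 + s, 10 + s)
                    for x, y, s in rng.uniform(0, 40, size=(nd, 3))
                ],
            )
            cost = np.array(
                [[iou(t, d.box) for d in dets.detections] for t in tracks]
            )
            matches, _, _ = associate(tracks, dets, 1e-9)
            got = sum(cost[i, j] for i, j in matches)
            assert got == pytest.approx(brute_force_best_assignment(cost))

    def test_empty_inputs(self):
        assert associate([], frame(1, [(0, 0, 5, 5)]), 0.3) == ([], [], [0])
        assert associate([BoundingBox(0, 0, 5, 5)], frame(1, []), 0.3) == (
            [],
            [0],
            [],
        )


class TestLifecycle:
    def test_single_object_confirmed_at_min_hits(self):
        cfg = TrackerConfig(min_hits=3)
        tracker = SortTracker(cfg, frame_height=1080)
        for i in range(1, 6):
            tracks = tracker.step(frame(i, [(100, 100 + 2 * i, 20, 20)]))
            assert len(tracks) == 1
            expected = (
                TrackStatus.CONFIRMED if i >= 3 else TrackStatus.TENTATIVE
            )
            assert tracks[0].status is expected
        assert final_count(tracker.register) == 1

    def test_long_dropout_spawns_new_id(self):
        cfg = TrackerConfig(min_hits=1, max_age=2)
        tracker = SortTracker(cfg, frame_height=1080)
        tracker.step(frame(1, [(100, 100, 20, 20)]))
        first_id = tracker.tracks[0].track_id
        for i in range(2, 8):
            tracker.step(frame(i, []))
        tracker.step(frame(8, [(100, 100, 20, 20)]))
        alive = [
            t
            for t in tracker.tracks
            if t.status in (TrackStatus.TENTATIVE, TrackStatus.CONFIRMED)
        ]
        assert len(alive) == 1 and alive[0].track_id != first_id

    def test_short_dropout_keeps_id(self):
        cfg = TrackerConfig(min_hits=1, max_age=5)
        tracker = SortTracker(cfg, frame_height=1080)
        tracker.step(frame(1, [(100, 100, 20, 20)]))
        tracker.step(frame(2, []))
        tracker.step(frame(3, [(100, 100, 20, 20)]))
        ids = {t.track_id for t in tracker.tracks}
        assert ids == {1}

    def test_empty_video(self):
        tracker = SortTracker(TrackerConfig(), frame_height=1080)
        for i in range(1, 5):
            assert tracker.step(frame(i, [])) == []
        assert final_count(tracker.register) == 0

    def test_out_of_order_frame_rejected(self):
        tracker = SortTracker(TrackerConfig(), frame_height=1080)
        tracker.step(frame(3, []))
        with pytest.raises(ValueError, match="strictly increasing"):
            tracker.step(frame(3, []))

    def test_hit_streak_resets_after_miss(self):
        cfg = TrackerConfig(min_hits=3, max_age=10)
        tracker = SortTracker(cfg, frame_height=1080)
        b = (100, 100, 20, 20)
        tracker.step(frame(1, [b]))
        tracker.step(frame(2, []))  # miss: streak resets
        tracker.step(frame(3, [b]))
        tracker.step(frame(4, [b]))
        assert tracker.tracks[0].status is TrackStatus.TENTATIVE
        tracker.step(frame(5, [b]))
        assert tracker.tracks[0].status is TrackStatus.CONFIRMED


class TestRetirement:
    def make_tracker(self):
        return SortTracker(
            TrackerConfig(min_hits=1, max_age=3), frame_height=1080
        )

    def test_strict_boundary(self):
        tracker = self.make_tracker()
        tracker.step(frame(1, [(100, 1069, 20, 20)]))  # center v = 1079
        assert tracker.tracks[0].status is TrackStatus.CONFIRMED
        tracker2 = self.make_tracker()
        tracker2.step(frame(1, [(100, 1075, 20, 20)]))  # center v = 1085
        assert tracker2.tracks[0].status is TrackStatus.RETIRED
        assert tracker2.register.retired_ids == {1}

    def test_retired_id_never_revived(self):
        tracker = self.make_tracker()
        tracker.step(frame(1, [(100, 1075, 20, 20)]))
        assert tracker.tracks[0].status is TrackStatus.RETIRED
        tracker.step(frame(2, [(100, 1075, 20, 20)]))
        ids = [t.track_id for t in tracker.tracks]
        assert ids == [1, 2]  # same spot, new id
        assert tracker.tracks[0].status is TrackStatus.RETIRED

    def test_count_modes(self):
        tracker = self.make_tracker()
        tracker.step(frame(1, [(100, 100, 20, 20), (100, 1075, 20, 20)]))
        assert final_count(tracker.register, "confirmed") == 2
        assert final_count(tracker.register, "retired") == 1


class TestConservationOnSimulator:
    def test_every_plant_counted_once(self, small_scene_noisefree):
        sim = small_scene_noisefree
        tracker_cfg = TrackerConfig(min_hits=1)
        tracker = SortTracker(
            tracker_cfg, frame_height=sim.detections.frame_size[1]
        )
        for f in sim.detections.iter_frames():
            tracker.step(f)
        assert final_count(tracker.register) == sim.target_count

    def test_ids_unique_over_run(self, small_scene_noisy):
        sim = small_scene_noisy
        tracker = SortTracker(
            TrackerConfig(), frame_height=sim.detections.frame_size[1]
        )
        for f in sim.detections.iter_frames():
            tracker.step(f)
        ids = [t.track_id for t in tracker.tracks]
        assert len(ids) == len(set(ids))
        assert ids == sorted(ids)
        assert tracker.register.retired_ids <= set(ids)
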