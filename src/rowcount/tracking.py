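"""SORT-style multi-object tracking with permanent-ID counting.

The tracker follows the classic simple-online-realtime-tracking recipe:
a constant-velocity Kalman filter per track over the state
``[u, v, s, r, du, dv, ds]`` (box centre, area, aspect ratio and their
velocities; the aspect ratio is modelled constant), IoU cost between
predicted and detected boxes, optimal one-to-one assignment via the
Hungarian algorithm, and a hits/age lifecycle.

The counting extension: when a track's centre crosses the lower edge of
the frame (``v >= frame_height``; image y grows downward) the track is
*retired* — removed from matching with its id permanently blacklisted —
so a seedling leaving the bottom of a forward-walking video can never be
re-identified and double counted.  The row count is the number of ids
that ever reached the confirmed state; retirement exists to guarantee
each of those is unique per physical plant.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detections import BoundingBox, Detection, FrameDetections, box_iou

__all__ = [
    "TrackStatus",
    "TrackerConfig",
    "CountRegister",
    "Track",
    "SortTracker",
    "iou",
    "associate",
    "final_count",
]

iou = box_iou  # association cost; re-exported under the tracking name


class TrackStatus(enum.Enum):
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"
    RETIRED = "retired"


@dataclass
class TrackerConfig:
    """Lifecycle and noise parameters of the tracker.

    ``max_age`` defaults to 8 frames (~0.25 s at 30 fps, versus the
    single frame of the original SORT) because hand-held field video
    shows short motion-blur dropouts and the clustering stage can
    briefly eliminate a valid seedling near a density boundary; a track
    must coast across such gaps or every gap double-counts its plant.
    ``min_hits`` of 5 consecutive matches (~0.17 s) keeps marginal
    flickering detections — low-confidence off-row hits, one-frame
    false positives — from ever confirming, and ``iou_threshold`` is
    0.2 rather than the pedestrian-tracking 0.3 because the targets are
    small (a couple of px of localisation noise is a large IoU drop on
    a 10 px box).  ``count_mode`` selects whether the final count is
    the ids ever confirmed (default) or the ids retired at the lower
    edge.
    """

    iou_threshold: float = 0.2
    max_age: int = 8
    min_hits: int = 5
    process_noise_scale: float = 1.0
    measurement_noise_scale: float = 1.0
    count_mode: str = "confirmed"  # or "retired"

    def __post_init__(self) -> None:
        if not 0.0 < self.iou_threshold < 1.0:
            raise ValueError("iou_threshold must be in (0,1)")
        if self.max_age < 1 or self.min_hits < 1:
            raise ValueError("max_age and min_hits must be >= 1")
        if self.count_mode not in ("confirmed", "retired"):
            raise ValueError("count_mode must be 'confirmed' or 'retired'")


@dataclass
class CountRegister:
    """Book-keeping of counted and retired ids."""

    confirmed_ids: set[int] = field(default_factory=set)
    retired_ids: set[int] = field(default_factory=set)

    @property
    def running_count(self) -> int:
        return len(self.confirmed_ids)


# ---------------------------------------------------------------------------
# Kalman filter over [u, v, s, r, du, dv, ds]
# ---------------------------------------------------------------------------


def _box_to_z(box: BoundingBox) -> np.ndarray:
    u, v = box.center
    return np.array([u, v, box.area, box.width / box.height], dtype=float)


def _x_to_box(x: np.ndarray) -> BoundingBox:
    s = max(float(x[2]), 1e-6)
    r = max(float(x[3]), 1e-6)
    w = np.sqrt(s * r)
    h = s / w
    return BoundingBox(float(x[0]) - w / 2, float(x[1]) - h / 2, w, h)


class _KalmanBox:
    """Constant-velocity Kalman filter with the standard SORT matrices."""

    F = np.eye(7)
    F[0, 4] = F[1, 5] = F[2, 6] = 1.0
    H = np.eye(4, 7)

    def __init__(self, box: BoundingBox, q_scale: float, r_scale: float) -> None:
        self.x = np.zeros(7)
        self.x[:4] = _box_to_z(box)
        self.P = np.diag([10.0, 10.0, 10.0, 10.0, 1e4, 1e4, 1e4])
        self.Q = np.diag([1.0, 1.0, 1.0, 1.0, 0.01, 0.01, 1e-4]) * q_scale
        self.R = np.diag([1.0, 1.0, 10.0, 10.0]) * r_scale

    def predict(self) -> BoundingBox:
        if self.x[2] + self.x[6] <= 0:
            # area would go non-positive; clamp by zeroing its velocity
            warnings.warn("predicted area non-positive; clamping", stacklevel=2)
            self.x[6] = 0.0
        self.x = self.F @ self.x
        self.P = self.F @ self.P @ self.F.T + self.Q
        return _x_to_box(self.x)

    def update(self, box: BoundingBox) -> None:
        z = _box_to_z(box)
        y = z - self.H @ self.x
        S = self.H @ self.P @ self.H.T + self.R
        K = np.linalg.solve(S.T, (self.P @ self.H.T).T).T
        self.x = self.x + K @ y
        self.P = (np.eye(7) - K @ self.H) @ self.P


@dataclass
class Track:
    """One tracked object with SORT lifecycle state.

    ``hits`` counts all matches; ``hit_streak`` counts consecutive
    matches and is what confirmation tests — a tentative track must be
    matched ``min_hits`` frames in a row, so ghost tracks living off
    occasionally stolen detections in dense regions never confirm.
    """

    track_id: int
    kf: _KalmanBox
    hits: int = 1
    hit_streak: int = 1
    age: int = 0
    time_since_update: int = 0
    status: TrackStatus = TrackStatus.TENTATIVE

    @property
    def box(self) -> BoundingBox:
        return _x_to_box(self.kf.x)

    @property
    def center(self) -> tuple[float, float]:
        return (float(self.kf.x[0]), float(self.kf.x[1]))

    def predict(self) -> BoundingBox:
        if self.status in (TrackStatus.DELETED, TrackStatus.RETIRED):
            raise ValueError("cannot predict a deleted/retired track")
        self.age += 1
        if self.time_since_update > 0:
            self.hit_streak = 0
        self.time_since_update += 1
        return self.kf.predict()


# ---------------------------------------------------------------------------
# association
# ---------------------------------------------------------------------------


def associate(
    track_boxes: list[BoundingBox],
    detections: FrameDetections | list[Detection],
    threshold: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Optimal one-to-one IoU assignment with a rejection threshold.

    Returns ``(matches, unmatched_tracks, unmatched_detections)`` where
    matches are ``(track_index, detection_index)`` pairs.  The Hungarian
    assignment maximises total IoU; any assigned pair below
    ``threshold`` is rejected into the unmatched sets.
    """
    dets = (
        detections.detections
        if isinstance(detections, FrameDetections)
        else list(detections)
    )
    nt, nd = len(track_boxes), len(dets)
    if nt == 0 or nd == 0:
        return [], list(range(nt)), list(range(nd))
    cost = np.zeros((nt, nd))
    for i, tb in enumerate(track_boxes):
        for j, d in enumerate(dets):
            cost[i, j] = box_iou(tb, d.box)
    rows, cols = linear_sum_assignment(-cost)
    matches: list[tuple[int, int]] = []
    unmatched_t = set(range(nt))
    unmatched_d = set(range(nd))
    for i, j in zip(rows, cols):
        if cost[i, j] >= threshold:
            matches.append((int(i), int(j)))
            unmatched_t.discard(int(i))
            unmatched_d.discard(int(j))
    return matches, sorted(unmatched_t), sorted(unmatched_d)


# ---------------------------------------------------------------------------
# tracker
# ---------------------------------------------------------------------------


class SortTracker:
    """Frame-by-frame tracker with permanent-ID counting.

    Feed frames in strictly increasing index order through
    :meth:`step`; missing frames should be presented as empty frames so
    track ages advance.  ``log_rows`` accumulates a per-frame track log
    ``(frame, id, x, y, w, h, status, cumulative_count)`` suitable for
    CSV export or on-screen overlay rendering.
    """

    def __init__(self, config: TrackerConfig | None = None, frame_height: int = 1080):
        self.config = config or TrackerConfig()
        self.frame_height = frame_height
        self.tracks: list[Track] = []
        self.register = CountRegister()
        self.next_id = 1
        self.last_frame: int | None = None
        self.log_rows: list[tuple] = []

    # -- lifecycle helpers -------------------------------------------------

    def _spawn(self, det: Detection) -> Track:
        t = Track(
            self.next_id,
            _KalmanBox(
                det.box,
                self.config.process_noise_scale,
                self.config.measurement_noise_scale,
            ),
        )
        self.next_id += 1
        self.tracks.append(t)
        if t.hits >= self.config.min_hits:
            t.status = TrackStatus.CONFIRMED
            self.register.confirmed_ids.add(t.track_id)
        return t

    def _retire_crossing(self) -> None:
        """Retire any active track whose centre crossed the lower edge.

        Retirement is absorbing: the id goes into ``retired_ids`` and the
        track never matches again.  The rule is strict at the boundary —
        ``v >= frame_height`` retires, ``frame_height - 1`` does not.
        """
        for t in self.tracks:
            if t.status in (TrackStatus.DELETED, TrackStatus.RETIRED):
                continue
            if t.center[1] >= self.frame_height:
                t.status = TrackStatus.RETIRED
                self.register.retired_ids.add(t.track_id)

    # -- main entry --------------------------------------------------------

    def step(self, frame: FrameDetections) -> list[Track]:
        """Advance one frame: predict → associate → update → lifecycle.

        Returns the list of active (tentative or confirmed) tracks after
        the frame is absorbed.
        """
        if self.last_frame is not None and frame.frame_index <= self.last_frame:
            raise ValueError(
                f"frames must be strictly increasing; got {frame.frame_index} "
                f"after {self.last_frame}"
            )
        self.last_frame = frame.frame_index

        active = [
            t
            for t in self.tracks
            if t.status in (TrackStatus.TENTATIVE, TrackStatus.CONFIRMED)
        ]
        predicted = [t.predict() for t in active]

        matches, unmatched_t, unmatched_d = associate(
            predicted, frame, self.config.iou_threshold
        )
        for ti, dj in matches:
            t = active[ti]
            t.kf.update(frame.detections[dj].box)
            t.hits += 1
            # predict() already zeroed the streak if last frame was a miss
            t.hit_streak += 1
            t.time_since_update = 0
            if (
                t.status is TrackStatus.TENTATIVE
                and t.hit_streak >= self.config.min_hits
            ):
                t.status = TrackStatus.CONFIRMED
                self.register.confirmed_ids.add(t.track_id)
        for ti in unmatched_t:
            t = active[ti]
            if t.time_since_update > self.config.max_age:
                t.status = TrackStatus.DELETED
        for dj in unmatched_d:
            self._spawn(frame.detections[dj])

        self._retire_crossing()

        out = [
            t
            for t in self.tracks
            if t.status in (TrackStatus.TENTATIVE, TrackStatus.CONFIRMED)
        ]
        count = final_count(self.register, self.config.count_mode)
        for t in out:
            b = t.box
            self.log_rows.append(
                (
                    frame.frame_index,
                    t.track_id,
                    b.x_left,
                    b.y_top,
                    b.width,
                    b.height,
                    t.status.value,
                    count,
                    t.time_since_update,
                )
            )
        return out


def final_count(register: CountRegister, count_mode: str = "confirmed") -> int:
    """The predicted row count ŷ.

    Default: number of ids ever confirmed (each counted once; retirement
    guarantees an id cannot be resurrected into a second plant).  The
    ``retired`` mode counts only ids that actually crossed the lower
    edge — tracks still mid-frame when the video ends are then excluded.
    """
    if count_mode == "retired":
        return len(register.retired_ids)
    return len(register.confirmed_ids)
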