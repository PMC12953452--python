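"""Detection, tracking and counting evaluation metrics.

Detection quality uses precision P = TP/(TP+FP), recall R = TP/(TP+FN)
and the all-point average precision AP = Σ P_i·ΔR_i over the
confidence-swept PR curve (no 11-point or COCO interpolation).

Tracking quality uses three ratios over a video:

* ID switch rate  W_ID = Q_sh / S
* tracking accuracy  P_tr = M_mat / S
* tracking precision  P_mt = M_mat / T_mat

where Q_sh counts identity switches, S is the number of seedlings the
tracker counted, T_mat the number of ground-truth identities matched at
least once and M_mat the number of those tracked correctly (dominant
track id covering at least half of their matched frames — a
convention, since the literature leaves "correctly tracked"
operational details open).

Counting quality uses Acc = (1 − |ŷ−y|/y)·100 % per video and
R² = 1 − Σ(y_i−ŷ_i)²/Σ(y_i−ȳ)² across videos.
"""

from __future__ import annotations

import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .detections import FrameDetections, IdentifiedVideo, VideoDetections, box_iou

__all__ = [
    "DetectionEval",
    "TrackingEval",
    "CountingEval",
    "match_for_detection_eval",
    "precision_recall",
    "average_precision",
    "detection_eval",
    "tracking_eval",
    "acc",
    "r_squared",
    "counting_eval",
    "tracking_delta",
]


@dataclass
class DetectionEval:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    ap: float | None = None
    iou_threshold: float = 0.5


@dataclass
class TrackingEval:
    """Tracking ratios; stored as fractions, printed as percentages."""

    w_id: float
    p_tr: float
    p_mt: float
    q_sh: int = 0
    s: int = 0
    m_mat: int = 0
    t_mat: int = 0

    @classmethod
    def from_counts(cls, q_sh: int, s: int, m_mat: int, t_mat: int) -> "TrackingEval":
        if m_mat > t_mat:
            raise ValueError("M_mat cannot exceed T_mat")
        return cls(
            w_id=q_sh / s if s else 0.0,
            p_tr=m_mat / s if s else 0.0,
            p_mt=m_mat / t_mat if t_mat else 0.0,
            q_sh=q_sh,
            s=s,
            m_mat=m_mat,
            t_mat=t_mat,
        )

    @property
    def w_id_pct(self) -> float:
        return 100.0 * self.w_id

    @property
    def p_tr_pct(self) -> float:
        return 100.0 * self.p_tr

    @property
    def p_mt_pct(self) -> float:
        return 100.0 * self.p_mt


@dataclass
class CountingEval:
    y: int
    y_hat: int
    acc_pct: float


def tracking_delta(a: TrackingEval, b: TrackingEval) -> dict[str, float]:
    """Percentage-point differences a − b of the tracking ratios.

    Rounded to two decimals, the precision at which such tables are
    normally printed.
    """
    return {
        "w_id": round(a.w_id_pct - b.w_id_pct, 2),
        "p_tr": round(a.p_tr_pct - b.p_tr_pct, 2),
        "p_mt": round(a.p_mt_pct - b.p_mt_pct, 2),
    }


# ---------------------------------------------------------------------------
# detection metrics
# ---------------------------------------------------------------------------


def match_for_detection_eval(
    pred: FrameDetections, truth: FrameDetections, iou_thr: float = 0.5
) -> tuple[int, int, int]:
    """Greedy one-to-one matching of one frame → (TP, FP, FN).

    Predictions are visited in descending confidence; each may claim the
    unused truth box of highest IoU provided IoU >= ``iou_thr``.
    """
    if pred.frame_index != truth.frame_index:
        raise ValueError("pred and truth frames must share frame_index")
    order = sorted(
        range(len(pred)), key=lambda i: -pred.detections[i].confidence
    )
    used = [False] * len(truth)
    tp = 0
    for i in order:
        best_j, best_iou = -1, iou_thr
        for j, t in enumerate(truth.detections):
            if used[j]:
                continue
            v = box_iou(pred.detections[i].box, t.box)
            if v >= best_iou:
                best_iou, best_j = v, j
        if best_j >= 0:
            used[best_j] = True
            tp += 1
    fp = len(pred) - tp
    fn = len(truth) - tp
    return tp, fp, fn


def precision_recall(tp: int, fp: int, fn: int) -> tuple[float, float]:
    """P and R from match counts.

    An empty prediction set yields P = 1 by convention (no prediction,
    no false alarm) with a warning; an empty truth set is a fixture bug
    and raises.
    """
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("no ground-truth positives; recall undefined")
    if tp + fp == 0:
        warnings.warn("no predictions; precision defined as 1", stacklevel=2)
        p = 1.0
    else:
        p = tp / (tp + fp)
    return p, tp / (tp + fn)


def average_precision(pr_points: list[tuple[float, float]]) -> float:
    """All-point AP = Σ P_i · ΔR_i over an ordered PR curve.

    ``pr_points`` is a list of (P_i, R_i) with non-decreasing recall;
    ΔR_1 is measured from zero.  Empty curve → 0.
    """
    if not pr_points:
        return 0.0
    recalls = [r for _, r in pr_points]
    if any(b < a - 1e-12 for a, b in zip(recalls, recalls[1:])):
        raise ValueError("recall must be non-decreasing")
    ap = 0.0
    prev_r = 0.0
    for p, r in pr_points:
        ap += p * (r - prev_r)
        prev_r = r
    return ap


def detection_eval(
    pred: VideoDetections,
    truth: VideoDetections,
    iou_thr: float = 0.5,
) -> DetectionEval:
    """Video-level P/R/AP via a confidence sweep.

    Predictions across all frames are sorted by confidence; each is
    greedily matched within its frame.  The cumulative (P_i, R_i) after
    every prediction forms the PR curve fed to
    :func:`average_precision`.
    """
    tmap = truth.frame_map()
    n_truth = truth.n_detections
    if n_truth == 0:
        raise ValueError("truth video has no detections")
    entries = []  # (confidence, frame_index, det)
    for f in pred.frames:
        for d in f.detections:
            entries.append((d.confidence, f.frame_index, d))
    entries.sort(key=lambda e: -e[0])
    used: dict[int, list[bool]] = {
        i: [False] * len(f) for i, f in tmap.items()
    }
    flags = []
    for conf, fi, d in entries:
        tf = tmap.get(fi)
        hit = False
        if tf is not None:
            best_j, best_iou = -1, iou_thr
            for j, t in enumerate(tf.detections):
                if used[fi][j]:
                    continue
                v = box_iou(d.box, t.box)
                if v >= best_iou:
                    best_iou, best_j = v, j
            if best_j >= 0:
                used[fi][best_j] = True
                hit = True
        flags.append(hit)
    cum_tp = np.cumsum(flags) if flags else np.array([])
    pr = [
        (ct / (i + 1), ct / n_truth) for i, ct in enumerate(cum_tp)
    ]
    tp = int(cum_tp[-1]) if len(cum_tp) else 0
    fp = len(flags) - tp
    fn = n_truth - tp
    p, r = precision_recall(tp, fp, fn) if flags else (1.0, 0.0)
    return DetectionEval(tp, fp, fn, p, r, average_precision(pr), iou_thr)


# ---------------------------------------------------------------------------
# tracking metrics
# ---------------------------------------------------------------------------


def tracking_eval(
    track_rows: list[tuple],
    truth: IdentifiedVideo,
    s: int,
    match_threshold: float | None = None,
    dominant_coverage: float = 0.5,
    min_truth_height: float = 10.0,
) -> TrackingEval:
    """Score a track log against ground-truth identities.

    ``track_rows`` are the tracker's log rows
    ``(frame, id, x, y, w, h, status, count, time_since_update)``; only
    rows observed this frame (``time_since_update == 0``) take part.
    Per frame, tracks are matched one-to-one to truth identities by
    centre distance (Hungarian), with matches beyond ``match_threshold``
    rejected; the default threshold is half the median truth box width
    over the whole video.  Truth boxes below ``min_truth_height`` pixels
    are excluded from matching: deep in the perspective-compressed far
    field neighbouring plants sit closer together than any localisation
    noise, so identity assignment there is unresolvable for any tracker
    and would only add spurious switches.  Q_sh counts frame
    transitions where a truth identity's matched track id changes;
    ``s`` is the tracker's final count.
    """
    if not truth.video.frames:
        raise ValueError("truth video is empty")
    widths = [
        d.box.width
        for f in truth.video.frames
        for d in f.detections
        if d.box.height >= min_truth_height
    ]
    if match_threshold is None:
        match_threshold = float(np.median(widths)) / 2.0 if widths else 10.0

    by_frame: dict[int, list[tuple[int, float, float]]] = defaultdict(list)
    for row in track_rows:
        frame, tid, x, y, w, h = row[0], row[1], row[2], row[3], row[4], row[5]
        tsu = row[8] if len(row) > 8 else 0
        if tsu == 0:
            by_frame[frame].append((tid, x + w / 2.0, y + h / 2.0))

    if not by_frame:
        warnings.warn("empty track log; all tracking metrics zero", stacklevel=2)
        return TrackingEval.from_counts(0, s, 0, 0)

    matched_frames: dict[int, list[int]] = defaultdict(list)  # identity -> track ids
    q_sh = 0
    last_tid: dict[int, int] = {}
    for f in truth.video.frames:
        fi = f.frame_index
        all_ids = truth.ids.get(fi, [])
        evaluable = [
            (d, ident)
            for d, ident in zip(f.detections, all_ids)
            if d.box.height >= min_truth_height
        ]
        tracks = by_frame.get(fi, [])
        if not tracks or not evaluable:
            continue
        truth_ids = [ident for _, ident in evaluable]
        t_centers = np.array([[x, y] for _, x, y in tracks])
        g_centers = np.array([d.center for d, _ in evaluable])
        cost = np.linalg.norm(
            g_centers[:, None, :] - t_centers[None, :, :], axis=2
        )
        rows, cols = linear_sum_assignment(cost)
        for gi, ti in zip(rows, cols):
            if cost[gi, ti] > match_threshold:
                continue
            ident = truth_ids[gi]
            tid = tracks[ti][0]
            if ident in last_tid and last_tid[ident] != tid:
                q_sh += 1
            last_tid[ident] = tid
            matched_frames[ident].append(tid)

    t_mat = len(matched_frames)
    m_mat = 0
    for ident, tids in matched_frames.items():
        _, dominant = Counter(tids).most_common(1)[0]
        if dominant / len(tids) >= dominant_coverage:
            m_mat += 1
    return TrackingEval.from_counts(q_sh, s, m_mat, t_mat)


# ---------------------------------------------------------------------------
# counting metrics
# ---------------------------------------------------------------------------


def acc(y: int, y_hat: int) -> float:
    """Counting accuracy (1 − |ŷ−y|/y)·100, in percent.

    Can be negative for a gross over-count; exactly 100 iff ŷ = y.
    """
    if y <= 0:
        raise ValueError("ground-truth count must be positive")
    return (1.0 - abs(y_hat - y) / y) * 100.0


def counting_eval(y: int, y_hat: int) -> CountingEval:
    return CountingEval(y, y_hat, acc(y, y_hat))


def r_squared(pairs: list[tuple[float, float]]) -> float:
    """Coefficient of determination of per-video counts vs ground truth.

    ``R² = 1 − Σ(y_i − ŷ_i)² / Σ(y_i − ȳ)²`` over (y_i, ŷ_i) pairs.
    """
    if len(pairs) < 2:
        raise ValueError("need at least two (y, y_hat) pairs")
    y = np.array([p[0] for p in pairs], dtype=float)
    yh = np.array([p[1] for p in pairs], dtype=float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("ground-truth counts are constant; R^2 undefined")
    return 1.0 - float(((y - yh) ** 2).sum()) / ss_tot
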