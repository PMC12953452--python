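"""Detection containers and plain-text detection-format I/O.

Frame-indexed bounding boxes are the common currency of
tracking-by-detection pipelines.  This module defines the domain types
(:class:`BoundingBox`, :class:`Detection`, :class:`FrameDetections`,
:class:`VideoDetections`) and readers/writers for the two text dialects
detectors commonly export:

* MOT-challenge CSV — ``frame,id,x,y,w,h,conf,-1,-1,-1``, one detection
  per line, 1-based frame indices;
* YOLO label files — one file per frame, ``class cx cy w h [conf]`` with
  coordinates normalised to the frame size.

Conventions: the image origin is the top-left corner with y increasing
downward, so the "lower edge" of a 1080-row frame is ``y = 1080``.  A
detection's position, used for clustering and counting everywhere in
this package, is the geometric centre of its box — derived in exactly
one place (:attr:`BoundingBox.center`).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

__all__ = [
    "DEFAULT_FRAME_SIZE",
    "BoundingBox",
    "Detection",
    "FrameDetections",
    "VideoDetections",
    "IdentifiedVideo",
    "MotParseError",
    "box_iou",
    "clip_box",
    "read_mot_file",
    "write_mot_file",
    "read_yolo_dir",
]

DEFAULT_FRAME_SIZE: tuple[int, int] = (1920, 1080)


class MotParseError(ValueError):
    """Raised for malformed rows in a MOT-dialect file; names the line."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box in pixel coordinates, origin top-left.

    ``width`` and ``height`` must be strictly positive; degenerate boxes
    are rejected at construction so downstream geometry (IoU, centres)
    never divides by zero.
    """

    x_left: float
    y_top: float
    width: float
    height: float

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError(
                f"box width/height must be positive, got {self.width}x{self.height}"
            )

    @property
    def x_right(self) -> float:
        return self.x_left + self.width

    @property
    def y_bottom(self) -> float:
        return self.y_top + self.height

    @property
    def center(self) -> tuple[float, float]:
        """Geometric centre; the single authoritative centre derivation."""
        return (self.x_left + self.width / 2.0, self.y_top + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height


def box_iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes, in [0, 1]."""
    ix = min(a.x_right, b.x_right) - max(a.x_left, b.x_left)
    iy = min(a.y_bottom, b.y_bottom) - max(a.y_top, b.y_top)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def clip_box(box: BoundingBox, frame_size: tuple[int, int]) -> BoundingBox | None:
    """Intersect ``box`` with the frame rectangle.

    Returns the clipped box, or ``None`` when the box lies fully outside
    the frame (the degenerate flag — callers must handle it explicitly
    rather than receiving a zero-area box).
    """
    w, h = frame_size
    x0 = max(box.x_left, 0.0)
    y0 = max(box.y_top, 0.0)
    x1 = min(box.x_right, float(w))
    y1 = min(box.y_bottom, float(h))
    if x1 - x0 <= 0 or y1 - y0 <= 0:
        return None
    return BoundingBox(x0, y0, x1 - x0, y1 - y0)


@dataclass(frozen=True)
class Detection:
    """One detection: a box on one frame plus a detector confidence.

    Confidence is clamped into [0, 1] with a warning — detector exports
    vary and an out-of-range score is not worth aborting a run for.
    """

    frame_index: int
    box: BoundingBox
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.confidence <= 1.0:
            warnings.warn(
                f"confidence {self.confidence} outside [0,1]; clamping",
                stacklevel=3,
            )
            object.__setattr__(
                self, "confidence", min(1.0, max(0.0, self.confidence))
            )

    @property
    def center(self) -> tuple[float, float]:
        return self.box.center


@dataclass
class FrameDetections:
    """All detections of a single frame."""

    frame_index: int
    detections: list[Detection] = field(default_factory=list)
    frame_size: tuple[int, int] = DEFAULT_FRAME_SIZE

    def __post_init__(self) -> None:
        for d in self.detections:
            if d.frame_index != self.frame_index:
                raise ValueError(
                    f"detection frame {d.frame_index} != frame {self.frame_index}"
                )

    def __len__(self) -> int:
        return len(self.detections)


@dataclass
class VideoDetections:
    """An ordered sequence of frames; missing indices are treated as empty."""

    frames: list[FrameDetections] = field(default_factory=list)
    fps: float = 30.0
    frame_size: tuple[int, int] = DEFAULT_FRAME_SIZE

    def __post_init__(self) -> None:
        idx = [f.frame_index for f in self.frames]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("frame indices must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def n_detections(self) -> int:
        return sum(len(f) for f in self.frames)

    @property
    def frame_range(self) -> tuple[int, int] | None:
        if not self.frames:
            return None
        return (self.frames[0].frame_index, self.frames[-1].frame_index)

    def frame_map(self) -> dict[int, FrameDetections]:
        return {f.frame_index: f for f in self.frames}

    def iter_frames(self, fill_missing: bool = True) -> Iterator[FrameDetections]:
        """Yield frames in index order; gaps become empty frames."""
        if not self.frames:
            return
        if not fill_missing:
            yield from self.frames
            return
        fmap = self.frame_map()
        lo, hi = self.frame_range
        for i in range(lo, hi + 1):
            yield fmap.get(i, FrameDetections(i, [], self.frame_size))


@dataclass
class IdentifiedVideo:
    """Detections with per-detection identities (ground-truth tracks).

    ``ids[frame_index][j]`` is the identity of
    ``video.frame_map()[frame_index].detections[j]``.
    """

    video: VideoDetections
    ids: dict[int, list[int]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for f in self.video.frames:
            got = len(self.ids.get(f.frame_index, []))
            if got != len(f):
                raise ValueError(
                    f"frame {f.frame_index}: {got} ids for {len(f)} detections"
                )


# ---------------------------------------------------------------------------
# MOT-dialect CSV
# ---------------------------------------------------------------------------


def read_mot_file(
    path: str | Path,
    kind: str = "detections",
    fps: float = 30.0,
    frame_size: tuple[int, int] = DEFAULT_FRAME_SIZE,
) -> VideoDetections | IdentifiedVideo:
    """Read a MOT-challenge detection or ground-truth CSV.

    Rows are ``frame,id,x,y,w,h,conf[,...]``.  For ``kind="detections"``
    the id column is ignored (conventionally -1) and a
    :class:`VideoDetections` is returned; for ``kind="ground_truth"`` the
    ids are preserved and an :class:`IdentifiedVideo` is returned.
    """
    if kind not in ("detections", "ground_truth"):
        raise ValueError(f"unknown kind {kind!r}")
    path = Path(path)
    per_frame: dict[int, list[Detection]] = {}
    per_frame_ids: dict[int, list[int]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) < 7:
                raise MotParseError(
                    f"{path}:{lineno}: expected >=7 comma-separated fields, "
                    f"got {len(parts)}"
                )
            try:
                frame = int(float(parts[0]))
                track_id = int(float(parts[1]))
                x, y, w, h, conf = (float(v) for v in parts[2:7])
            except ValueError as exc:
                raise MotParseError(f"{path}:{lineno}: {exc}") from None
            if w <= 0 or h <= 0:
                raise MotParseError(
                    f"{path}:{lineno}: non-positive box size {w}x{h}"
                )
            det = Detection(frame, BoundingBox(x, y, w, h), conf)
            per_frame.setdefault(frame, []).append(det)
            per_frame_ids.setdefault(frame, []).append(track_id)
    frames = [
        FrameDetections(i, per_frame[i], frame_size) for i in sorted(per_frame)
    ]
    video = VideoDetections(frames, fps=fps, frame_size=frame_size)
    if kind == "ground_truth":
        return IdentifiedVideo(video, {i: per_frame_ids[i] for i in sorted(per_frame)})
    return video


def write_mot_file(
    video: VideoDetections,
    path: str | Path,
    ids: dict[int, list[int]] | None = None,
) -> Path:
    """Write a MOT-dialect CSV, one detection per line, frames in order.

    Floats are written with :func:`repr`-style formatting so a
    write→read round trip reproduces the in-memory values exactly.
    Without ``ids`` the id column is -1 for every row.
    """
    path = Path(path)
    with path.open("w") as fh:
        for f in video.frames:
            frame_ids = (ids or {}).get(f.frame_index, [-1] * len(f))
            for det, tid in zip(f.detections, frame_ids):
                b = det.box
                fh.write(
                    f"{f.frame_index},{tid},{b.x_left},{b.y_top},"
                    f"{b.width},{b.height},{det.confidence},-1,-1,-1\n"
                )
    return path


# ---------------------------------------------------------------------------
# YOLO per-frame label files
# ---------------------------------------------------------------------------

_FRAME_NUM = re.compile(r"(\d+)")


def read_yolo_dir(
    path: str | Path,
    frame_size: tuple[int, int] = DEFAULT_FRAME_SIZE,
    fps: float = 30.0,
) -> VideoDetections:
    """Read a directory of YOLO-style label files, one ``.txt`` per frame.

    The frame index is the last integer in each filename (``000017.txt``
    → frame 17).  Lines are ``class cx cy w h [conf]`` with coordinates
    normalised to [0, 1]; ``frame_size`` denormalises them.
    """
    path = Path(path)
    w_px, h_px = frame_size
    frames: list[FrameDetections] = []
    files = sorted(path.glob("*.txt"))
    entries = []
    for fp in files:
        nums = _FRAME_NUM.findall(fp.stem)
        if not nums:
            raise ValueError(f"cannot infer frame index from {fp.name!r}")
        entries.append((int(nums[-1]), fp))
    for frame, fp in sorted(entries):
        dets: list[Detection] = []
        for lineno, line in enumerate(fp.read_text().splitlines(), start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise MotParseError(
                    f"{fp}:{lineno}: expected 5 or 6 fields, got {len(parts)}"
                )
            cx, cy, bw, bh = (float(v) for v in parts[1:5])
            conf = float(parts[5]) if len(parts) == 6 else 1.0
            bw_px, bh_px = bw * w_px, bh * h_px
            if bw_px <= 0 or bh_px <= 0:
                raise MotParseError(f"{fp}:{lineno}: non-positive box size")
            dets.append(
                Detection(
                    frame,
                    BoundingBox(cx * w_px - bw_px / 2, cy * h_px - bh_px / 2, bw_px, bh_px),
                    conf,
                )
            )
        frames.append(FrameDetections(frame, dets, frame_size))
    return VideoDetections(frames, fps=fps, frame_size=frame_size)
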