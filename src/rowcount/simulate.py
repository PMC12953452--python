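"""Synthetic oblique-view walking video of a crop row, as detections.

The simulator emulates the acquisition protocol behind the counting
pipeline: a smartphone held ~0.5 m above the ground, pitched 45°
(oblique) or 90° (straight down), walked at ~0.8 m/s along a 14.4 m
planting bed at 30 fps and 1920×1080 resolution.  Seedlings sit on a
jittered grid at 0.05 m nominal spacing; drainage ditches of 0.3 m
flank the bed, with optional sparse clutter rows beyond them.  A
pinhole projection turns plant positions into per-frame bounding boxes
with full ground truth (identities and per-row counts), and a detector
noise model corrupts them into realistic detections.

Geometry.  World axes: X along the walk, Y lateral, Z up.  The camera
pitches ``tilt_deg`` below the horizontal.  The default focal length is
derived so the lateral image scale where the optical axis meets the
ground at the 45° reference geometry is the calibrated 800 px/m
(f = 800 · h / sin 45° ≈ 566 px — consistent with an ultra-wide phone
lens at 1920 px).  Perspective then produces the "small in the
distance, large in the foreground" compression the clustering stage
must cope with: distant plants image a few pixels, foreground plants
tens of pixels.

Plants are modelled as flat rosettes (canopy disk of ``canopy_diameter``
plus a small vertical extent ``plant_height``): a box's width is the
projected canopy, its height the foreshortened canopy plus the
projected vertical extent.

Detector noise.  Four mechanisms, all seeded: (i) misses driven by box
height through a logistic curve (small = likely missed, emulating weak
detector confidence on few-pixel targets); (ii) persistent "canopy
merge" misses — world-space neighbour pairs closer than the canopy
diameter are indistinguishable from above, so one member of such a pair
is dropped for the whole video with a probability that scales from 0 at
45° tilt to full at 90° (the oblique view exposes separating vertical
structure; the vertical view does not); (iii) centre/size jitter and a
size-dependent confidence model; (iv) Poisson false positives biased
toward the ditch edges.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy.spatial import cKDTree

from .detections import (
    BoundingBox,
    Detection,
    FrameDetections,
    IdentifiedVideo,
    VideoDetections,
    write_mot_file,
)

__all__ = [
    "SceneConfig",
    "NoiseConfig",
    "GroundTruthScene",
    "SimulatedVideo",
    "layout_plants",
    "project",
    "render_truth",
    "corrupt",
    "generate",
    "mean_max_iou",
]


@dataclass
class SceneConfig:
    """Field and acquisition geometry.

    Lengths in metres, angles in degrees, image quantities in pixels.
    Defaults describe the reference plot: a 1.2 m × 14.4 m bed, 0.05 m
    plant spacing, 0.3 m ditches, camera 0.5 m high walked at 0.8 m/s.
    The single seeded lane with 0.10 m lateral scatter yields ≈280
    target plants per bed — a thinned stand of the reference geometry,
    chosen so every scale of the pipeline (box sizes, spacings, eps
    ranges) matches the calibrated field setup.
    """

    plot_length: float = 14.4
    plot_width: float = 1.2
    plant_spacing: float = 0.05
    ditch_width: float = 0.3
    camera_height: float = 0.5
    tilt_deg: float = 45.0
    walk_speed: float = 0.8
    fps: float = 30.0
    frame_size: tuple[int, int] = (1920, 1080)
    focal_px: float | None = None
    emergence_rate: float = 0.97
    n_lanes: int = 1
    n_side_rows: int = 0
    side_row_sparsity: float = 0.3
    side_row_lateral: float | None = None  # default: adjacent bed centre
    lateral_sigma: float = 0.28
    along_jitter_sigma: float = 0.01
    canopy_diameter: float = 0.08
    plant_height: float = 0.04
    start_margin: float = 0.5
    end_margin: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.focal_px is None:
            # lateral central-band scale of 800 px/m at the 45° reference
            self.focal_px = 800.0 * self.camera_height / math.sin(math.radians(45.0))
        if self.side_row_lateral is None:
            # centre of the adjacent bed, one ditch away
            self.side_row_lateral = self.plot_width + self.ditch_width

    @property
    def n_frames(self) -> int:
        span = self.start_margin + self.plot_length + self.end_margin
        return int(math.ceil(span / self.walk_speed * self.fps)) + 1

    def camera_x(self, frame_index: int) -> float:
        """Camera position along the row for a 1-based frame index."""
        return -self.start_margin + (frame_index - 1) * self.walk_speed / self.fps


@dataclass
class NoiseConfig:
    """Detector noise model; all rates/probabilities in [0, 1].

    Misses are temporally correlated the way real detectors miss: each
    plant draws a persistent size threshold (logistic-distributed around
    ``miss_midpoint_px``), is undetectable while its box is smaller,
    and additionally flickers off in a small fraction of frames.  The
    marginal miss probability at a given box height is exactly the
    logistic curve; the per-plant persistence is what makes tracks
    plausible rather than confetti.
    """

    center_jitter_frac: float = 0.05  # of box size (localisation error scales
    center_jitter_floor: float = 0.3  # with object size); plus a pixel floor
    size_jitter_frac: float = 0.08
    miss_midpoint_px: float = 8.0  # box height of 50 % miss probability
    miss_steepness_px: float = 2.0
    flicker_rate: float = 0.08  # per-frame independent dropout
    side_row_threshold_boost: float = 6.0  # px; off-row targets are harder for
    # a detector trained on valid-region annotations only
    side_conf_mean: float = 0.18  # off-row hits score low: the detector was
    side_conf_sigma: float = 0.08  # never trained on neighbouring-row plants
    canopy_merge_rate: float = 0.6  # per eligible pair, at 90° tilt
    fp_rate: float = 0.2  # expected spurious one-frame boxes per frame
    fp_ditch_bias: float = 0.7  # fraction of FPs placed at ditch edges
    weed_rate_per_meter: float = 0.5  # persistent clutter objects (weeds,
    # soil clods) in the non-target strip, detected frame after frame;
    # ~0.5 per row-metre matches a managed trial plot that is weeded
    # but not spotless
    weed_lateral_spread: float = 0.9  # m beyond the bed edge that weeds
    # occupy (the ditch plus the margin of the neighbouring bed)
    conf_midpoint_px: float = 10.0
    conf_steepness_px: float = 4.0
    conf_sigma: float = 0.08
    confidence_model: str = "logistic"  # or "perfect" (keep truth confidence)

    @classmethod
    def none(cls) -> "NoiseConfig":
        """A noiseless detector: detections equal the rendered truth."""
        return cls(
            center_jitter_frac=0.0,
            center_jitter_floor=0.0,
            size_jitter_frac=0.0,
            miss_midpoint_px=-1e9,  # logistic ≈ 0 for every box
            flicker_rate=0.0,
            side_row_threshold_boost=0.0,
            canopy_merge_rate=0.0,
            fp_rate=0.0,
            weed_rate_per_meter=0.0,
            conf_sigma=0.0,
            confidence_model="perfect",
        )

    def miss_probability(self, box_height: float | np.ndarray) -> np.ndarray:
        """Logistic miss curve: near 1 for tiny boxes, near 0 above ~20 px."""
        z = (np.asarray(box_height, dtype=float) - self.miss_midpoint_px)
        z = np.clip(z / self.miss_steepness_px, -60.0, 60.0)
        return 1.0 / (1.0 + np.exp(z))

    def mean_confidence(self, box_height: float | np.ndarray) -> np.ndarray:
        z = (np.asarray(box_height, dtype=float) - self.conf_midpoint_px)
        z = np.clip(z / self.conf_steepness_px, -60.0, 60.0)
        return 0.3 + 0.65 / (1.0 + np.exp(-z))


@dataclass
class GroundTruthScene:
    """Plant world positions and the per-row true counts."""

    positions: np.ndarray  # (n, 2): x along row, lateral
    row_ids: np.ndarray  # (n,): 0 = target row, ±1.. = clutter rows

    @property
    def n_plants(self) -> int:
        return len(self.positions)

    @property
    def target_count(self) -> int:
        return int((self.row_ids == 0).sum())

    def row_counts(self) -> dict[int, int]:
        ids, counts = np.unique(self.row_ids, return_counts=True)
        return {int(i): int(c) for i, c in zip(ids, counts)}


@dataclass
class SimulatedVideo:
    """Bundle of detections, ground truth and provenance."""

    detections: VideoDetections
    truth: IdentifiedVideo
    scene: GroundTruthScene
    scene_config: SceneConfig
    noise_config: NoiseConfig
    seed: int

    @property
    def target_count(self) -> int:
        return self.scene.target_count


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------


def layout_plants(
    config: SceneConfig, rng: np.random.Generator | None = None
) -> GroundTruthScene:
    """Place plants on a jittered grid, plus optional clutter rows.

    Each grid site along the bed is occupied with probability
    ``emergence_rate``.  Side rows sit ``side_row_lateral`` metres off
    the bed centre (beyond the ditch) with occupancy thinned by
    ``side_row_sparsity``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sites = np.arange(
        config.plant_spacing / 2, config.plot_length, config.plant_spacing
    )
    positions: list[tuple[float, float]] = []
    row_ids: list[int] = []

    lane_offsets = (
        np.linspace(-config.plot_width / 4, config.plot_width / 4, config.n_lanes)
        if config.n_lanes > 1
        else np.array([0.0])
    )
    for lane in lane_offsets:
        occupied = rng.random(len(sites)) < config.emergence_rate
        for x in sites[occupied]:
            xj = x + rng.normal(0.0, config.along_jitter_sigma)
            yj = lane + rng.normal(0.0, config.lateral_sigma)
            yj = float(np.clip(yj, -config.plot_width / 2, config.plot_width / 2))
            positions.append((xj, yj))
            row_ids.append(0)

    for side in range(1, config.n_side_rows + 1):
        sign = -1 if side % 2 else 1
        ring = (side + 1) // 2
        base = sign * (
            config.side_row_lateral + (ring - 1) * (config.plot_width + config.ditch_width)
        )
        occupied = rng.random(len(sites)) < (
            config.emergence_rate * config.side_row_sparsity
        )
        # the ditch is bare soil: clutter stays outside bed edge + ditch
        inner = config.plot_width / 2 + config.ditch_width + 0.02
        for x in sites[occupied]:
            xj = x + rng.normal(0.0, config.along_jitter_sigma)
            off = abs(base) + rng.normal(0.0, config.lateral_sigma)
            yj = sign * max(off, inner)
            positions.append((xj, yj))
            row_ids.append(sign * ring)

    pos = (
        np.asarray(positions, dtype=float).reshape(-1, 2)
        if positions
        else np.empty((0, 2))
    )
    return GroundTruthScene(pos, np.asarray(row_ids, dtype=int))


# ---------------------------------------------------------------------------
# projection
# ---------------------------------------------------------------------------


def _camera_basis(tilt_deg: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    phi = math.radians(tilt_deg)
    forward = np.array([math.cos(phi), 0.0, -math.sin(phi)])
    right = np.array([0.0, -1.0, 0.0])  # image u grows toward world -Y
    down = np.cross(forward, right)  # image v grows downward
    return right, down, forward


def project(
    world_points: np.ndarray,
    cam_x: float,
    config: SceneConfig,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pinhole projection of world points (n, 3) → (u, v, depth).

    The camera sits at ``(cam_x, 0, camera_height)`` pitched
    ``tilt_deg`` below the horizontal, advancing along +X.  Plants ahead
    of the walker appear near the image top and flow downward as the
    camera passes.  Points with non-positive depth are behind the
    camera; their u/v are NaN.
    """
    pts = np.atleast_2d(np.asarray(world_points, dtype=float))
    cam = np.array([cam_x, 0.0, config.camera_height])
    right, down, forward = _camera_basis(config.tilt_deg)
    rel = pts - cam
    z = rel @ forward
    w, h = config.frame_size
    with np.errstate(divide="ignore", invalid="ignore"):
        u = w / 2.0 + config.focal_px * (rel @ right) / z
        v = h / 2.0 + config.focal_px * (rel @ down) / z
    bad = z <= 1e-9
    u[bad] = np.nan
    v[bad] = np.nan
    return u, v, z


def _box_sizes(
    ranges: np.ndarray, depths: np.ndarray, config: SceneConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Projected box width/height of the rosette model.

    Width is the projected canopy disk; height is the canopy disk
    foreshortened by the view elevation plus the projected vertical
    plant extent.
    """
    sin_elev = np.clip(config.camera_height / ranges, 0.0, 1.0)
    cos_elev = np.sqrt(1.0 - sin_elev**2)
    w = config.focal_px * config.canopy_diameter / depths
    h = (
        config.focal_px
        * (config.canopy_diameter * sin_elev + config.plant_height * cos_elev)
        / depths
    )
    return np.maximum(w, 1.0), np.maximum(h, 1.0)


def render_truth(scene: GroundTruthScene, config: SceneConfig) -> IdentifiedVideo:
    """Project the scene into per-frame ground-truth boxes with identities.

    A plant contributes a box while its projected centre lies inside
    the frame; boxes may overhang the frame edges (detectors report
    partially visible targets).  Once a plant's centre passes the lower
    edge it is gone for good — the camera has walked past it.
    """
    n = scene.n_plants
    world = np.column_stack([scene.positions, np.zeros(n)])
    w_px, h_px = config.frame_size
    frames: list[FrameDetections] = []
    ids: dict[int, list[int]] = {}
    for fi in range(1, config.n_frames + 1):
        cam_x = config.camera_x(fi)
        u, v, z = project(world, cam_x, config)
        cam = np.array([cam_x, 0.0, config.camera_height])
        ranges = np.linalg.norm(world - cam, axis=1)
        ok = (
            (z > 1e-9)
            & (u >= 0)
            & (u < w_px)
            & (v >= 0)
            & (v < h_px)
        )
        if not ok.any():
            continue
        bw, bh = _box_sizes(ranges[ok], z[ok], config)
        dets = [
            Detection(fi, BoundingBox(uu - ww / 2, vv - hh / 2, ww, hh), 1.0)
            for uu, vv, ww, hh in zip(u[ok], v[ok], bw, bh)
        ]
        frames.append(FrameDetections(fi, dets, config.frame_size))
        ids[fi] = [int(i) for i in np.flatnonzero(ok)]
    video = VideoDetections(frames, fps=config.fps, frame_size=config.frame_size)
    return IdentifiedVideo(video, ids)


# ---------------------------------------------------------------------------
# detector noise
# ---------------------------------------------------------------------------


def _merge_view_factor(tilt_deg: float) -> float:
    """Canopy-merge strength: 0 at <=45° tilt, 1 at 90°.

    Interlocked rosettes cannot be separated from straight above; the
    oblique view exposes vertical structure that splits them.  The
    factor interpolates between those regimes on sin(tilt).
    """
    s45 = math.sin(math.radians(45.0))
    s = math.sin(math.radians(tilt_deg))
    return float(np.clip((s - s45) / (1.0 - s45), 0.0, 1.0))


def corrupt(
    truth: IdentifiedVideo,
    noise: NoiseConfig,
    seed: int,
    scene: GroundTruthScene | None = None,
    config: SceneConfig | None = None,
) -> VideoDetections:
    """Apply the detector noise model to rendered truth boxes.

    With ``scene``/``config`` supplied, the canopy-merge and ditch-bias
    terms use world geometry; without them only the height-miss, jitter,
    confidence and uniform false-positive terms apply.  Deterministic
    for a given seed.
    """
    rng = np.random.default_rng(seed)

    merged: set[int] = set()
    if scene is not None and config is not None and noise.canopy_merge_rate > 0:
        factor = _merge_view_factor(config.tilt_deg)
        if factor > 0 and scene.n_plants >= 2:
            tree = cKDTree(scene.positions)
            pairs = sorted(tree.query_pairs(config.canopy_diameter))
            p = noise.canopy_merge_rate * factor
            for a, b in pairs:
                if a in merged or b in merged:
                    continue
                if rng.random() < p:
                    merged.add(b if rng.random() < 0.5 else a)

    # persistent per-plant detectability thresholds with logistic marginal:
    # threshold = midpoint + steepness * logit(U)
    size_thresholds: dict[int, float] = {}

    def _threshold(ident: int) -> float:
        if ident not in size_thresholds:
            u = min(max(rng.random(), 1e-12), 1 - 1e-12)
            thr = noise.miss_midpoint_px + (
                noise.miss_steepness_px * math.log(u / (1 - u))
            )
            if scene is not None and scene.row_ids[ident] != 0:
                thr += noise.side_row_threshold_boost
            size_thresholds[ident] = thr
        return size_thresholds[ident]

    # persistent clutter objects (weeds, soil clods) along the ditches:
    # real objects that the detector fires on frame after frame
    weeds: np.ndarray | None = None
    weed_conf: np.ndarray | None = None
    weed_size: np.ndarray | None = None
    if (
        scene is not None
        and config is not None
        and noise.weed_rate_per_meter > 0
    ):
        n_weeds = rng.poisson(noise.weed_rate_per_meter * config.plot_length)
        if n_weeds:
            along = rng.uniform(0.0, config.plot_length, n_weeds)
            lat = (
                config.plot_width / 2
                + rng.uniform(0.0, noise.weed_lateral_spread, n_weeds)
            ) * rng.choice([-1.0, 1.0], n_weeds)
            weeds = np.column_stack([along, lat, np.zeros(n_weeds)])
            weed_conf = rng.uniform(0.3, 0.7, n_weeds)
            weed_size = rng.uniform(0.4, 0.9, n_weeds) * config.canopy_diameter

    w_px, h_px = truth.video.frame_size
    frames: list[FrameDetections] = []
    for f in truth.video.frames:
        fi = f.frame_index
        frame_ids = truth.ids.get(fi, [])
        dets: list[Detection] = []
        for det, ident in zip(f.detections, frame_ids):
            if ident in merged:
                continue
            bh = det.box.height
            if bh < _threshold(ident):
                continue
            if noise.flicker_rate > 0 and rng.random() < noise.flicker_rate:
                continue
            cx, cy = det.box.center
            sigma = max(
                noise.center_jitter_floor, noise.center_jitter_frac * bh
            )
            cx += rng.normal(0.0, sigma)
            cy += rng.normal(0.0, sigma)
            bw2 = max(det.box.width * (1 + rng.normal(0.0, noise.size_jitter_frac)), 1.0)
            bh2 = max(bh * (1 + rng.normal(0.0, noise.size_jitter_frac)), 1.0)
            if noise.confidence_model == "perfect":
                conf = det.confidence
            elif scene is not None and scene.row_ids[ident] != 0:
                # out-of-domain hit: scores low, only occasionally above
                # a sensible confidence threshold
                conf = float(
                    np.clip(
                        rng.normal(noise.side_conf_mean, noise.side_conf_sigma),
                        0.01,
                        0.999,
                    )
                )
            else:
                conf = float(
                    np.clip(
                        noise.mean_confidence(bh2) + rng.normal(0.0, noise.conf_sigma),
                        0.05,
                        0.999,
                    )
                )
            dets.append(
                Detection(fi, BoundingBox(cx - bw2 / 2, cy - bh2 / 2, bw2, bh2), conf)
            )
        # persistent weed/clod detections
        if weeds is not None and config is not None:
            cam_x = config.camera_x(fi)
            u, vv, z = project(weeds, cam_x, config)
            cam = np.array([cam_x, 0.0, config.camera_height])
            ranges = np.linalg.norm(weeds - cam, axis=1)
            ok = (
                (z > 1e-9) & (u >= 0) & (u < w_px) & (vv >= 0) & (vv < h_px)
            )
            for wi in np.flatnonzero(ok):
                scale_f = weed_size[wi] / config.canopy_diameter
                bw_w, bh_w = _box_sizes(
                    np.array([ranges[wi]]), np.array([z[wi]]), config
                )
                bw_w, bh_w = scale_f * bw_w[0], scale_f * bh_w[0]
                if bh_w < noise.miss_midpoint_px:
                    continue
                if noise.flicker_rate > 0 and rng.random() < noise.flicker_rate:
                    continue
                dets.append(
                    Detection(
                        fi,
                        BoundingBox(
                            u[wi] - bw_w / 2, vv[wi] - bh_w / 2,
                            max(bw_w, 1.0), max(bh_w, 1.0),
                        ),
                        float(weed_conf[wi]),
                    )
                )
        # one-frame false positives, biased toward ditch edges
        n_fp = rng.poisson(noise.fp_rate) if noise.fp_rate > 0 else 0
        for _ in range(n_fp):
            if scene is not None and config is not None:
                if rng.random() < noise.fp_ditch_bias:
                    lat = (
                        (config.plot_width / 2 + rng.random() * config.ditch_width)
                        * rng.choice([-1.0, 1.0])
                    )
                else:
                    lat = rng.uniform(-1.5, 1.5)
                along = config.camera_x(fi) + rng.uniform(0.2, 5.0)
                u, v, z = project(
                    np.array([[along, lat, 0.0]]), config.camera_x(fi), config
                )
                if not np.isfinite(u[0]) or not (0 <= u[0] < w_px and 0 <= v[0] < h_px):
                    continue
                size = rng.uniform(6.0, 25.0)
                box = BoundingBox(u[0] - size / 2, v[0] - size / 2, size, size)
            else:
                size = rng.uniform(6.0, 25.0)
                box = BoundingBox(
                    rng.uniform(0, w_px - size), rng.uniform(0, h_px - size), size, size
                )
            dets.append(Detection(fi, box, float(rng.uniform(0.2, 0.6))))
        if dets:
            frames.append(FrameDetections(fi, dets, truth.video.frame_size))
    return VideoDetections(
        frames, fps=truth.video.fps, frame_size=truth.video.frame_size
    )


# ---------------------------------------------------------------------------
# end-to-end generation
# ---------------------------------------------------------------------------


def generate(
    scene_config: SceneConfig | None = None,
    noise_config: NoiseConfig | None = None,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> SimulatedVideo:
    """Layout → render → corrupt; optionally write the bundle to disk.

    Files written: ``det.txt`` and ``gt.txt`` (MOT dialect),
    ``scene.yaml`` (config echo incl. seed) and ``truth.json`` (per-row
    counts).  Deterministic per (configs, seed).
    """
    scene_config = scene_config or SceneConfig()
    noise_config = noise_config or NoiseConfig()
    ss = np.random.SeedSequence(seed)
    layout_seed, corrupt_seed = (int(s) & 0x7FFFFFFF for s in ss.generate_state(2))
    scene = layout_plants(scene_config, np.random.default_rng(layout_seed))
    truth = render_truth(scene, scene_config)
    detections = corrupt(truth, noise_config, corrupt_seed, scene, scene_config)
    sim = SimulatedVideo(detections, truth, scene, scene_config, noise_config, seed)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_mot_file(detections, out / "det.txt")
        write_mot_file(truth.video, out / "gt.txt", ids=truth.ids)
        echo = {
            "scene": asdict(scene_config),
            "noise": asdict(noise_config),
            "seed": seed,
        }
        (out / "scene.yaml").write_text(yaml.safe_dump(echo, sort_keys=True))
        (out / "truth.json").write_text(
            json.dumps(
                {
                    "target_count": scene.target_count,
                    "row_counts": {str(k): v for k, v in scene.row_counts().items()},
                    "n_frames": scene_config.n_frames,
                    "seed": seed,
                },
                indent=2,
            )
        )
    return sim


def mean_max_iou(video: VideoDetections, max_frames: int | None = None) -> float:
    """Mean over boxes of their best IoU with another same-frame box.

    A crowding statistic: 0 when nothing overlaps, toward 1 when boxes
    stack on top of each other.
    """
    from .detections import box_iou

    totals, count = 0.0, 0
    for fnum, f in enumerate(video.frames):
        if max_frames is not None and fnum >= max_frames:
            break
        boxes = [d.box for d in f.detections]
        if len(boxes) < 2:
            continue
        for i, a in enumerate(boxes):
            best = 0.0
            for j, b in enumerate(boxes):
                if i != j:
                    v = box_iou(a, b)
                    if v > best:
                        best = v
            totals += best
            count += 1
    return totals / count if count else 0.0
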