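"""Adaptive density clustering for perspective-distorted crop rows.

Oblique (45°) walking video compresses distant plants into a dense band
near the image top while foreground plants spread out — "small in the
distance, large in the foreground".  A fixed-radius DBSCAN cannot serve
both regimes: a radius tuned to the dense far field classifies valid
foreground seedlings as noise, while a radius tuned to the foreground
merges the target row with clutter from neighbouring rows.

The adaptive variant implemented here recomputes both DBSCAN parameters
from local statistics of the detection centres, per frame:

* per-point radius ``eps_x = clip(max(1, Δv/α) · median(D_filtered),
  eps_floor, eps_max)`` where ``Δv`` is a vertical span (by default the
  whole frame's, optionally the point's k-NN set's), ``α`` a
  normalisation constant mapping the span to a scale factor, and
  ``median(D_filtered)`` the outlier-filtered median horizontal
  inter-plant spacing in the point's neighbourhood.  eps therefore
  tracks the local spacing: small in the dense far field, growing
  toward the sparse foreground, up to a hard ceiling of 250 px
  (≈0.3125 m at the 800 px/m central-band calibration — wider than the
  0.3 m drainage ditch, so the radius can never bridge into a
  neighbouring row while hunting for min_samples);
* per-point density threshold ``min_samples = max(floor,
  ceil(mean_k(ρ) · δ))`` aggregating the neighbourhood densities ρ over
  the k-NN set with a decay factor δ — denser regions demand more
  support for a core point.

Points with fewer than ``min_samples`` neighbours inside their radius
are noise; they form the candidate elimination set of non-target
detections.  Clusters are connected components of core points, and the
largest cluster is retained as the target row.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .detections import FrameDetections

__all__ = [
    "NOISE",
    "ROLE_NOISE",
    "ROLE_BORDER",
    "ROLE_CORE",
    "DegenerateFrameError",
    "AdapDBSCANConfig",
    "PointSet",
    "AdaptiveParams",
    "ClusterLabeling",
    "horizontal_spacings",
    "filter_spacings",
    "adaptive_eps",
    "adaptive_min_samples",
    "compute_adaptive_params",
    "cluster",
    "adaptive_labeling",
    "fixed_dbscan",
    "select_target",
]

NOISE = -1
ROLE_NOISE = 0
ROLE_BORDER = 1
ROLE_CORE = 2


class DegenerateFrameError(ValueError):
    """A frame has too few points for adaptive statistics."""


@dataclass
class AdapDBSCANConfig:
    """Tunable parameters of the adaptive clustering stage.

    ``alpha`` (px) normalises the neighbourhood vertical span into the
    eps scale factor; ``delta`` in (0, 1] decays the mean neighbourhood
    density into min_samples; ``k_neighbors`` sets the local-statistics
    neighbourhood; ``eps_max`` (250 px) and ``eps_floor`` (1 px) are the
    dual-threshold radius bounds; ``pixels_per_meter`` (800) is the
    central-band image calibration used only for unit conversion and
    reporting.
    """

    alpha: float = 120.0
    delta: float = 0.5
    k_neighbors: int = 5
    eps_max: float = 250.0
    eps_floor: float = 1.0
    spacing_outlier_multiplier: float = 1.5
    min_samples_floor: int = 2
    pixels_per_meter: float = 800.0
    border_points: bool = True
    min_samples_mode: str = "local"  # "local" (per-point) or "frame"
    delta_v_mode: str = "frame"  # "frame" (whole-frame span) or "local" (k-NN span)

    def __post_init__(self) -> None:
        if self.eps_floor > self.eps_max:
            raise ValueError("eps_floor must not exceed eps_max")
        if self.delta <= 0:
            raise ValueError("delta must be positive")
        if self.k_neighbors < 2:
            raise ValueError("k_neighbors must be >= 2")
        if self.min_samples_mode not in ("local", "frame"):
            raise ValueError("min_samples_mode must be 'local' or 'frame'")
        if self.delta_v_mode not in ("frame", "local"):
            raise ValueError("delta_v_mode must be 'frame' or 'local'")

    @property
    def eps_max_meters(self) -> float:
        """The eps ceiling expressed in metres at the calibrated scale."""
        return self.eps_max / self.pixels_per_meter


@dataclass
class PointSet:
    """Detection centres of one frame, with back-references.

    ``source_indices[i]`` is the position of point ``i`` in the
    originating :class:`FrameDetections`.
    """

    points: np.ndarray  # (n, 2) float
    source_indices: np.ndarray  # (n,) int

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        self.source_indices = np.asarray(self.source_indices, dtype=int)
        if len(self.source_indices) != len(self.points):
            raise ValueError("points and source_indices length mismatch")

    @classmethod
    def from_frame(
        cls, frame: FrameDetections, indices: Sequence[int] | None = None
    ) -> "PointSet":
        if indices is None:
            indices = range(len(frame.detections))
        pts = [frame.detections[i].center for i in indices]
        return cls(np.asarray(pts, dtype=float).reshape(-1, 2), np.asarray(list(indices)))

    def __len__(self) -> int:
        return len(self.points)

    @cached_property
    def tree(self) -> cKDTree:
        return cKDTree(self.points)


@dataclass
class AdaptiveParams:
    """Per-point adaptive parameters for one frame."""

    eps: np.ndarray  # (n,) per-point radius, px
    rho: np.ndarray  # (n,) neighbourhood density within eps (incl. self)
    min_samples: np.ndarray  # (n,) per-point density threshold
    frame_min_samples: int  # frame-level aggregate (alternative mode)
    delta_v: np.ndarray  # (n,) vertical span of the k-NN set, px
    median_spacing: np.ndarray  # (n,) filtered median horizontal gap, px


@dataclass
class ClusterLabeling:
    """Cluster assignment of a frame's points.

    ``labels`` holds cluster ids >= 0 or :data:`NOISE`; ``roles`` holds
    :data:`ROLE_CORE` / :data:`ROLE_BORDER` / :data:`ROLE_NOISE`;
    ``elimination_set`` lists the indices of noise points (the candidate
    set of non-target detections).
    """

    labels: np.ndarray
    roles: np.ndarray

    @property
    def elimination_set(self) -> np.ndarray:
        return np.flatnonzero(self.labels == NOISE)

    @property
    def n_clusters(self) -> int:
        return int(self.labels.max() + 1) if (self.labels >= 0).any() else 0


# ---------------------------------------------------------------------------
# parameter building blocks
# ---------------------------------------------------------------------------


def horizontal_spacings(points: PointSet, k: int) -> np.ndarray:
    """Absolute x-differences from each point to its k nearest neighbours.

    Neighbours are nearest in Euclidean (image-plane) distance; the
    returned array has shape ``(n, k)``.  Duplicate points yield zero
    spacings.  Requires at least two points.
    """
    n = len(points)
    if n < 2:
        raise DegenerateFrameError("horizontal spacings need >= 2 points")
    k = min(k, n - 1)
    _, idx = points.tree.query(points.points, k=k + 1)
    idx = np.atleast_2d(idx)[:, 1:]  # drop self (column 0)
    x = points.points[:, 0]
    return np.abs(x[idx] - x[:, None])


def filter_spacings(spacings: Sequence[float] | np.ndarray, multiplier: float) -> np.ndarray:
    """Drop implausibly large spacings by an upper IQR fence.

    Values above ``Q3 + multiplier·IQR`` (quartiles by linear
    interpolation) are removed; the minimum always survives, so the
    result is never empty.
    """
    arr = np.asarray(spacings, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("cannot filter an empty spacing list")
    q1, q3 = np.percentile(arr, [25, 75])
    return arr[arr <= q3 + multiplier * (q3 - q1)]


def adaptive_eps(
    delta_v: float | np.ndarray,
    median_spacing: float | np.ndarray,
    config: AdapDBSCANConfig,
) -> float | np.ndarray:
    """Neighbourhood radius from local span and spacing.

    ``eps = clip(max(1, Δv/α) · median_spacing, eps_floor, eps_max)``.
    The unit scale floor keeps compact (dense) neighbourhoods at their
    local spacing; the ceiling stops the radius from bridging the
    inter-row ditch.
    """
    dv = np.asarray(delta_v, dtype=float)
    med = np.asarray(median_spacing, dtype=float)
    if np.any(med <= 0):
        raise ValueError("median_spacing must be positive")
    scale = np.maximum(1.0, dv / config.alpha)
    eps = np.clip(scale * med, config.eps_floor, config.eps_max)
    return float(eps) if eps.ndim == 0 else eps


def adaptive_min_samples(
    rho: Sequence[float] | np.ndarray, delta: float, floor: int
) -> int:
    """Density threshold from neighbourhood densities.

    ``min_samples = max(floor, ceil(mean(rho) · delta))`` — denser
    neighbourhoods require more support for a core point.
    """
    arr = np.asarray(rho, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError("empty density list")
    return max(int(floor), math.ceil(arr.mean() * delta))


def _neighborhood_gap_medians(
    points: PointSet, k: int, multiplier: float
) -> np.ndarray:
    """Filtered median of adjacent horizontal gaps per k-NN neighbourhood.

    For each point, the x-coordinates of {point} ∪ kNN are sorted and
    differenced into k adjacent inter-plant gaps; gaps above the IQR
    fence are masked out and the median of the surviving *positive*
    gaps is returned (x-aligned neighbours are one occupied position,
    not a zero spacing).  A neighbourhood with no positive gap reports
    0, which the caller clamps to the radius floor.  This is the
    horizontal inter-plant spacing statistic feeding eps.
    """
    _, idx = points.tree.query(points.points, k=k + 1)
    idx = np.atleast_2d(idx)
    xs = np.sort(points.points[idx, 0], axis=1)
    gaps = np.diff(xs, axis=1)  # (n, k)
    q1, q3 = np.percentile(gaps, [25, 75], axis=1)
    fence = q3 + multiplier * (q3 - q1)
    masked = np.where((gaps <= fence[:, None]) & (gaps > 0), gaps, np.nan)
    with np.errstate(invalid="ignore"):
        med = np.nanmedian(masked, axis=1)
    return np.where(np.isnan(med), 0.0, med)


def compute_adaptive_params(
    points: PointSet, config: AdapDBSCANConfig
) -> AdaptiveParams:
    """Two-pass dynamic parameter determination for one frame.

    Pass 1 derives, per point, the vertical span Δv (frame-wide by
    default, k-NN-local via ``delta_v_mode``), the filtered median
    horizontal gap, the radius eps_x, and the density ρ_x (points
    within eps_x, self included).  Pass 2 aggregates ρ over each
    point's k-NN set into the min_samples threshold.

    Frames with fewer than ``k_neighbors + 1`` points carry too little
    local structure for the statistics and raise
    :class:`DegenerateFrameError`; :func:`adaptive_labeling` maps that to
    an all-noise labelling.
    """
    n = len(points)
    k = config.k_neighbors
    if n < k + 1:
        raise DegenerateFrameError(
            f"{n} points < k_neighbors + 1 = {k + 1}; degenerate frame"
        )
    tree = points.tree
    _, idx = tree.query(points.points, k=k + 1)  # (n, k+1), col 0 = self
    if config.delta_v_mode == "local":
        ys = points.points[idx, 1]
        delta_v = ys.max(axis=1) - ys.min(axis=1)
    else:
        # whole-frame vertical span: one scale factor per frame, so eps
        # tracks the local spacing linearly instead of quadratically
        span = float(points.points[:, 1].max() - points.points[:, 1].min())
        delta_v = np.full(n, span)
    med = _neighborhood_gap_medians(points, k, config.spacing_outlier_multiplier)

    scale = np.maximum(1.0, delta_v / config.alpha)
    eps = np.clip(scale * med, config.eps_floor, config.eps_max)
    # duplicate-heavy neighbourhoods can have zero median gap
    eps = np.where(med > 0, eps, config.eps_floor)

    rho = np.asarray(
        tree.query_ball_point(points.points, eps, return_length=True), dtype=float
    )
    frame_ms = adaptive_min_samples(rho, config.delta, config.min_samples_floor)
    local_ms = np.maximum(
        config.min_samples_floor,
        np.ceil(rho[idx].mean(axis=1) * config.delta),
    ).astype(int)
    ms = (
        local_ms
        if config.min_samples_mode == "local"
        else np.full(n, frame_ms, dtype=int)
    )
    return AdaptiveParams(
        eps=eps,
        rho=rho,
        min_samples=ms,
        frame_min_samples=frame_ms,
        delta_v=delta_v,
        median_spacing=med,
    )


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def _expand(
    points: PointSet,
    eps: np.ndarray,
    core: np.ndarray,
    border_points: bool,
) -> ClusterLabeling:
    """DBSCAN-style expansion with per-point radii.

    Clusters are connected components of core points under *mutual*
    reachability: two cores connect only when their distance is within
    both radii.  (One-sided reachability lets a single sparse core with
    an inflated radius bridge a dense cluster across the inter-row
    ditch, which is exactly the leak the adaptive radius exists to
    prevent.)  Non-core points within some core's radius become border
    members of the nearest such core's cluster; everything else is
    noise.  Component construction is order-independent, and the
    nearest-core border rule makes the labelling deterministic.
    """
    n = len(points)
    labels = np.full(n, NOISE, dtype=int)
    roles = np.full(n, ROLE_NOISE, dtype=np.int8)
    if n == 0:
        return ClusterLabeling(labels, roles)
    roles[core] = ROLE_CORE

    neigh = points.tree.query_ball_point(points.points, eps)

    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    pts = points.points
    core_idx = np.flatnonzero(core)
    for i in core_idx:
        for j in neigh[i]:
            if core[j] and j != i:
                # mutual reachability: also inside j's own radius
                if float(np.hypot(*(pts[j] - pts[i]))) <= eps[j]:
                    union(i, j)

    root_to_label: dict[int, int] = {}
    for i in core_idx:
        r = find(i)
        if r not in root_to_label:
            root_to_label[r] = len(root_to_label)
        labels[i] = root_to_label[r]

    if border_points:
        best_dist = np.full(n, np.inf)
        for i in core_idx:
            for j in neigh[i]:
                if core[j]:
                    continue
                d = float(np.hypot(*(pts[j] - pts[i])))
                if d < best_dist[j]:
                    best_dist[j] = d
                    labels[j] = labels[i]
                    roles[j] = ROLE_BORDER
    return ClusterLabeling(labels, roles)


def cluster(
    points: PointSet,
    params: AdaptiveParams,
    *,
    border_points: bool = True,
) -> ClusterLabeling:
    """Label points using the adaptive per-point parameters.

    A point is core iff its density ρ_x reaches its min_samples
    threshold; see :func:`_expand` for the expansion semantics.
    """
    core = params.rho >= params.min_samples
    return _expand(points, params.eps, core, border_points)


def adaptive_labeling(
    points: PointSet, config: AdapDBSCANConfig
) -> tuple[ClusterLabeling, AdaptiveParams | None]:
    """Adaptive parameters + clustering with degenerate-frame fallback.

    Frames too small for the local statistics come back fully noise.
    """
    try:
        params = compute_adaptive_params(points, config)
    except DegenerateFrameError:
        n = len(points)
        return (
            ClusterLabeling(
                np.full(n, NOISE, dtype=int), np.full(n, ROLE_NOISE, dtype=np.int8)
            ),
            None,
        )
    return cluster(points, params, border_points=config.border_points), params


def fixed_dbscan(
    points: PointSet,
    eps: float,
    min_samples: int,
    *,
    border_points: bool = True,
) -> ClusterLabeling:
    """Classic fixed-parameter DBSCAN — the conventional baseline mode."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    n = len(points)
    if n == 0:
        return ClusterLabeling(
            np.full(0, NOISE, dtype=int), np.full(0, ROLE_NOISE, dtype=np.int8)
        )
    eps_arr = np.full(n, float(eps))
    rho = np.asarray(
        points.tree.query_ball_point(points.points, eps_arr, return_length=True)
    )
    core = rho >= min_samples
    return _expand(points, eps_arr, core, border_points)


def select_target(
    labeling: ClusterLabeling,
    points: PointSet,
    frame_size: tuple[int, int],
) -> np.ndarray:
    """Indices of points retained as the target row.

    Noise is dropped; of the remaining clusters the largest by member
    count is kept (ties broken by cluster centroid closest to the
    frame's vertical midline — the walked row sits under the camera).
    Returns indices into the :class:`PointSet`; an empty array means the
    frame contributes nothing.
    """
    labels = labeling.labels
    valid = labels >= 0
    if not valid.any():
        return np.empty(0, dtype=int)
    ids, counts = np.unique(labels[valid], return_counts=True)
    best = counts.max()
    candidates = ids[counts == best]
    if len(candidates) > 1:
        midline = frame_size[0] / 2.0
        offsets = [
            abs(points.points[labels == c, 0].mean() - midline) for c in candidates
        ]
        target = candidates[int(np.argmin(offsets))]
    else:
        target = candidates[0]
    return np.flatnonzero(labels == target)
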