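# Methods

This note records the models, conventions and defaults behind
`rowcount`, in enough detail to reproduce or deliberately change any of
them. Nothing here states a result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem setting and assumptions

The pipeline counts the seedlings of one *row unit* (the bed between
two drainage ditches) from per-frame bounding-box detections of a
camera walked along the furrow. Assumptions baked into the design:

* image origin top-left, y down; the camera advances so plants enter
  near the image top and leave across the *lower* edge;
* frames arrive in order at a constant rate; missing frames are empty;
* detections carry a confidence in [0, 1]; the detector itself is out
  of scope — any MOT-dialect CSV or YOLO label directory works;
* plants are stationary; all image motion comes from the walk.

## Adaptive density clustering

Per frame, detection centres are clustered with per-point DBSCAN
parameters derived in two passes:

1. For each point: its k-NN set (`k_neighbors`), the filtered median
   horizontal gap of that set, a vertical span Δv, hence the radius
   `eps_x = clip(max(1, Δv/α)·median(D_filtered), eps_floor, eps_max)`,
   and the density `ρ_x` = points within `eps_x` (self included).
2. `min_samples_x = max(floor, ceil(mean(ρ over the k-NN set)·δ))`.

A point is core iff `ρ_x ≥ min_samples_x`; clusters are connected
components of cores under **mutual** reachability (an edge needs the
distance inside *both* radii — one-sided reachability lets a single
sparse point with an inflated radius bridge a dense cluster across the
ditch); non-core points inside some core's radius join the nearest
such core's cluster as border members; the rest are noise.

Choices a reader should know about:

* **Horizontal gap statistic.** The spacing set is the adjacent gaps
  of the x-sorted neighbourhood (the inter-plant spacing a field
  scientist would measure), IQR-fenced (`Q3 + 1.5·IQR`, type-7
  quantiles) and reduced by the median. Only positive gaps enter the
  median: x-aligned duplicates are one occupied position, not a zero
  spacing; a neighbourhood with no positive gap gets the floor radius.
  The standalone utility `horizontal_spacings` (|Δx| to the k nearest
  neighbours) is also provided.
* **Δv support.** Default is the whole frame's vertical span
  (`delta_v_mode="frame"`), so each frame has one scale factor and
  `eps` tracks the local gap *linearly*. With the k-NN-local span
  (`delta_v_mode="local"`, also implemented) both Δv and the gap grow
  with local spacing, making eps roughly quadratic in spacing — on
  oblique scenes that either collapses the dense far band below the
  point spacing or saturates the ceiling and bridges the ditch.
* **min_samples locality.** Default per-point (`min_samples_mode=
  "local"`): the threshold must be regional — dense far-field
  neighbourhoods demand more support than sparse foreground ones, and
  a single frame-level mean (also available, `"frame"`) is dominated
  by the perspective-stacked far field and eliminates valid foreground
  plants.
* **Elimination mode.** The pipeline drops *noise points only* by
  default (`elimination_mode="noise"`): the rule is locally determined
  and therefore temporally stable, which matters because every
  spurious retained→eliminated→retained cycle risks double-counting a
  plant downstream. The stricter `"target_cluster"` mode additionally
  keeps only the largest cluster (tie → centroid nearest the vertical
  midline, `select_target`); it also removes *clustered* clutter but
  makes per-frame retention depend on global connectivity, which
  fragments and flaps on perspective scenes.
* **Defaults.** `alpha = 120 px`, `delta = 0.5`, `k_neighbors = 5`,
  `eps_floor = 1 px`, `eps_max = 250 px`, `min_samples_floor = 2`,
  IQR multiplier 1.5, calibration 800 px/m. α and δ are free
  constants; α = 120 puts eps at ≈2–4× the local plant spacing on the
  calibrated scene geometry at every depth — above the spacing (so the
  stand stays clustered), below the projected ditch gap (so rows stay
  separate). The 250 px ceiling is ≈0.3125 m at the central-band
  scale; note that deeper in the frame the same 250 px corresponds to
  a *larger* metric distance, which is why clutter directly at the bed
  edge can never be separated by a pixel-radius rule (the residual
  false positives live there).

## Tracking and counting

Standard SORT: state `[u, v, s, r, du, dv, ds]` (centre, area, aspect
ratio constant), F the constant-velocity transition,
`Q = diag(1,1,1,1,.01,.01,1e-4)`, `R = diag(1,1,10,10)`,
`P₀ = diag(10,10,10,10,1e4,1e4,1e4)` (scales config-exposed); Hungarian
assignment on IoU; a predicted area that would go non-positive zeroes
its velocity with a warning.

Lifecycle defaults and why they differ from pedestrian tracking:

* `iou_threshold = 0.2` (not 0.3): targets are tens of pixels at most,
  so a couple of pixels of localisation error is a large IoU drop; the
  lower gate mainly aids re-acquisition after short coasts.
* `min_hits = 5` *consecutive* matches (hit streak, as in the original
  SORT): flickering marginal detections — low-confidence off-row hits,
  one-frame false positives, ghost tracks living off occasionally
  stolen detections in dense regions — never confirm.
* `max_age = 8` frames (~0.27 s at 30 fps): a track must coast across
  short detector dropouts and brief clustering eliminations; with a
  small max_age every such gap respawns a new id and double-counts.

Counting: ŷ = |confirmed ids| (`count_mode="confirmed"`). Retirement —
centre `v ≥ frame_height`, evaluated once per frame after the update —
permanently blacklists the id, so no plant that left the bottom edge
can be counted twice; `count_mode="retired"` instead counts only ids
that actually crossed, which excludes plants still mid-frame when the
video ends.

## Evaluation conventions

* Detection: greedy confidence-descending one-to-one matching at
  IoU ≥ 0.5 per frame; AP is the raw all-point sum `Σ Pᵢ·ΔRᵢ` over the
  confidence sweep (no 11-point/101-point interpolation). `P` with no
  predictions is defined as 1 (warned); no ground truth raises.
* Tracking: tracks are matched to ground-truth identities per frame by
  centre distance (Hungarian; threshold = half the median truth box
  width). Truth boxes under 10 px are not evaluable — in the
  perspective-compressed far field neighbouring plants sit closer than
  any localisation noise, so identity there is unresolvable for any
  method. `Q_sh` counts frame transitions where an identity's matched
  track id changes; `T_mat` = identities matched at least once;
  `M_mat` = identities whose dominant track id covers ≥ 50 % of their
  matched frames. These are conventions, not fidelity claims; on
  heavily stacked simulated scenes `W_ID` is structurally pessimistic
  (coasting tracks hand their identity to near neighbours and back),
  and `P_tr = M_mat/S` can exceed 1 when more identities are matched
  than plants counted.
* Counting: `Acc` may be negative for gross over-counts; `R²` requires
  ≥ 2 videos with non-constant truth.

## Scene simulator

Geometry: world X along the walk, Y lateral, Z up; camera at height
0.5 m pitched 45° or 90°, advancing `walk_speed/fps` per frame from
0.5 m before the bed to 0.1 m past it. Focal length defaults to
`800 · h / sin 45° ≈ 566 px`, derived so the lateral scale where the
optical axis meets the ground at the 45° reference is the calibrated
800 px/m (consistent with an ultra-wide phone lens at 1920 px).

Plants: one seeded line per bed at 0.05 m nominal spacing, each site
occupied with probability `emergence_rate = 0.97`, jittered 0.01 m
along and 0.28 m laterally (clipped to the bed) — ≈280 plants on the
full bed, a thinned stand that keeps every pixel scale (box sizes,
spacings, eps ranges) at the calibrated field geometry. Optional
clutter rows sit at the neighbouring bed centre (1.5 m), thinned by
`side_row_sparsity`, never inside the ditch. Each plant is a flat
rosette (canopy 0.08 m, vertical extent 0.04 m): box width is the
projected canopy, box height the view-foreshortened canopy plus the
projected vertical extent, so the 45° view produces the
characteristic few-pixel distant / tens-of-pixels foreground boxes
and the 90° view near-constant sizes. A plant is rendered while its
projected centre is inside the frame; boxes may overhang edges.

Detector noise (all seeded, marginal rates documented in
`NoiseConfig`):

* **Persistent size thresholds.** Each plant draws a detectability
  threshold `midpoint + steepness·logit(U)`; it is detected once its
  box height exceeds it (plus an 8 % per-frame flicker). The marginal
  miss curve at any height is exactly the logistic around 8 px, but
  misses are temporally correlated per plant, as real detector misses
  are — independent per-frame misses shred tracks into confetti no
  tracker could count.
* **Off-row domain bias.** A detector trained only on valid-region
  annotations fires weakly off-row: side-row plants need 6 px more
  size and score confidence ≈ N(0.18, 0.08), so only scattered
  low-confidence hits cross a sensible 0.25 threshold.
* **Canopy merge (view effect).** Neighbour pairs closer than the
  canopy diameter are interlocked; from straight above they are
  indistinguishable and one member goes undetected for the whole
  video with probability `0.6 · clip((sin tilt − sin 45°)/(1 − sin
  45°), 0, 1)` — zero at 45°, full at 90°. This is the mechanism that
  makes the vertical view under-count and the oblique view the better
  counting geometry; it is a detector-behaviour model, not a claim
  about rendered occlusion.
* **Clutter.** Persistent weeds/clods (0.5 per row-metre, a managed
  but not spotless trial plot) across the ditch and the neighbouring
  bed margin, detected frame after frame with confidence 0.3–0.7;
  plus Poisson one-frame false positives (0.2/frame, ditch-biased).
* **Localisation.** Centre jitter ∝ box size (5 %, floor 0.3 px) and
  8 % size jitter; confidence rises logistically with box size.

What the simulator does **not** model: rendered leaf-level occlusion,
motion blur, illumination, path offsets or camera shake (fields exist
but default off), and any appearance signal. Passing tests therefore
show that the *geometry-and-density* logic of the pipeline is sound
under realistic detector statistics; they do not certify performance
on real videos, where detector errors are richer and correlated with
appearance.

## Numerical and degenerate-input choices

* Quantiles: linear interpolation (type 7) everywhere.
* Frames with < 2 detections above the confidence threshold bypass
  clustering; frames with fewer than `k_neighbors + 1` points are
  degenerate for the local statistics and come back all-noise.
* Border assignment: nearest qualifying core, first-seen on ties;
  cluster ids are first-seen ordered — the labelling is deterministic.
* Confidence outside [0, 1] is clamped with a warning; boxes with
  non-positive width/height are rejected at parse time with the line
  number.
* MOT files are written with full `repr` float precision so a
  write→read round trip is exact.

## Problem sizes used by tests and the acceptance script

Multi-seed experiments (adaptive-vs-fixed pairing, 45° vs 90°
comparison, count R² across stand densities) run on half-length 7.2 m
rows (~140 plants, ~290 frames) with 10 seeds — enough rows and plants
for stable directions while keeping the full suite in a few minutes.
Count conservation runs on the full 14.4 m default scene (~280
plants). The worked metric examples are closed-form and instant.

## Known limitations

* Clutter within ~one radius of the outermost target plants (ditch-edge
  weeds, near-edge neighbour plants) is not separable by any density
  rule and appears as a small positive count bias (~2–4 % on the
  default clutter scene).
* The 250 px radius ceiling is calibrated for the central band; its
  metric reach grows with depth, so deep clutter adjacent to the stand
  can be absorbed there.
* SORT has no appearance model: a track lost for longer than
  `max_age` frames while its plant is still visible becomes a second
  count; the hit-streak and coasting defaults make this rare but not
  impossible.
* Identity-level tracking metrics on heavily stacked scenes are
  pessimistic (see conventions above); counting metrics are the
  reliable summary there.
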