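import numpy as np
import pytest

from rowcount import (
    AdapDBSCANConfig,
    PointSet,
    adaptive_eps,
    adaptive_labeling,
    adaptive_min_samples,
    cluster,
    compute_adaptive_params,
    filter_spacings,
    fixed_dbscan,
    horizontal_spacings,
    select_target,
)
from rowcount.clustering import (
    NOISE,
    ROLE_CORE,
    ROLE_NOISE,
    AdaptiveParams,
    DegenerateFrameError,
)

from .oracles import brute_force_dbscan, labels_equivalent


def pset(points):
    pts = np.asarray(points, dtype=float)
    return PointSet(pts, np.arange(len(pts)))


class TestHorizontalSpacings:
    def test_collinear_middle_point(self):
        ps = pset([(0, 0), (100, 0), (200, 0)])
        sp = horizontal_spacings(ps, k=2)
        assert sorted(sp[1]) == [100, 100]

    def test_duplicates_give_zero_spacing(self):
        ps = pset([(50, 50), (50, 50), (60, 50)])
        sp = horizontal_spacings(ps, k=2)
        assert 0.0 in sp[0]

    def test_matches_pairwise_bruteforce(self, rng):
        pts = rng.uniform(0, 500, size=(50, 2))
        ps = pset(pts)
        k = 6
        sp = horizontal_spacings(ps, k)
        for i in range(len(pts)):
            d = np.hypot(*(pts - pts[i]).T)
            order = np.argsort(d)
            neighbours = [j for j in order if j != i][:k]
            expect = sorted(abs(pts[j, 0] - pts[i, 0]) for j in neighbours)
            assert sorted(sp[i]) == pytest.approx(expect)

    def test_single_point_degenerate(self):
        with pytest.raises(DegenerateFrameError):
            horizontal_spacings(pset([(0, 0)]), k=2)


class TestFilterSpacings:
    def test_outlier_removed(self):
        # Q3 of {10,10,10,10,500} is 10, IQR 0 -> fence 10; 500 dropped
        out = filter_spacings([10, 10, 10, 10, 500], 1.5)
        assert list(out) == [10, 10, 10, 10]

    def test_all_equal_unchanged(self):
        assert list(filter_spacings([7, 7, 7], 1.5)) == [7, 7, 7]

    def test_single_element_unchanged(self):
        assert list(filter_spacings([42.0], 1.5)) == [42.0]

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            filter_spacings([], 1.5)

    def test_minimum_always_survives(self, rng):
        for _ in range(50):
            vals = rng.lognormal(2, 1, size=rng.integers(1, 30))
            out = filter_spacings(vals, 1.5)
            assert len(out) >= 1
            assert vals.min() in out


class TestAdaptiveEps:
    CFG = AdapDBSCANConfig(alpha=100.0)

    def test_scale_clamps_to_one_below_alpha(self):
        assert adaptive_eps(50.0, 60.0, self.CFG) == 60.0

    def test_direct_substitution(self):
        # delta_v = 2*alpha doubles the local spacing
        assert adaptive_eps(200.0, 60.0, self.CFG) == 120.0

    def test_ceiling_binds(self):
        assert adaptive_eps(1e6, 200.0, self.CFG) == 250.0

    def test_nonpositive_spacing_errors(self):
        with pytest.raises(ValueError):
            adaptive_eps(10.0, 0.0, self.CFG)


class TestAdaptiveMinSamples:
    def test_mean_times_delta(self):
        assert adaptive_min_samples([4, 4, 4, 4], 0.5, 2) == 2
        assert adaptive_min_samples([10, 10], 0.5, 2) == 5

    def test_floor_binds(self):
        assert adaptive_min_samples([10, 10], 1e-9, 2) == 2

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            adaptive_min_samples([], 0.5, 2)


class TestComputeAdaptiveParams:
    def test_uniform_line_eps_equals_spacing(self):
        ps = pset([(50 * i, 300.0) for i in range(20)])
        params = compute_adaptive_params(ps, AdapDBSCANConfig())
        assert np.allclose(params.delta_v, 0.0)
        assert np.allclose(params.eps, 50.0)
        lab = cluster(ps, params)
        assert lab.n_clusters == 1
        assert len(lab.elimination_set) == 0

    def test_perspective_grid_eps_monotone(self):
        # rows whose spacing shrinks toward the image top (small y)
        pts = []
        for j, y in enumerate(range(100, 1100, 100)):
            step = 15 + 8 * j
            pts += [(x, y + 0.1 * x) for x in np.arange(200, 1700, step)]
        ps = pset(pts)
        params = compute_adaptive_params(ps, AdapDBSCANConfig())
        ys = ps.points[:, 1]
        order = np.argsort(ys)
        band_eps = [
            np.median(params.eps[order][i : i + 40])
            for i in range(0, len(order) - 40, 40)
        ]
        diffs = np.diff(band_eps)
        assert (diffs >= -1e-9).mean() > 0.8  # non-decreasing toward bottom

    def test_two_points_degenerate_all_noise(self):
        ps = pset([(0, 0), (500, 500)])
        lab, params = adaptive_labeling(ps, AdapDBSCANConfig())
        assert params is None
        assert set(lab.labels) == {NOISE}

    def test_eps_respects_bounds_on_simulated_frames(self, small_scene_noisy):
        cfg = AdapDBSCANConfig()
        checked = 0
        for frame in small_scene_noisy.detections.frames[::17]:
            if len(frame) < cfg.k_neighbors + 1:
                continue
            params = compute_adaptive_params(PointSet.from_frame(frame), cfg)
            assert (params.eps >= cfg.eps_floor).all()
            assert (params.eps <= cfg.eps_max).all()
            assert (params.rho >= 1).all()
            checked += 1
        assert checked > 3


class TestCluster:
    def test_dense_grid_single_cluster(self):
        pts = [(30 * i, 30 * j) for i in range(5) for j in range(5)]
        ps = pset(pts)
        n = len(pts)
        params = AdaptiveParams(
            eps=np.full(n, 100.0),
            rho=np.full(n, 9.0),
            min_samples=np.full(n, 3),
            frame_min_samples=3,
            delta_v=np.zeros(n),
            median_spacing=np.full(n, 30.0),
        )
        lab = cluster(ps, params)
        assert lab.n_clusters == 1
        assert len(lab.elimination_set) == 0

    def test_groups_beyond_eps_max_never_merge(self):
        rng = np.random.default_rng(0)
        left = rng.uniform(0, 200, size=(30, 2)) + [100, 400]
        right = rng.uniform(0, 200, size=(30, 2)) + [800, 400]  # gap > 250 px
        ps = pset(np.vstack([left, right]))
        lab, _ = adaptive_labeling(ps, AdapDBSCANConfig())
        left_labels = set(lab.labels[:30]) - {NOISE}
        right_labels = set(lab.labels[30:]) - {NOISE}
        assert not (left_labels & right_labels)

    def test_isolated_point_is_noise(self):
        pts = [(30 * i, 30 * j) for i in range(4) for j in range(4)]
        pts.append((1500.0, 1000.0))
        ps = pset(pts)
        lab, _ = adaptive_labeling(ps, AdapDBSCANConfig())
        assert lab.labels[-1] == NOISE
        assert lab.roles[-1] == ROLE_NOISE
        assert len(ps) - 1 - (lab.labels[:-1] >= 0).sum() <= 2

    def test_core_points_have_clusters_and_noise_in_elimination_set(
        self, small_scene_noisy
    ):
        frame = small_scene_noisy.detections.frames[40]
        ps = PointSet.from_frame(frame)
        lab, _ = adaptive_labeling(ps, AdapDBSCANConfig())
        assert (lab.labels[lab.roles == ROLE_CORE] >= 0).all()
        assert set(lab.elimination_set) == set(np.flatnonzero(lab.labels == NOISE))


class TestFixedDBSCAN:
    def test_huge_eps_single_cluster(self, rng):
        ps = pset(rng.uniform(0, 300, size=(40, 2)))
        lab = fixed_dbscan(ps, eps=1e6, min_samples=2)
        assert lab.n_clusters == 1

    def test_tiny_eps_all_noise(self, rng):
        ps = pset(rng.uniform(0, 1000, size=(30, 2)))
        lab = fixed_dbscan(ps, eps=1e-6, min_samples=2)
        assert set(lab.labels) == {NOISE}

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(25):
            n = rng.integers(10, 120)
            pts = rng.uniform(0, 400, size=(n, 2))
            eps = rng.uniform(15, 80)
            ms = int(rng.integers(2, 6))
            lab = fixed_dbscan(pset(pts), eps, ms)
            exp_labels, exp_roles = brute_force_dbscan(pts, eps, ms)
            assert labels_equivalent(lab.labels, exp_labels)
            assert (lab.roles == exp_roles).all()

    def test_matches_sklearn_core_and_noise(self, rng):
        sklearn = pytest.importorskip("sklearn.cluster")
        for _ in range(10):
            pts = rng.uniform(0, 300, size=(80, 2))
            eps, ms = 30.0, 4
            lab = fixed_dbscan(pset(pts), eps, ms)
            ref = sklearn.DBSCAN(eps=eps, min_samples=ms).fit(pts)
            ref_core = np.zeros(len(pts), bool)
            ref_core[ref.core_sample_indices_] = True
            assert ((lab.roles == ROLE_CORE) == ref_core).all()
            assert ((lab.labels == NOISE) == (ref.labels_ == -1)).all()
            # cores partition identically
            assert labels_equivalent(
                lab.labels[ref_core], ref.labels_[ref_core]
            )


class TestLimitEquivalence:
    def test_adaptive_equals_fixed_on_homogeneous_line(self):
        xs = np.arange(0, 2000, 40.0)
        ps = pset([(x, 500.0) for x in xs])
        cfg = AdapDBSCANConfig()
        params = compute_adaptive_params(ps, cfg)
        assert (params.delta_v / cfg.alpha <= 1).all()
        lab_adaptive = cluster(ps, params)
        lab_fixed = fixed_dbscan(
            ps, float(np.median(params.eps)), params.frame_min_samples
        )
        assert labels_equivalent(lab_adaptive.labels, lab_fixed.labels)


class TestSelectTarget:
    def test_single_cluster_plus_noise(self):
        labels = np.array([0, 0, 0, NOISE])
        roles = np.array([2, 2, 1, 0], dtype=np.int8)
        from rowcount.clustering import ClusterLabeling

        ps = pset([(100, 100), (110, 100), (120, 100), (900, 900)])
        keep = select_target(ClusterLabeling(labels, roles), ps, (1920, 1080))
        assert list(keep) == [0, 1, 2]

    def test_largest_cluster_wins(self, rng):
        central = rng.normal([960, 500], 40, size=(40, 2))
        side = rng.normal([100, 300], 20, size=(6, 2))
        ps = pset(np.vstack([central, side]))
        from rowcount.clustering import ClusterLabeling

        labels = np.array([0] * 40 + [1] * 6)
        roles = np.full(46, 2, dtype=np.int8)
        keep = select_target(ClusterLabeling(labels, roles), ps, (1920, 1080))
        assert set(keep) == set(range(40))

    def test_empty_labeling_empty_result(self):
        from rowcount.clustering import ClusterLabeling

        ps = pset([(0, 0), (10, 10)])
        lab = ClusterLabeling(np.array([NOISE, NOISE]), np.zeros(2, np.int8))
        assert len(select_target(lab, ps, (1920, 1080))) == 0

    def test_tie_broken_by_midline_distance(self):
        from rowcount.clustering import ClusterLabeling

        ps = pset([(900, 100), (920, 100), (100, 100), (120, 100)])
        lab = ClusterLabeling(
            np.array([0, 0, 1, 1]), np.full(4, 2, dtype=np.int8)
        )
        keep = select_target(lab, ps, (1920, 1080))
        assert set(keep) == {0, 1}


def test_adaptive_separates_rows_better_than_fixed(clutter_scene):
    """Perspective clutter: the adaptive radius removes the majority of
    side-row points while retaining more valid target-row points than
    fixed DBSCAN at the frame-median eps (whose single radius cannot
    serve the dense far field and the sparse foreground at once)."""
    sim = clutter_scene
    truth = sim.truth
    tmap = truth.video.frame_map()
    cfg = AdapDBSCANConfig()
    counts = {"a_side": 0, "f_side": 0, "a_tgt": 0, "f_tgt": 0,
              "n_side": 0, "n_tgt": 0}
    for frame in sim.detections.frames[60:260:20]:
        tf = tmap.get(frame.frame_index)
        if tf is None:
            continue
        keep_idx = [
            i for i, d in enumerate(frame.detections) if d.confidence >= 0.25
        ]
        if len(keep_idx) < cfg.k_neighbors + 1:
            continue
        centers = np.array([d.center for d in tf.detections])
        ids = truth.ids[frame.frame_index]
        ps = PointSet.from_frame(frame, keep_idx)
        lab_a, params = adaptive_labeling(ps, cfg)
        if params is None:
            continue
        lab_f = fixed_dbscan(
            ps, float(np.median(params.eps)), params.frame_min_samples
        )
        keep_a = set(select_target(lab_a, ps, frame.frame_size).tolist())
        keep_f = set(select_target(lab_f, ps, frame.frame_size).tolist())
        for pi in range(len(ps)):
            d = np.hypot(*(centers - ps.points[pi]).T)
            j = int(np.argmin(d))
            if d[j] > 25:
                continue  # weed or one-frame FP, not a plant
            kind = "tgt" if sim.scene.row_ids[ids[j]] == 0 else "side"
            counts["n_" + kind] += 1
            counts["a_" + kind] += pi not in keep_a
            counts["f_" + kind] += pi not in keep_f
    assert counts["n_side"] > 10 and counts["n_tgt"] > 100
    # most clutter goes...
    assert counts["a_side"] / counts["n_side"] >= 0.5
    # ...and fewer valid seedlings go with it than under the fixed radius
    assert counts["a_tgt"] / counts["n_tgt"] < counts["f_tgt"] / counts["n_tgt"]
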