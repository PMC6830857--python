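import itertools
import warnings

import numpy as np
import pytest

import gastro3d as g
from gastro3d.outlier_removal import (
    OUTLIER_MARK,
    CleaningConfig,
    Plane,
    PointCloudStage,
    bbox_diagonal,
    gather_neighborhood,
    plane_fit_filter,
    ransac_plane,
    remove_isolated,
    run_outlier_removal,
    smooth_mesh_filter,
)


def isolated_oracle(points, A):
    """Exhaustive O(N^2) nearest-neighbour isolation filter."""
    pts = np.asarray(points, dtype=float)
    r = bbox_diagonal(pts)
    d2 = np.sum((pts[:, None, :] - pts[None, :, :]) ** 2, axis=-1)
    np.fill_diagonal(d2, np.inf)
    nn = np.sqrt(d2.min(axis=1))
    return nn <= A * r


class TestBBoxDiagonal:
    def test_unit_cube_corners(self):
        corners = np.array(list(itertools.product([0, 1], repeat=3)), dtype=float)
        assert bbox_diagonal(corners) == pytest.approx(np.sqrt(3))

    def test_single_point_is_zero(self):
        assert bbox_diagonal(np.array([[3.0, 4.0, 5.0]])) == 0.0

    def test_matches_direct_formula(self, rng):
        pts = rng.uniform(0, 2, size=(1000, 3))
        expect = np.linalg.norm(pts.max(axis=0) - pts.min(axis=0))
        assert bbox_diagonal(pts) == pytest.approx(expect, rel=1e-12)

    def test_empty_cloud_raises(self):
        with pytest.raises(ValueError):
            bbox_diagonal(np.zeros((0, 3)))


class TestRemoveIsolated:
    def test_planted_far_point_removed(self, rng):
        pts = np.vstack([rng.uniform(0, 1, size=(1000, 3)), [[3.0, 3.0, 3.0]]])
        out = remove_isolated(pts, A=0.05)
        assert 1000 not in out.ids  # the planted point had id 1000
        assert len(out) >= 990

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pts = np.vstack(
            [
                rng.uniform(0, 1, size=(400, 3)),
                rng.uniform(0, 1, size=(1, 3)) + 2.5,  # far cluster seedling
                rng.uniform(-1.5, -1.2, size=(3, 3)),
            ]
        )
        keep = isolated_oracle(pts, 0.05)
        out = remove_isolated(pts, A=0.05)
        np.testing.assert_array_equal(np.sort(out.ids), np.flatnonzero(keep))

    def test_coincident_points_all_kept(self):
        pts = np.zeros((5, 3))
        out = remove_isolated(pts, A=0.05)
        assert len(out) == 5  # r = 0 so the threshold is 0 and NN distance is 0

    def test_r_is_recomputed_on_survivors(self, rng):
        pts = np.vstack([rng.uniform(0, 1, size=(500, 3)), [[5.0, 5.0, 5.0]]])
        out = remove_isolated(pts, A=0.05)
        assert out.r == pytest.approx(bbox_diagonal(out.points))
        assert out.r < bbox_diagonal(pts)

    def test_recall_non_increasing_in_A(self, small_scene):
        """A larger isolation scale removes fewer planted isolated outliers."""
        iso_ids = np.flatnonzero(small_scene.labels == g.PointLabel.ISOLATED_OUTLIER)
        recalls = []
        for A in (0.02, 0.05, 0.1, 0.3):
            out = remove_isolated(small_scene.points, A=A)
            removed = set(range(len(small_scene.points))) - set(out.ids.tolist())
            recalls.append(len(removed & set(iso_ids.tolist())) / len(iso_ids))
        assert all(a >= b for a, b in zip(recalls, recalls[1:]))


class TestGatherNeighborhood:
    def test_cap_returns_nearest_100(self, rng):
        pts = rng.normal(size=(151, 3)) * 0.01
        pts[0] = 0
        stage = PointCloudStage.from_points(pts, "P_prime")
        cfg = CleaningConfig(M=10)
        nb = gather_neighborhood(0, stage, cfg)
        assert nb.shape == (100, 3)
        # the returned set is exactly the 100 nearest
        d = np.linalg.norm(pts[1:] - pts[0], axis=1)
        cutoff = np.sort(d)[99]
        assert np.all(np.linalg.norm(nb - pts[0], axis=1) <= cutoff + 1e-12)

    def test_census_failure_marks_outlier(self):
        pts = np.random.default_rng(0).normal(size=(60, 3))
        stage = PointCloudStage.from_points(pts, "P_prime")
        cfg = CleaningConfig(M=80)  # only 59 possible neighbours
        assert gather_neighborhood(0, stage, cfg) == OUTLIER_MARK

    def test_tie_at_cap_boundary_prefers_lowest_index(self):
        # centre at origin; 99 unique near points, then two exactly equidistant
        rng = np.random.default_rng(1)
        near = rng.normal(size=(99, 3)) * 0.01
        tie_a = np.array([[0.5, 0.0, 0.0]])
        tie_b = np.array([[0.0, 0.5, 0.0]])
        pts = np.vstack([[0.0, 0.0, 0.0], near, tie_a, tie_b])
        stage = PointCloudStage.from_points(pts, "P_prime")
        cfg = CleaningConfig(M=10)
        nb = gather_neighborhood(0, stage, cfg)
        assert len(nb) == 100
        # index 100 (tie_a) wins over index 101 (tie_b)
        assert any(np.allclose(p, tie_a[0]) for p in nb)
        assert not any(np.allclose(p, tie_b[0]) for p in nb)


class TestRansacPlane:
    def test_three_points_define_exact_plane(self):
        pts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]])
        plane = ransac_plane(pts, iters=10, seed=0)
        np.testing.assert_allclose(np.abs(plane.normal), [0, 0, 1], atol=1e-12)
        np.testing.assert_allclose(plane.distance(pts), 0, atol=1e-12)

    def test_dominant_plane_recovered_against_contaminants(self, rng):
        on = np.column_stack([rng.uniform(-1, 1, (100, 2)), np.zeros(100)])
        off = np.column_stack([rng.uniform(-1, 1, (5, 2)), np.full(5, 5.0)])
        pts = np.vstack([on, off])
        plane = ransac_plane(pts, iters=len(pts) ** 3, seed=0)  # exhaustive budget
        assert abs(abs(plane.normal[2]) - 1) < 1e-9
        assert abs(plane.offset) < 1e-9

    def test_coplanar_cloud_all_residuals_zero(self, rng):
        xy = rng.uniform(size=(30, 2))
        pts = np.column_stack([xy, xy @ [0.3, -0.2] + 1.0])  # a tilted plane
        plane = ransac_plane(pts, iters=500, seed=0)
        assert plane.distance(pts).max() < 1e-9

    def test_collinear_input_raises(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            ransac_plane(pts, iters=50, seed=0)

    def test_deterministic_for_fixed_seed(self, rng):
        pts = rng.normal(size=(40, 3))
        p1 = ransac_plane(pts, iters=50, seed=123)
        p2 = ransac_plane(pts, iters=50, seed=123)
        np.testing.assert_array_equal(p1.normal, p2.normal)
        assert p1.offset == p2.offset

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_exhaustive_budget_maximises_inlier_count(self, seed):
        """Against brute-force enumeration of every triple at n <= 15."""
        rng = np.random.default_rng(seed)
        n_on = rng.integers(8, 13)
        basis = rng.normal(size=(2, 3))
        on = rng.uniform(-1, 1, (n_on, 2)) @ basis
        off = on.mean(axis=0) + rng.normal(size=(3, 3))
        pts = np.vstack([on, off])
        eps = 0.01 * bbox_diagonal(pts)

        best_count = -1
        for tri in itertools.combinations(range(len(pts)), 3):
            a, b, c = pts[list(tri)]
            nrm = np.cross(b - a, c - a)
            if np.linalg.norm(nrm) < 1e-12:
                continue
            nrm = nrm / np.linalg.norm(nrm)
            d = np.abs((pts - a) @ nrm)
            best_count = max(best_count, int((d <= eps).sum()))

        plane = ransac_plane(pts, iters=len(pts) ** 3, seed=seed)
        got = int((plane.distance(pts) <= eps).sum())
        assert got == best_count


class TestPlaneFitFilter:
    def test_worked_example_removes_only_offset_points(self):
        # 200 coplanar + 10 perpendicular-offset points, all with >= M coplanar neighbours
        gx, gy = np.meshgrid(np.arange(20), np.arange(10))
        on = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(200)]).astype(float)
        rng = np.random.default_rng(0)
        off_xy = rng.uniform(2, 17, size=(10, 2))
        off = np.column_stack([off_xy, np.ones(10)])
        pts = np.vstack([on, off])
        stage = PointCloudStage.from_points(pts, "P_prime")
        out, report = plane_fit_filter(stage, CleaningConfig(ransac_seed=0))
        removed = sorted(report.removed_per_stage["P_hat"])
        assert removed == list(range(200, 210))
        assert report.avg_D == pytest.approx(10.0 / 210.0, rel=1e-6)

    def test_perfect_plane_loses_nothing(self):
        gx, gy = np.meshgrid(np.arange(15), np.arange(15))
        pts = np.column_stack([gx.ravel(), gy.ravel(), np.zeros(225)]).astype(float)
        stage = PointCloudStage.from_points(pts, "P_prime")
        out, report = plane_fit_filter(stage, CleaningConfig())
        assert len(out) == 225  # all D = 0, strict > keeps everything
        assert report.avg_D == 0.0

    def test_all_census_failures_yield_empty_stage_with_warning(self, rng):
        pts = rng.normal(size=(30, 3))
        stage = PointCloudStage.from_points(pts, "P_prime")
        with pytest.warns(UserWarning, match="census"):
            out, _ = plane_fit_filter(stage, CleaningConfig(M=80))
        assert len(out) == 0

    def test_fixed_seed_reproduces_removal_set(self, rng):
        pts = rng.normal(size=(300, 3))
        pts[:, 2] *= 0.05
        stage = PointCloudStage.from_points(pts, "P_prime")
        cfg = CleaningConfig(M=20, ransac_seed=7)
        out1, rep1 = plane_fit_filter(stage, cfg)
        out2, rep2 = plane_fit_filter(stage, cfg)
        assert rep1.removed_per_stage == rep2.removed_per_stage
        assert (out1.points == out2.points).all()


class TestSmoothMeshFilter:
    def test_huge_B_removes_nothing(self, small_scene):
        stage = PointCloudStage.from_points(
            small_scene.points[small_scene.inlier_mask], "P_hat"
        )
        out, _ = smooth_mesh_filter(stage, CleaningConfig(B=1e9))
        assert len(out) == len(stage)

    def test_planted_radial_outliers_removed_inliers_kept(self):
        rng = np.random.default_rng(5)
        d = rng.normal(size=(1200, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        sigma0 = 0.01
        r_in = 1.0 + rng.normal(0, sigma0, 1200)
        inl = r_in[:, None] * d
        d_out = rng.normal(size=(30, 3))
        d_out /= np.linalg.norm(d_out, axis=1, keepdims=True)
        out_pts = (1.0 + 10 * sigma0) * d_out
        pts = np.vstack([inl, out_pts])
        stage = PointCloudStage.from_points(pts, "P_hat")
        cleaned, rep = smooth_mesh_filter(stage, CleaningConfig(B=5))
        removed = set(rep.removed_per_stage["P_tilde"])
        assert set(range(1200, 1230)) <= removed  # all planted points gone
        kept_inliers = len([i for i in cleaned.ids if i < 1200])
        assert kept_inliers >= 0.99 * 1200

    def test_sigma_floor_protects_exact_surface(self):
        # points exactly on the smooth mesh cannot all be removed when sigma ~ 0
        gxy = np.random.default_rng(0).uniform(-1, 1, (300, 2))
        pts = np.column_stack([gxy, np.zeros(300)])
        stage = PointCloudStage.from_points(pts, "P_hat")

        def flat_normals(p):
            n = np.zeros_like(p)
            n[:, 2] = 1.0
            return n

        out, rep = smooth_mesh_filter(stage, CleaningConfig(), normals_provider=flat_normals)
        assert len(out) == len(stage)  # sigma ~ 0 but the floor keeps the cut empty


class TestFullCascade:
    def test_stage_sizes_monotone_and_labels_recovered(self, small_scene):
        cleaned, report = run_outlier_removal(small_scene.points, CleaningConfig(ransac_seed=11))
        n0 = len(small_scene.points)
        n1 = n0 - len(report.removed_per_stage["P_prime"])
        n2 = n1 - len(report.removed_per_stage["P_hat"])
        n3 = n2 - len(report.removed_per_stage["P_tilde"])
        assert n0 >= n1 >= n2 >= n3 == len(cleaned)
        ev = g.evaluate(small_scene, cleaned)
        assert ev.outlier_recall >= 0.9
        assert ev.inlier_precision >= 0.9

    def test_rerun_with_same_seed_is_bit_identical(self, small_scene):
        cfg = CleaningConfig(ransac_seed=3)
        c1, r1 = run_outlier_removal(small_scene.points, cfg)
        c2, r2 = run_outlier_removal(small_scene.points, cfg)
        assert (c1.points == c2.points).all()
        assert r1.removed_per_stage == r2.removed_per_stage

    def test_accepts_sparse_reconstruction_input(self, small_scene):
        cleaned, _ = run_outlier_removal(small_scene.recon, CleaningConfig(ransac_seed=1))
        assert set(cleaned.ids.tolist()) <= set(small_scene.recon.points)

    def test_report_partitions_removals(self, small_scene):
        cleaned, report = run_outlier_removal(small_scene.points, CleaningConfig(ransac_seed=0))
        removed = report.all_removed()
        assert len(removed) == len(set(removed))
        assert set(removed) | set(cleaned.ids.tolist()) == set(range(len(small_scene.points)))


class TestPlaneType:
    def test_normal_is_normalised_with_offset_rescaled(self):
        p = Plane(normal=[0, 0, 2.0], offset=4.0)
        np.testing.assert_allclose(p.normal, [0, 0, 1])
        assert p.offset == pytest.approx(2.0)
        # distance of origin to plane z = -2
        assert p.distance([[0, 0, 0]])[0] == pytest.approx(2.0)
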