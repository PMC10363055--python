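"""Metric oracles: DSC, surface distances, percentiles, curves, statistics."""

import numpy as np
import pytest
from scipy import stats as sps

from mandseg.io import BinaryMask, SurfaceMesh
from mandseg.metrics import (
    Curve3D,
    EvaluateConfig,
    average_surface_distance,
    bbox_iou,
    classify_significance,
    curve_distance,
    dice_coefficient,
    evaluate,
    extract_caudolateral_curve,
    hausdorff95,
    holm_sidak_correct,
    paired_t_test,
    pairwise_comparison,
    point_triangle_distances,
    surface_distances,
)
from mandseg.preprocess import BoundingBox3D

from conftest import unit_square_mesh


class TestDice:
    def test_identical_and_disjoint(self, rng):
        m = rng.random((6, 6, 6)) < 0.4
        m[0, 0, 0] = True
        assert dice_coefficient(m, m) == 100.0
        assert dice_coefficient(m, ~m) == 0.0

    def test_shifted_cube_half_overlap(self):
        a = np.zeros((6, 6, 6), dtype=bool)
        b = np.zeros((6, 6, 6), dtype=bool)
        a[1:3, 1:3, 1:3] = True
        b[1:3, 1:3, 2:4] = True  # shift by 1: TP=4, FN=4, FP=4
        assert dice_coefficient(a, b) == pytest.approx(50.0)

    def test_both_empty_undefined(self):
        e = np.zeros((4, 4, 4), dtype=bool)
        with pytest.raises(ValueError, match="undefined"):
            dice_coefficient(e, e)

    def test_symmetric_and_matches_brute_force(self, rng):
        for _ in range(30):
            a = rng.random((8, 8, 8)) < 0.5
            b = rng.random((8, 8, 8)) < 0.5
            if not (a.any() or b.any()):
                continue
            tp = int((a & b).sum())
            expected = 200.0 * tp / (a.sum() + b.sum())
            assert dice_coefficient(a, b) == pytest.approx(expected)
            assert dice_coefficient(b, a) == pytest.approx(dice_coefficient(a, b))


class TestBBoxIoU:
    def test_identical_disjoint_partial(self):
        a = BoundingBox3D((0, 0, 0), (10, 10, 10))
        assert bbox_iou(a, a) == 100.0
        b = BoundingBox3D((20, 20, 20), (25, 25, 25))
        assert bbox_iou(a, b) == 0.0
        c = BoundingBox3D((5, 5, 5), (15, 15, 15))
        assert bbox_iou(a, c) == pytest.approx(100.0 * 125 / 1875)

    def test_matches_voxelized_oracle(self, rng):
        for _ in range(30):
            lo_a = rng.integers(0, 6, 3)
            lo_b = rng.integers(0, 6, 3)
            a = BoundingBox3D(tuple(lo_a), tuple(lo_a + rng.integers(1, 6, 3)))
            b = BoundingBox3D(tuple(lo_b), tuple(lo_b + rng.integers(1, 6, 3)))
            grid_a = np.zeros((12, 12, 12), dtype=bool)
            grid_b = np.zeros((12, 12, 12), dtype=bool)
            grid_a[a.slices()] = True
            grid_b[b.slices()] = True
            inter = (grid_a & grid_b).sum()
            union = (grid_a | grid_b).sum()
            assert bbox_iou(a, b) == pytest.approx(100.0 * inter / union)


class TestSurfaceDistances:
    def test_identical_meshes_zero(self):
        mesh = unit_square_mesh()
        d = surface_distances(mesh, mesh, n_samples=500, seed=0)
        assert np.allclose(d, 0.0, atol=1e-12)
        assert average_surface_distance(mesh, mesh, 500, 0) == pytest.approx(0.0, abs=1e-12)
        assert hausdorff95(mesh, mesh, 500, 0) == pytest.approx(0.0, abs=1e-12)

    def test_parallel_squares_offset(self):
        for offset in (1.0, 2.5):
            a = unit_square_mesh(z=0.0)
            b = unit_square_mesh(z=offset)
            d = surface_distances(a, b, n_samples=2000, seed=1)
            assert np.allclose(d, offset, atol=1e-6)
            assert average_surface_distance(a, b, 2000, 1) == pytest.approx(offset, abs=1e-6)

    def test_one_directional_asymmetry(self):
        # small square inside the footprint of a big square 1 mm above:
        # small -> big is exactly 1 mm, big -> small is often larger
        small = unit_square_mesh(z=0.0)
        big = SurfaceMesh(
            np.array([[1.0, -3, -3], [1.0, 4, -3], [1.0, 4, 4], [1.0, -3, 4]]),
            np.array([[0, 1, 2], [0, 2, 3]]))
        d_ab = average_surface_distance(small, big, 3000, 2)
        d_ba = average_surface_distance(big, small, 3000, 2)
        assert d_ab == pytest.approx(1.0, abs=1e-6)
        assert d_ba > d_ab + 0.5

    def test_point_triangle_distance_analytic_cases(self):
        a = np.array([[0.0, 0, 0]])
        b = np.array([[0.0, 1, 0]])
        c = np.array([[0.0, 0, 1]])
        # above interior, beyond edge, beyond vertex
        cases = [
            (np.array([[2.0, 0.2, 0.2]]), 2.0),
            (np.array([[0.0, -1.0, 0.5]]), 1.0),
            (np.array([[0.0, 2.0, -1.0]]), np.sqrt(2.0)),
        ]
        for p, expected in cases:
            assert point_triangle_distances(p, a, b, c)[0] == pytest.approx(expected)

    def test_pruned_search_matches_brute_force(self):
        import trimesh
        from mandseg.metrics import (_min_distance_brute, _min_distance_to_mesh,
                                     sample_surface_points)

        sph = trimesh.creation.icosphere(subdivisions=4, radius=10.0)
        mesh = SurfaceMesh(np.asarray(sph.vertices), np.asarray(sph.faces))
        assert mesh.n_faces > 512  # exercises the pruned path
        rng = np.random.default_rng(3)
        pts = sample_surface_points(mesh, 200, rng) + rng.normal(0, 2.0, (200, 3))
        fast = _min_distance_to_mesh(pts, mesh)
        brute = _min_distance_brute(pts, mesh.triangles())
        assert np.allclose(fast, brute, atol=1e-12)


class TestHausdorff95:
    def test_constant_distance_set(self):
        a = unit_square_mesh(z=0.0)
        b = unit_square_mesh(z=3.0)
        assert hausdorff95(a, b, 1000, 0) == pytest.approx(3.0, abs=1e-6)

    def test_percentile_of_multiset_matches_sorted_oracle(self):
        d = np.array([0.0] * 95 + [10.0] * 5)
        # oracle: linear interpolation between order statistics
        expected = np.percentile(d, 95)
        rank = 0.95 * (len(d) - 1)
        lo, hi = int(np.floor(rank)), int(np.ceil(rank))
        s = np.sort(d)
        oracle = s[lo] + (rank - lo) * (s[hi] - s[lo])
        assert expected == pytest.approx(oracle)
        assert 0.0 <= oracle < 10.0

    def test_robust_to_single_outlier(self, small_phantom):
        from mandseg.postprocess import postprocess_prediction

        _, gt = small_phantom
        mesh = postprocess_prediction(gt)
        d = surface_distances(mesh, mesh, n_samples=5000, seed=0)
        base95 = float(np.percentile(d, 95))
        d_out = np.concatenate([d, [50.0]])  # one far outlier
        out95 = float(np.percentile(d_out, 95))
        assert out95 - base95 < 0.05 * max(base95, 1.0)
        assert d_out.max() == 50.0


class TestMonteCarloStability:
    def test_two_seeds_agree_within_two_percent(self, small_phantom):
        from mandseg.postprocess import PostprocessConfig, postprocess_prediction
        from mandseg.postprocess import erode, structuring_element

        _, gt = small_phantom
        ref = postprocess_prediction(gt, PostprocessConfig())
        pred = postprocess_prediction(
            BinaryMask(erode(gt).voxels, spacing=gt.spacing), PostprocessConfig())
        a = average_surface_distance(pred, ref, 100_000, seed=1)
        b = average_surface_distance(pred, ref, 100_000, seed=2)
        assert abs(a - b) <= 0.02 * max(a, b)


class TestCaudolateralCurve:
    @staticmethod
    def _half_torus_mesh(radius=14.0, tube=3.0, n_bins=64):
        from mandseg.postprocess import extract_surface

        n = 48
        zz, yy, xx = np.meshgrid(np.arange(n), np.arange(n), np.arange(n),
                                 indexing="ij", sparse=True)
        cy = cx = (n - 1) / 2
        z0 = 28.0
        ang = np.arctan2(xx - cx, yy - cy)
        rho = np.hypot(yy - cy, xx - cx)
        solid = ((np.square(rho - radius) + np.square(zz - z0) <= tube ** 2)
                 & (np.abs(ang) <= np.deg2rad(100)))
        return extract_surface(solid.astype(float), 0.5), (cy, cx, z0, radius, tube)

    def test_curve_near_analytic_rim(self):
        mesh, (cy, cx, z0, radius, tube) = self._half_torus_mesh()
        curve = extract_caudolateral_curve(mesh, n_bins=48)
        # caudolateral rim of the solid: the circle at 45 degrees between
        # caudal-most and outermost points of the tube section
        pts = curve.points
        rho = np.hypot(pts[:, 1] - cy, pts[:, 2] - cx)
        dist_to_rim = np.hypot(rho - radius, pts[:, 0] - z0) - tube
        assert np.all(np.abs(dist_to_rim) <= 2.0)  # within 2 voxel lengths
        assert np.all(pts[:, 0] >= z0 - 1.0)  # caudal side only

    def test_mirrored_mesh_gives_mirrored_curve(self):
        mesh, _ = self._half_torus_mesh()
        mirrored = SurfaceMesh(mesh.vertices * np.array([1.0, 1.0, -1.0]),
                               mesh.faces[:, ::-1])
        c1 = extract_caudolateral_curve(mesh, n_bins=48).points
        c2 = extract_caudolateral_curve(mirrored, n_bins=48).points
        flipped = c1 * np.array([1.0, 1.0, -1.0])
        # same point set up to ordering: compare via nearest-neighbour distance
        from scipy.spatial import cKDTree
        d, _ = cKDTree(flipped).query(c2)
        assert np.percentile(d, 90) < 1.5

    def test_small_mesh_rejected(self):
        mesh = unit_square_mesh()
        with pytest.raises(ValueError, match="degenerate"):
            extract_caudolateral_curve(mesh)


class TestCurveDistance:
    def test_identical_zero(self):
        c = Curve3D(np.array([[0.0, 0, 0], [0, 1, 0], [0, 2, 0]]))
        assert curve_distance(c, c) == 0.0

    def test_parallel_lines(self):
        a = Curve3D(np.array([[0.0, 0, 0], [0, 1, 0], [0, 2, 0]]))
        b = Curve3D(np.array([[2.0, 0, 0], [2, 1, 0], [2, 2, 0]]))
        assert curve_distance(a, b) == pytest.approx(2.0)

    def test_translation_along_itself_zero_within_overlap(self):
        a = Curve3D(np.array([[0.0, 0, 1], [0, 0, 2], [0, 0, 3]]))
        b = Curve3D(np.array([[0.0, 0, 0], [0, 0, 2], [0, 0, 4]]))
        assert curve_distance(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_point_segment_oracle(self, rng):
        for _ in range(10):
            a = Curve3D(np.cumsum(rng.uniform(0.1, 1, (5, 3)), axis=0))
            b = Curve3D(np.cumsum(rng.uniform(0.1, 1, (6, 3)), axis=0))
            got = curve_distance(a, b)
            mins = []
            for p in a.points:
                best = np.inf
                for s, e in zip(b.points[:-1], b.points[1:]):
                    seg = e - s
                    t = np.clip(np.dot(p - s, seg) / np.dot(seg, seg), 0, 1)
                    best = min(best, np.linalg.norm(p - (s + t * seg)))
                mins.append(best)
            assert got == pytest.approx(np.mean(mins), abs=1e-12)

    def test_degenerate_curve_rejected(self):
        with pytest.raises(ValueError):
            Curve3D(np.array([[0.0, 0, 0]]))


class TestEvaluate:
    def test_perfect_prediction(self, small_phantom):
        _, gt = small_phantom
        cfg = EvaluateConfig(n_surface_samples=3000)
        rep = evaluate(gt, gt, cfg)
        assert rep.dsc == 100.0
        assert rep.asd == pytest.approx(0.0, abs=1e-9)
        assert rep.hd95 == pytest.approx(0.0, abs=1e-9)
        assert rep.ccd == pytest.approx(0.0, abs=1e-9)
        assert rep.bb_iou == 100.0
        assert rep.flags == []

    def test_empty_prediction_flagged_not_crashed(self, small_phantom):
        _, gt = small_phantom
        pred = BinaryMask(np.zeros(gt.shape, dtype=bool),
                          spacing=gt.spacing, origin=gt.origin)
        rep = evaluate(pred, gt, EvaluateConfig(n_surface_samples=1000))
        assert rep.dsc == 0.0
        assert "empty_prediction" in rep.flags or "no_surface" in rep.flags
        assert np.isnan(rep.asd)

    def test_fields_match_individual_ops(self, small_phantom):
        from mandseg.postprocess import erode, postprocess_prediction
        from mandseg.preprocess import compute_bounding_box

        _, gt = small_phantom
        pred = BinaryMask(erode(gt).voxels, spacing=gt.spacing, origin=gt.origin)
        cfg = EvaluateConfig(n_surface_samples=4000, seed=5)
        rep = evaluate(pred, gt, cfg)
        assert rep.dsc == pytest.approx(dice_coefficient(pred, gt))
        assert rep.bb_iou == pytest.approx(
            bbox_iou(compute_bounding_box(pred), compute_bounding_box(gt)))
        pm = postprocess_prediction(pred, cfg.postprocess)
        gm = postprocess_prediction(gt, cfg.postprocess)
        assert rep.asd == pytest.approx(
            average_surface_distance(pm, gm, 4000, 5), rel=1e-9)


class TestVoxelOracleAgreement:
    def test_mesh_asd_close_to_voxel_surface_oracle(self, rng):
        """Mesh ASD of marching-cubes surfaces vs. exhaustive distance between
        voxel surface point sets, within 1.5 voxel lengths (<= 16^3 grids)."""
        from scipy import ndimage
        from mandseg.postprocess import extract_surface

        for _ in range(5):
            a = np.zeros((16, 16, 16), dtype=bool)
            c = rng.integers(5, 11, 3)
            r = rng.integers(3, 5)
            zz, yy, xx = np.ogrid[:16, :16, :16]
            a |= ((zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2) <= r ** 2
            shift = rng.integers(-2, 3, 3)
            b = np.roll(a, shift, axis=(0, 1, 2))
            surf_a = a & ~ndimage.binary_erosion(a)
            surf_b = b & ~ndimage.binary_erosion(b)
            pa, pb = np.argwhere(surf_a).astype(float), np.argwhere(surf_b).astype(float)
            voxel_asd = np.mean([np.min(np.linalg.norm(pb - p, axis=1)) for p in pa])
            mesh_a = extract_surface(a.astype(float), 0.5)
            mesh_b = extract_surface(b.astype(float), 0.5)
            mesh_asd = average_surface_distance(mesh_a, mesh_b, 5000, 0)
            assert abs(mesh_asd - voxel_asd) <= 1.5


class TestStatistics:
    def test_paired_t_known_fixture(self):
        b = np.array([1.0, 2.0, 3.0, 4.0])
        a = np.zeros(4)
        d = b - a
        t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        expected = 2 * sps.t.sf(abs(t), df=3)
        assert paired_t_test(a, b) == pytest.approx(expected, abs=1e-6)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            paired_t_test([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_antisymmetric_differences_near_one(self):
        a = np.array([1.0, -1.0, 2.0, -2.0, 0.5, -0.5])
        b = np.zeros(6)
        assert paired_t_test(a, b) > 0.9

    def test_holm_sidak_closed_form(self):
        # m=2, p=(0.01, 0.04) -> (1-0.99^2, 0.04) with monotonicity
        out = holm_sidak_correct([0.01, 0.04])
        assert out[0] == pytest.approx(1 - 0.99 ** 2, abs=1e-12)
        assert out[1] == pytest.approx(0.04, abs=1e-12)

    def test_holm_sidak_edge_cases(self):
        assert holm_sidak_correct([0.2])[0] == pytest.approx(0.2)
        assert np.allclose(holm_sidak_correct([0.0, 0.0, 0.0]), 0.0)

    def test_holm_sidak_matches_formula_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 8))
            p = rng.random(m)
            got = holm_sidak_correct(p)
            order = np.argsort(p)
            expected_sorted = []
            running = 0.0
            for i, idx in enumerate(order):  # i is 0-based; exponent m-i
                val = 1 - (1 - p[idx]) ** (m - i)
                running = max(running, min(val, 1.0))
                expected_sorted.append(running)
            expected = np.empty(m)
            expected[order] = expected_sorted
            assert np.allclose(got, expected, atol=1e-12)
            assert np.all(got >= p - 1e-12)  # correction never lowers p

    @pytest.mark.parametrize("p,expected", [
        (0.5, "not significant"), (0.05, "not significant"),
        (0.03, "significant"), (0.01, "significant"),
        (0.005, "very significant"), (0.001, "very significant"),
        (0.0005, "highly significant"), (0.0, "highly significant"),
    ])
    def test_significance_classes_printed_boundaries(self, p, expected):
        assert classify_significance(p) == expected

    def test_pairwise_comparison_structure(self, rng):
        vals = {"m1": rng.normal(0, 1, 10), "m2": rng.normal(1, 1, 10),
                "m3": rng.normal(2, 1, 10)}
        recs = pairwise_comparison(vals, metric="asd")
        assert len(recs) == 3
        for r in recs:
            assert r["p_corrected"] >= r["p_raw"] - 1e-12
            assert r["class"] in ("not significant", "significant",
                                  "very significant", "highly significant")
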