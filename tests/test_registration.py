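"""Rigid registration: Kabsch landmark fit, ICP, distances, cropping, colormaps."""

import numpy as np
import pytest
import trimesh
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from craniosort.registration import (
    DistanceSummary,
    LandmarkSet,
    RigidTransform,
    RoiMesh,
    crop_roi,
    distance_summary,
    export_colormap,
    icp_refine,
    kabsch,
    landmark_align,
    read_colormap,
)
from craniosort.simulate import SurfaceGeneratorParams, simulate_surface_pair

from .conftest import brute_force_surface_distance, planar_grid, random_rotation

COARSE = SurfaceGeneratorParams(sigma_c=0.0, n_rings=4, n_theta=12)


def random_landmarks(rng, spread=20.0) -> LandmarkSet:
    labels = ("anterior", "posterior", "lateral", "medial")
    return LandmarkSet({
        facet: {lab: (spread * rng.standard_normal(3)).tolist() for lab in labels}
        for facet in ("left", "right")
    })


class TestRigidTransform:
    def test_identity_and_inverse_roundtrip(self, rng):
        R = random_rotation(rng)
        t = rng.standard_normal(3)
        T = RigidTransform(R, t)
        pts = rng.standard_normal((10, 3))
        np.testing.assert_allclose(T.inverse().apply(T.apply(pts)), pts, atol=1e-12)
        np.testing.assert_allclose(RigidTransform.identity().apply(pts), pts)

    def test_reflection_rejected(self):
        R = np.diag([1.0, 1.0, -1.0])
        with pytest.raises(ValueError, match="proper"):
            RigidTransform(R, np.zeros(3))

    def test_compose_order(self, rng):
        A = RigidTransform(random_rotation(rng), rng.standard_normal(3))
        B = RigidTransform(random_rotation(rng), rng.standard_normal(3))
        pts = rng.standard_normal((5, 3))
        np.testing.assert_allclose(A.compose(B).apply(pts), A.apply(B.apply(pts)),
                                   atol=1e-9)


class TestLandmarkAlign:
    def test_identity_when_destination_equals_source(self, rng):
        lm = random_landmarks(rng)
        T = landmark_align(lm, lm)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, np.zeros(3), atol=1e-9)

    def test_pure_translation_recovered_exactly(self, rng):
        lm = random_landmarks(rng)
        shift = np.array([1.0, 2.0, 3.0])
        dst = LandmarkSet({f: {l: (np.asarray(p) + shift).tolist()
                               for l, p in pts.items()}
                           for f, pts in lm.facets.items()})
        T = landmark_align(lm, dst)
        np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-9)
        np.testing.assert_allclose(T.translation, shift, atol=1e-9)

    def test_known_rigid_transform_recovered(self, rng):
        for _ in range(20):
            lm = random_landmarks(rng)
            R0 = random_rotation(rng)
            t0 = 10 * rng.standard_normal(3)
            truth = RigidTransform(R0, t0)
            dst = lm.transformed(truth)
            T = landmark_align(lm, dst)
            np.testing.assert_allclose(T.rotation, R0, atol=1e-6)
            np.testing.assert_allclose(T.translation, t0, atol=1e-6)

    def test_matches_brute_force_optimizer_residual(self, rng):
        """Closed-form fit attains the same least-squares residual as a
        general-purpose 6-dof numerical minimizer on 50 random noisy instances."""

        def residual(src, dst, T):
            return float(np.sum((T.apply(src) - dst) ** 2))

        for i in range(50):
            src = 15 * rng.standard_normal((8, 3))
            R0 = random_rotation(rng, max_angle=0.5)
            dst = src @ R0.T + 5 * rng.standard_normal(3)
            dst = dst + 0.2 * rng.standard_normal(dst.shape)  # noise: nonzero residual

            ours = residual(src, dst, kabsch(src, dst))

            def cost(x):
                R = Rotation.from_rotvec(x[:3]).as_matrix()
                return float(np.sum((src @ R.T + x[3:] - dst) ** 2))

            best = min(
                minimize(cost, x0, method="BFGS").fun
                for x0 in (np.zeros(6),
                           np.concatenate([Rotation.from_matrix(R0).as_rotvec(),
                                           np.zeros(3)]))
            )
            assert ours <= best + 1e-6, f"instance {i}: closed form worse than optimizer"
            assert abs(ours - best) < 1e-6, f"instance {i}: residuals disagree"

    def test_agrees_with_trimesh_procrustes(self, rng):
        src = 10 * rng.standard_normal((8, 3))
        dst = src @ random_rotation(rng).T + rng.standard_normal(3)
        dst += 0.1 * rng.standard_normal(dst.shape)
        T = kabsch(src, dst)
        _, transformed, cost = trimesh.registration.procrustes(
            src, dst, reflection=False, scale=False)
        ours = float(np.mean(np.sum((T.apply(src) - dst) ** 2, axis=1)))
        assert ours == pytest.approx(cost, rel=1e-9, abs=1e-12)

    def test_collinear_points_rejected(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(pts, pts + 1.0)

    def test_mismatched_labels_rejected(self, rng):
        lm = random_landmarks(rng)
        one_facet = LandmarkSet({"left": lm.facets["left"]})
        with pytest.raises(ValueError, match="differ"):
            landmark_align(lm, one_facet)


class TestDistanceSummary:
    def test_identical_surfaces_are_zero(self, grid_roi):
        s = distance_summary(grid_roi, grid_roi, RigidTransform.identity())
        assert s.rms == s.min == s.max == s.sd == 0.0

    def test_parallel_planes_at_offset(self):
        a = RoiMesh(planar_grid(z=0.0), provenance="test")
        b = RoiMesh(planar_grid(z=0.5), provenance="test")
        s = distance_summary(a, b, RigidTransform.identity())
        assert s.rms == pytest.approx(0.5, abs=1e-12)
        assert s.min == pytest.approx(0.5, abs=1e-12)
        assert s.max == pytest.approx(0.5, abs=1e-12)
        assert s.sd == pytest.approx(0.0, abs=1e-12)

    def test_matches_exhaustive_nearest_triangle_oracle(self, rng):
        """Vectorised surface distances equal a scalar per-triangle scan."""
        dst = trimesh.creation.icosphere(subdivisions=2, radius=8.0)  # 320 faces
        assert len(dst.faces) <= 500
        pts = rng.uniform(-12, 12, size=(40, 3))
        src = RoiMesh(trimesh.Trimesh(vertices=pts, faces=[[0, 1, 2]],
                                      process=False), provenance="test")
        got = distance_summary(src, RoiMesh(dst, provenance="test"),
                               RigidTransform.identity())
        expected = brute_force_surface_distance(pts, dst)
        np.testing.assert_allclose(got.per_vertex, expected, atol=1e-9)

    def test_summary_statistics_consistent(self, rng):
        d = np.abs(rng.standard_normal(100))
        s = DistanceSummary.from_distances(d)
        assert s.rms == pytest.approx(np.sqrt(np.mean(d**2)))
        assert s.sd == pytest.approx(np.std(d))
        assert s.min <= s.max
        # rms can exceed the mean; only min <= max is an invariant

    def test_vertex_mode(self):
        a = RoiMesh(planar_grid(z=0.0), provenance="test")
        b = RoiMesh(planar_grid(z=0.25), provenance="test")
        s = distance_summary(a, b, RigidTransform.identity(), mode="vertex")
        assert s.rms == pytest.approx(0.25, abs=1e-12)


class TestICP:
    def test_exact_copy_registers_to_zero(self):
        oc, c1, *_ = simulate_surface_pair(COARSE, individual_seed=1, matched=True)
        # undo the pose by landmark alignment is not needed: src == dst geometry
        sup = icp_refine(oc, oc, RigidTransform.identity())
        assert sup.summary.rms < 1e-9
        assert sup.converged

    def test_small_displacement_recovered(self, rng):
        oc, _, oc_lm, _ = simulate_surface_pair(COARSE, individual_seed=2,
                                                matched=True)
        R0 = random_rotation(rng, max_angle=0.1)
        t0 = 0.5 * rng.standard_normal(3)
        displacement = RigidTransform(R0, t0)
        moved = oc.transformed(displacement)
        init = landmark_align(oc_lm.transformed(displacement), oc_lm)
        sup = icp_refine(moved, oc, init, convergence_tolerance=1e-9)
        assert sup.summary.rms < 1e-6
        # recovered transform inverts the displacement
        recovered = sup.transform.compose(RigidTransform(R0, t0))
        np.testing.assert_allclose(recovered.rotation, np.eye(3), atol=1e-4)
        np.testing.assert_allclose(recovered.translation, np.zeros(3), atol=1e-4)

    def test_landmark_then_icp_recovers_large_pose(self, rng):
        oc, c1, oc_lm, c1_lm = simulate_surface_pair(COARSE, individual_seed=3,
                                                     matched=True)
        init = landmark_align(oc_lm, c1_lm)
        sup = icp_refine(oc, c1, init, convergence_tolerance=1e-9)
        assert sup.summary.rms < 1e-6

    def test_rms_monotone_nonincreasing(self, rng):
        for seed in (4, 5):
            oc, c1, oc_lm, c1_lm = simulate_surface_pair(
                SurfaceGeneratorParams(sigma_c=0.3, n_rings=4, n_theta=12),
                individual_seed=seed, matched=(seed == 4))
            sup = icp_refine(oc, c1, landmark_align(oc_lm, c1_lm),
                             max_iterations=40)
            trace = np.asarray(sup.rms_trace)
            assert (np.diff(trace) <= 1e-12).all(), "RMS increased during ICP"

    def test_registration_invariant_under_common_rigid_motion(self, rng):
        oc, c1, oc_lm, c1_lm = simulate_surface_pair(
            SurfaceGeneratorParams(sigma_c=0.2, n_rings=4, n_theta=12),
            individual_seed=6, matched=True)
        base = icp_refine(oc, c1, landmark_align(oc_lm, c1_lm), max_iterations=30)
        W = RigidTransform(random_rotation(rng), 20 * rng.standard_normal(3))
        sup2 = icp_refine(oc.transformed(W), c1.transformed(W),
                          landmark_align(oc_lm.transformed(W), c1_lm.transformed(W)),
                          max_iterations=30)
        assert sup2.summary.rms == pytest.approx(base.summary.rms, abs=1e-6)

    def test_nonconvergence_is_flagged_not_raised(self):
        oc, c1, oc_lm, c1_lm = simulate_surface_pair(
            SurfaceGeneratorParams(sigma_c=0.4, n_rings=4, n_theta=12),
            individual_seed=7, matched=False)
        sup = icp_refine(oc, c1, landmark_align(oc_lm, c1_lm),
                         max_iterations=2, convergence_tolerance=1e-12)
        assert sup.converged is False
        assert sup.n_iterations == 2

    def test_surface_noise_rms_tracks_noise_amplitude(self):
        """With sigma = 0.1 mm congruency noise the registered RMS stays near 0.1."""
        rmss = []
        for seed in range(10):
            oc, c1, oc_lm, c1_lm = simulate_surface_pair(
                SurfaceGeneratorParams(sigma_c=0.1, n_rings=4, n_theta=12),
                individual_seed=100 + seed, matched=True)
            sup = icp_refine(oc, c1, landmark_align(oc_lm, c1_lm), max_iterations=30)
            rmss.append(sup.summary.rms)
        mean_rms = float(np.mean(rmss))
        assert abs(mean_rms - 0.1) < 0.03 * 10  # within 30% of the noise amplitude
        assert 0.07 < mean_rms < 0.13


class TestCropRoi:
    def test_contour_enclosing_whole_mesh_keeps_everything(self):
        mesh = planar_grid(nx=5, ny=5)
        theta = np.linspace(0, 2 * np.pi, 40)
        contour = np.column_stack([10 * np.cos(theta) + 2, 10 * np.sin(theta) + 2,
                                   np.zeros_like(theta)])
        contour[-1] = contour[0]
        roi = crop_roi(mesh, contour)
        assert len(roi.vertices) == len(mesh.vertices)
        assert len(roi.faces) == len(mesh.faces)

    def test_half_plane_contour_selects_half_grid(self):
        mesh = planar_grid(nx=6, ny=6)  # x, y in 0..5
        # rectangle around x in [-0.5, 2.5]: keeps x = 0,1,2 columns = half
        rect = np.array([[-0.5, -0.5, 0], [2.5, -0.5, 0], [2.5, 5.5, 0],
                         [-0.5, 5.5, 0], [-0.5, -0.5, 0]], dtype=float)
        roi = crop_roi(mesh, rect)
        assert len(roi.vertices) == len(mesh.vertices) // 2

    def test_agrees_with_independent_point_in_polygon_oracle(self, rng):
        import shapely

        mesh = planar_grid(nx=8, ny=8)
        theta = np.linspace(0, 2 * np.pi, 25)
        radii = rng.uniform(2.0, 4.0)
        contour = np.column_stack([
            3.5 + radii * np.cos(theta), 3.5 + radii * np.sin(theta),
            np.zeros_like(theta)])
        contour[-1] = contour[0]
        roi = crop_roi(mesh, contour)
        poly = shapely.Polygon(contour[:-1, :2])
        expected = sum(poly.contains(shapely.Point(p[:2])) for p in mesh.vertices)
        assert len(roi.vertices) == expected

    def test_degenerate_contours_rejected(self):
        mesh = planar_grid()
        open_contour = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [9, 9, 0]], float)
        with pytest.raises(ValueError, match="closed"):
            crop_roi(mesh, open_contour)
        line = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [0, 0, 0]], float)
        with pytest.raises(ValueError, match="collinear"):
            crop_roi(mesh, line)
        far = np.array([[50, 50, 0], [51, 50, 0], [51, 51, 0], [50, 51, 0],
                        [50, 50, 0]], float)
        with pytest.raises(ValueError, match="no vertices"):
            crop_roi(mesh, far)


class TestColormap:
    def _superimposition(self, distances, mesh):
        from craniosort.registration import Superimposition

        return Superimposition("a", "b", RigidTransform.identity(),
                               DistanceSummary.from_distances(distances))

    def test_round_trip_recovers_scalars(self, tmp_path, grid_roi):
        d = np.linspace(0.0, 1.0, len(grid_roi.vertices))
        sup = self._superimposition(d, grid_roi)
        path = tmp_path / "map.ply"
        export_colormap(sup, grid_roi, path, scale=(0.0, 1.0))
        _, scalars = read_colormap(path)
        np.testing.assert_allclose(scalars, d, atol=1e-6)

    def test_values_clipped_to_scale_and_monotone(self, tmp_path, grid_roi):
        d = np.linspace(0.0, 2.0, len(grid_roi.vertices))
        sup = self._superimposition(d, grid_roi)
        path = tmp_path / "map.ply"
        export_colormap(sup, grid_roi, path, scale=(0.0, 1.0))
        _, scalars = read_colormap(path)
        assert scalars.max() <= 1.0 + 1e-6
        assert (np.diff(scalars) >= -1e-6).all()  # monotone in the distances

    def test_invalid_scale_rejected(self, tmp_path, grid_roi):
        sup = self._superimposition(np.zeros(len(grid_roi.vertices)), grid_roi)
        with pytest.raises(ValueError, match="scale"):
            export_colormap(sup, grid_roi, tmp_path / "x.ply", scale=(1.0, 1.0))
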