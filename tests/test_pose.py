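import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from capmorph.exceptions import (
    AmbiguousNormalError,
    DegenerateClusterError,
    LegAmbiguityError,
    MinModulesError,
    TooFewClustersError,
)
from capmorph.fiducials import FiducialCluster
from capmorph.mesh_io import ColoredMesh
from capmorph.phantom import PhantomSpec, make_cap_scan, make_head, _triangle_patch
from capmorph.pose import (
    ModuleGeometry,
    ModulePose,
    align_module_model,
    build_sparse_sample,
    estimate_head_center,
    inward_normal,
    principal_axes,
    project_feet,
)


def _planar_grid():
    xs, ys = np.meshgrid(np.arange(5.0), np.arange(5.0))
    return np.column_stack([xs.ravel(), ys.ravel(), np.zeros(25)])


def _cluster_from(points):
    points = np.asarray(points, float)
    return FiducialCluster(np.arange(len(points)), points, points.mean(axis=0))


class TestPrincipalAxes:
    def test_planar_grid_normal_is_z(self):
        _, axes = principal_axes(_planar_grid())
        assert abs(abs(axes[2, 2]) - 1.0) < 1e-9
        assert np.abs(axes[2, :2]).max() < 1e-9

    def test_equivariance_under_rotation(self):
        # anisotropic grid so all three principal directions are distinct
        xs, ys = np.meshgrid(np.arange(7.0), np.arange(4.0))
        pts = np.column_stack([xs.ravel(), ys.ravel(), 0.1 * xs.ravel()])
        q = Rotation.from_euler("xyz", [30, 45, -20], degrees=True).as_matrix()
        _, axes = principal_axes(pts)
        _, axes_r = principal_axes(pts @ q.T)
        for a, ar in zip(axes, axes_r):
            assert min(np.linalg.norm(ar - q @ a), np.linalg.norm(ar + q @ a)) < 1e-9

    def test_collinear_points_degenerate(self):
        pts = np.outer(np.arange(3.0), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateClusterError):
            principal_axes(pts)


class TestHeadCenter:
    def test_mean_of_sphere_samples_near_origin(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=(40, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        d[:, 2] = np.abs(d[:, 2])  # upper hemisphere, well distributed
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        center = estimate_head_center(100.0 * d)
        assert np.linalg.norm(center) < 60.0  # biased upward but near origin
        assert np.linalg.norm(center[:2]) < 30.0

    def test_repeated_centroid_returns_value(self):
        assert np.allclose(
            estimate_head_center([[1, 2, 3]] * 3), [1, 2, 3]
        )

    def test_two_clusters_rejected(self):
        with pytest.raises(TooFewClustersError):
            estimate_head_center([[0, 0, 0], [1, 1, 1]])


class TestInwardNormal:
    def test_sign_flips_with_head_center(self):
        _, axes = principal_axes(_planar_grid() + [0, 0, 100.0])
        centroid = np.array([2.0, 2.0, 100.0])
        n_down = inward_normal(axes, centroid, np.zeros(3))
        n_up = inward_normal(axes, centroid, np.array([0, 0, 200.0]))
        assert np.allclose(n_down, [0, 0, -1], atol=1e-9)
        assert np.allclose(n_up, [0, 0, 1], atol=1e-9)

    def test_ambiguous_when_center_in_plane(self):
        _, axes = principal_axes(_planar_grid())
        with pytest.raises(AmbiguousNormalError):
            inward_normal(axes, np.array([2.0, 2.0, 0.0]), np.array([50.0, 0, 0]))


class TestAlignModuleModel:
    def test_identity_pose_recovered(self, geometry):
        pts, _ = _triangle_patch(geometry)
        pose = align_module_model(
            _cluster_from(pts), geometry, normal=np.array([0, 0, -1.0])
        )
        assert np.allclose(pose.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(pose.translation, 0, atol=1e-9)
        assert pose.residual_rms < 1e-9

    def test_known_pose_recovered(self, geometry):
        pts, _ = _triangle_patch(geometry)
        rot = Rotation.from_euler("xyz", [25, -40, 110], degrees=True).as_matrix()
        t = np.array([30.0, -20.0, 80.0])
        moved = pts @ rot.T + t
        normal = rot @ np.array([0, 0, -1.0])  # inward = local -z
        pose = align_module_model(_cluster_from(moved), geometry, normal)
        angle_err = np.degrees(
            np.arccos(np.clip((np.trace(pose.rotation.T @ rot) - 1) / 2, -1, 1))
        )
        assert angle_err < 0.5
        assert np.linalg.norm(pose.translation - t) < 0.2

    def test_equilateral_triangle_ambiguous(self, geometry):
        side = 20.0
        tri = np.array(
            [[0, 0, 0], [side, 0, 0], [side / 2, side * np.sqrt(3) / 2, 0]]
        )
        pts = np.concatenate([tri, tri.mean(axis=0, keepdims=True)])
        with pytest.raises(LegAmbiguityError):
            align_module_model(
                _cluster_from(pts), geometry, normal=np.array([0, 0, -1.0])
            )


class TestProjectFeet:
    def test_identity_returns_offsets(self, geometry):
        pose = ModulePose(np.eye(3), np.zeros(3))
        assert np.allclose(project_feet(pose, geometry), geometry.foot_offsets)

    def test_pure_translation(self, geometry):
        pose = ModulePose(np.eye(3), [0, 0, 50.0])
        assert np.allclose(
            project_feet(pose, geometry), geometry.foot_offsets + [0, 0, 50.0]
        )

    def test_feet_distance_to_fiducial_plane_equals_height(self, geometry):
        rot = Rotation.from_euler("zyx", [15, 30, -10], degrees=True).as_matrix()
        pose = ModulePose(rot, [5.0, 6.0, 7.0])
        feet = project_feet(pose, geometry)
        plane_normal = rot @ np.array([0, 0, 1.0])
        plane_point = pose.translation
        d = np.abs((feet - plane_point) @ plane_normal)
        assert np.allclose(d, geometry.height, atol=1e-9)


class TestBuildSparseSample:
    def test_default_phantom_gives_68_points(self, default_scan):
        sample = build_sparse_sample(default_scan, seed=1)
        assert len(sample.points) == 68
        assert sample.n_modules == 17

    def test_noise_free_foot_recovery(self, clean_scan, clean_truth):
        sample = build_sparse_sample(clean_scan, seed=1)
        truth_feet = clean_truth.foot_points.reshape(-1, 4, 3)
        errs = []
        for module in sample.points.reshape(-1, 4, 3):
            j = np.argmin(
                np.linalg.norm(
                    truth_feet.mean(axis=1) - module.mean(axis=0), axis=1
                )
            )
            for foot in module:
                errs.append(np.linalg.norm(truth_feet[j] - foot, axis=1).min())
        assert np.mean(errs) <= 0.5

    def test_noisy_foot_recovery(self, default_scan, default_truth):
        sample = build_sparse_sample(default_scan, seed=1)
        truth_feet = default_truth.foot_points.reshape(-1, 4, 3)
        errs = []
        for module in sample.points.reshape(-1, 4, 3):
            j = np.argmin(
                np.linalg.norm(
                    truth_feet.mean(axis=1) - module.mean(axis=0), axis=1
                )
            )
            for foot in module:
                errs.append(np.linalg.norm(truth_feet[j] - foot, axis=1).min())
        assert np.mean(errs) <= 1.5  # vertex noise regime

    def test_occluded_modules_reduce_sample(self, clean_truth, geometry):
        scan = make_cap_scan(
            clean_truth, clean_truth.spec, geometry, occluded=(3, 11)
        )
        sample = build_sparse_sample(scan, k=15, seed=1)
        assert len(sample.points) == 60

    def test_failed_modules_warn_and_skip(self, clean_truth, geometry, caplog):
        """Asking for 17 clusters when only 15 modules are visible splits
        some fiducials; the broken clusters fail the pose fit and are
        skipped with a warning."""
        scan = make_cap_scan(
            clean_truth, clean_truth.spec, geometry, occluded=(3, 11)
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="capmorph.pose"):
            sample = build_sparse_sample(scan, k=17, seed=1)
        n_warn = sum(
            1 for r in caplog.records if "skipped" in r.getMessage()
        )
        assert n_warn >= 2
        assert len(sample.points) == 4 * (17 - n_warn)

    def test_no_red_vertices_raises(self, sphere_mesh):
        with pytest.raises(MinModulesError):
            build_sparse_sample(sphere_mesh, seed=0)

    def test_equivariance_under_rigid_motion(self, clean_truth, geometry):
        scan = make_cap_scan(clean_truth, clean_truth.spec, geometry)
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        t = np.array([5.0, -8.0, 12.0])
        moved = ColoredMesh(scan.vertices @ rot.T + t, scan.faces, scan.colors)
        a = build_sparse_sample(scan, seed=1)
        b = build_sparse_sample(moved, seed=1)
        # same module ordering (same k-means seed on isometric distances)
        assert np.abs(a.points @ rot.T + t - b.points).max() < 1e-6
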