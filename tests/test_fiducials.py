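import colorsys

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from capmorph.exceptions import InfeasibleClusteringError, TooFewPointsError
from capmorph.fiducials import (
    ColorFilterSpec,
    FiducialCluster,
    cluster_fiducials,
    filter_fiducial_vertices,
    rgb_to_hsv,
)
from capmorph.mesh_io import ColoredMesh


def _mesh_with_colors(colors):
    colors = np.asarray(colors, float)
    n = len(colors)
    return ColoredMesh(np.random.default_rng(0).normal(size=(n, 3)),
                       np.zeros((0, 3)), colors)


class TestColorFilter:
    @pytest.mark.parametrize(
        "color,passes",
        [
            ((1.0, 0.0, 0.0), True),    # pure red
            ((0.5, 0.5, 0.5), False),   # achromatic, saturation 0
            ((0.8, 0.1, 0.1), True),    # dark red
            ((0.45, 0.0, 0.0), False),  # red channel below threshold
            ((1.0, 0.0, 0.15), True),   # hue wraps below 1.0 (magenta-ish red)
            ((0.0, 1.0, 0.0), False),   # green
        ],
    )
    def test_threshold_cases(self, color, passes):
        mesh = _mesh_with_colors([color])
        got = filter_fiducial_vertices(mesh)
        assert (0 in got) == passes

    def test_matches_colorsys_oracle_on_random_colors(self):
        rng = np.random.default_rng(7)
        colors = rng.uniform(size=(500, 3))
        spec = ColorFilterSpec()
        got = set(filter_fiducial_vertices(_mesh_with_colors(colors), spec))
        expected = set()
        for i, (r, g, b) in enumerate(colors):
            h, s, v = colorsys.rgb_to_hsv(r, g, b)
            if (
                r >= spec.red_min
                and s >= spec.sat_min
                and (h <= spec.hue_max or h >= 1 - spec.hue_max)
            ):
                expected.add(i)
        assert got == expected

    def test_hsv_agrees_with_colorsys(self):
        rng = np.random.default_rng(3)
        colors = rng.uniform(size=(200, 3))
        hsv = rgb_to_hsv(colors)
        for (r, g, b), (h, s, v) in zip(colors, hsv):
            eh, es, ev = colorsys.rgb_to_hsv(r, g, b)
            assert abs(h - eh) < 1e-12 or abs(abs(h - eh) - 1.0) < 1e-12
            assert abs(s - es) < 1e-12 and abs(v - ev) < 1e-12

    def test_filter_is_monotone_in_thresholds(self):
        rng = np.random.default_rng(11)
        mesh = _mesh_with_colors(rng.uniform(size=(400, 3)))
        base = set(filter_fiducial_vertices(mesh, ColorFilterSpec(0.5, 0.7, 0.1)))
        tighter = [
            ColorFilterSpec(0.6, 0.7, 0.1),
            ColorFilterSpec(0.5, 0.8, 0.1),
            ColorFilterSpec(0.5, 0.7, 0.05),
        ]
        for spec in tighter:
            assert set(filter_fiducial_vertices(mesh, spec)) <= base

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            ColorFilterSpec(red_min=1.5)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(
        st.tuples(
            st.floats(0, 1, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
            st.floats(0, 1, allow_nan=False),
        )
    )
    def test_hsv_conversion_property(self, rgb):
        """For any RGB triple the conversion agrees with the standard
        hexcone model (colorsys), modulo the 1.0 == 0.0 hue wrap."""
        h, s, v = rgb_to_hsv(np.array([rgb]))[0]
        eh, es, ev = colorsys.rgb_to_hsv(*rgb)
        assert 0.0 <= h < 1.0 + 1e-12 and 0.0 <= s <= 1.0
        assert min(abs(h - eh), abs(abs(h - eh) - 1.0)) < 1e-9
        assert abs(s - es) < 1e-9 and abs(v - ev) < 1e-9

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
        st.floats(0, 1, allow_nan=False),
    )
    def test_monotonicity_property(self, red_min, sat_min, hue_max):
        """Any tightening of the thresholds can only shrink the result."""
        rng = np.random.default_rng(99)
        mesh = _mesh_with_colors(rng.uniform(size=(150, 3)))
        loose = set(
            filter_fiducial_vertices(
                mesh, ColorFilterSpec(red_min * 0.5, sat_min * 0.5,
                                      hue_max + (1 - hue_max) * 0.5)
            )
        )
        tight = set(
            filter_fiducial_vertices(
                mesh, ColorFilterSpec(red_min, sat_min, hue_max)
            )
        )
        assert tight <= loose


def _blobs(rng, k=17, sigma=2.0, n_per=30, min_sep=80.0):
    """k isotropic blobs with pairwise centroid separations >= min_sep."""
    centers = []
    while len(centers) < k:
        c = rng.uniform(-200, 200, 3)
        if all(np.linalg.norm(c - o) >= min_sep for o in centers):
            centers.append(c)
    centers = np.asarray(centers)
    pts = np.concatenate(
        [c + rng.normal(0, sigma, (n_per, 3)) for c in centers]
    )
    labels = np.repeat(np.arange(k), n_per)
    return pts, labels, centers


class TestClustering:
    def test_recovers_generating_assignment(self):
        rng = np.random.default_rng(5)
        pts, labels, centers = _blobs(rng)
        clusters = cluster_fiducials(pts, k=17, seed=0)
        assert len(clusters) == 17
        # oracle: membership must match nearest-generating-centroid
        for c in clusters:
            gen = np.argmin(
                np.linalg.norm(centers - c.centroid, axis=1)
            )
            assert set(c.member_indices) == set(np.flatnonzero(labels == gen))

    def test_single_cluster_contains_all_points(self):
        rng = np.random.default_rng(2)
        pts = rng.normal(0, 5, (40, 3))  # diameter well under 50 mm
        (cluster,) = cluster_fiducials(pts, k=1, seed=0)
        assert cluster.size == 40
        assert np.allclose(cluster.centroid, pts.mean(axis=0))

    def test_overstretched_blob_is_infeasible(self):
        rng = np.random.default_rng(9)
        pts = np.column_stack(
            [rng.uniform(0, 60.1, 200), rng.normal(0, 1, 200), rng.normal(0, 1, 200)]
        )
        pts[0, 0], pts[1, 0] = 0.0, 60.0  # force 60 mm extent
        with pytest.raises(InfeasibleClusteringError):
            cluster_fiducials(pts, k=1, diameter_bound=50.0, seed=0, restarts=3)

    def test_too_few_points(self):
        with pytest.raises(TooFewPointsError):
            cluster_fiducials(np.zeros((5, 3)), k=17)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(13)
        pts, _, _ = _blobs(rng, k=6)
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [20, -35, 60], degrees=True).as_matrix()
        moved = pts @ rot.T + np.array([12.0, -40.0, 7.0])
        a = cluster_fiducials(pts, k=6, seed=4)
        b = cluster_fiducials(moved, k=6, seed=4)
        parts_a = {frozenset(c.member_indices) for c in a}
        parts_b = {frozenset(c.member_indices) for c in b}
        assert parts_a == parts_b

    def test_determinism(self):
        rng = np.random.default_rng(21)
        pts, _, _ = _blobs(rng, k=5)
        a = cluster_fiducials(pts, k=5, seed=3)
        b = cluster_fiducials(pts, k=5, seed=3)
        for ca, cb in zip(a, b):
            assert np.array_equal(ca.member_indices, cb.member_indices)

    def test_cluster_needs_three_members(self):
        with pytest.raises(ValueError):
            FiducialCluster([0, 1], np.zeros((2, 3)), np.zeros(3))


class TestPhantomPurity:
    def test_only_fiducial_vertices_pass_on_phantom(self, default_scan, default_truth):
        """On a default phantom the filter keeps >= 99% of fiducial vertices
        and no hair/skin vertices."""
        idx = filter_fiducial_vertices(default_scan)
        n_hair = default_truth.scalp_mesh.n_vertices
        n_fid = 17 * 45  # modules x patch vertices
        assert np.all(idx >= n_hair)  # zero hair vertices pass
        assert len(idx) >= 0.99 * n_fid
        # every passing vertex is pure red up to generator bookkeeping
        assert len(idx) <= n_fid
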