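import numpy as np
import pytest

from capmorph.exceptions import (
    EmptyMaskError,
    FullMaskError,
    LandmarkError,
    MeshFormatError,
    MissingColorError,
)
from capmorph.mesh_io import (
    ColoredMesh,
    LandmarkSet,
    read_colored_mesh,
    read_landmarks,
    surface_from_binary_mask,
    write_colored_mesh,
    write_landmarks,
)


@pytest.fixture
def random_mesh():
    rng = np.random.default_rng(42)
    return ColoredMesh(
        vertices=rng.normal(scale=50.0, size=(20, 3)),
        faces=[[0, 1, 2], [2, 3, 4], [5, 6, 7]],
        colors=rng.uniform(size=(20, 3)),
    )


class TestColoredMesh:
    def test_face_index_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="out of range"):
            ColoredMesh([[0, 0, 0]] * 3, [[0, 1, 5]], [[0, 0, 0]] * 3)

    def test_color_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="color"):
            ColoredMesh([[0, 0, 0]] * 3, [[0, 1, 2]], [[0, 0, 2.0]] * 3)


class TestMeshRoundTrip:
    def test_ply_binary_vertices_bit_exact(self, random_mesh, tmp_path):
        path = tmp_path / "m.ply"
        write_colored_mesh(random_mesh, path)
        back = read_colored_mesh(path)
        assert np.array_equal(back.vertices, random_mesh.vertices)
        assert np.array_equal(back.faces, random_mesh.faces)
        assert np.abs(back.colors - random_mesh.colors).max() <= 1.0 / 255.0

    def test_obj_round_trip(self, random_mesh, tmp_path):
        path = tmp_path / "m.obj"
        write_colored_mesh(random_mesh, path)
        back = read_colored_mesh(path)
        assert np.allclose(back.vertices, random_mesh.vertices)
        assert np.array_equal(back.faces, random_mesh.faces)
        assert np.abs(back.colors - random_mesh.colors).max() <= 1.0 / 255.0

    def test_extreme_colors_survive_exactly(self, tmp_path):
        mesh = ColoredMesh(
            np.eye(3), [[0, 1, 2]], [[0.0, 1.0, 0.0], [1.0, 0.0, 1.0], [0.0, 0.0, 1.0]]
        )
        path = tmp_path / "c.ply"
        write_colored_mesh(mesh, path)
        back = read_colored_mesh(path)
        assert np.array_equal(back.colors, mesh.colors)

    def test_point_cloud_round_trips_with_zero_faces(self, tmp_path):
        mesh = ColoredMesh(np.eye(3) * 10, np.zeros((0, 3)), np.eye(3))
        path = tmp_path / "pc.ply"
        write_colored_mesh(mesh, path)
        back = read_colored_mesh(path)
        assert back.n_faces == 0
        assert np.array_equal(back.vertices, mesh.vertices)

    def test_phantom_scan_counts_preserved(self, default_scan, tmp_path):
        path = tmp_path / "scan.ply"
        write_colored_mesh(default_scan, path)
        back = read_colored_mesh(path)
        assert back.n_vertices == default_scan.n_vertices
        assert back.n_faces == default_scan.n_faces


class TestMeshReading:
    def test_eight_bit_colors_rescaled(self, tmp_path):
        text = (
            "ply\nformat ascii 1.0\nelement vertex 4\n"
            "property float x\nproperty float y\nproperty float z\n"
            "property uchar red\nproperty uchar green\nproperty uchar blue\n"
            "element face 2\nproperty list uchar int vertex_indices\nend_header\n"
            "0 0 0 255 0 0\n1 0 0 255 0 0\n0 1 0 255 0 0\n1 1 0 255 0 0\n"
            "3 0 1 2\n3 1 3 2\n"
        )
        path = tmp_path / "red.ply"
        path.write_text(text)
        mesh = read_colored_mesh(path)
        assert mesh.n_vertices == 4 and mesh.n_faces == 2
        assert np.allclose(mesh.colors, [1.0, 0.0, 0.0])

    def test_missing_color_raises(self, tmp_path):
        text = (
            "ply\nformat ascii 1.0\nelement vertex 3\n"
            "property float x\nproperty float y\nproperty float z\n"
            "element face 1\nproperty list uchar int vertex_indices\nend_header\n"
            "0 0 0\n1 0 0\n0 1 0\n3 0 1 2\n"
        )
        path = tmp_path / "plain.ply"
        path.write_text(text)
        with pytest.raises(MissingColorError):
            read_colored_mesh(path)

    def test_garbage_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.ply"
        path.write_text("this is not a ply file\n")
        with pytest.raises(MeshFormatError):
            read_colored_mesh(path)


class TestMaskFromIntensity:
    def test_head_blob_extracted_and_filled(self):
        from capmorph.mesh_io import binary_mask_from_intensity

        rng = np.random.default_rng(0)
        n = 31
        c = (n - 1) / 2.0
        idx = np.indices((n, n, n)).astype(float)
        dist = np.sqrt(((idx - c) ** 2).sum(axis=0))
        vol = np.where(dist <= 10, 1000.0, 0.0)
        vol[15, 15, 15] = 0.0                     # internal "hole"
        vol[2, 2, 2] = 800.0                      # disconnected speck
        vol += rng.uniform(0, 20.0, vol.shape)    # background noise
        mask = binary_mask_from_intensity(vol, threshold=0.1)
        assert mask[15, 15, 15]                   # hole filled
        assert not mask[2, 2, 2]                  # speck dropped
        assert abs(mask.sum() - (dist <= 10).sum()) < 50

    def test_flat_volume_rejected(self):
        from capmorph.exceptions import EmptyMaskError
        from capmorph.mesh_io import binary_mask_from_intensity

        with pytest.raises(EmptyMaskError):
            binary_mask_from_intensity(np.zeros((5, 5, 5)))


class TestSurfaceFromMask:
    def test_sphere_mask_radii(self):
        n = 45
        c = (n - 1) / 2.0
        idx = np.indices((n, n, n)).astype(float)
        dist = np.sqrt(((idx - c) ** 2).sum(axis=0))
        mesh = surface_from_binary_mask(dist <= 20.0, voxel_size=1.0)
        radii = np.linalg.norm(mesh.vertices - [c, c, c], axis=1)
        assert radii.min() > 20.0 - 0.6
        assert radii.max() < 20.0 + 0.6

    def test_single_voxel_volume_near_one(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        mesh = surface_from_binary_mask(mask, voxel_size=1.0)
        tm = mesh.as_trimesh()
        assert tm.is_watertight
        assert abs(abs(tm.volume) - 1.0) < 0.2
        assert np.allclose(mesh.vertices.mean(axis=0), [2, 2, 2], atol=1e-6)

    def test_output_is_closed(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[2:6, 2:6, 2:6] = True
        mesh = surface_from_binary_mask(mask)
        tm = mesh.as_trimesh()
        assert tm.is_watertight  # every edge shared by exactly 2 faces
        assert tm.volume > 0  # outward winding

    def test_voxel_size_scales_to_mm(self):
        mask = np.zeros((5, 5, 5), bool)
        mask[2, 2, 2] = True
        mesh = surface_from_binary_mask(mask, voxel_size=2.0)
        assert abs(abs(mesh.as_trimesh().volume) - 8.0) < 1.6

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            surface_from_binary_mask(np.zeros((4, 4, 4), bool))

    def test_full_mask_raises(self):
        with pytest.raises(FullMaskError):
            surface_from_binary_mask(np.ones((4, 4, 4), bool))


class TestLandmarks:
    def test_file_round_trip(self, tmp_path):
        lm = LandmarkSet([0, 110, 2], [0, -110, 1], [-90, 0, -20], [90, 0, -20])
        path = tmp_path / "lm.txt"
        write_landmarks(lm, path)
        back = read_landmarks(path)
        assert np.allclose(back.as_array(), lm.as_array())

    def test_aliases_accepted(self, tmp_path):
        path = tmp_path / "lm.txt"
        path.write_text(
            "Nasion 0 110 0\ninion 0 -110 0\nLPA -90 0 -20\nRPA 90 0 -20\n"
        )
        lm = read_landmarks(path)
        assert np.allclose(lm.left_preauricular, [-90, 0, -20])

    def test_missing_landmark_raises(self, tmp_path):
        path = tmp_path / "lm.txt"
        path.write_text("nasion 0 110 0\ninion 0 -110 0\nlpa -90 0 0\n")
        with pytest.raises(LandmarkError, match="missing"):
            read_landmarks(path)

    @pytest.mark.parametrize(
        "pts",
        [
            # coincident pair
            ([0, 1, 0], [0, 1, 0], [1, 0, 0], [0, 0, 1]),
            # collinear
            ([0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]),
            # non-finite
            ([np.nan, 1, 0], [0, -1, 0], [1, 0, 0], [-1, 0, 0]),
        ],
    )
    def test_invalid_landmark_sets_rejected(self, pts):
        with pytest.raises(LandmarkError):
            LandmarkSet(*pts)
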