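"""Colored surface-mesh and landmark I/O.

The pipeline's carrier type is :class:`ColoredMesh`: a triangulated surface
in millimeters with per-vertex RGB in [0, 1].  Scans, templates and phantom
outputs all use it.  Internally generated data follow one right-handed
convention: millimeters, nose toward +Y, left ear toward -X, vertex toward
+Z.  External meshes are accepted as-is; registration handles orientation.

File formats: PLY (ascii or binary-little-endian read; binary-little-endian
written, float64 vertices + 8-bit colors) and OBJ with the common per-vertex
color extension (``v x y z r g b``).  Landmarks are plain text, one
``name x y z`` line per landmark, in mm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import trimesh

from .exceptions import (
    EmptyMaskError,
    FullMaskError,
    LandmarkError,
    MaskError,
    MeshFormatError,
    MissingColorError,
)

__all__ = [
    "ColoredMesh",
    "LandmarkSet",
    "read_colored_mesh",
    "write_colored_mesh",
    "read_landmarks",
    "write_landmarks",
    "binary_mask_from_intensity",
    "surface_from_binary_mask",
]


@dataclass
class ColoredMesh:
    """Triangulated surface with per-vertex normalized RGB color.

    Attributes
    ----------
    vertices : (n, 3) float64 array, millimeters.
    faces : (m, 3) int array of vertex-index triples.
    colors : (n, 3) float64 array, each channel in [0, 1].
    """

    vertices: np.ndarray
    faces: np.ndarray
    colors: np.ndarray

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=np.float64).reshape(-1, 3)
        self.faces = np.asarray(self.faces, dtype=np.int64).reshape(-1, 3)
        self.colors = np.asarray(self.colors, dtype=np.float64).reshape(-1, 3)
        n = len(self.vertices)
        if len(self.colors) != n:
            raise ValueError(
                f"color count {len(self.colors)} != vertex count {n}"
            )
        if len(self.faces):
            if n < 3:
                raise ValueError("faces present but fewer than 3 vertices")
            if self.faces.min() < 0 or self.faces.max() >= n:
                raise ValueError("face indices out of range")
        if len(self.colors) and (
            self.colors.min() < 0.0 or self.colors.max() > 1.0
        ):
            raise ValueError("color channels must lie in [0, 1]")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def as_trimesh(self) -> trimesh.Trimesh:
        """View as a :class:`trimesh.Trimesh` (no vertex merging)."""
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.faces, process=False
        )

    def copy(self) -> "ColoredMesh":
        return ColoredMesh(
            self.vertices.copy(), self.faces.copy(), self.colors.copy()
        )

    def vertex_normals(self) -> np.ndarray:
        return np.asarray(self.as_trimesh().vertex_normals, dtype=np.float64)


@dataclass
class LandmarkSet:
    """The four cranial landmarks, in mm: nasion, inion, preauriculars."""

    nasion: np.ndarray
    inion: np.ndarray
    left_preauricular: np.ndarray
    right_preauricular: np.ndarray

    def __post_init__(self):
        for name in ("nasion", "inion", "left_preauricular", "right_preauricular"):
            p = np.asarray(getattr(self, name), dtype=np.float64).reshape(3)
            if not np.all(np.isfinite(p)):
                raise LandmarkError(f"landmark {name!r} is not finite")
            setattr(self, name, p)
        pts = self.as_array()
        for i in range(4):
            for j in range(i + 1, 4):
                if np.allclose(pts[i], pts[j]):
                    raise LandmarkError("landmarks must be pairwise distinct")
        # collinearity: rank of centered points must exceed 1
        centered = pts - pts.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
            raise LandmarkError("the four landmarks are collinear")

    def as_array(self) -> np.ndarray:
        """Stack as (4, 3): nasion, inion, LPA, RPA."""
        return np.stack(
            [self.nasion, self.inion, self.left_preauricular, self.right_preauricular]
        )

    def as_dict(self) -> dict:
        return {
            "nasion": self.nasion,
            "inion": self.inion,
            "lpa": self.left_preauricular,
            "rpa": self.right_preauricular,
        }


# ---------------------------------------------------------------------------
# Mesh reading
# ---------------------------------------------------------------------------

def read_colored_mesh(path, fmt: str | None = None) -> ColoredMesh:
    """Read a PLY or OBJ mesh with per-vertex color.

    Parameters
    ----------
    path : file path.
    fmt : "ply" or "obj"; inferred from the suffix when omitted.

    Raises
    ------
    MissingColorError
        If the file has no per-vertex colors.
    MeshFormatError
        If the file cannot be parsed as the named format.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt not in ("ply", "obj"):
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")
    try:
        loaded = trimesh.load(
            str(path), file_type=fmt, process=False, maintain_order=True
        )
    except FileNotFoundError:
        raise
    except Exception as exc:  # trimesh raises assorted types on bad input
        raise MeshFormatError(f"could not parse {path} as {fmt}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: no geometry found")
        loaded = geoms[0]
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    raw_faces = getattr(loaded, "faces", None)  # PointCloud for 0-face files
    faces = (
        np.asarray(raw_faces, dtype=np.int64)
        if raw_faces is not None and len(raw_faces)
        else np.zeros((0, 3), dtype=np.int64)
    )
    visual = getattr(loaded, "visual", None)
    if visual is None or getattr(visual, "kind", None) != "vertex":
        raise MissingColorError(f"{path}: no per-vertex colors present")
    colors = np.asarray(visual.vertex_colors, dtype=np.float64)[:, :3]
    if colors.max() > 1.0:  # 8-bit colors
        colors = colors / 255.0
    return ColoredMesh(vertices, faces, np.clip(colors, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Mesh writing
#
# PLY is written by hand in binary-little-endian with float64 vertex
# coordinates: trimesh's exporter stores float32 positions, which would break
# the round-trip guarantee that binary PLY preserves coordinates bit-for-bit.
# ---------------------------------------------------------------------------

def write_colored_mesh(mesh: ColoredMesh, path, fmt: str | None = None) -> None:
    """Write ``mesh`` to ``path`` as PLY (binary) or OBJ (ascii).

    Colors are stored as 8-bit in PLY (round-trip exact at 0.0 and 1.0,
    otherwise within 1/255) and as full-precision floats in OBJ.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "ply":
        _write_ply(mesh, path)
    elif fmt == "obj":
        _write_obj(mesh, path)
    else:
        raise MeshFormatError(f"unsupported mesh format {fmt!r}")


def _write_ply(mesh: ColoredMesh, path: Path) -> None:
    n_v, n_f = mesh.n_vertices, mesh.n_faces
    header = "\n".join(
        [
            "ply",
            "format binary_little_endian 1.0",
            f"element vertex {n_v}",
            "property double x",
            "property double y",
            "property double z",
            "property uchar red",
            "property uchar green",
            "property uchar blue",
            f"element face {n_f}",
            "property list uchar int vertex_indices",
            "end_header",
            "",
        ]
    )
    vert = np.empty(
        n_v,
        dtype=[
            ("xyz", "<f8", (3,)),
            ("rgb", "u1", (3,)),
        ],
    )
    vert["xyz"] = mesh.vertices
    vert["rgb"] = np.rint(mesh.colors * 255.0).astype(np.uint8)
    face = np.empty(n_f, dtype=[("n", "u1"), ("idx", "<i4", (3,))])
    face["n"] = 3
    face["idx"] = mesh.faces
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(vert.tobytes())
        fh.write(face.tobytes())


def _write_obj(mesh: ColoredMesh, path: Path) -> None:
    lines = []
    for (x, y, z), (r, g, b) in zip(mesh.vertices, mesh.colors):
        lines.append(f"v {x:.17g} {y:.17g} {z:.17g} {r:.9g} {g:.9g} {b:.9g}")
    for a, b, c in mesh.faces:
        lines.append(f"f {a + 1} {b + 1} {c + 1}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Landmark files
# ---------------------------------------------------------------------------

_LANDMARK_ALIASES = {
    "nasion": "nasion",
    "nz": "nasion",
    "inion": "inion",
    "iz": "inion",
    "lpa": "left_preauricular",
    "left_preauricular": "left_preauricular",
    "rpa": "right_preauricular",
    "right_preauricular": "right_preauricular",
}


def read_landmarks(path) -> LandmarkSet:
    """Read a four-line ``name x y z`` landmark file (mm)."""
    found: dict[str, np.ndarray] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise LandmarkError(
                f"{path}:{lineno}: expected 'name x y z', got {raw!r}"
            )
        key = _LANDMARK_ALIASES.get(parts[0].lower())
        if key is None:
            raise LandmarkError(f"{path}:{lineno}: unknown landmark {parts[0]!r}")
        try:
            found[key] = np.array([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise LandmarkError(f"{path}:{lineno}: bad coordinate: {exc}") from exc
    missing = {"nasion", "inion", "left_preauricular", "right_preauricular"} - set(found)
    if missing:
        raise LandmarkError(f"{path}: missing landmarks {sorted(missing)}")
    return LandmarkSet(**found)


def write_landmarks(landmarks: LandmarkSet, path) -> None:
    rows = [
        ("nasion", landmarks.nasion),
        ("inion", landmarks.inion),
        ("lpa", landmarks.left_preauricular),
        ("rpa", landmarks.right_preauricular),
    ]
    text = "\n".join(f"{n} {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}" for n, p in rows)
    Path(path).write_text(text + "\n")


# ---------------------------------------------------------------------------
# Head-mask extraction from an anatomical intensity volume
# ---------------------------------------------------------------------------

def binary_mask_from_intensity(
    volume: np.ndarray,
    threshold: float = 0.1,
    percentile: float = 99.9,
) -> np.ndarray:
    """Normalized thresholding of an anatomical volume into a head mask.

    Intensities are scaled to [0, 1] by the given robust percentile, the
    result thresholded, the largest connected component kept and internal
    holes filled.  The threshold and normalization percentile are
    configuration: anatomical sequences differ in background level.
    """
    from scipy import ndimage

    vol = np.asarray(volume, dtype=np.float64)
    if vol.ndim != 3:
        raise MaskError(f"expected a 3D volume, got {vol.ndim} dimensions")
    scale = np.percentile(vol, percentile)
    if scale <= 0:
        raise EmptyMaskError("volume has no positive intensities")
    mask = (vol / scale) >= threshold
    if not mask.any():
        raise EmptyMaskError("no voxels above the normalized threshold")
    labels, n = ndimage.label(mask)
    if n > 1:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    return ndimage.binary_fill_holes(mask)


# ---------------------------------------------------------------------------
# Iso-surface extraction from a binary head mask
# ---------------------------------------------------------------------------

def surface_from_binary_mask(
    volume: np.ndarray,
    voxel_size: float | tuple = 1.0,
    upsample: int = 4,
    smooth_iterations: int = 6,
) -> ColoredMesh:
    """Triangulated iso-surface of a binary mask, scaled to millimeters.

    The mask is interpreted cell-wise (each foreground voxel is a filled
    ``voxel_size`` cube): the volume is upsampled by nearest-neighbor
    repetition, padded, and passed through marching cubes at level 0.5;
    a light volume-preserving Laplacian smoothing removes the staircase
    chamfers.  Voxel index ``i`` maps to coordinate ``i * voxel_size``
    (voxel centers on the index lattice).

    Colors are set to a neutral constant gray.

    Raises
    ------
    EmptyMaskError / FullMaskError
        For masks with no foreground or no interior boundary.
    """
    from skimage import measure

    mask = np.asarray(volume).astype(bool)
    if mask.ndim != 3:
        raise MaskError(f"expected a 3D volume, got {mask.ndim} dimensions")
    if not mask.any():
        raise EmptyMaskError("binary mask has no foreground voxels")
    if mask.all():
        raise FullMaskError("binary mask has no background boundary inside the volume")
    voxel = np.broadcast_to(np.asarray(voxel_size, dtype=float), (3,)).copy()
    u = int(upsample)
    up = mask.astype(np.float32)
    for axis in range(3):
        up = up.repeat(u, axis=axis)
    up = np.pad(up, 1)
    spacing = voxel / u
    verts, faces, _, _ = measure.marching_cubes(up, 0.5, spacing=tuple(spacing))
    # padded subvoxel s along one axis has center ((s - 1 + 0.5)/u - 0.5)*voxel
    verts = verts - spacing * 0.5 - voxel * 0.5
    faces = faces[:, ::-1]  # outward winding
    tm = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    if smooth_iterations > 0:
        trimesh.smoothing.filter_laplacian(
            tm, iterations=int(smooth_iterations), volume_constraint=True
        )
    vertices = np.asarray(tm.vertices, dtype=np.float64)
    colors = np.full((len(vertices), 3), 0.5)
    return ColoredMesh(vertices, np.asarray(tm.faces, dtype=np.int64), colors)
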