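"""Synthetic cap-scan phantoms with ground truth.

The phantom emulates what the 3D scanner sees over a head wearing the
photogrammetric cap, together with the ground truth an MRI would provide:

* a smooth head: a perturbed ellipsoid (defaults 90/110/95 mm semi-axes,
  3 mm seeded shape bumps that vanish at the landmark directions);
* a hair envelope: the scalp offset outward by a smoothly varying hair
  thickness (hair under the cap is partially compressed; the cap-less
  variant uses a larger, uncompressed thickness);
* per module: a dark body and a pure-red triangulated fiducial triangle
  (legs 20/15 mm) at ``height`` above the scalp, feet combed through to
  scalp contact; true poses and foot-contact points are recorded;
* Gaussian vertex noise on everything the scanner "sees".

Cohort realism for the method comparison comes from
:func:`participant_spec`: per-participant anisotropic size jitter of the
semi-axes (so the generating atlas-to-participant transform is a known
anisotropic scaling) and small tangential jitter of where the landmarks
sit on the head (anatomical variation / manual-picking error, the factor
that degrades the four-point "basic 4" registration in practice).

All randomness flows from ``spec.seed``; identical specs give
bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import trimesh

from ._geometry import unit
from .exceptions import ModuleOverlapError, PhantomError, ResolutionError
from .mesh_io import ColoredMesh, LandmarkSet
from .montage import MontagePointSet, compute_montages
from .pose import ModuleGeometry, ModulePose

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "make_head",
    "make_cap_scan",
    "without_cap_scan",
    "strip_legs_variant",
    "participant_spec",
    "atlas_spec",
    "make_atlas",
    "truth_montages",
]

DEFAULT_SEMI_AXES = (90.0, 110.0, 95.0)

_SKIN_COLOR = (0.80, 0.65, 0.55)
_BODY_COLOR = (0.06, 0.06, 0.06)
_FIDUCIAL_COLOR = (1.0, 0.0, 0.0)
_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))


@dataclass(frozen=True)
class PhantomSpec:
    """Study conditions for one synthetic head / cap scan."""

    head_semi_axes: tuple = DEFAULT_SEMI_AXES
    shape_perturbation: float = 3.0     # mm amplitude of smooth bumps
    hair_thickness: float = 8.0         # mm, mean (cap-compressed) envelope
    hair_roughness: float = 0.6         # fractional smooth variation of hair
    uncompressed_hair_factor: float = 1.75  # cap-less hair envelope multiplier
    n_modules: int = 17
    module_layout: tuple | None = None  # unit directions; default Fibonacci
    module_min_elevation: float = 0.35  # min z-component of layout directions
    noise_sigma: float = 0.3            # mm scanner vertex noise
    seed: int = 0
    mesh_resolution: float = 4.0        # target edge length, mm
    preauricular_drop: float = 20.0     # mm below the nasion-inion equator
    landmark_jitter: float = 0.0        # mm tangential landmark variation

    def __post_init__(self):
        if min(self.head_semi_axes) <= 0:
            raise ValueError("semi-axes must be positive")
        if self.hair_thickness < 0 or self.noise_sigma < 0:
            raise ValueError("hair_thickness and noise_sigma must be >= 0")
        if self.n_modules < 1:
            raise ValueError("n_modules must be >= 1")


class _HeadShape:
    """Analytic radial model: perturbed ellipsoid r(d) over unit directions."""

    def __init__(self, semi_axes, perturbation, rng):
        self.semi = np.asarray(semi_axes, dtype=np.float64)
        self.perturbation = float(perturbation)
        self.bump_dirs = _random_units(rng, 6)
        amps = rng.uniform(-1.0, 1.0, 6)
        self.bump_amps = amps / np.abs(amps).sum()
        self.landmark_dirs = None  # set after landmark placement

    def ellipsoid_radius(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        return 1.0 / np.sqrt(((dirs / self.semi) ** 2).sum(axis=1))

    def radius(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        r = self.ellipsoid_radius(dirs)
        if self.perturbation != 0.0:
            f = (dirs @ self.bump_dirs.T) ** 3 @ self.bump_amps
            if self.landmark_dirs is not None:
                mask = np.prod(1.0 - (dirs @ self.landmark_dirs.T) ** 8, axis=1)
            else:
                mask = 1.0
            r = r + self.perturbation * f * mask
        return r

    def point(self, dirs: np.ndarray) -> np.ndarray:
        dirs = np.atleast_2d(dirs)
        return dirs * self.radius(dirs)[:, None]

    def project(self, points: np.ndarray) -> np.ndarray:
        """Radial projection onto the analytic surface."""
        points = np.atleast_2d(points)
        dirs = points / np.linalg.norm(points, axis=1, keepdims=True)
        return self.point(dirs)

    def normal(self, points: np.ndarray, h: float = 0.05) -> np.ndarray:
        """Outward surface normal via finite differences of the implicit
        function F(p) = |p| - r(p/|p|)."""

        def f(p):
            n = np.linalg.norm(p, axis=1)
            return n - self.radius(p / n[:, None])

        points = np.atleast_2d(points)
        grad = np.empty_like(points)
        for axis in range(3):
            e = np.zeros(3)
            e[axis] = h
            grad[:, axis] = (f(points + e) - f(points - e)) / (2 * h)
        return grad / np.linalg.norm(grad, axis=1, keepdims=True)


def _random_units(rng, n):
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def _smooth_field(rng):
    """A smooth seeded function on the sphere with values in [-1, 1]."""
    dirs = _random_units(rng, 6)
    amps = rng.uniform(-1.0, 1.0, 6)
    amps = amps / np.abs(amps).sum()

    def g(d):
        return (np.atleast_2d(d) @ dirs.T) ** 3 @ amps

    return g


@dataclass
class PhantomTruth:
    """Ground truth for one phantom (the simulation's stand-in for MRI)."""

    scalp_mesh: ColoredMesh
    landmarks: LandmarkSet
    spec: PhantomSpec
    module_poses: list = field(default_factory=list)
    foot_points: np.ndarray | None = None
    montage_truth: MontagePointSet | None = None
    ten20_truth: MontagePointSet | None = None
    shape: _HeadShape | None = None
    hair_field: object | None = None


def _subdivisions_for(spec: PhantomSpec) -> int:
    semi = np.asarray(spec.head_semi_axes)
    if spec.mesh_resolution > 0.05 * semi.min():
        raise ResolutionError(
            f"mesh resolution {spec.mesh_resolution} mm exceeds 5% of the "
            f"smallest semi-axis ({0.05 * semi.min():.2f} mm)"
        )
    # icosphere edge length is about 1.051 / 2^s at unit radius
    return max(0, math.ceil(math.log2(1.051 * semi.max() / spec.mesh_resolution)))


def _landmark_directions(spec: PhantomSpec, rng) -> np.ndarray:
    semi = np.asarray(spec.head_semi_axes)
    drop = spec.preauricular_drop
    dirs = np.array(
        [
            [0.0, 1.0, 0.0],                    # nasion  (+Y, front)
            [0.0, -1.0, 0.0],                   # inion
            [-1.0, 0.0, -drop / semi[0]],       # LPA, ~drop mm below equator
            [1.0, 0.0, -drop / semi[0]],        # RPA
        ]
    )
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    if spec.landmark_jitter > 0:
        scale = spec.landmark_jitter / semi.mean()
        for i in range(4):
            tangent = rng.normal(size=3)
            tangent -= np.dot(tangent, dirs[i]) * dirs[i]
            dirs[i] = unit(dirs[i] + scale * rng.normal() * unit(tangent))
    return dirs


def make_head(spec: PhantomSpec) -> PhantomTruth:
    """Watertight perturbed-ellipsoid scalp mesh with landmarks.

    Landmarks: nasion at the anterior pole, inion posterior, preauricular
    points at the lateral extremes ``preauricular_drop`` mm below the
    equator (so the four points are non-coplanar, as on a real head);
    optional seeded tangential jitter models anatomical variation.  The
    shape-perturbation field vanishes at the landmark directions, keeping
    landmark placement analytic.
    """
    rng = np.random.default_rng(spec.seed)
    shape = _HeadShape(spec.head_semi_axes, spec.shape_perturbation, rng)
    lm_dirs = _landmark_directions(spec, rng)
    shape.landmark_dirs = lm_dirs
    hair_field = _smooth_field(rng)

    ico = trimesh.creation.icosphere(subdivisions=_subdivisions_for(spec), radius=1.0)
    dirs = np.asarray(ico.vertices, dtype=np.float64)
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    vertices = shape.point(dirs)
    colors = np.tile(_SKIN_COLOR, (len(vertices), 1))
    scalp = ColoredMesh(vertices, np.asarray(ico.faces), colors)

    lpts = shape.point(lm_dirs)
    landmarks = LandmarkSet(lpts[0], lpts[1], lpts[2], lpts[3])
    return PhantomTruth(
        scalp_mesh=scalp,
        landmarks=landmarks,
        spec=spec,
        shape=shape,
        hair_field=hair_field,
    )


# ---------------------------------------------------------------------------
# Cap scan assembly
# ---------------------------------------------------------------------------

def _module_directions(spec: PhantomSpec) -> np.ndarray:
    if spec.module_layout is not None:
        dirs = np.asarray(spec.module_layout, dtype=np.float64)
        return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    n = spec.n_modules
    lo, hi = spec.module_min_elevation, 0.97
    out = []
    for i in range(n):
        z = lo + (hi - lo) * (i + 0.5) / n
        az = i * _GOLDEN_ANGLE
        r = math.sqrt(max(0.0, 1.0 - z * z))
        out.append([r * math.cos(az), r * math.sin(az), z])
    return np.asarray(out)


def _triangle_patch(geometry: ModuleGeometry, n: int = 8):
    """Triangulated fiducial triangle in the module frame (z = 0 plane)."""
    a, b, c = geometry.triangle_vertices
    verts, index = [], {}
    for i in range(n + 1):
        for j in range(n + 1 - i):
            index[(i, j)] = len(verts)
            verts.append(a + (b - a) * i / n + (c - a) * j / n)
    faces = []
    for i in range(n):
        for j in range(n - i):
            faces.append([index[(i, j)], index[(i + 1, j)], index[(i, j + 1)]])
            if i + j < n - 1:
                faces.append(
                    [index[(i + 1, j)], index[(i + 1, j + 1)], index[(i, j + 1)]]
                )
    return np.asarray(verts), np.asarray(faces)


def _module_rotation(normal: np.ndarray, angle: float) -> np.ndarray:
    """Rotation with local +z along ``normal`` and a free in-plane angle."""
    z = unit(normal)
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(z, ref)) > 0.99:
        ref = np.array([0.0, 1.0, 0.0])
    t1 = unit(np.cross(z, ref))
    t2 = np.cross(z, t1)
    x = math.cos(angle) * t1 + math.sin(angle) * t2
    y = np.cross(z, x)
    return np.column_stack([x, y, z])


def _hair_vertices(truth: PhantomTruth, spec: PhantomSpec, factor: float = 1.0):
    dirs = truth.scalp_mesh.vertices / np.linalg.norm(
        truth.scalp_mesh.vertices, axis=1, keepdims=True
    )
    thickness = (
        spec.hair_thickness
        * factor
        * (1.0 + spec.hair_roughness * truth.hair_field(dirs))
    )
    return truth.scalp_mesh.vertices + dirs * np.clip(thickness, 0.0, None)[:, None]


def _hair_colors(n: int, rng) -> np.ndarray:
    r = rng.uniform(0.25, 0.45, n)
    g = r * rng.uniform(0.60, 0.80, n)
    b = r * rng.uniform(0.40, 0.60, n)
    return np.column_stack([r, g, b])


def make_cap_scan(
    truth: PhantomTruth,
    spec: PhantomSpec | None = None,
    geometry: ModuleGeometry | None = None,
    occluded: tuple = (),
) -> ColoredMesh:
    """Simulated 3D scan of the head wearing the photogrammetric cap.

    The scan is the union of the hair envelope, the dark module bodies and
    the red fiducial triangles; feet are hidden under the hair (they are
    recorded as ground truth, not rendered).  Modules listed in
    ``occluded`` are left out of the scan (but not of the truth record).

    Fills ``truth.module_poses`` and ``truth.foot_points``.
    """
    spec = spec or truth.spec
    geometry = geometry or ModuleGeometry()
    shape = truth.shape
    if shape is None:
        raise PhantomError("truth was not produced by make_head")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 17]))

    dirs = _module_directions(spec)
    contacts = shape.point(dirs)
    if len(contacts) > 1:
        from scipy.spatial.distance import pdist

        if pdist(contacts).min() < 35.0:
            raise ModuleOverlapError(
                "two modules are closer than 35 mm and would intersect"
            )
    normals = shape.normal(contacts)
    foot_center = geometry.foot_offsets[:, :2].mean(axis=0)

    poses, foot_true = [], []
    parts_v, parts_f, parts_c = [], [], []

    # hair envelope (cap-compressed)
    hair_v = _hair_vertices(truth, spec)
    parts_v.append(hair_v)
    parts_f.append(truth.scalp_mesh.faces.copy())
    parts_c.append(_hair_colors(len(hair_v), rng))

    patch_v, patch_f = _triangle_patch(geometry)
    body_half = (11.0, 14.0)
    body_h = max(geometry.height - geometry.leg_length, 1.0)

    for mi, (p0, nrm) in enumerate(zip(contacts, normals)):
        angle = rng.uniform(0.0, 2.0 * math.pi)
        rot = _module_rotation(nrm, angle)
        center_offset = rot @ np.array([foot_center[0], foot_center[1], 0.0])
        t = p0 + geometry.height * nrm - center_offset
        # settle the module so the four feet straddle the curved scalp
        feet = geometry.foot_offsets @ rot.T + t
        sag = ((feet - shape.project(feet)) * nrm).sum(axis=1)
        t = t - nrm * sag.mean()
        pose = ModulePose(rot, t)
        feet = geometry.foot_offsets @ rot.T + t
        poses.append(pose)
        foot_true.append(shape.project(feet))

        if mi in occluded:
            continue
        # fiducial triangle on top of the module
        fv = patch_v @ rot.T + t
        parts_v.append(fv)
        parts_f.append(patch_f)
        parts_c.append(np.tile(_FIDUCIAL_COLOR, (len(fv), 1)))
        # dark module body below the fiducial plane
        box = trimesh.creation.box(
            extents=(2 * body_half[0], 2 * body_half[1], body_h)
        )
        bv = np.asarray(box.vertices) + np.array(
            [foot_center[0], foot_center[1], -body_h / 2.0]
        )
        parts_v.append(bv @ rot.T + t)
        parts_f.append(np.asarray(box.faces))
        parts_c.append(np.tile(_BODY_COLOR, (len(bv), 1)))

    truth.module_poses = poses
    truth.foot_points = np.concatenate(foot_true)

    offsets = np.cumsum([0] + [len(v) for v in parts_v[:-1]])
    vertices = np.concatenate(parts_v)
    faces = np.concatenate([f + o for f, o in zip(parts_f, offsets)])
    colors = np.concatenate(parts_c)
    if spec.noise_sigma > 0:
        vertices = vertices + rng.normal(0.0, spec.noise_sigma, vertices.shape)
    return ColoredMesh(vertices, faces, np.clip(colors, 0.0, 1.0))


def without_cap_scan(truth: PhantomTruth, spec: PhantomSpec | None = None):
    """Cap-less scan: the uncompressed hair envelope alone.

    Returns (mesh, landmarks): the landmark positions a rater would pick
    on the cap-less scan, i.e. the true landmarks pushed onto the hair
    envelope.
    """
    spec = spec or truth.spec
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 23]))
    verts = _hair_vertices(truth, spec, factor=spec.uncompressed_hair_factor)
    if spec.noise_sigma > 0:
        verts = verts + rng.normal(0.0, spec.noise_sigma, verts.shape)
    mesh = ColoredMesh(
        verts, truth.scalp_mesh.faces.copy(), _hair_colors(len(verts), rng)
    )
    lm = truth.landmarks
    dirs = np.stack(
        [
            unit(lm.nasion),
            unit(lm.inion),
            unit(lm.left_preauricular),
            unit(lm.right_preauricular),
        ]
    )
    thickness = (
        spec.hair_thickness
        * spec.uncompressed_hair_factor
        * (1.0 + spec.hair_roughness * truth.hair_field(dirs))
    )
    pts = truth.shape.point(dirs) + dirs * np.clip(thickness, 0.0, None)[:, None]
    landmarks = LandmarkSet(pts[0], pts[1], pts[2], pts[3])
    return mesh, landmarks


def strip_legs_variant(
    scan: ColoredMesh,
    truth: PhantomTruth,
    geometry: ModuleGeometry,
    variant: str = "without_legs",
    spec: PhantomSpec | None = None,
):
    """The two degraded control variants of the pipeline input.

    ``without_legs``: the scan is unchanged, but the returned geometry
    projects feet only to the bottom of the module body (the thin legs'
    length is not accounted for), so the sparse sample floats
    ``leg_length`` mm above the scalp.

    ``without_cap``: the cap-less scan (uncompressed hair envelope, no
    modules); the scalp estimate is then the scanned surface itself.

    Returns (mesh, geometry).
    """
    if variant == "without_legs":
        return scan, geometry.with_height(geometry.height - geometry.leg_length)
    if variant == "without_cap":
        mesh, _ = without_cap_scan(truth, spec)
        return mesh, geometry
    raise ValueError(f"unknown variant {variant!r}")


# ---------------------------------------------------------------------------
# Cohort helpers
# ---------------------------------------------------------------------------

def atlas_spec(resolution: float = 4.0) -> PhantomSpec:
    """The population-template head: the unperturbed default ellipsoid."""
    return PhantomSpec(
        shape_perturbation=0.0,
        hair_thickness=0.0,
        noise_sigma=0.0,
        landmark_jitter=0.0,
        seed=0,
        mesh_resolution=resolution,
    )


def make_atlas(resolution: float = 4.0) -> PhantomTruth:
    """Template head surface + canonical landmarks (the atlas stand-in)."""
    return make_head(atlas_spec(resolution))


def participant_spec(
    base: PhantomSpec,
    seed: int,
    scale_jitter: float = 0.06,
    landmark_jitter: float = 2.5,
    ear_drop_jitter: float = 8.0,
) -> PhantomSpec:
    """A cohort participant: the base conditions with per-participant
    anatomy.

    Three seeded sources of inter-individual variation:

    * anisotropic head size — per-axis scaling of the semi-axes (the known
      generating transform vs. the atlas);
    * ear height — the preauricular points sit ``20 +- ear_drop_jitter``
      mm below the nasion-inion equator; where the ears sit relative to
      the skull is not an affine function of head shape, which is what
      makes four-landmark affine registration fragile in practice;
    * small tangential jitter of each landmark on the surface (anatomical
      variation plus manual-picking error).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 97]))
    scales = 1.0 + rng.uniform(-scale_jitter, scale_jitter, 3)
    semi = tuple(np.asarray(DEFAULT_SEMI_AXES) * scales)
    drop = base.preauricular_drop + rng.uniform(-ear_drop_jitter, ear_drop_jitter)
    return replace(
        base,
        head_semi_axes=semi,
        landmark_jitter=landmark_jitter,
        preauricular_drop=drop,
        seed=seed,
    )


def generating_scales(spec: PhantomSpec) -> np.ndarray:
    """Per-axis scaling of the participant's base ellipsoid relative to the
    atlas: the known 'volumetric' generating transform."""
    return np.asarray(spec.head_semi_axes) / np.asarray(DEFAULT_SEMI_AXES)


def truth_montages(truth: PhantomTruth):
    """10-20 and above-ear 10-5 montages on the true scalp (cached)."""
    if truth.montage_truth is None:
        ten20, ten5 = compute_montages(truth.scalp_mesh, truth.landmarks)
        truth.ten20_truth = ten20
        truth.montage_truth = ten5
    return truth.ten20_truth, truth.montage_truth
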