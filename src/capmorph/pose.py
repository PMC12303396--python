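"""Module pose recovery and scalp foot projection.

Each photogrammetric module is a rigid body: a red 3-4-5 right-triangle
fiducial on top (vertical leg 20 mm, horizontal leg 15 mm) and four thin
feet that comb through the hair and rest on the scalp, ``height`` mm below
the fiducial plane.  Given one fiducial cluster from the scan, the pose is
recovered by fitting the fiducial plane (PCA), orienting its normal toward
the head center, locating the triangle corners, and using the 20-vs-15 mm
leg asymmetry to resolve the in-plane rotation; the module's feet are then
projected into the scan frame to give true scalp-contact points.

The module's local frame: fiducial plane at z = 0, +z pointing away from
the head, right-angle vertex of the triangle at the origin, vertical leg
along +y, horizontal leg along +x, feet at z = -height.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.spatial import ConvexHull, QhullError

from .exceptions import (
    AmbiguousNormalError,
    DegenerateClusterError,
    LegAmbiguityError,
    MinModulesError,
    PoseFitError,
    TooFewClustersError,
)
from .fiducials import ColorFilterSpec, FiducialCluster, cluster_fiducials, filter_fiducial_vertices
from .mesh_io import ColoredMesh

logger = logging.getLogger("capmorph.pose")

__all__ = [
    "ModuleGeometry",
    "ModulePose",
    "SparseScalpSample",
    "principal_axes",
    "estimate_head_center",
    "inward_normal",
    "triangle_corners",
    "align_module_model",
    "project_feet",
    "build_sparse_sample",
]


def _default_foot_offsets(height: float, half: float = 7.0,
                          center=(5.0, 20.0 / 3.0)) -> np.ndarray:
    """Four feet at the corners of a 14x14 mm square centered under the
    fiducial triangle's centroid, at z = -height."""
    cx, cy = center
    return np.array(
        [
            [cx - half, cy - half, -height],
            [cx + half, cy - half, -height],
            [cx + half, cy + half, -height],
            [cx - half, cy + half, -height],
        ]
    )


@dataclass
class ModuleGeometry:
    """Physical geometry of one photogrammetric module (mm).

    ``leg_vertical``/``leg_horizontal`` are the fiducial triangle legs
    (20/15 defaults: a 3-4-5 triangle with 25 mm hypotenuse), ``height``
    the distance from the fiducial plane to the foot tips, ``leg_length``
    the portion of that height contributed by the thin feet below the
    module body (the part ignored by the "without legs" control variant).
    """

    leg_vertical: float = 20.0
    leg_horizontal: float = 15.0
    height: float = 25.0
    leg_length: float = 10.0
    foot_offsets: np.ndarray | None = None

    def __post_init__(self):
        if self.leg_vertical <= 0 or self.leg_horizontal <= 0:
            raise ValueError("triangle legs must be positive")
        if not 0 <= self.leg_length <= self.height:
            raise ValueError("leg_length must lie in [0, height]")
        if self.foot_offsets is None:
            self.foot_offsets = _default_foot_offsets(self.height)
        self.foot_offsets = np.asarray(self.foot_offsets, dtype=np.float64).reshape(-1, 3)
        if not np.allclose(self.foot_offsets[:, 2], -self.height):
            raise ValueError("foot offsets must lie at z = -height")

    @property
    def hypotenuse(self) -> float:
        return float(np.hypot(self.leg_vertical, self.leg_horizontal))

    @property
    def triangle_vertices(self) -> np.ndarray:
        """Right-angle vertex at the origin, vertical leg +y, horizontal +x."""
        return np.array(
            [
                [0.0, 0.0, 0.0],
                [0.0, self.leg_vertical, 0.0],
                [self.leg_horizontal, 0.0, 0.0],
            ]
        )

    def with_height(self, height: float) -> "ModuleGeometry":
        """Copy with a different fiducial-plane-to-foot distance.

        Foot in-plane positions are preserved; only their depth changes.
        Used by the "without legs" analysis variant.
        """
        feet = self.foot_offsets.copy()
        feet[:, 2] = -height
        return ModuleGeometry(
            leg_vertical=self.leg_vertical,
            leg_horizontal=self.leg_horizontal,
            height=height,
            leg_length=min(self.leg_length, height),
            foot_offsets=feet,
        )


@dataclass
class ModulePose:
    """Rigid pose mapping module-frame points p to the scan frame R p + t."""

    rotation: np.ndarray
    translation: np.ndarray
    residual_rms: float = 0.0

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=np.float64).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=np.float64).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation must be proper (det +1)")

    def apply(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=np.float64)
        return points @ self.rotation.T + self.translation


@dataclass
class SparseScalpSample:
    """Projected module-foot points: the sparse scalp sampling.

    ``module_ids[i]`` is the index of the cluster that produced point ``i``;
    four points per successfully posed module.
    """

    points: np.ndarray
    module_ids: np.ndarray
    poses: list = field(default_factory=list)

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.module_ids = np.asarray(self.module_ids, dtype=np.int64).reshape(-1)
        if len(self.points) != len(self.module_ids):
            raise ValueError("points and module_ids length mismatch")

    @property
    def n_modules(self) -> int:
        return len(np.unique(self.module_ids))


# ---------------------------------------------------------------------------


def principal_axes(points: np.ndarray):
    """Centroid and orthonormal principal axes of a 3D point cluster.

    Axes are returned as rows, ordered by decreasing variance; the third
    row is the normal of the best-fit plane.

    Raises
    ------
    DegenerateClusterError
        For fewer than 3 points or (near-)collinear clusters.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if len(points) < 3:
        raise DegenerateClusterError("need at least 3 points for principal axes")
    centroid = points.mean(axis=0)
    centered = points - centroid
    _, svals, vt = np.linalg.svd(centered, full_matrices=False)
    if svals[1] <= 1e-8 * max(svals[0], 1.0):
        raise DegenerateClusterError("cluster points are collinear or coincident")
    axes = vt.copy()
    if np.linalg.det(axes) < 0:  # keep a right-handed frame
        axes[2] = -axes[2]
    return centroid, axes


def estimate_head_center(cluster_centroids) -> np.ndarray:
    """Mean of the cluster centroids.

    The modules cover the upper scalp, so the mean lies inside the head:
    good enough for the normal-sign decision it feeds.
    """
    centroids = np.asarray(cluster_centroids, dtype=np.float64).reshape(-1, 3)
    if len(centroids) < 3:
        raise TooFewClustersError(
            f"head-center estimate needs >= 3 cluster centroids, got {len(centroids)}"
        )
    return centroids.mean(axis=0)


def inward_normal(axes: np.ndarray, centroid: np.ndarray, head_center: np.ndarray) -> np.ndarray:
    """Plane normal signed to point from the cluster toward the head center."""
    normal = np.asarray(axes, dtype=np.float64).reshape(3, 3)[2]
    d = float(np.dot(normal, np.asarray(head_center, dtype=float) - centroid))
    if d == 0.0:
        raise AmbiguousNormalError("fiducial plane passes through the head center")
    return normal if d > 0 else -normal


def triangle_corners(points: np.ndarray, centroid: np.ndarray, axes: np.ndarray) -> np.ndarray:
    """The three corner vertices of an observed fiducial-triangle patch.

    Points are projected onto the fitted plane; the corners are the convex
    hull triple of maximal area.  Returned in 3D scan coordinates.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    uv = (points - centroid) @ axes[:2].T
    try:
        hull_idx = ConvexHull(uv).vertices
    except QhullError as exc:
        raise DegenerateClusterError(f"degenerate fiducial patch: {exc}") from exc
    if len(hull_idx) < 3:
        raise DegenerateClusterError("fewer than 3 hull vertices")
    best, best_area = None, -1.0
    for i, j, k in combinations(hull_idx, 3):
        a, b = uv[j] - uv[i], uv[k] - uv[i]
        area = abs(a[0] * b[1] - a[1] * b[0])
        if area > best_area:
            best_area, best = area, (i, j, k)
    return points[list(best)]


def _kabsch(source: np.ndarray, target: np.ndarray):
    """Least-squares proper rotation + translation mapping source -> target."""
    sc, tc = source.mean(axis=0), target.mean(axis=0)
    h = (source - sc).T @ (target - tc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ sc


def align_module_model(
    cluster: FiducialCluster,
    geometry: ModuleGeometry,
    normal: np.ndarray,
    residual_max: float = 2.0,
    leg_ratio_tol: float = 0.1,
) -> ModulePose:
    """Recover the 6-DOF module pose from one fiducial cluster.

    The observed triangle corners are identified (hypotenuse = longest
    side, right angle opposite it) and matched to the model triangle using
    the 20-vs-15 mm leg asymmetry; a three-point Procrustes fit then gives
    the rigid pose.  The fit is validated against the inward normal and
    the residual bound.

    Raises
    ------
    LegAmbiguityError
        When the observed leg-length ratio is within ``leg_ratio_tol`` of 1.
    PoseFitError
        When the corner residual RMS exceeds ``residual_max`` mm, or the
        recovered orientation contradicts the inward normal.
    """
    normal = np.asarray(normal, dtype=np.float64).reshape(3)
    centroid, axes = principal_axes(cluster.points)
    corners = triangle_corners(cluster.points, centroid, axes)

    sides = np.array(
        [
            np.linalg.norm(corners[1] - corners[2]),  # opposite corner 0
            np.linalg.norm(corners[0] - corners[2]),
            np.linalg.norm(corners[0] - corners[1]),
        ]
    )
    right_idx = int(np.argmax(sides))  # corner opposite the hypotenuse
    others = [i for i in range(3) if i != right_idx]
    a = corners[right_idx]
    legs = {i: float(np.linalg.norm(corners[i] - a)) for i in others}
    (i1, l1), (i2, l2) = sorted(legs.items(), key=lambda kv: kv[1])
    if l1 <= 0 or abs(l2 / l1 - 1.0) <= leg_ratio_tol:
        raise LegAmbiguityError(
            f"observed leg lengths {l1:.2f}/{l2:.2f} mm too symmetric to orient"
        )
    b = corners[i2]  # long (vertical) leg end
    c = corners[i1]  # short (horizontal) leg end

    # chirality check: as seen from outside the head, x cross y must point out
    observed_out = np.cross(c - a, b - a)
    if float(np.dot(observed_out, normal)) > 0:
        raise PoseFitError(
            "observed triangle chirality contradicts the inward normal"
        )

    model = geometry.triangle_vertices
    rot, t = _kabsch(model, np.stack([a, b, c]))
    posed = model @ rot.T + t
    residual = float(
        np.sqrt(np.mean(np.sum((posed - np.stack([a, b, c])) ** 2, axis=1)))
    )
    if residual > residual_max:
        raise PoseFitError(
            f"model-triangle fit residual {residual:.2f} mm > {residual_max} mm"
        )
    return ModulePose(rot, t, residual_rms=residual)


def project_feet(pose: ModulePose, geometry: ModuleGeometry) -> np.ndarray:
    """Module foot tips in scan coordinates: R f + t for each foot offset."""
    return pose.apply(geometry.foot_offsets)


def build_sparse_sample(
    mesh: ColoredMesh,
    filter_spec: ColorFilterSpec = ColorFilterSpec(),
    geometry: ModuleGeometry | None = None,
    k: int = 17,
    seed: int = 0,
    diameter_bound: float = 50.0,
    restarts: int = 10,
    min_modules: int = 6,
    residual_max: float = 2.0,
) -> SparseScalpSample:
    """Full detection chain: filter -> cluster -> pose -> feet.

    Modules whose pose cannot be recovered are skipped with a logged
    warning; the run fails only when fewer than ``min_modules`` succeed.
    """
    geometry = geometry or ModuleGeometry()
    idx = filter_fiducial_vertices(mesh, filter_spec)
    logger.info("color filter kept %d of %d vertices", len(idx), mesh.n_vertices)
    if len(idx) < k:
        raise MinModulesError(
            f"only {len(idx)} fiducial vertices pass the color filter; "
            f"cannot form {k} clusters"
        )
    clusters = cluster_fiducials(
        mesh.vertices[idx],
        k=k,
        diameter_bound=diameter_bound,
        seed=seed,
        restarts=restarts,
        indices=idx,
    )
    logger.info("formed %d fiducial clusters", len(clusters))
    head_center = estimate_head_center([c.centroid for c in clusters])

    points, module_ids, poses = [], [], []
    n_failed = 0
    for ci, cluster in enumerate(clusters):
        try:
            centroid, axes = principal_axes(cluster.points)
            normal = inward_normal(axes, centroid, head_center)
            pose = align_module_model(
                cluster, geometry, normal, residual_max=residual_max
            )
        except (DegenerateClusterError, LegAmbiguityError, PoseFitError,
                AmbiguousNormalError) as exc:
            n_failed += 1
            logger.warning("module %d skipped: %s", ci, exc)
            continue
        feet = project_feet(pose, geometry)
        points.append(feet)
        module_ids.extend([ci] * len(feet))
        poses.append(pose)
    n_ok = len(poses)
    logger.info("posed %d modules (%d failed), %d foot points",
                n_ok, n_failed, 4 * n_ok)
    if n_ok < min_modules:
        raise MinModulesError(
            f"only {n_ok} modules posed successfully (< {min_modules})"
        )
    return SparseScalpSample(
        np.concatenate(points), np.asarray(module_ids), poses=poses
    )
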