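"""Geodesic 10-20 and modified 10-5 electrode montages on a head surface.

Positions are constructed from the four cranial landmarks with plane-slice
geodesics: a "geodesic" between two surface points is the intersection of
the mesh with the plane through the two points and a third reference point,
restricted to the arc passing nearest the reference.  The construction:

1. The vertex Cz is found by alternating the sagittal (nasion-inion) and
   coronal (LPA-RPA) curves until their midpoints coincide.
2. Midline points sit at arc-length fractions of the sagittal curve.
3. A circumferential ("ring") curve is sliced through Fpz, Oz and the
   ear-level points T7/T8 (10%/90% of the coronal curve).
4. Transverse rows connect same-latitude left/right ring points through the
   corresponding midline point; electrodes sit at arc fractions of the rows.

The modified 10-5 montage is the full 5%-resolution grid restricted to
positions on or above the ring: 17 latitudes x 17 stations = 289 labeled
positions.  The 289-label registry is frozen as a text resource shipped
with the package (``data/ten5_above_ears_labels.txt``); the exact
above-ear membership is this package's definition, fixed for
reproducibility.  The 21 standard 10-20 labels are an exact subset, so the
two montages nest by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import trimesh

from ._geometry import (
    SurfaceLocator,
    fit_plane,
    point_at_arclength,
    polyline_length,
    project_to_polyline,
    slice_polyline,
    unit,
)
from .exceptions import (
    CzConvergenceError,
    LandmarkError,
    MontageError,
    NoIntersectionError,
    OpenSurfaceError,
)
from .mesh_io import ColoredMesh, LandmarkSet

__all__ = [
    "SurfaceCurve",
    "MontagePointSet",
    "geodesic_curve",
    "fractional_point",
    "compute_1020",
    "compute_105_above_ears",
    "compute_montages",
    "TEN20_LABELS",
    "ten5_labels",
]

ROW_PREFIXES = [
    "Fp", "AFp", "AF", "AFF", "F", "FFC", "FC", "FCC", "C",
    "CCP", "CP", "CPP", "P", "PPO", "PO", "POO", "O",
]
LATITUDES = [0.10 + 0.05 * i for i in range(17)]

TEN20_LABELS = [
    "Fp1", "Fpz", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]

_RING_OVERRIDES_LEFT = {0: "Fp1", 8: "T7", 16: "O1"}
_RING_OVERRIDES_RIGHT = {0: "Fp2", 8: "T8", 16: "O2"}

_EXPECTED_COUNTS = {"ten20": 21, "ten5_above_ears": 289}


def _column_label(prefix: str, k: int, edge_row: bool = False) -> str:
    """Label of row station k (0..16 left-to-right; 8 is the midline).

    Left hemisphere takes odd numbers, right even, ``h`` marks the 5%
    intermediates.  On the front/back edge rows (Fp, O) the canonical
    Fp1/Fp2/O1/O2 sit at the row ends (on the circumferential curve), so
    interior numbering starts one step further out.
    """
    j = k - 8
    if j == 0:
        return prefix + "z"
    m = abs(j)
    if j < 0:  # left hemisphere
        if m % 2 == 1:
            return f"{prefix}{m}h"
        return f"{prefix}{m + 1}" if edge_row else f"{prefix}{m - 1}"
    if m % 2 == 1:
        return f"{prefix}{m + 1}h"
    return f"{prefix}{m + 2}" if edge_row else f"{prefix}{m}"


def ten5_labels() -> list[str]:
    """The frozen 289-label registry, in row-major (front-to-back,
    left-to-right) order."""
    labels = []
    for i, prefix in enumerate(ROW_PREFIXES):
        for k in range(17):
            if k == 0:
                labels.append(_RING_OVERRIDES_LEFT.get(i, prefix + "7"))
            elif k == 16:
                labels.append(_RING_OVERRIDES_RIGHT.get(i, prefix + "8"))
            else:
                labels.append(_column_label(prefix, k, edge_row=i in (0, 16)))
    return labels


def _load_registry() -> list[str]:
    try:
        text = (
            resources.files("capmorph").joinpath("data/ten5_above_ears_labels.txt")
        ).read_text()
        return [ln.strip() for ln in text.splitlines() if ln.strip()]
    except FileNotFoundError:  # pragma: no cover - resource ships with the code
        return ten5_labels()


@dataclass
class SurfaceCurve:
    """A polyline lying on the mesh surface, with arc-length access."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.atleast_2d(np.asarray(self.points, dtype=np.float64))

    @property
    def length(self) -> float:
        return polyline_length(self.points)

    def point_at(self, fraction: float) -> np.ndarray:
        return point_at_arclength(self.points, fraction * self.length)


def fractional_point(curve: SurfaceCurve, fraction: float) -> np.ndarray:
    """Point at arc-length ``fraction`` in [0, 1] along the curve."""
    return curve.point_at(fraction)


@dataclass
class MontagePointSet:
    """Labeled electrode positions on one surface."""

    labels: list
    positions: np.ndarray
    montage_id: str

    def __post_init__(self):
        self.labels = list(self.labels)
        self.positions = np.asarray(self.positions, dtype=np.float64).reshape(-1, 3)
        if len(self.labels) != len(self.positions):
            raise ValueError("labels/positions length mismatch")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate montage labels")
        expected = _EXPECTED_COUNTS.get(self.montage_id)
        if expected is not None and len(self.labels) != expected:
            raise ValueError(
                f"montage {self.montage_id!r} must have {expected} labels, "
                f"got {len(self.labels)}"
            )

    def as_dict(self) -> dict:
        return dict(zip(self.labels, self.positions))

    def subset(self, labels) -> "MontagePointSet":
        d = self.as_dict()
        return MontagePointSet(
            list(labels), np.stack([d[l] for l in labels]), montage_id="subset"
        )

    def to_file(self, path) -> None:
        lines = [
            f"{l} {p[0]:.9f} {p[1]:.9f} {p[2]:.9f}"
            for l, p in zip(self.labels, self.positions)
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path, montage_id: str = "subset") -> "MontagePointSet":
        labels, pos = [], []
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            parts = ln.split()
            labels.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
        return cls(labels, np.asarray(pos), montage_id)


# ---------------------------------------------------------------------------
# Plane-slice geodesics
# ---------------------------------------------------------------------------

def _slice_paths(tm: trimesh.Trimesh, normal, origin) -> list:
    segments = trimesh.intersections.mesh_plane(
        tm, plane_normal=normal, plane_origin=origin
    )
    if len(segments) == 0:
        raise NoIntersectionError("slicing plane does not intersect the mesh")
    path = trimesh.load_path(segments)
    return [np.asarray(d, dtype=np.float64) for d in path.discrete]


def _best_loop(paths: list, a: np.ndarray, b: np.ndarray):
    """The slice component nearest both endpoints."""
    best, best_cost = None, np.inf
    for pts in paths:
        _, _, da = project_to_polyline(pts, a)
        _, _, db = project_to_polyline(pts, b)
        if da + db < best_cost:
            best_cost, best = da + db, pts
    return best, best_cost


def _arc_on_loop(loop: np.ndarray, a, b, through) -> np.ndarray:
    """Arc of a slice curve from a to b passing nearest ``through``."""
    closed = np.linalg.norm(loop[0] - loop[-1]) < 1e-9
    pts = loop[:-1] if closed else loop
    cyc = np.vstack([pts, pts[0]]) if closed else pts
    total = polyline_length(cyc)
    _, sa, _ = project_to_polyline(cyc, a)
    _, sb, _ = project_to_polyline(cyc, b)

    def forward(s0, s1):
        if s1 >= s0:
            return slice_polyline(cyc, s0, s1)
        if not closed:
            return None
        head = slice_polyline(cyc, s0, total)
        tail = slice_polyline(cyc, 0.0, s1)
        return np.vstack([head, tail[1:]])

    candidates = [arc for arc in (forward(sa, sb), forward(sb, sa)) if arc is not None]
    if not candidates:
        raise OpenSurfaceError("slice curve is open between the endpoints")
    # orient every candidate from a to b
    oriented = []
    for arc in candidates:
        if np.linalg.norm(arc[0] - a) > np.linalg.norm(arc[-1] - a):
            arc = arc[::-1]
        oriented.append(arc)
    if len(oriented) == 1:
        return oriented[0]
    through = np.asarray(through, dtype=np.float64)
    dists = [
        np.min(np.linalg.norm(arc - through, axis=1)) for arc in oriented
    ]
    return oriented[int(np.argmin(dists))]


def geodesic_curve(
    mesh: ColoredMesh | trimesh.Trimesh,
    a,
    b,
    through,
) -> SurfaceCurve:
    """Plane-slice geodesic from ``a`` to ``b``.

    The curve is the intersection of the mesh with the plane containing
    ``a``, ``b`` and ``through``, restricted to the arc passing nearest
    ``through``.  ``a == b`` yields a zero-length curve.
    """
    tm = mesh.as_trimesh() if isinstance(mesh, ColoredMesh) else mesh
    a = np.asarray(a, dtype=np.float64).reshape(3)
    b = np.asarray(b, dtype=np.float64).reshape(3)
    through = np.asarray(through, dtype=np.float64).reshape(3)
    if np.linalg.norm(a - b) < 1e-12:
        return SurfaceCurve(a[None])
    n = np.cross(b - a, through - a)
    if np.linalg.norm(n) < 1e-9:
        raise MontageError("a, b and the reference point are collinear")
    paths = _slice_paths(tm, unit(n), a)
    loop, cost = _best_loop(paths, a, b)
    scale = float(np.ptp(tm.bounds)) if len(tm.vertices) else 1.0
    if cost > 0.1 * max(scale, 1.0):
        raise NoIntersectionError(
            "slicing plane misses the surface near the requested endpoints"
        )
    arc = _arc_on_loop(loop, a, b, through)
    # pin exact endpoints
    arc = np.vstack([a, arc[1:-1], b]) if len(arc) > 2 else np.vstack([a, b])
    return SurfaceCurve(arc)


# ---------------------------------------------------------------------------
# Montage grid construction
# ---------------------------------------------------------------------------

def _pinned_fraction_point(arcpts: np.ndarray, pin_s: float, frac: float) -> np.ndarray:
    """Point at combined fraction with an interior pin at arc length pin_s.

    ``frac`` in [0, 1]; the pin sits at frac = 0.5, and each half is
    parametrized by its own arc length.
    """
    total = polyline_length(arcpts)
    if frac <= 0.5:
        return point_at_arclength(arcpts, 2.0 * frac * pin_s)
    return point_at_arclength(arcpts, pin_s + (2.0 * frac - 1.0) * (total - pin_s))


class _MontageBuilder:
    def __init__(
        self,
        mesh: ColoredMesh,
        landmarks: LandmarkSet,
        cz_tol: float = 0.5,
        max_iter: int = 20,
        landmark_tol: float = 10.0,
    ):
        self.tm = mesh.as_trimesh()
        self.lm = landmarks
        self.cz_tol = cz_tol
        self.max_iter = max_iter
        loc = SurfaceLocator(self.tm)
        _, dists, _ = loc.query(landmarks.as_array())
        if dists.max() > landmark_tol:
            raise LandmarkError(
                f"landmark lies {dists.max():.1f} mm off the surface "
                f"(> {landmark_tol} mm)"
            )
        self._locator = loc

    # -- Cz ---------------------------------------------------------------
    def _initial_cz(self) -> np.ndarray:
        """Nasion-inion midpoint pushed to the surface along the head's
        up direction, (RPA - LPA) x (nasion - inion) (right-handed
        anatomical frame: x left->right, y back->front, z up)."""
        lm = self.lm
        up = unit(
            np.cross(
                lm.right_preauricular - lm.left_preauricular,
                lm.nasion - lm.inion,
            )
        )
        diag = float(np.linalg.norm(self.tm.bounds[1] - self.tm.bounds[0]))
        probe = 0.5 * (lm.nasion + lm.inion) + 1.5 * diag * up
        cz, _, _ = self._locator.query(probe)
        return cz[0]

    def find_cz(self):
        """Alternate sagittal/coronal midpoints until they coincide."""
        lm = self.lm
        cz = self._initial_cz()
        for _ in range(self.max_iter):
            sag = geodesic_curve(self.tm, lm.nasion, lm.inion, cz)
            cz_s = sag.point_at(0.5)
            cor = geodesic_curve(self.tm, lm.left_preauricular,
                                 lm.right_preauricular, cz_s)
            cz_new = cor.point_at(0.5)
            if np.linalg.norm(cz_new - cz_s) <= self.cz_tol:
                sag = geodesic_curve(self.tm, lm.nasion, lm.inion, cz_new)
                return cz_new, sag, cor
            cz = cz_new
        raise CzConvergenceError(
            f"Cz iteration did not converge in {self.max_iter} iterations"
        )

    # -- full grid ---------------------------------------------------------
    def build(self) -> dict:
        lm = self.lm
        cz, sag, cor = self.find_cz()
        midline = {w: sag.point_at(w) for w in LATITUDES}
        fpz, oz = midline[0.10], midline[0.90]
        t7 = cor.point_at(0.1)
        t8 = cor.point_at(0.9)

        # circumferential curve through Fpz, T7, Oz, T8 (least-squares plane)
        origin, normal = fit_plane(np.stack([fpz, t7, oz, t8]))
        paths = _slice_paths(self.tm, normal, origin)
        ring, _ = _best_loop(paths, fpz, oz)
        sides = {}
        for side, ear, ear_lm in (("L", t7, lm.left_preauricular),
                                  ("R", t8, lm.right_preauricular)):
            arc = _arc_on_loop(ring, fpz, oz, ear)
            # confirm the arc is on the requested hemisphere
            mid = point_at_arclength(arc, 0.5 * polyline_length(arc))
            other = t8 if side == "L" else t7
            if np.linalg.norm(mid - other) < np.linalg.norm(mid - ear):
                raise MontageError("ring arc landed on the wrong hemisphere")
            _, pin_s, _ = project_to_polyline(arc, ear)
            sides[side] = (arc, pin_s)

        def ring_point(side: str, v: float) -> np.ndarray:
            arc, pin_s = sides[side]
            return _pinned_fraction_point(arc, pin_s, v)

        grid: dict[str, np.ndarray] = {}
        for i, (w, prefix) in enumerate(zip(LATITUDES, ROW_PREFIXES)):
            left = ring_point("L", w)
            right = ring_point("R", w)
            mid = midline[w]
            grid[_RING_OVERRIDES_LEFT.get(i, prefix + "7")] = left
            grid[_RING_OVERRIDES_RIGHT.get(i, prefix + "8")] = right
            grid[prefix + "z"] = mid
            row = geodesic_curve(self.tm, left, right, mid)
            _, pin_s, _ = project_to_polyline(row.points, mid)
            for k in range(1, 16):
                if k == 8:
                    continue
                label = _column_label(prefix, k, edge_row=i in (0, 16))
                grid[label] = _pinned_fraction_point(row.points, pin_s, k / 16.0)
        grid["Cz"] = cz
        return grid


def _compute_grid(mesh: ColoredMesh, landmarks: LandmarkSet, **kw) -> dict:
    return _MontageBuilder(mesh, landmarks, **kw).build()


def compute_1020(mesh: ColoredMesh, landmarks: LandmarkSet, **kw) -> MontagePointSet:
    """The 21 international 10-20 positions on the mesh."""
    grid = _compute_grid(mesh, landmarks, **kw)
    return MontagePointSet(
        TEN20_LABELS, np.stack([grid[l] for l in TEN20_LABELS]), "ten20"
    )


def compute_105_above_ears(
    mesh: ColoredMesh, landmarks: LandmarkSet, **kw
) -> MontagePointSet:
    """The 289-point modified (above-the-ears) 10-5 montage."""
    grid = _compute_grid(mesh, landmarks, **kw)
    registry = _load_registry()
    return MontagePointSet(
        registry, np.stack([grid[l] for l in registry]), "ten5_above_ears"
    )


def compute_montages(mesh: ColoredMesh, landmarks: LandmarkSet, **kw):
    """Both montages from one grid construction (they nest exactly)."""
    grid = _compute_grid(mesh, landmarks, **kw)
    registry = _load_registry()
    ten20 = MontagePointSet(
        TEN20_LABELS, np.stack([grid[l] for l in TEN20_LABELS]), "ten20"
    )
    ten5 = MontagePointSet(
        registry, np.stack([grid[l] for l in registry]), "ten5_above_ears"
    )
    return ten20, ten5
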