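"""Shared low-level geometry helpers (internal).

Closest-point queries use a KD-tree over face centroids with exact
point-triangle distances on the candidate set, which keeps the package free
of optional spatial-index dependencies.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy.spatial import cKDTree


def unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero vector")
    return v / n


class SurfaceLocator:
    """Closest-point-on-surface queries for one triangle mesh."""

    def __init__(self, tm: trimesh.Trimesh, n_candidates: int = 24):
        self._triangles = np.asarray(tm.triangles, dtype=np.float64)
        self._tree = cKDTree(self._triangles.mean(axis=1))
        self._k = min(int(n_candidates), len(self._triangles))

    def query(self, points: np.ndarray):
        """Return (closest_points, distances, face_indices)."""
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        n = len(points)
        _, cand = self._tree.query(points, k=self._k)
        cand = np.atleast_2d(cand)
        tris = self._triangles[cand.ravel()]          # (n*k, 3, 3)
        rep = np.repeat(points, self._k, axis=0)      # (n*k, 3)
        nearest = trimesh.triangles.closest_point(tris, rep)
        d2 = ((nearest - rep) ** 2).sum(axis=1).reshape(n, self._k)
        best = d2.argmin(axis=1)
        rows = np.arange(n)
        closest = nearest.reshape(n, self._k, 3)[rows, best]
        faces = cand[rows, best]
        return closest, np.sqrt(d2[rows, best]), faces


def fit_plane(points: np.ndarray):
    """Least-squares plane through points: returns (origin, unit normal)."""
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    origin = points.mean(axis=0)
    _, _, vt = np.linalg.svd(points - origin, full_matrices=False)
    return origin, vt[2]


# ---------------------------------------------------------------------------
# Polyline helpers.  A polyline is an (n, 3) array of consecutive vertices.
# ---------------------------------------------------------------------------

def polyline_length(points: np.ndarray) -> float:
    points = np.asarray(points, dtype=np.float64)
    if len(points) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def cumulative_arclength(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=np.float64)
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def point_at_arclength(points: np.ndarray, s: float) -> np.ndarray:
    """Point at arc length ``s`` along the polyline (clamped to its ends)."""
    cum = cumulative_arclength(points)
    total = cum[-1]
    if total == 0:
        return points[0].copy()
    s = min(max(s, 0.0), total)
    i = int(np.searchsorted(cum, s, side="right") - 1)
    i = min(i, len(points) - 2)
    seg = cum[i + 1] - cum[i]
    t = 0.0 if seg == 0 else (s - cum[i]) / seg
    return points[i] * (1 - t) + points[i + 1] * t


def project_to_polyline(points: np.ndarray, p: np.ndarray):
    """Closest point on the polyline to ``p``.

    Returns (closest_point, arclength_position, distance).
    """
    points = np.asarray(points, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64).reshape(3)
    a = points[:-1]
    b = points[1:]
    ab = b - a
    denom = (ab * ab).sum(axis=1)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(((p - a) * ab).sum(axis=1) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    d2 = ((proj - p) ** 2).sum(axis=1)
    i = int(d2.argmin())
    cum = cumulative_arclength(points)
    seglen = np.linalg.norm(ab[i])
    return proj[i], float(cum[i] + t[i] * seglen), float(np.sqrt(d2[i]))


def insert_point(points: np.ndarray, s: float) -> np.ndarray:
    """Polyline with an explicit vertex inserted at arc length ``s``."""
    cum = cumulative_arclength(points)
    p = point_at_arclength(points, s)
    i = int(np.searchsorted(cum, s, side="right"))
    return np.vstack([points[:i], p, points[i:]])


def slice_polyline(points: np.ndarray, s0: float, s1: float) -> np.ndarray:
    """Sub-polyline between arc lengths s0 <= s1, with exact endpoints."""
    cum = cumulative_arclength(points)
    p0 = point_at_arclength(points, s0)
    p1 = point_at_arclength(points, s1)
    interior = points[(cum > s0 + 1e-12) & (cum < s1 - 1e-12)]
    return np.vstack([p0, interior, p1])
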