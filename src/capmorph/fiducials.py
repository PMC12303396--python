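"""Fiducial isolation: color filtering and per-module clustering.

Each cap module carries a bright red 3-4-5 right-triangle fiducial on top.
Scan vertices belonging to fiducials are isolated with joint thresholds on
the normalized red channel, HSV saturation and HSV hue (red straddles the
hue origin, so the hue test accepts both ends of the hue circle), then
partitioned into one cluster per module with seeded k-means constrained by
a maximum intra-cluster diameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist
from sklearn.cluster import KMeans

from .exceptions import InfeasibleClusteringError, TooFewPointsError
from .mesh_io import ColoredMesh

__all__ = [
    "ColorFilterSpec",
    "FiducialCluster",
    "rgb_to_hsv",
    "filter_fiducial_vertices",
    "cluster_fiducials",
]


@dataclass(frozen=True)
class ColorFilterSpec:
    """Thresholds of the red-fiducial color filter.

    A vertex passes when ``red >= red_min`` and ``saturation >= sat_min``
    and its hue is within ``hue_max`` of the hue origin on the [0, 1)
    circle (i.e. ``hue <= hue_max`` or ``hue >= 1 - hue_max``).
    """

    red_min: float = 0.5
    sat_min: float = 0.7
    hue_max: float = 0.1

    def __post_init__(self):
        for name in ("red_min", "sat_min", "hue_max"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class FiducialCluster:
    """One module's fiducial vertices.

    ``member_indices`` index into the scan's vertex array; ``points`` are
    the member coordinates in mm and ``centroid`` their mean.
    """

    member_indices: np.ndarray
    points: np.ndarray
    centroid: np.ndarray

    def __post_init__(self):
        self.member_indices = np.asarray(self.member_indices, dtype=np.int64)
        self.points = np.asarray(self.points, dtype=np.float64).reshape(-1, 3)
        self.centroid = np.asarray(self.centroid, dtype=np.float64).reshape(3)
        if len(self.points) < 3:
            raise ValueError("a fiducial cluster needs at least 3 members")

    @property
    def size(self) -> int:
        return len(self.points)

    def diameter(self) -> float:
        """Maximum pairwise member distance (mm)."""
        return float(pdist(self.points).max()) if len(self.points) > 1 else 0.0


def rgb_to_hsv(rgb: np.ndarray) -> np.ndarray:
    """Vectorized hexcone RGB -> HSV, all channels in [0, 1] (hue in [0, 1)).

    This is the single place the color model is computed; swapping the
    interpretation of "normalized color" only requires touching this
    routine and :func:`filter_fiducial_vertices`.
    """
    rgb = np.asarray(rgb, dtype=np.float64).reshape(-1, 3)
    maxc = rgb.max(axis=1)
    minc = rgb.min(axis=1)
    delta = maxc - minc
    sat = np.where(maxc > 0, delta / np.where(maxc > 0, maxc, 1.0), 0.0)
    hue = np.zeros(len(rgb))
    nz = delta > 0
    r, g, b = rgb[:, 0], rgb[:, 1], rgb[:, 2]
    d = np.where(nz, delta, 1.0)
    is_r = nz & (maxc == r)
    is_g = nz & ~is_r & (maxc == g)
    is_b = nz & ~is_r & ~is_g
    hue[is_r] = ((g - b)[is_r] / d[is_r]) % 6.0
    hue[is_g] = (b - r)[is_g] / d[is_g] + 2.0
    hue[is_b] = (r - g)[is_b] / d[is_b] + 4.0
    return np.column_stack([hue / 6.0, sat, maxc])


def filter_fiducial_vertices(
    mesh: ColoredMesh, spec: ColorFilterSpec = ColorFilterSpec()
) -> np.ndarray:
    """Indices of scan vertices passing the red/saturation/hue filter.

    An empty result is valid (a scan with no fiducials in view).
    """
    hsv = rgb_to_hsv(mesh.colors)
    hue, sat = hsv[:, 0], hsv[:, 1]
    red = mesh.colors[:, 0]
    keep = (
        (red >= spec.red_min)
        & (sat >= spec.sat_min)
        & ((hue <= spec.hue_max) | (hue >= 1.0 - spec.hue_max))
    )
    return np.flatnonzero(keep)


def cluster_fiducials(
    points: np.ndarray,
    k: int = 17,
    diameter_bound: float = 50.0,
    seed: int = 0,
    restarts: int = 10,
    indices: np.ndarray | None = None,
    min_members: int = 3,
) -> list[FiducialCluster]:
    """Partition filtered fiducial points into ``k`` per-module clusters.

    Seeded k-means (k-means++ initialization) is run with up to
    ``restarts`` independent initializations; a solution is accepted only
    if every cluster has at least ``min_members`` points and maximum
    pairwise diameter ``<= diameter_bound`` mm.

    Parameters
    ----------
    points : (n, 3) point coordinates, mm.
    indices : optional original vertex indices carried into the clusters
        (defaults to 0..n-1).

    Raises
    ------
    TooFewPointsError
        If fewer points than clusters.
    InfeasibleClusteringError
        If no admissible partition is found within the restart budget.
    """
    points = np.asarray(points, dtype=np.float64).reshape(-1, 3)
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(points) < max(k, 1):
        raise TooFewPointsError(
            f"{len(points)} points cannot form {k} clusters"
        )
    if indices is None:
        indices = np.arange(len(points))
    indices = np.asarray(indices, dtype=np.int64)

    rng = np.random.default_rng(seed)
    last_violation = ""
    for _ in range(max(1, int(restarts))):
        km = KMeans(
            n_clusters=k,
            n_init=1,
            init="k-means++",
            random_state=int(rng.integers(0, 2**31 - 1)),
        ).fit(points)
        labels = km.labels_
        clusters = []
        ok = True
        for c in range(k):
            members = np.flatnonzero(labels == c)
            if len(members) < min_members:
                ok, last_violation = False, f"cluster {c} has {len(members)} members"
                break
            pts = points[members]
            diam = pdist(pts).max() if len(pts) > 1 else 0.0
            if diam > diameter_bound:
                ok, last_violation = (
                    False,
                    f"cluster {c} diameter {diam:.1f} mm > {diameter_bound} mm",
                )
                break
            clusters.append(
                FiducialCluster(indices[members], pts, pts.mean(axis=0))
            )
        if ok:
            return clusters
    raise InfeasibleClusteringError(
        f"no {k}-partition within the {diameter_bound} mm diameter bound "
        f"after {restarts} restarts (last violation: {last_violation})"
    )
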