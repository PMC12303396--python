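"""Closed-form montage positions on an analytic sphere.

Independent oracle for the plane-slice montage construction: on a sphere
with ideal landmarks every curve is a circle, so each electrode position
follows from vector geometry alone (no meshes, no slicing code).
"""

import numpy as np

LATITUDES = [0.10 + 0.05 * i for i in range(17)]


def _circle_through(r, p1, p2, p3):
    """Circle = sphere(radius r, center 0) cut by the plane through
    p1, p2, p3.  Returns (center, radius, unit plane normal)."""
    n = np.cross(p2 - p1, p3 - p1)
    n = n / np.linalg.norm(n)
    d = np.dot(n, p1)
    center = d * n
    radius = np.sqrt(max(r * r - d * d, 0.0))
    return center, radius, n


def _arc_point(center, radius, normal, a, b, frac):
    """Point at angular fraction ``frac`` along the minor arc a -> b of the
    circle (center, radius, normal)."""
    ua = (a - center) / np.linalg.norm(a - center)
    ub = (b - center) / np.linalg.norm(b - center)
    ang = np.arctan2(np.dot(np.cross(ua, ub), normal), np.dot(ua, ub))
    t = frac * ang
    p = np.cos(t) * ua + np.sin(t) * np.cross(normal, ua)
    return center + radius * p


def sphere_grid(r=100.0):
    """All 17x17 grid positions, keyed like the package's label registry."""
    from capmorph.montage import (
        _RING_OVERRIDES_LEFT,
        _RING_OVERRIDES_RIGHT,
        ROW_PREFIXES,
        _column_label,
    )

    nasion = np.array([0.0, r, 0.0])
    cz = np.array([0.0, 0.0, r])

    def midline(w):  # polar angle w*pi from nasion along the sagittal circle
        t = w * np.pi
        return np.array([0.0, r * np.cos(t), r * np.sin(t)])

    z0 = r * np.sin(0.1 * np.pi)     # ring plane height
    r0 = r * np.cos(0.1 * np.pi)     # ring circle radius

    def ring(side, v):  # v in [0,1]: Fpz -> Oz along one side
        az = 0.5 * np.pi + (np.pi * v if side == "L" else -np.pi * v)
        return np.array([r0 * np.cos(az), r0 * np.sin(az), z0])

    grid = {}
    for i, (w, prefix) in enumerate(zip(LATITUDES, ROW_PREFIXES)):
        left, right, mid = ring("L", w), ring("R", w), midline(w)
        grid[_RING_OVERRIDES_LEFT.get(i, prefix + "7")] = left
        grid[_RING_OVERRIDES_RIGHT.get(i, prefix + "8")] = right
        grid[prefix + "z"] = mid
        center, radius, normal = _circle_through(r, left, mid, right)
        for k in range(1, 16):
            if k == 8:
                continue
            u = k / 16.0
            if u < 0.5:
                p = _arc_point(center, radius, normal, left, mid, 2 * u)
            else:
                p = _arc_point(center, radius, normal, mid, right, 2 * u - 1)
            grid[_column_label(prefix, k, edge_row=i in (0, 16))] = p
    return grid
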