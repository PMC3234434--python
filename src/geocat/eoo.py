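"""Extent of occurrence: convex hull of the projected points and its area.

The extent of occurrence (EOO, IUCN criterion B1) is the area of the
smallest convex polygon containing every occurrence site.  The hull is
computed with quickhull — a divide-and-conquer recursion that repeatedly
takes the point farthest from the current chord — and the area with the
shoelace formula in the planar equal-area frame.

The hull is *strict*: collinear boundary points are not reported as
vertices (the area is unaffected and the output is canonical).  Vertices
are returned counter-clockwise starting from the lowest-x point (ties
broken by lowest y).  Sets with fewer than three non-collinear distinct
points are degenerate and get EOO = 0; the rating module decides what that
means for a category.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: collinearity tolerance for cross products, km² (points within this signed
#: area of a chord are treated as on it)
_EPS = 1e-9


@dataclass
class EooResult:
    hull_vertices: np.ndarray  # (k, 2) CCW, first = lowest x then lowest y
    area_km2: float
    n_points_used: int
    degenerate: bool


def _cross(o, a, b) -> float:
    """2x signed area of triangle (o, a, b); >0 means b left of o->a."""
    return (a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0])


def _hull_side(points: np.ndarray, a, b, out: list) -> None:
    """Recursively collect hull vertices strictly left of chord a->b."""
    if len(points) == 0:
        return
    d = (b[0] - a[0]) * (points[:, 1] - a[1]) - (b[1] - a[1]) * (points[:, 0] - a[0])
    left = points[d > _EPS]
    if len(left) == 0:
        return
    dl = (b[0] - a[0]) * (left[:, 1] - a[1]) - (b[1] - a[1]) * (left[:, 0] - a[0])
    # farthest from the chord; np.argmax takes the lowest index on ties,
    # which is deterministic because the input was canonically sorted
    far = left[int(np.argmax(dl))]
    _hull_side(left, a, far, out)
    out.append((float(far[0]), float(far[1])))
    _hull_side(left, far, b, out)


def quickhull(points) -> np.ndarray:
    """Strict convex hull of 2-D points, CCW from the lowest-x vertex.

    Duplicates are removed first.  Collinear boundary points are excluded.
    A single point yields itself; two distinct points (or any fully
    collinear set) yield the two extreme points of the segment.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) == 0:
        raise ValueError("quickhull needs a non-empty (n, 2) point array")
    # canonical lexicographic sort makes tie-breaking deterministic
    pts = np.unique(pts, axis=0)  # sorts by (x, y) and deduplicates
    if len(pts) == 1:
        return pts.copy()

    lo, hi = pts[0], pts[-1]  # extreme in x (then y)
    d = (hi[0] - lo[0]) * (pts[:, 1] - lo[1]) - (hi[1] - lo[1]) * (pts[:, 0] - lo[0])
    if np.all(np.abs(d) <= _EPS):
        return np.array([lo, hi])  # fully collinear: segment endpoints

    upper: list = []
    lower: list = []
    _hull_side(pts, lo, hi, upper)   # points left of lo->hi
    _hull_side(pts, hi, lo, lower)   # points left of hi->lo
    ring = [tuple(lo)] + upper + [tuple(hi)] + lower
    hull = np.array(ring)
    # the left-of recursion yields a clockwise ring; flip to CCW, then
    # rotate the start to the lowest-x (then lowest-y) vertex
    x, y = hull[:, 0], hull[:, 1]
    signed2 = float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    if signed2 < 0:
        hull = hull[::-1]
    start = int(np.lexsort((hull[:, 1], hull[:, 0]))[0])
    return np.roll(hull, -start, axis=0)


def polygon_area(vertices) -> float:
    """Shoelace area of a simple polygon; 0 for fewer than 3 vertices."""
    v = np.asarray(vertices, dtype=float)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def compute_eoo(projected) -> EooResult:
    """EOO of a projected point set: quickhull + shoelace area."""
    if len(projected) == 0:
        raise ValueError("no visible points")
    hull = quickhull(projected.xy)
    area = polygon_area(hull)
    return EooResult(
        hull_vertices=hull,
        area_km2=area,
        n_points_used=len(projected),
        degenerate=len(hull) < 3,
    )
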