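import math

import numpy as np
import pytest

from geocat import GeoCatProject, Occurrence, OccurrenceSet
from geocat.projection import AUTHALIC_RADIUS_KM


def make_square_set(side_km: float = 4.0, base_lat: float = 0.0,
                    base_lon: float = 30.0, taxon: str = "Quadrata exempli") -> OccurrenceSet:
    """Four occurrences whose projected images form a side_km square.

    Latitude spacing uses asin (y = R sin(lat)), longitude spacing the arc
    formula, so in the data-centred equal-area frame the hull area is
    side_km**2 regardless of the standard parallel.
    """
    dlat = math.degrees(math.asin(side_km / AUTHALIC_RADIUS_KM)) if base_lat == 0.0 else \
        math.degrees(math.asin(side_km / AUTHALIC_RADIUS_KM + math.sin(math.radians(base_lat)))) - base_lat
    dlon = math.degrees(side_km / AUTHALIC_RADIUS_KM)
    occs = [
        Occurrence(id="sw", lat=base_lat, lon=base_lon),
        Occurrence(id="se", lat=base_lat, lon=base_lon + dlon),
        Occurrence(id="nw", lat=base_lat + dlat, lon=base_lon),
        Occurrence(id="ne", lat=base_lat + dlat, lon=base_lon + dlon),
    ]
    return OccurrenceSet(taxon_name=taxon, occurrences=occs)


@pytest.fixture
def square_set() -> OccurrenceSet:
    return make_square_set()


@pytest.fixture
def square_project(square_set) -> GeoCatProject:
    return GeoCatProject(taxon_name=square_set.taxon_name, occurrence_set=square_set)


def gift_wrap_hull(points: np.ndarray) -> np.ndarray:
    """Independent O(n*h) convex-hull oracle (Jarvis march), strict vertices,
    CCW from the lowest-x (then lowest-y) point."""
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) == 1:
        return pts.copy()
    start = pts[0]  # lexicographic minimum
    hull = [tuple(start)]
    current = start
    while True:
        candidate = None
        for p in pts:
            if np.array_equal(p, current):
                continue
            if candidate is None:
                candidate = p
                continue
            cross = ((candidate[0] - current[0]) * (p[1] - current[1])
                     - (candidate[1] - current[1]) * (p[0] - current[0]))
            if cross < 0:
                candidate = p
            elif cross == 0:
                # collinear: keep the farther one (strict hull)
                if (np.hypot(*(p - current)) > np.hypot(*(candidate - current))):
                    candidate = p
        if np.array_equal(candidate, start):
            break
        hull.append(tuple(candidate))
        current = candidate
        if len(hull) > len(pts):  # safety against degenerate loops
            break
    arr = np.array(hull)
    if len(arr) == 2 or (len(arr) > 2 and _collinear(arr)):
        lo, hi = arr[np.lexsort((arr[:, 1], arr[:, 0]))][[0, -1]]
        return np.array([lo, hi])
    return arr


def _collinear(arr: np.ndarray) -> bool:
    a, b = arr[0], arr[1]
    d = (b[0] - a[0]) * (arr[:, 1] - a[1]) - (b[1] - a[1]) * (arr[:, 0] - a[0])
    return bool(np.all(np.abs(d) <= 1e-9))
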