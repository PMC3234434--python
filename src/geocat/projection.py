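"""Equal-area projection of occurrence coordinates to a planar km frame.

Range areas are reported in km², so hull and grid geometry must be computed
in an equal-area plane, not in raw degrees.  We use a cylindrical equal-area
projection on the authalic sphere, centred per dataset: the central meridian
``lon0`` is the midpoint of the (seam-recentred) longitude range and the
standard parallel ``lat_ts`` is the mean latitude of the visible points, so
shape distortion is smallest where the data are.

Forward mapping (λ, φ in degrees, output km)::

    x = R · radians(λ − λ0) · cos(φ_ts)
    y = R · sin(φ) / cos(φ_ts)

with R the authalic Earth radius.  The Jacobian of this map is constant and
equal to 1 on the model sphere, so planar polygon areas equal spherical
areas exactly — the property EOO/AOO need.

Point sets that straddle the ±180° seam are recentred by rotating
longitudes through the largest empty gap; sets spanning ≥ 180° of longitude
are refused, as no planar hull is meaningful at that extent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Authalic Earth radius in km (sphere with Earth's surface area).
AUTHALIC_RADIUS_KM = 6371.0072


@dataclass(frozen=True)
class ProjectionParams:
    lon0: float
    lat_ts: float
    R: float = AUTHALIC_RADIUS_KM


@dataclass
class ProjectedPointSet:
    """Visible occurrence coordinates in the planar km frame."""

    ids: list
    xy: np.ndarray  # shape (n, 2), km
    params: ProjectionParams

    def __len__(self) -> int:
        return len(self.ids)


def _wrap_lon(lon):
    """Wrap longitudes into [-180, 180)."""
    return (np.asarray(lon, dtype=float) + 180.0) % 360.0 - 180.0


def _recenter_lons(lons: np.ndarray) -> np.ndarray:
    """Shift longitudes so the set does not straddle the antimeridian.

    Finds the largest empty circular gap between sorted longitudes and cuts
    the circle there, then unwraps so all values lie in one contiguous
    interval.  Raises if the occupied arc spans >= 180 degrees.
    """
    lons = _wrap_lon(lons)
    uniq = np.unique(lons)
    if uniq.size == 1:
        return lons
    gaps = np.diff(uniq)
    wrap_gap = uniq[0] + 360.0 - uniq[-1]
    k = int(np.argmax(gaps))
    if wrap_gap >= gaps[k]:
        # the empty arc crosses the seam: values are already contiguous
        extent = 360.0 - wrap_gap
        shifted = lons
    else:
        # cut at the largest interior gap; the arc starts at uniq[k+1]
        extent = 360.0 - gaps[k]
        shifted = np.where(lons <= uniq[k], lons + 360.0, lons)
    if extent >= 180.0:
        raise ValueError("longitudinal range too wide for planar analysis (>= 180 degrees)")
    return shifted


def forward(lat, lon, params: ProjectionParams):
    """Project degrees to planar km; vectorised."""
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    c = math.cos(math.radians(params.lat_ts))
    dlon = (lon - params.lon0 + 180.0) % 360.0 - 180.0
    x = params.R * np.radians(dlon) * c
    y = params.R * np.sin(np.radians(lat)) / c
    return x, y


def inverse(x, y, params: ProjectionParams):
    """Planar km back to degrees; exact inverse of :func:`forward`."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    c = math.cos(math.radians(params.lat_ts))
    lon = params.lon0 + np.degrees(x / (params.R * c))
    lat = np.degrees(np.arcsin(np.clip(y * c / params.R, -1.0, 1.0)))
    return lat, _wrap_lon(lon)


def project_points(occ_set) -> ProjectedPointSet:
    """Project the visible occurrences of a set into the planar km frame.

    Only visible records with in-range coordinates participate.  Raises if
    none qualify or the set spans >= 180 degrees of longitude.
    """
    # longitudes are wrapped into [-180, 180) here, so adding 360 to every
    # longitude changes nothing; latitude must be physically valid
    vis = [o for o in occ_set.visible_occurrences()
           if o.has_coords() and -90.0 <= o.lat <= 90.0 and math.isfinite(o.lon)]
    if not vis:
        raise ValueError("no visible occurrences with valid coordinates")
    lats = np.array([o.lat for o in vis], dtype=float)
    lons = np.array([o.lon for o in vis], dtype=float)

    unwrapped = _recenter_lons(lons)
    lon0 = _wrap_lon((unwrapped.min() + unwrapped.max()) / 2.0).item()
    lat_ts = float(np.mean(lats))
    if abs(lat_ts) > 89.999:
        raise ValueError("mean latitude too close to a pole for a cylindrical frame")
    params = ProjectionParams(lon0=lon0, lat_ts=lat_ts)
    x, y = forward(lats, lons, params)
    return ProjectedPointSet(ids=[o.id for o in vis],
                             xy=np.column_stack([x, y]),
                             params=params)
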