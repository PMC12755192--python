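"""Spherical geometry kernels shared by the trait metrics.

All distances are great-circle (haversine) on a sphere of radius
``EARTH_RADIUS_M`` = 6,371,000 m. Planar work (convex hulls, areas) is done
in a local Lambert azimuthal equal-area projection centred per point set,
which preserves areas — the property that matters for range-size polygons —
and keeps distortion negligible at home-range scale.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0
#: metres per degree of arc on the reference sphere (pi * R / 180)
M_PER_DEG = EARTH_RADIUS_M * np.pi / 180.0


def great_circle_distance(
    lon1, lat1, lon2, lat2, radius_m: float = EARTH_RADIUS_M
):
    """Haversine distance in metres between (lon1, lat1) and (lon2, lat2).

    Accepts scalars or numpy arrays (broadcasting); coordinates in decimal
    degrees. Symmetric, zero iff the points coincide.
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * radius_m * np.arcsin(np.minimum(1.0, np.sqrt(a)))
    if np.ndim(d) == 0:
        return float(d)
    return d


def azimuthal_equal_area(lon, lat, lon0: float, lat0: float,
                         radius_m: float = EARTH_RADIUS_M):
    """Project lon/lat (degrees) to a Lambert azimuthal equal-area plane
    centred at (lon0, lat0); returns (x, y) in metres.

    Valid everywhere except the antipode of the centre; inputs within a few
    hundred km of the centre have sub-metre-scale distortion.
    """
    lam = np.radians(np.asarray(lon, dtype=float) - lon0)
    phi = np.radians(np.asarray(lat, dtype=float))
    phi0 = np.radians(lat0)
    denom = 1.0 + np.sin(phi0) * np.sin(phi) + np.cos(phi0) * np.cos(phi) * np.cos(lam)
    if np.any(denom <= 1e-12):
        raise ValueError("point antipodal to projection centre")
    k = np.sqrt(2.0 / denom)
    x = radius_m * k * np.cos(phi) * np.sin(lam)
    y = radius_m * k * (np.cos(phi0) * np.sin(phi) - np.sin(phi0) * np.cos(phi) * np.cos(lam))
    return x, y


def unit_vector_mean(lon, lat):
    """Spherical mean of points: average of unit vectors, renormalised,
    returned as (lon, lat) in degrees. Antimeridian-safe.

    Raises ValueError when the mean vector is (numerically) zero, i.e. the
    points are balanced around the globe and no mean direction exists.
    """
    lam = np.radians(np.asarray(lon, dtype=float))
    phi = np.radians(np.asarray(lat, dtype=float))
    x = np.mean(np.cos(phi) * np.cos(lam))
    y = np.mean(np.cos(phi) * np.sin(lam))
    z = np.mean(np.sin(phi))
    norm = np.sqrt(x * x + y * y + z * z)
    if norm < 1e-12:
        raise ValueError("degenerate spherical mean: points cancel out")
    return float(np.degrees(np.arctan2(y, x))), float(np.degrees(np.arcsin(z / norm)))
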