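"""Great-circle geometry on a spherical Earth.

All distances use the haversine formula on a sphere of radius 6371 km; at the
sub-300-km ranges of central-place foraging trips the spherical error is
negligible. Positions may also be propagated on a local east/north tangent
plane anchored at a colony and converted back to latitude/longitude.
"""

from __future__ import annotations

import numpy as np

EARTH_RADIUS_M = 6_371_000.0


def _validate_latlon(lat, lon) -> None:
    lat = np.asarray(lat, dtype=float)
    lon = np.asarray(lon, dtype=float)
    if not (np.all(np.abs(lat) <= 90.0) and np.all(np.abs(lon) <= 180.0)):
        raise ValueError("coordinates outside [-90, 90] x [-180, 180]")
    if np.any(~np.isfinite(lat)) or np.any(~np.isfinite(lon)):
        raise ValueError("non-finite coordinates")


def haversine_m(lat1, lon1, lat2, lon2):
    """Great-circle distance in metres between points in decimal degrees.

    Symmetric and non-negative; accepts scalars or broadcastable arrays.
    """
    _validate_latlon(lat1, lon1)
    _validate_latlon(lat2, lon2)
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float))
                      for x in (lat1, lon1, lat2, lon2))
    dphi = p2 - p1
    dlam = l2 - l1
    a = np.sin(dphi / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    return 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(a))


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Initial great-circle bearing from point 1 to point 2.

    Radians, clockwise from true north, in (-pi, pi].
    """
    p1, l1, p2, l2 = (np.radians(np.asarray(x, dtype=float))
                      for x in (lat1, lon1, lat2, lon2))
    dlam = l2 - l1
    y = np.sin(dlam) * np.cos(p2)
    x = np.cos(p1) * np.sin(p2) - np.sin(p1) * np.cos(p2) * np.cos(dlam)
    return np.arctan2(y, x)


def wrap_angle(a):
    """Wrap angles (radians) into (-pi, pi]."""
    a = np.asarray(a, dtype=float)
    w = -((-a + np.pi) % (2.0 * np.pi) - np.pi)
    return w


def enu_to_latlon(lat0: float, lon0: float, x_east_m, y_north_m):
    """Convert local tangent-plane offsets (metres) at (lat0, lon0) to lat/lon."""
    lat = np.asarray(lat0, dtype=float) + np.degrees(np.asarray(y_north_m) / EARTH_RADIUS_M)
    lon = np.asarray(lon0, dtype=float) + np.degrees(
        np.asarray(x_east_m) / (EARTH_RADIUS_M * np.cos(np.radians(lat0)))
    )
    return lat, lon


def latlon_to_enu(lat0: float, lon0: float, lat, lon):
    """Inverse of :func:`enu_to_latlon` (small-offset approximation)."""
    y = np.radians(np.asarray(lat, dtype=float) - lat0) * EARTH_RADIUS_M
    x = np.radians(np.asarray(lon, dtype=float) - lon0) * EARTH_RADIUS_M * np.cos(np.radians(lat0))
    return x, y
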