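"""Distance and bearing computations.

Geographic grids use spherical great-circle formulas on the authalic
radius (6371.0088 km); cartesian grids use the planar metric with
coordinates already in km.  Bearings are degrees clockwise from north in
[0, 360).
"""

from __future__ import annotations

import numpy as np

from isomigrate.grid import CARTESIAN, GEOGRAPHIC

EARTH_RADIUS_KM = 6371.0088


def _check_crs(crs: str) -> None:
    if crs not in (CARTESIAN, GEOGRAPHIC):
        raise ValueError(f"unknown crs {crs!r}")


def great_circle_km(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Great-circle distance in km (haversine), vectorized."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_deg(lon1, lat1, lon2, lat2) -> np.ndarray:
    """Initial great-circle bearing from point 1 to point 2."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    x = np.sin(dlon) * np.cos(lat2)
    y = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(x, y)) % 360.0


def destination_point(lon, lat, bearing_deg, dist_km):
    """Point reached travelling ``dist_km`` on ``bearing_deg`` from (lon, lat)."""
    lat1 = np.radians(lat)
    lon1 = np.radians(lon)
    brg = np.radians(bearing_deg)
    delta = np.asarray(dist_km, dtype=float) / EARTH_RADIUS_KM
    lat2 = np.arcsin(
        np.sin(lat1) * np.cos(delta) + np.cos(lat1) * np.sin(delta) * np.cos(brg)
    )
    lon2 = lon1 + np.arctan2(
        np.sin(brg) * np.sin(delta) * np.cos(lat1),
        np.cos(delta) - np.sin(lat1) * np.sin(lat2),
    )
    lon2 = (np.degrees(lon2) + 540.0) % 360.0 - 180.0
    return lon2, np.degrees(lat2)


def planar_km(x1, y1, x2, y2) -> np.ndarray:
    return np.hypot(np.asarray(x2) - x1, np.asarray(y2) - y1)


def planar_bearing_deg(x1, y1, x2, y2) -> np.ndarray:
    """Bearing on the plane, degrees clockwise from +y (north)."""
    return np.degrees(np.arctan2(np.asarray(x2) - x1, np.asarray(y2) - y1)) % 360.0


def planar_destination(x, y, bearing_deg, dist_km):
    brg = np.radians(bearing_deg)
    return x + dist_km * np.sin(brg), y + dist_km * np.cos(brg)


def distance_km(x1, y1, x2, y2, crs: str) -> np.ndarray:
    """Distance between points in the metric of ``crs``."""
    _check_crs(crs)
    if crs == GEOGRAPHIC:
        return great_circle_km(x1, y1, x2, y2)
    return planar_km(x1, y1, x2, y2)


def bearing_deg(x1, y1, x2, y2, crs: str) -> np.ndarray:
    _check_crs(crs)
    if crs == GEOGRAPHIC:
        return initial_bearing_deg(x1, y1, x2, y2)
    return planar_bearing_deg(x1, y1, x2, y2)


def move(x, y, bearing, dist_km, crs: str):
    _check_crs(crs)
    if crs == GEOGRAPHIC:
        return destination_point(x, y, bearing, dist_km)
    return planar_destination(x, y, bearing, dist_km)


def pairwise_distance_matrix(xs, ys, crs: str) -> np.ndarray:
    """Symmetric n x n distance matrix between points."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    return distance_km(xs[:, None], ys[:, None], xs[None, :], ys[None, :], crs)
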