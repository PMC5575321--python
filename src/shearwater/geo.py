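"""Spherical geodesy primitives used throughout the package.

All distances and bearings are computed on a sphere of mean Earth radius
R = 6371.0088 km.  At trip scales (tens to hundreds of km) the discrepancy
with an ellipsoidal model is well below 0.5 %, far smaller than GPS noise
or any analysis scale in the pipeline.  Conventions:

* coordinates are WGS84 decimal degrees, longitude first;
* bearings are degrees clockwise from geographic north in [0, 360);
* turning angles are signed, clockwise positive, wrapped to (-180, 180].
"""

from __future__ import annotations

import warnings

import numpy as np

EARTH_RADIUS_M = 6_371_008.8


def wrap180(angle_deg):
    """Wrap angles (degrees) into (-180, 180]."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = -((-a + 180.0) % 360.0 - 180.0)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap360(angle_deg):
    """Wrap angles (degrees) into [0, 360)."""
    a = np.asarray(angle_deg, dtype=float)
    wrapped = a % 360.0
    return wrapped if wrapped.ndim else float(wrapped)


def geodesic_distance(lon1, lat1, lon2, lat2):
    """Great-circle distance in metres (haversine, vectorised)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float))
                              for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_M * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.ndim else float(d)


def initial_bearing(lon1, lat1, lon2, lat2, warn_degenerate: bool = False):
    """Initial great-circle bearing, degrees clockwise from north in [0, 360).

    Identical points have no defined bearing; 0 is returned (optionally with
    a warning) so downstream code never sees NaN.
    """
    lo1, la1, lo2, la2 = (np.radians(np.asarray(x, dtype=float))
                          for x in (lon1, lat1, lon2, lat2))
    dlon = lo2 - lo1
    y = np.sin(dlon) * np.cos(la2)
    x = np.cos(la1) * np.sin(la2) - np.sin(la1) * np.cos(la2) * np.cos(dlon)
    theta = np.degrees(np.arctan2(y, x))
    degenerate = (y == 0) & (x == 0)
    if np.any(degenerate):
        if warn_degenerate:
            warnings.warn("bearing between identical points is undefined; returning 0")
        theta = np.where(degenerate, 0.0, theta)
    b = wrap360(theta)
    return b if np.ndim(b) else float(b)


def destination_point(lon, lat, bearing_deg, distance_m):
    """Great-circle forward problem: point reached from (lon, lat)."""
    la1 = np.radians(np.asarray(lat, dtype=float))
    lo1 = np.radians(np.asarray(lon, dtype=float))
    brg = np.radians(np.asarray(bearing_deg, dtype=float))
    delta = np.asarray(distance_m, dtype=float) / EARTH_RADIUS_M
    la2 = np.arcsin(np.sin(la1) * np.cos(delta) + np.cos(la1) * np.sin(delta) * np.cos(brg))
    lo2 = lo1 + np.arctan2(np.sin(brg) * np.sin(delta) * np.cos(la1),
                           np.cos(delta) - np.sin(la1) * np.sin(la2))
    lon2, lat2 = np.degrees(lo2), np.degrees(la2)
    lon2 = wrap180(lon2)
    if np.ndim(lon2):
        return lon2, lat2
    return float(lon2), float(lat2)


class AzimuthalEquidistant:
    """Spherical azimuthal-equidistant projection about a centre point.

    Distances from the centre (and azimuths about it) are preserved exactly,
    which keeps a metric simplification tolerance meaningful at trip scale.
    Coordinates are metres, x east / y north of the centre.
    """

    def __init__(self, lon0: float, lat0: float):
        self.lon0 = float(lon0)
        self.lat0 = float(lat0)
        self._la0 = np.radians(lat0)
        self._lo0 = np.radians(lon0)

    def forward(self, lon, lat):
        lo = np.radians(np.asarray(lon, dtype=float))
        la = np.radians(np.asarray(lat, dtype=float))
        cos_c = (np.sin(self._la0) * np.sin(la)
                 + np.cos(self._la0) * np.cos(la) * np.cos(lo - self._lo0))
        c = np.arccos(np.clip(cos_c, -1.0, 1.0))
        # k -> 1 as c -> 0
        with np.errstate(invalid="ignore", divide="ignore"):
            k = np.where(c > 1e-12, c / np.sin(np.where(c > 1e-12, c, 1.0)), 1.0)
        x = EARTH_RADIUS_M * k * np.cos(la) * np.sin(lo - self._lo0)
        y = EARTH_RADIUS_M * k * (np.cos(self._la0) * np.sin(la)
                                  - np.sin(self._la0) * np.cos(la) * np.cos(lo - self._lo0))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_M
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_M
        c = np.hypot(x, y)
        safe_c = np.where(c > 1e-12, c, 1.0)
        la = np.arcsin(np.clip(np.cos(c) * np.sin(self._la0)
                               + np.where(c > 1e-12, y * np.sin(safe_c) / safe_c, 0.0)
                               * np.cos(self._la0), -1.0, 1.0))
        lo = self._lo0 + np.arctan2(x * np.sin(safe_c),
                                    safe_c * np.cos(self._la0) * np.cos(safe_c)
                                    - y * np.sin(self._la0) * np.sin(safe_c))
        lo = np.where(c > 1e-12, lo, self._lo0)
        la = np.where(c > 1e-12, la, self._la0)
        lon, lat = wrap180(np.degrees(lo)), np.degrees(la)
        if np.ndim(lon):
            return lon, lat
        return float(lon), float(lat)
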