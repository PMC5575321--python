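"""Solar position for day/night classification.

Implements the NOAA solar-calculator ephemeris (truncated VSOP-style series
as used in the NOAA Solar Calculator spreadsheet): accurate to well under
0.1 degrees of solar elevation over the satellite-GPS era, which places the
nautical-twilight boundary (elevation = -12 degrees) to well within a
5-minute fix interval.

Night is defined as the Sun more than 12 degrees below the horizon, i.e.
between the end of evening nautical twilight and the start of morning
nautical twilight.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

NAUTICAL_TWILIGHT_ELEVATION_DEG = -12.0


def _julian_day(times: pd.DatetimeIndex) -> np.ndarray:
    """Julian day (UT) from tz-aware or naive-UTC timestamps."""
    t = pd.DatetimeIndex(times)
    if t.tz is not None:
        t = t.tz_convert("UTC").tz_localize(None)
    epoch = np.datetime64("2000-01-01T12:00:00")
    days = (t.values - epoch) / np.timedelta64(1, "s") / 86400.0
    return 2451545.0 + days


def solar_elevation_deg(times, lon, lat) -> np.ndarray:
    """Apparent-free geometric solar elevation (degrees) at UTC `times`.

    `lon`, `lat` may be scalars or arrays broadcastable against `times`.
    Atmospheric refraction is ignored: the -12 degree twilight threshold is a
    geometric definition.
    """
    jd = _julian_day(pd.DatetimeIndex(np.atleast_1d(np.asarray(times, dtype="datetime64[ns]"))))
    T = (jd - 2451545.0) / 36525.0  # Julian centuries since J2000.0

    # Geometric mean longitude and anomaly of the Sun (degrees)
    L0 = np.mod(280.46646 + T * (36000.76983 + T * 0.0003032), 360.0)
    M = 357.52911 + T * (35999.05029 - 0.0001537 * T)
    Mr = np.radians(M)
    # Equation of centre and true longitude
    C = (np.sin(Mr) * (1.914602 - T * (0.004817 + 0.000014 * T))
         + np.sin(2 * Mr) * (0.019993 - 0.000101 * T)
         + np.sin(3 * Mr) * 0.000289)
    true_long = L0 + C
    omega = np.radians(125.04 - 1934.136 * T)
    app_long = np.radians(true_long - 0.00569 - 0.00478 * np.sin(omega))

    # Obliquity (corrected) and solar declination
    eps0 = (23.0 + (26.0 + (21.448 - T * (46.815 + T * (0.00059 - T * 0.001813))) / 60.0) / 60.0)
    eps = np.radians(eps0 + 0.00256 * np.cos(omega))
    decl = np.arcsin(np.sin(eps) * np.sin(app_long))

    # Equation of time (minutes)
    y = np.tan(eps / 2.0) ** 2
    L0r = np.radians(L0)
    eot = 4.0 * np.degrees(
        y * np.sin(2 * L0r) - 2.0 * 0.016708634 * np.sin(Mr)
        + 4.0 * 0.016708634 * y * np.sin(Mr) * np.cos(2 * L0r)
        - 0.5 * y * y * np.sin(4 * L0r)
        - 1.25 * 0.016708634 ** 2 * np.sin(2 * Mr))

    frac_day = np.mod(jd + 0.5, 1.0)  # fraction of UT day from midnight
    lon = np.asarray(lon, dtype=float)
    lat_r = np.radians(np.asarray(lat, dtype=float))
    # True solar time in minutes, then hour angle (degrees)
    tst = np.mod(frac_day * 1440.0 + eot + 4.0 * lon, 1440.0)
    ha = np.where(tst / 4.0 < 0.0, tst / 4.0 + 180.0, tst / 4.0 - 180.0)
    ha_r = np.radians(ha)

    cos_zenith = (np.sin(lat_r) * np.sin(decl)
                  + np.cos(lat_r) * np.cos(decl) * np.cos(ha_r))
    elev = 90.0 - np.degrees(np.arccos(np.clip(cos_zenith, -1.0, 1.0)))
    return elev


def is_night(times, lon, lat) -> np.ndarray:
    """Boolean night mask: solar elevation below -12 degrees."""
    return solar_elevation_deg(times, lon, lat) < NAUTICAL_TWILIGHT_ELEVATION_DEG
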