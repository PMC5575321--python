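"""Outbound and homing orientation metrics.

Covers the initial-orientation statistic (virtual vanishing bearing at a
10 km radius from the colony), the coastal/pelagic split of the homing
section at a 40 km coastline threshold, per-fix homeward deviations of
flight legs, track straightness, and homing departure timing.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .geo import geodesic_distance, initial_bearing, wrap180
from .track_io import CoastDistance, Trip

logger = logging.getLogger(__name__)


def radius_crossing(trip: Trip, radius_m: float) -> tuple[float, float, int, float] | None:
    """First outbound crossing of a colony-centred radius.

    Returns (lon, lat, index_of_first_outside_fix, fraction_along_leg) with
    the crossing point located by linear interpolation within the crossing
    leg, or None when the trip never reaches the radius.
    """
    d = trip.colony_distance()
    outside = np.flatnonzero(d >= radius_m)
    if outside.size == 0:
        logger.info("trip %s never reaches %.0f m from colony", trip.trip_id, radius_m)
        return None
    i = int(outside[0])
    if i == 0:
        return float(trip.lon[0]), float(trip.lat[0]), 0, 0.0
    f = (radius_m - d[i - 1]) / (d[i] - d[i - 1])
    lon = trip.lon[i - 1] + f * (trip.lon[i] - trip.lon[i - 1])
    lat = trip.lat[i - 1] + f * (trip.lat[i] - trip.lat[i - 1])
    return float(lon), float(lat), i, float(f)


def outbound_vanishing_bearing(trip: Trip, radius_m: float = 10_000.0) -> float | None:
    """Bearing from the colony to the 10 km outbound crossing point.

    The virtual vanishing bearing: the compass direction (degrees clockwise
    from north) under which the bird 'vanished' from the colony as it first
    reached ``radius_m`` on the outward stage.  None when never reached.
    """
    crossing = radius_crossing(trip, radius_m)
    if crossing is None:
        return None
    lon, lat, _, _ = crossing
    return float(initial_bearing(trip.colony[0], trip.colony[1], lon, lat))


def coast_distance_at_radius(trip: Trip, coast: CoastDistance,
                             radius_m: float = 10_000.0) -> float | None:
    """Distance to the coastline at the outbound radius crossing point."""
    crossing = radius_crossing(trip, radius_m)
    if crossing is None:
        return None
    lon, lat, _, _ = crossing
    return float(coast(lon, lat)[0])


def phase_split(trip: Trip, onset_idx: int, coast: CoastDistance,
                threshold_m: float = 40_000.0) -> tuple[np.ndarray, np.ndarray]:
    """Split the homing section into pelagic and coastal fix indices.

    Pelagic: fixes from the homing onset up to (excluding) the first fix
    within ``threshold_m`` of the coastline; coastal: that fix to the end.
    A trip that never leaves the 40 km band has an empty pelagic phase and
    a coastal phase running from onset to arrival.  The two phases
    partition the homing indices exactly.
    """
    idx = np.arange(onset_idx, len(trip))
    d = coast(trip.lon[idx], trip.lat[idx])
    within = np.flatnonzero(d <= threshold_m)
    if within.size == 0:
        # never comes within the threshold (cannot happen for a trip ending
        # at a colony on the coast, but guard anyway)
        return idx, np.array([], dtype=int)
    split = int(within[0])
    return idx[:split], idx[split:]


def annotate_phase(trip: Trip, pelagic_idx, coastal_idx) -> Trip:
    out = trip.copy()
    phase = np.array([None] * len(trip), dtype=object)
    phase[np.asarray(pelagic_idx, dtype=int)] = "pelagic"
    phase[np.asarray(coastal_idx, dtype=int)] = "coastal"
    out.fixes["phase"] = phase
    return out


def homeward_deviation(trip: Trip, indices=None,
                       flight_state: str = "commute") -> pd.DataFrame:
    """Signed deviations of flight legs from the instantaneous home bearing.

    For each consecutive pair of fixes whose first member is labelled as
    directed flight, the deviation is the wrapped difference between the
    leg's bearing and the bearing from the fix to the colony: 0 means dead
    on course for home, positive clockwise, in (-180, 180].
    """
    f = trip.fixes
    if "state" not in f:
        raise ValueError("assign behavioural states before computing deviations")
    if indices is None:
        indices = np.arange(len(trip) - 1)
    indices = np.asarray(indices, dtype=int)
    indices = indices[indices < len(trip) - 1]
    state = f["state"].to_numpy(dtype=object)
    fly = np.array([state[i] == flight_state and state[i + 1] == flight_state
                    for i in indices], dtype=bool)
    idx = indices[fly] if indices.size else indices
    if idx.size == 0:
        return pd.DataFrame(columns=["trip_id", "fix_idx", "deviation_deg"])
    lon, lat = trip.lon, trip.lat
    b_leg = np.atleast_1d(initial_bearing(lon[idx], lat[idx], lon[idx + 1], lat[idx + 1]))
    b_home = np.atleast_1d(initial_bearing(lon[idx], lat[idx], *trip.colony))
    dev = np.atleast_1d(wrap180(b_leg - b_home))
    return pd.DataFrame({"trip_id": trip.trip_id, "fix_idx": idx,
                         "deviation_deg": dev})


def straightness(trip: Trip, start_idx: int, end_idx: int) -> float:
    """Straightness index of a track section: beeline / path length.

    1 for a perfectly straight section, approaching 0 for convoluted or
    out-and-back sections.  (The ratio is taken this way round so it is
    bounded by 1, consistent with reported straightness values of directed
    homing flight in the 0.85-0.95 range.)
    """
    if end_idx - start_idx < 1:
        raise ValueError("section needs at least 2 fixes")
    lon = trip.lon[start_idx:end_idx + 1]
    lat = trip.lat[start_idx:end_idx + 1]
    path = float(np.sum(geodesic_distance(lon[:-1], lat[:-1], lon[1:], lat[1:])))
    if path <= 0:
        raise ValueError("zero path length: straightness undefined")
    beeline = float(geodesic_distance(lon[0], lat[0], lon[-1], lat[-1]))
    return beeline / path


def homing_departure_timing(trip_rows: pd.DataFrame) -> pd.DataFrame:
    """Qualifying rows for the homing-timing model: night arrivals only.

    Input: one row per trip with columns bird_id, treatment, trip_id,
    onset_time (UTC), onset_distance_m, arrival_night (bool).  Output keeps
    trips arriving at night and adds the onset time-of-day in decimal UTC
    hours — the response modelled against the distance to the colony at the
    start of homing.
    """
    qual = trip_rows[trip_rows["arrival_night"].astype(bool)].copy()
    if qual.empty:
        logger.info("no night-arrival trips for homing-timing analysis")
        return qual.assign(onset_tod_h=pd.Series(dtype=float))
    t = pd.to_datetime(qual["onset_time"])
    qual["onset_tod_h"] = (t.dt.hour + t.dt.minute / 60.0 + t.dt.second / 3600.0)
    return qual
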