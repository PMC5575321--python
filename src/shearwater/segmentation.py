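"""Behavioural segmentation of trips and homing-onset detection.

Trips are decomposed into behaviourally consistent units by classic
Douglas-Peucker polyline simplification: retained vertices mark changes in
behavioural consistency, and the runs between them are the segments.  The
decision to home is then found by scanning segments backwards from the
colony arrival and accumulating the maximal contiguous suffix of segments
that each make significant homeward progress; the onset is the start of the
earliest segment in that suffix.  Segmentation is blind to treatment by
construction: nothing in this module takes a treatment argument.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geo import AzimuthalEquidistant, geodesic_distance, initial_bearing, wrap180
from .track_io import Trip

logger = logging.getLogger(__name__)


@dataclass
class Segment:
    """A contiguous run of fixes between Douglas-Peucker breakpoints."""

    start_idx: int
    end_idx: int                    # inclusive
    net_displacement_m: float
    path_length_m: float
    net_homeward_gain_m: float      # decrease in colony distance start -> end
    mean_homeward_deviation_deg: float  # circular mean of leg deviations from home
    qualifies_homeward: bool = False


@dataclass
class HomingAnnotation:
    onset_idx: int | None
    onset_time: object | None
    colony_distance_at_onset_m: float | None
    reason: str = ""


def douglas_peucker_indices(x: np.ndarray, y: np.ndarray, tolerance: float) -> np.ndarray:
    """Indices of retained vertices of classic DP simplification.

    Iterative (stack-based) recursion on the planar polyline (x, y): the
    vertex of maximum perpendicular distance from the chord is retained if
    that distance exceeds ``tolerance``, and both halves are re-examined.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    n = len(x)
    keep = np.zeros(n, dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, n - 1)]
    while stack:
        i0, i1 = stack.pop()
        if i1 - i0 < 2:
            continue
        dx, dy = x[i1] - x[i0], y[i1] - y[i0]
        seg = np.hypot(dx, dy)
        xs, ys = x[i0 + 1:i1], y[i0 + 1:i1]
        if seg < 1e-12:  # closed chord: distance to the point itself
            d = np.hypot(xs - x[i0], ys - y[i0])
        else:
            d = np.abs(dy * (xs - x[i0]) - dx * (ys - y[i0])) / seg
        k = int(np.argmax(d))
        if d[k] > tolerance:
            j = i0 + 1 + k
            keep[j] = True
            stack.append((i0, j))
            stack.append((j, i1))
    return np.flatnonzero(keep)


def _segment_stats(trip: Trip, i0: int, i1: int) -> tuple[float, float, float, float]:
    lon, lat = trip.lon, trip.lat
    clon, clat = trip.colony
    net = geodesic_distance(lon[i0], lat[i0], lon[i1], lat[i1])
    path = float(np.sum(geodesic_distance(lon[i0:i1], lat[i0:i1],
                                          lon[i0 + 1:i1 + 1], lat[i0 + 1:i1 + 1])))
    d0 = geodesic_distance(lon[i0], lat[i0], clon, clat)
    d1 = geodesic_distance(lon[i1], lat[i1], clon, clat)
    gain = d0 - d1
    # leg-wise deviation from the instantaneous home bearing, circular mean
    b_leg = np.atleast_1d(initial_bearing(lon[i0:i1], lat[i0:i1], lon[i0 + 1:i1 + 1], lat[i0 + 1:i1 + 1]))
    b_home = np.atleast_1d(initial_bearing(lon[i0:i1], lat[i0:i1], clon, clat))
    dev = np.radians(wrap180(b_leg - b_home))
    mean_dev = float(np.degrees(np.arctan2(np.mean(np.sin(dev)), np.mean(np.cos(dev)))))
    return float(net), path, float(gain), mean_dev


def douglas_peucker_segments(trip: Trip, tolerance_m: float = 1000.0,
                             min_homeward_gain_m: float = 0.0,
                             max_homeward_deviation_deg: float = 60.0,
                             min_displacement_m: float = 1000.0,
                             min_homeward_efficiency: float = 0.4) -> list[Segment]:
    """Split a trip into inter-breakpoint segments via Douglas-Peucker.

    The track is projected into an azimuthal-equidistant plane about its
    centroid so the metric tolerance is meaningful, simplified with the
    given tolerance, and each inter-breakpoint run is summarised.  A segment
    qualifies as homeward ('significant homeward movement') when it

    * gains more than ``min_homeward_gain_m`` towards the colony,
    * points home on average (circular-mean leg deviation within
      ``max_homeward_deviation_deg``),
    * displaces at least ``min_displacement_m``, and
    * converts at least ``min_homeward_efficiency`` of its path length into
      homeward gain — directed flight achieves ~cos(deviation) here whereas
      foraging jitter and drift convert almost none of their path.
    """
    proj = AzimuthalEquidistant(float(np.mean(trip.lon)), float(np.mean(trip.lat)))
    x, y = proj.forward(trip.lon, trip.lat)
    idx = douglas_peucker_indices(np.asarray(x), np.asarray(y), tolerance_m)
    segments = []
    for i0, i1 in zip(idx[:-1], idx[1:]):
        net, path, gain, mean_dev = _segment_stats(trip, int(i0), int(i1))
        qualifies = (gain > min_homeward_gain_m
                     and abs(mean_dev) < max_homeward_deviation_deg
                     and net >= min_displacement_m
                     and gain >= min_homeward_efficiency * path)
        segments.append(Segment(int(i0), int(i1), net, path, gain, mean_dev,
                                qualifies))
    return segments


def homing_onset(trip: Trip, segments: list[Segment],
                 attendance_radius_m: float = 1000.0,
                 refine: bool = True,
                 refine_min_homeward_speed_ms: float = 3.0) -> HomingAnnotation:
    """Locate the decision to home by a backward scan over segments.

    Scanning from the last segment backwards, the maximal contiguous suffix
    in which every segment qualifies as homeward is accumulated; the trip's
    homing section starts with the earliest segment of that suffix.  Trips
    whose final fix is not at the colony raise; trips with no qualifying
    final segment return an empty annotation (the trip is excluded from
    homing analyses).

    Simplification breakpoints blur the exact turning point when movement
    near the turn happens to lie close to the homing chord, so with
    ``refine`` the onset is sharpened using the leg-wise homeward speed
    (homeward gain per unit time): directed homing sustains roughly the
    commuting speed times cos(deviation), whereas resting drift and
    foraging search cannot exceed their own (much lower) ground speed
    toward home.  Walking backward leg by leg from inside the homing
    suffix, a leg continues the walk if its homeward speed reaches
    ``refine_min_homeward_speed_ms``; a fast but off-course leg (a heading
    excursion while clearly in flight) is forgiven unless the previous leg
    was also off course; the first slow-ground-speed leg — movement that
    cannot be homing flight — ends the walk, and the onset is the fix just
    after the walk stops.
    """
    d_end = float(geodesic_distance(trip.lon[-1], trip.lat[-1], *trip.colony))
    if d_end > attendance_radius_m:
        raise ValueError(
            f"trip does not end at colony ({d_end:.0f} m > {attendance_radius_m:.0f} m)")
    suffix_start = None
    for k in range(len(segments) - 1, -1, -1):
        if segments[k].qualifies_homeward:
            suffix_start = k
        else:
            break
    if suffix_start is None:
        logger.info("trip %s: no homeward suffix found; excluded from homing analyses",
                    trip.trip_id)
        return HomingAnnotation(None, None, None, reason="no homeward segment suffix")
    first = segments[suffix_start]
    i = first.start_idx
    if refine:
        lon, lat = trip.lon, trip.lat
        d_col = geodesic_distance(lon, lat, *trip.colony)
        t = trip.fixes["time"].to_numpy()
        leg_s = (t[1:] - t[:-1]) / np.timedelta64(1, "s")
        ground_speed = geodesic_distance(lon[:-1], lat[:-1], lon[1:], lat[1:]) / leg_s
        homeward_speed = -np.diff(d_col) / leg_s
        homeward = homeward_speed >= refine_min_homeward_speed_ms
        flying = ground_speed >= refine_min_homeward_speed_ms
        # anchor at the arrival (certainly homing), skip the deceleration
        # legs at the colony, then walk; the stopping rule bounds the walk
        j = len(leg_s) - 1
        while j > 0 and not homeward[j]:
            j -= 1
        while j >= 0:
            if homeward[j] or (flying[j] and j >= 1 and homeward[j - 1]):
                j -= 1
            else:
                break
        i = j + 1
    return HomingAnnotation(
        onset_idx=i,
        onset_time=trip.fixes["time"].iloc[i],
        colony_distance_at_onset_m=float(
            geodesic_distance(trip.lon[i], trip.lat[i], *trip.colony)),
    )


def segments_table(trip: Trip, segments: list[Segment]):
    """Per-trip segment summary table (one row per segment)."""
    import pandas as pd
    rows = [{
        "trip_id": trip.trip_id,
        "start_time": trip.fixes["time"].iloc[s.start_idx],
        "end_time": trip.fixes["time"].iloc[s.end_idx],
        "start_idx": s.start_idx,
        "end_idx": s.end_idx,
        "net_displacement_m": s.net_displacement_m,
        "path_length_m": s.path_length_m,
        "net_homeward_gain_m": s.net_homeward_gain_m,
        "mean_homeward_deviation_deg": s.mean_homeward_deviation_deg,
        "qualifies_homeward": s.qualifies_homeward,
    } for s in segments]
    return pd.DataFrame(rows)
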