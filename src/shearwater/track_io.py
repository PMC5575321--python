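"""Reading, splitting and regularising central-place foraging tracks.

The on-disk format is a Movebank-style CSV of timestamped GPS fixes plus a
bird metadata table (treatment, deployment/retrieval masses and dates) and a
GeoJSON coastline.  In memory a deployment is a per-bird DataFrame of fixes
and a :class:`Trip` is one colony departure-to-return loop, carried as a
DataFrame with one row per fix and annotation columns added as the pipeline
progresses (``speed``, ``turn``, ``state``, ``night``, ``phase``).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from . import solar
from .geo import (AzimuthalEquidistant, geodesic_distance, initial_bearing,
                  wrap180)

logger = logging.getLogger(__name__)

TREATMENTS = ("control", "magnetic", "anosmic")

#: column aliases accepted for Movebank-style CSVs
_COLUMN_ALIASES = {
    "bird_id": ("individual-local-identifier", "individual_id", "bird_id", "id"),
    "time": ("timestamp", "time", "study-local-timestamp"),
    "lon": ("location-long", "lon", "longitude"),
    "lat": ("location-lat", "lat", "latitude"),
}


class TrackFormatError(ValueError):
    """A required column is missing or a file is malformed/empty."""


@dataclass
class Trip:
    """One foraging trip: ordered fixes of a single colony departure/return.

    ``fixes`` columns always include time (UTC), lon, lat, interpolated,
    gap (interpolated through a data gap longer than the configured
    threshold); downstream stages append speed, turn, state, night, phase.
    """

    bird_id: str
    treatment: str
    colony: tuple[float, float]  # (lon, lat)
    fixes: pd.DataFrame
    trip_id: str = ""
    interval_s: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise ValueError("a trip needs at least 2 fixes")
        t = self.fixes["time"].to_numpy()
        if not (np.diff(t) > np.timedelta64(0, "s")).all():
            raise ValueError("fix times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def times(self) -> pd.Series:
        return self.fixes["time"]

    @property
    def lon(self) -> np.ndarray:
        return self.fixes["lon"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self.fixes["lat"].to_numpy(dtype=float)

    def colony_distance(self) -> np.ndarray:
        """Great-circle distance of every fix from the colony (m)."""
        return geodesic_distance(self.lon, self.lat, self.colony[0], self.colony[1])

    def copy(self) -> "Trip":
        return replace(self, fixes=self.fixes.copy())


def _resolve_columns(df: pd.DataFrame) -> dict[str, str]:
    resolved = {}
    lowered = {c.lower(): c for c in df.columns}
    for canonical, aliases in _COLUMN_ALIASES.items():
        for alias in aliases:
            if alias in lowered:
                resolved[canonical] = lowered[alias]
                break
        else:
            raise TrackFormatError(
                f"missing required column {canonical!r} "
                f"(accepted names: {', '.join(aliases)})")
    return resolved


def read_tracks(path, metadata: pd.DataFrame | None = None) -> dict[str, pd.DataFrame]:
    """Read a Movebank-style CSV into one ordered track per bird.

    Rows with missing coordinates/timestamps or duplicated timestamps
    (within a bird) are dropped with a logged count.  Returns a dict
    mapping bird id to a DataFrame with columns time, lon, lat.
    """
    df = pd.read_csv(path)
    if df.empty:
        raise TrackFormatError(f"empty track file: {path}")
    cols = _resolve_columns(df)
    df = df.rename(columns={v: k for k, v in cols.items()})
    df["time"] = pd.to_datetime(df["time"], utc=True, format="mixed")
    n0 = len(df)
    df = df.dropna(subset=["time", "lon", "lat"])
    if (dropped := n0 - len(df)):
        logger.warning("dropped %d rows with missing fields", dropped)
    tracks: dict[str, pd.DataFrame] = {}
    for bird_id, g in df.groupby("bird_id", sort=False):
        g = g.sort_values("time", kind="stable")
        n_before = len(g)
        g = g.drop_duplicates(subset="time", keep="first")
        if (ndup := n_before - len(g)):
            logger.warning("bird %s: dropped %d duplicate timestamps", bird_id, ndup)
        tracks[str(bird_id)] = g[["time", "lon", "lat"]].reset_index(drop=True)
    if metadata is not None:
        known = set(metadata["bird_id"].astype(str))
        unknown = set(tracks) - known
        if unknown:
            logger.warning("tracks for birds absent from metadata: %s", sorted(unknown))
    return tracks


def read_metadata(path) -> pd.DataFrame:
    """Read the bird metadata table (treatment, masses, dates)."""
    meta = pd.read_csv(path)
    required = {"bird_id", "treatment"}
    if missing := required - set(meta.columns):
        raise TrackFormatError(f"metadata missing columns: {sorted(missing)}")
    meta["bird_id"] = meta["bird_id"].astype(str)
    bad = set(meta["treatment"]) - set(TREATMENTS)
    if bad:
        raise TrackFormatError(f"unknown treatment labels: {sorted(bad)}")
    for col in ("deploy_date", "first_departure_date", "retrieve_date"):
        if col in meta.columns:
            meta[col] = pd.to_datetime(meta[col], utc=True, format="mixed")
    return meta


def read_coastline(path) -> BaseGeometry:
    """Read a GeoJSON coastline into a shapely geometry (WGS84 degrees)."""
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in gj["features"]]
        if not geoms:
            raise TrackFormatError("coastline GeoJSON has no features")
        return unary_union(geoms)
    if gj.get("type") == "Feature":
        return shapely_shape(gj["geometry"])
    return shapely_shape(gj)


def split_trips(track: pd.DataFrame, colony: tuple[float, float],
                attendance_radius_m: float = 1000.0,
                min_duration_s: float = 3600.0,
                min_range_m: float = 2000.0,
                bird_id: str = "", treatment: str = "control") -> list[Trip]:
    """Split a multi-trip deployment into separate foraging trips.

    A trip is a maximal run of fixes outside the colony-attendance radius,
    bracketed by the last at-colony fix before departure and the first after
    return (so every trip starts and ends at the colony).  Excursions that
    last under ``min_duration_s`` or never exceed ``min_range_m`` from the
    colony are treated as colony loafing and discarded with a logged count.
    """
    if attendance_radius_m <= 0:
        raise ValueError("attendance_radius_m must be positive")
    d = geodesic_distance(track["lon"].to_numpy(), track["lat"].to_numpy(),
                          colony[0], colony[1])
    away = d > attendance_radius_m
    if not away.any():
        return []
    trips: list[Trip] = []
    n_discarded = 0
    # runs of consecutive True in `away`
    edges = np.flatnonzero(np.diff(away.astype(int)))
    starts = [i + 1 for i in edges if not away[i]] + ([0] if away[0] else [])
    ends = [i for i in edges if away[i]] + ([len(away) - 1] if away[-1] else [])
    starts.sort(); ends.sort()
    counter = 0
    for s, e in zip(starts, ends):
        i0 = max(s - 1, 0)            # last at-colony fix before departure
        i1 = min(e + 1, len(away) - 1)  # first at-colony fix after return
        seg = track.iloc[i0:i1 + 1].reset_index(drop=True)
        dur = (seg["time"].iloc[-1] - seg["time"].iloc[0]).total_seconds()
        if dur < min_duration_s or d[s:e + 1].max() < min_range_m:
            n_discarded += 1
            continue
        counter += 1
        trips.append(Trip(bird_id=bird_id, treatment=treatment, colony=colony,
                          fixes=seg, trip_id=f"{bird_id}_t{counter}"))
    if n_discarded:
        logger.info("bird %s: discarded %d short excursions", bird_id, n_discarded)
    return trips


def interpolate_trip(trip: Trip, interval_s: float = 300.0,
                     gap_threshold_s: float = 3600.0) -> Trip:
    """Resample a trip onto an exact time grid with cubic splines.

    Longitude and latitude are each fit as a natural cubic spline of time
    and evaluated on an arithmetic grid at ``interval_s`` spanning the
    original time range; the last original time is appended if the grid does
    not land on it.  Fixes synthesised inside data gaps longer than
    ``gap_threshold_s`` are flagged ``gap=True`` — splines bridged across
    long outages fabricate plausible-looking movement, so downstream state
    classification excludes them from model fitting.
    """
    if len(trip) < 4:
        raise ValueError("cubic-spline interpolation needs at least 4 fixes")
    t0 = trip.fixes["time"].iloc[0]
    secs = (trip.fixes["time"] - t0).dt.total_seconds().to_numpy()
    grid = np.arange(0.0, secs[-1] + 1e-9, float(interval_s))
    if grid[-1] < secs[-1] - 1e-9:
        grid = np.append(grid, secs[-1])
    lon_s = CubicSpline(secs, trip.lon)
    lat_s = CubicSpline(secs, trip.lat)
    # a grid point is 'original' if it coincides with an input fix time
    orig = np.isin(np.round(grid, 6), np.round(secs, 6))
    gap_len = np.diff(secs)
    idx_right = np.searchsorted(secs, grid, side="left")
    inside_gap = np.zeros(len(grid), dtype=bool)
    interior = (~orig) & (idx_right > 0) & (idx_right < len(secs))
    inside_gap[interior] = gap_len[idx_right[interior] - 1] > gap_threshold_s
    fixes = pd.DataFrame({
        "time": t0 + pd.to_timedelta(grid, unit="s"),
        "lon": lon_s(grid),
        "lat": lat_s(grid),
        "interpolated": ~orig,
        "gap": inside_gap,
    })
    return replace(trip, fixes=fixes, interval_s=float(interval_s))


def speed_and_turn(trip: Trip) -> Trip:
    """Annotate each fix with speed (m/s) and signed turning angle (deg).

    ``speed[i]`` is the great-circle distance from fix i-1 to fix i divided
    by the elapsed time; ``turn[i]`` is the wrapped difference between the
    bearings of legs (i-1, i) and (i, i+1), clockwise positive, in
    (-180, 180].  The first fix has no speed; the first and last have no
    turn (NaN) and are excluded from downstream feature sets.
    """
    f = trip.fixes
    lon, lat = trip.lon, trip.lat
    dt = np.diff((f["time"] - f["time"].iloc[0]).dt.total_seconds().to_numpy())
    dist = geodesic_distance(lon[:-1], lat[:-1], lon[1:], lat[1:])
    speed = np.concatenate([[np.nan], dist / dt])
    brg = initial_bearing(lon[:-1], lat[:-1], lon[1:], lat[1:])
    brg = np.atleast_1d(brg)
    turn = np.full(len(f), np.nan)
    if len(brg) >= 2:
        turn[1:-1] = wrap180(brg[1:] - brg[:-1])
    out = trip.copy()
    out.fixes["speed"] = speed
    out.fixes["turn"] = turn
    return out


class CoastDistance:
    """Geodesic distance from points to a coastline geometry.

    The coastline is projected once into an azimuthal-equidistant plane
    about a reference point; planar distances are then evaluated with
    shapely.  AEQ distortion grows as (d/R)^2/6 away from the reference
    (~0.04 % at 300 km), negligible against the 40 km coastal threshold.
    Points inside a polygon coastline are at distance 0.
    """

    def __init__(self, coastline: BaseGeometry, ref_lon: float, ref_lat: float):
        from shapely.ops import transform
        self.proj = AzimuthalEquidistant(ref_lon, ref_lat)
        self._geom = transform(lambda x, y: self.proj.forward(x, y), coastline)

    def __call__(self, lon, lat) -> np.ndarray:
        from shapely.geometry import Point
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        x, y = self.proj.forward(lon, lat)
        return np.array([self._geom.distance(Point(xi, yi))
                         for xi, yi in zip(np.atleast_1d(x), np.atleast_1d(y))])


def distance_to_coast(lon, lat, coastline: BaseGeometry) -> float:
    """Minimum geodesic distance (m) from one point to the coastline."""
    if coastline.is_empty:
        raise ValueError("coastline geometry is empty")
    d = CoastDistance(coastline, float(lon), float(lat))(lon, lat)
    return float(d[0])


def night_mask(trip: Trip) -> Trip:
    """Annotate fixes with a per-trip night flag (nautical night).

    One reference location (the trip's median lon/lat) and one reference
    date (the median fix date) are used for the whole trip: each fix's UTC
    time-of-day is mapped onto the reference date and the fix is night when
    the solar elevation there is below -12 degrees.
    """
    f = trip.fixes
    med_lon = float(np.median(trip.lon))
    med_lat = float(np.median(trip.lat))
    t = f["time"].dt.tz_convert("UTC") if f["time"].dt.tz is not None else f["time"]
    med_date = t.dt.floor("D").astype("int64").median()
    ref_date = pd.to_datetime(int(med_date))
    tod = t - t.dt.floor("D")
    ref_times = (ref_date + tod).to_numpy()
    elev = solar.solar_elevation_deg(ref_times, med_lon, med_lat)
    night = elev < solar.NAUTICAL_TWILIGHT_ELEVATION_DEG
    if night.all():
        warnings.warn("reference date/location yields polar night: all fixes night")
    elif not night.any():
        # could be polar day or simply a day-only trip; warn only if the trip
        # spans a full diel cycle
        if (t.iloc[-1] - t.iloc[0]) > pd.Timedelta(hours=20):
            warnings.warn("no night fixes found on a multi-day trip")
    out = trip.copy()
    out.fixes["night"] = night
    return out


def write_trip_csv(trip: Trip, path) -> None:
    """Write a per-trip annotated CSV (time, lon, lat, annotations)."""
    df = trip.fixes.copy()
    df.insert(0, "trip_id", trip.trip_id)
    df.insert(0, "bird_id", trip.bird_id)
    df.insert(2, "treatment", trip.treatment)
    df.to_csv(path, index=False)
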