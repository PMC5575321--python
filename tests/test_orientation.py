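import numpy as np
import pandas as pd
import pytest

from conftest import COLONY, make_trip, straight_trip
from shearwater import orientation as om
from shearwater.geo import destination_point, geodesic_distance, wrap180
from shearwater.simulate import SimConfig, make_coastline, simulate_trip
from shearwater.track_io import CoastDistance


def test_vanishing_bearing_due_north_and_west():
    north = straight_trip(bearing_deg=0.0, n=20)
    west = straight_trip(bearing_deg=270.0, n=20)
    assert om.outbound_vanishing_bearing(north) == pytest.approx(0.0, abs=0.5)
    assert om.outbound_vanishing_bearing(west) == pytest.approx(270.0, abs=0.5)


def test_vanishing_bearing_crossing_interpolated():
    # steps of 2,010 m: the 10 km radius falls inside the 5th leg
    trip = straight_trip(bearing_deg=45.0, n=10, speed=6.7)
    cross = om.radius_crossing(trip, 10_000.0)
    assert cross is not None
    lon, lat, idx, frac = cross
    assert 0 < frac < 1
    assert geodesic_distance(COLONY[0], COLONY[1], lon, lat) == pytest.approx(
        10_000.0, rel=1e-3)


def test_trip_never_reaching_radius_returns_none():
    trip = straight_trip(n=3, speed=1.0)
    assert om.outbound_vanishing_bearing(trip, 10_000.0) is None


def test_simulated_departure_bearings_recovered():
    """Circular mean of vanishing bearings within 3 deg of scripted mu."""
    cfg = SimConfig(rng_seed=5, trip_days_range=(0.5, 0.8),
                    foraging_distance_km_range=(40.0, 60.0),
                    outbound_kappa_bird=1e6)  # pin every trip to mu
    rng = np.random.default_rng(11)
    bearings = []
    for i in range(50):
        trip, gt = simulate_trip(rng, cfg, "control",
                                 pd.Timestamp("2016-07-01T00:00Z"), f"b{i}")
        vb = om.outbound_vanishing_bearing(trip)
        if vb is not None:
            bearings.append(vb)
    rad = np.radians(bearings)
    mean = np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad)))) % 360
    assert abs(wrap180(mean - cfg.outbound_mu_deg["control"])) < 3.0


def test_coast_distance_at_radius_offshore_vs_hugging():
    cfg = SimConfig()
    coast = CoastDistance(make_coastline(cfg), *COLONY)
    offshore = straight_trip(bearing_deg=60.0, n=20)    # away from the island
    hugging = straight_trip(bearing_deg=240.0, n=20)    # straight at the island
    d_off = om.coast_distance_at_radius(offshore, coast)
    d_hug = om.coast_distance_at_radius(hugging, coast)
    assert d_off > d_hug


def test_coast_distance_at_radius_matches_brute_force(colony_sim):
    coast = CoastDistance(colony_sim.coastline, *COLONY)
    rng = np.random.default_rng(2)
    for i in range(10):
        trip = straight_trip(bearing_deg=rng.uniform(0, 360), n=15)
        got = om.coast_distance_at_radius(trip, coast)
        lon, lat, _, _ = om.radius_crossing(trip, 10_000.0)
        assert got == pytest.approx(coast(lon, lat)[0], abs=1e-6)


# ------------------------------------------------------------------ phase split

def _homing_trip_with_states(n=60, bearing=300.0):
    pts = [destination_point(*COLONY, bearing, 150_000.0)]
    from shearwater.geo import initial_bearing
    while geodesic_distance(pts[-1][0], pts[-1][1], *COLONY) > 2200:
        b = initial_bearing(pts[-1][0], pts[-1][1], *COLONY)
        pts.append(destination_point(*pts[-1], b, 2000.0))
    pts.append(COLONY)
    trip = make_trip([p[0] for p in pts], [p[1] for p in pts])
    trip.fixes["state"] = "commute"
    return trip


def test_phase_split_partitions_homing_exactly():
    cfg = SimConfig()
    coast = CoastDistance(make_coastline(cfg), *COLONY)
    trip = _homing_trip_with_states()
    pel, cst = om.phase_split(trip, 0, coast, 40_000.0)
    joined = np.concatenate([pel, cst])
    assert np.array_equal(np.sort(joined), np.arange(0, len(trip)))
    assert len(np.intersect1d(pel, cst)) == 0
    # split index = first fix within 40 km of the coast (brute force)
    d = coast(trip.lon, trip.lat)
    first_within = int(np.flatnonzero(d <= 40_000.0)[0])
    assert len(pel) == first_within


def test_trip_entirely_within_threshold_has_empty_pelagic():
    cfg = SimConfig()
    coast = CoastDistance(make_coastline(cfg), *COLONY)
    trip = _homing_trip_with_states()
    pel, cst = om.phase_split(trip, 0, coast, threshold_m=1_000_000.0)
    assert len(pel) == 0 and len(cst) == len(trip)


# ------------------------------------------------------------------ deviations

def test_flight_straight_at_colony_zero_deviation():
    trip = _homing_trip_with_states()
    dev = om.homeward_deviation(trip)
    assert np.abs(dev["deviation_deg"]).max() < 1.0


def test_flight_perpendicular_right_of_home_is_plus_90():
    # colony due north: flying east means home is 90 deg to the left
    start = destination_point(*COLONY, 180.0, 50_000.0)
    pts = [start] + [destination_point(*start, 90.0, 2000.0 * k) for k in (1, 2, 3)]
    trip = make_trip([p[0] for p in pts], [p[1] for p in pts])
    trip.fixes["state"] = "commute"
    dev = om.homeward_deviation(trip)["deviation_deg"].to_numpy()
    assert dev[0] == pytest.approx(90.0, abs=1.0)
    # continuing east, home falls progressively further behind the right wing
    assert np.all(np.diff(dev) > 0)
    assert np.all((dev >= 89.0) & (dev < 120.0))


def test_deviation_requires_flight_pairs():
    trip = _homing_trip_with_states()
    trip.fixes["state"] = "rest"
    assert om.homeward_deviation(trip).empty


def test_deviation_rotation_equivariance():
    """Rotating a trip about the colony leaves the deviations unchanged."""
    rng = np.random.default_rng(3)
    brg = rng.uniform(0, 360, 40)
    pts = [destination_point(*COLONY, 270.0, 80_000.0)]
    for b in brg:
        pts.append(destination_point(*pts[-1], b, 1500.0))
    def build(rot):
        rpts = []
        for lon, lat in pts:
            d = geodesic_distance(COLONY[0], COLONY[1], lon, lat)
            from shearwater.geo import initial_bearing
            az = initial_bearing(COLONY[0], COLONY[1], lon, lat)
            rpts.append(destination_point(*COLONY, (az + rot) % 360, d))
        t = make_trip([p[0] for p in rpts], [p[1] for p in rpts])
        t.fixes["state"] = "commute"
        return om.homeward_deviation(t)["deviation_deg"].to_numpy()
    base, rot = build(0.0), build(117.0)
    # small-angle distortions only (spherical rotation via bearings)
    assert rot == pytest.approx(base, abs=0.5)


def test_simulated_homing_bias_recovered():
    """von Mises deviation bias mu=20 recovered within 3 deg at n~500."""
    rng = np.random.default_rng(12)
    cfg = SimConfig(rng_seed=1, homing_bias_deg={"control": 20.0, "magnetic": 0.0,
                                                 "anosmic": 22.0},
                    homing_bias_bird_sd_deg=0.0,
                    trip_days_range=(1.0, 1.5),
                    foraging_distance_km_range=(150.0, 200.0))
    coast = CoastDistance(make_coastline(cfg), *COLONY)
    devs = []
    for i in range(6):
        trip, gt = simulate_trip(rng, cfg, "control",
                                 pd.Timestamp("2016-07-01T00:00Z"), f"b{i}",
                                 coast=coast)
        trip.fixes["state"] = gt.states
        pel, cst = om.phase_split(trip, gt.onset_idx, coast)
        devs.append(om.homeward_deviation(trip, pel)["deviation_deg"].to_numpy())
    d = np.concatenate(devs)
    assert len(d) > 400
    rad = np.radians(d)
    mean = np.degrees(np.arctan2(np.mean(np.sin(rad)), np.mean(np.cos(rad))))
    assert mean == pytest.approx(20.0, abs=3.0)


# ---------------------------------------------------------------- straightness

def test_straight_section_straightness_one():
    trip = straight_trip(n=20)
    assert om.straightness(trip, 0, len(trip) - 1) == pytest.approx(1.0, abs=1e-9)


def test_straightness_invariant_to_subsampling_straight_track():
    trip = straight_trip(n=40)
    sub = make_trip(trip.lon[::4], trip.lat[::4])
    assert om.straightness(sub, 0, len(sub) - 1) == pytest.approx(1.0, abs=1e-9)


def test_out_and_back_straightness_small():
    out = [destination_point(*COLONY, 0.0, 2000.0 * k) for k in range(20)]
    back = out[-2::-1]
    pts = out + back
    trip = make_trip([p[0] for p in pts], [p[1] for p in pts])
    assert om.straightness(trip, 0, len(trip) - 1) < 0.01


def test_straightness_matches_brute_force_leg_sum():
    rng = np.random.default_rng(6)
    lons = 5 + np.cumsum(rng.normal(0, 0.01, 25))
    lats = 39.5 + np.cumsum(rng.normal(0, 0.01, 25))
    trip = make_trip(lons, lats)
    path = sum(geodesic_distance(lons[i], lats[i], lons[i + 1], lats[i + 1])
               for i in range(24))
    bee = geodesic_distance(lons[0], lats[0], lons[-1], lats[-1])
    assert om.straightness(trip, 0, 24) == pytest.approx(bee / path, rel=1e-12)
    assert 0 < om.straightness(trip, 0, 24) <= 1


def test_zero_path_length_raises():
    trip = make_trip([5.0, 5.0], [39.5, 39.5])
    with pytest.raises(ValueError, match="zero path"):
        om.straightness(trip, 0, 1)


# ------------------------------------------------------------- homing timing

def test_homing_timing_table():
    rows = pd.DataFrame({
        "bird_id": ["a", "b", "c"], "treatment": ["control"] * 3,
        "trip_id": ["t1", "t2", "t3"],
        "onset_time": pd.to_datetime(["2016-07-01 14:30:00",
                                      "2016-07-02 16:00:00",
                                      "2016-07-03 09:15:00"], utc=True),
        "onset_distance_m": [120e3, 180e3, 60e3],
        "arrival_night": [True, True, False]})
    out = om.homing_departure_timing(rows)
    assert len(out) == 2
    assert out["onset_tod_h"].tolist() == pytest.approx([14.5, 16.0])


def test_homing_timing_no_night_arrivals_empty():
    rows = pd.DataFrame({
        "bird_id": ["a"], "treatment": ["control"], "trip_id": ["t1"],
        "onset_time": pd.to_datetime(["2016-07-01 14:30:00"], utc=True),
        "onset_distance_m": [120e3], "arrival_night": [False]})
    assert om.homing_departure_timing(rows).empty
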