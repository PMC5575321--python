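import numpy as np
import pandas as pd
import pytest

from shearwater.geo import destination_point
from shearwater.pipeline import RunConfig, run_pipeline
from shearwater.simulate import SimConfig, simulate_colony, write_dataset
from shearwater.track_io import Trip

COLONY = (5.0, 39.5)


def small_sim_config(seed: int = 11) -> SimConfig:
    """A scaled-down colony: 3 birds/treatment, 1-2 day trips, 60-100 km."""
    return SimConfig(rng_seed=seed,
                     n_birds={"control": 3, "magnetic": 3, "anosmic": 3},
                     trip_days_range=(1.0, 2.0),
                     foraging_distance_km_range=(60.0, 100.0),
                     pre_departure_days_range=(1, 2))


def make_trip(lons, lats, interval_s=300.0, colony=COLONY, t0="2016-07-01T00:00:00Z",
              bird_id="b1", treatment="control", trip_id="b1_t1") -> Trip:
    n = len(lons)
    fixes = pd.DataFrame({
        "time": pd.Timestamp(t0) + pd.to_timedelta(np.arange(n) * interval_s, unit="s"),
        "lon": np.asarray(lons, float), "lat": np.asarray(lats, float),
        "interpolated": False, "gap": False,
    })
    return Trip(bird_id=bird_id, treatment=treatment, colony=colony, fixes=fixes,
                trip_id=trip_id, interval_s=interval_s)


def straight_trip(bearing_deg=0.0, n=20, speed=6.7, interval_s=300.0,
                  start=COLONY) -> Trip:
    lons, lats = [start[0]], [start[1]]
    for _ in range(n - 1):
        p = destination_point(lons[-1], lats[-1], bearing_deg, speed * interval_s)
        lons.append(p[0]); lats.append(p[1])
    return make_trip(lons, lats, interval_s=interval_s, colony=start)


@pytest.fixture(scope="session")
def colony_sim():
    return simulate_colony(small_sim_config())


@pytest.fixture(scope="session")
def dataset_dir(tmp_path_factory, colony_sim):
    d = tmp_path_factory.mktemp("dataset")
    write_dataset(colony_sim, d)
    return d


@pytest.fixture(scope="session")
def pipeline_result(dataset_dir):
    cfg = RunConfig(
        tracks_path=str(dataset_dir / "tracks.csv"),
        metadata_path=str(dataset_dir / "metadata.csv"),
        weighings_path=str(dataset_dir / "weighings.csv"),
        coastline_path=str(dataset_dir / "coastline.geojson"),
        out_dir=str(dataset_dir / "out"),
        K_max=6, n_init=2, K_override=3, ww_iterations=300, glmm_thin=6,
        rng_seed=1)
    return run_pipeline(cfg, colony=COLONY)
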