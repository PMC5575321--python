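"""End-to-end orchestration of the trajectory-analysis pipeline.

``run_pipeline`` takes a :class:`RunConfig` pointing at a Movebank-style
track CSV, a metadata table, repeat-weighing table and coastline GeoJSON,
and executes every stage in order: trip splitting, spline regularisation,
kinematics, night classification, mixture-model state classification,
segmentation and homing-onset detection, orientation metrics, and the full
statistical battery.  All stage parameters live in the config; fixed seeds
make every numeric output reproducible run to run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behaviour_states as bs
from . import glmm, inference, orientation, segmentation, track_io

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths plus every stage parameter of the pipeline."""

    tracks_path: str = ""
    metadata_path: str = ""
    weighings_path: str = ""
    coastline_path: str = ""
    out_dir: str = "pipeline_out"
    # trip handling
    attendance_radius_m: float = 1000.0
    min_trip_duration_s: float = 3600.0
    min_trip_range_m: float = 2000.0
    interval_s: float = 300.0
    gap_threshold_s: float = 3600.0
    # segmentation / homing
    dp_tolerance_m: float = 1000.0
    max_homeward_deviation_deg: float = 60.0
    min_segment_displacement_m: float = 1000.0
    # orientation
    vanishing_radius_m: float = 10_000.0
    coastal_threshold_m: float = 40_000.0
    # behavioural states
    K_min: int = 1
    K_max: int = 10
    n_init: int = 4
    K_override: int | None = None
    # inference
    ww_iterations: int = 5000
    rng_seed: int = 0
    glmm_thin: int = 3          # keep every n-th fix in per-fix GLMMs
    run_glmm: bool = True
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        if unknown := set(raw) - known:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    def validate(self) -> None:
        for name in ("tracks_path", "metadata_path", "coastline_path"):
            p = getattr(self, name)
            if not p or not Path(p).exists():
                raise FileNotFoundError(f"{name} does not exist: {p!r}")
        for name in ("attendance_radius_m", "vanishing_radius_m",
                     "coastal_threshold_m", "dp_tolerance_m"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class PipelineResult:
    config: RunConfig
    trips: list
    n_states: int
    state_models: list
    behaviour_table: pd.DataFrame
    diurnal: pd.DataFrame
    segments: pd.DataFrame
    trip_summary: pd.DataFrame
    deviations: pd.DataFrame
    outbound_ww: object
    stats: dict
    mass_records: pd.DataFrame | None
    run_log: dict


def _stage(name):
    logger.info("stage: %s", name)


def run_pipeline(config: RunConfig, colony: tuple[float, float] | None = None) -> PipelineResult:
    config.validate()
    rng_seed = int(config.rng_seed)

    _stage("read inputs")
    metadata = track_io.read_metadata(config.metadata_path)
    coastline = track_io.read_coastline(config.coastline_path)
    tracks = track_io.read_tracks(config.tracks_path, metadata)
    weighings = (pd.read_csv(config.weighings_path)
                 if config.weighings_path and Path(config.weighings_path).exists()
                 else None)
    treatment_of = metadata.set_index("bird_id")["treatment"].to_dict()
    if colony is None:
        # colony = modal first-fix location across deployments
        first = pd.DataFrame([t.iloc[0] for t in tracks.values()])
        colony = (float(first["lon"].median()), float(first["lat"].median()))
    coast = track_io.CoastDistance(coastline, colony[0], colony[1])

    _stage("split, interpolate, kinematics, night")
    trips = []
    for bird_id, track in tracks.items():
        for trip in track_io.split_trips(
                track, colony, config.attendance_radius_m,
                config.min_trip_duration_s, config.min_trip_range_m,
                bird_id=bird_id, treatment=treatment_of.get(bird_id, "control")):
            if len(trip) < 4:
                continue
            trip = track_io.interpolate_trip(trip, config.interval_s,
                                             config.gap_threshold_s)
            trip = track_io.speed_and_turn(trip)
            trip = track_io.night_mask(trip)
            trips.append(trip)
    if not trips:
        raise RuntimeError("stage split: no trips recovered from tracks")

    _stage("behavioural states")
    X = bs.pooled_features(trips)
    models = bs.fit_state_models(X, range(config.K_min, config.K_max + 1),
                                 n_init=config.n_init, rng_seed=rng_seed)
    K = config.K_override or bs.select_n_states(models)
    model = next(m for m in models if m.K == K)
    trips = [bs.assign_states(model, t) for t in trips]
    behaviour_table = bs.behaviour_proportions(trips)
    diurnal = bs.diurnal_profile(trips)

    _stage("segmentation, homing onset, orientation")
    seg_tables, summary_rows, dev_rows = [], [], []
    for trip in trips:
        segs = segmentation.douglas_peucker_segments(
            trip, config.dp_tolerance_m,
            max_homeward_deviation_deg=config.max_homeward_deviation_deg,
            min_displacement_m=config.min_segment_displacement_m)
        seg_tables.append(segmentation.segments_table(trip, segs))
        ann = segmentation.homing_onset(trip, segs, config.attendance_radius_m)
        vb = orientation.outbound_vanishing_bearing(trip, config.vanishing_radius_m)
        cd10 = orientation.coast_distance_at_radius(trip, coast,
                                                    config.vanishing_radius_m)
        row = {"bird_id": trip.bird_id, "treatment": trip.treatment,
               "trip_id": trip.trip_id,
               "duration_h": (trip.times.iloc[-1] - trip.times.iloc[0])
               .total_seconds() / 3600.0,
               "total_distance_km": float(np.sum(track_io.geodesic_distance(
                   trip.lon[:-1], trip.lat[:-1], trip.lon[1:], trip.lat[1:])) / 1e3),
               "outbound_bearing_deg": vb, "coast_distance_at_10km_m": cd10,
               "onset_idx": ann.onset_idx, "onset_time": ann.onset_time,
               "onset_distance_m": ann.colony_distance_at_onset_m,
               "arrival_night": bool(trip.fixes["night"].iloc[-1]),
               "straightness_pelagic": np.nan}
        if ann.onset_idx is not None:
            pel, cst = orientation.phase_split(trip, ann.onset_idx, coast,
                                               config.coastal_threshold_m)
            trip = orientation.annotate_phase(trip, pel, cst)
            for phase, idx in (("pelagic", pel), ("coastal", cst)):
                dev = orientation.homeward_deviation(trip, idx)
                if not dev.empty:
                    dev["phase"] = phase
                    dev["bird_id"] = trip.bird_id
                    dev["treatment"] = trip.treatment
                    dev_rows.append(dev)
            if len(pel) >= 2:
                row["straightness_pelagic"] = orientation.straightness(
                    trip, int(pel[0]), int(pel[-1]))
        summary_rows.append(row)
    segments = pd.concat(seg_tables, ignore_index=True)
    trip_summary = pd.DataFrame(summary_rows)
    deviations = (pd.concat(dev_rows, ignore_index=True)
                  if dev_rows else pd.DataFrame(
                      columns=["trip_id", "fix_idx", "deviation_deg", "phase",
                               "bird_id", "treatment"]))

    _stage("statistics")
    stats: dict = {}
    ob = trip_summary.dropna(subset=["outbound_bearing_deg"])
    ww = inference.iterated_watson_williams(
        ob.rename(columns={"outbound_bearing_deg": "angle_deg"})
        [["bird_id", "treatment", "angle_deg"]].reset_index(drop=True),
        n_iter=config.ww_iterations, rng_seed=rng_seed)
    stats["outbound_ww"] = ww

    cd = trip_summary.dropna(subset=["coast_distance_at_10km_m"])
    stats["coast_distance_lmm"] = inference.fit_lmm(
        cd, "coast_distance_at_10km_m", groups="bird_id")
    stats["duration_lmm"] = inference.fit_lmm(trip_summary, "duration_h",
                                              groups="bird_id")
    stats["distance_lmm"] = inference.fit_lmm(trip_summary, "total_distance_km",
                                              groups="bird_id")
    st = trip_summary.dropna(subset=["straightness_pelagic"])
    if len(st) >= 6:
        stats["straightness_lmm"] = inference.fit_lmm(st, "straightness_pelagic",
                                                      groups="bird_id")

    timing = orientation.homing_departure_timing(
        trip_summary.dropna(subset=["onset_time"]))
    if len(timing) >= 6:
        timing = timing.assign(onset_distance_km=timing["onset_distance_m"] / 1e3)
        stats["timing_lr"] = inference.lmm_lr_term_tests(
            timing, "onset_tod_h", "bird_id",
            [("base", "1", 0),
             ("distance", "onset_distance_km", 1),
             ("treatment", "onset_distance_km + C(treatment)", 2),
             ("interaction", "onset_distance_km * C(treatment)", 2)])

    for phase in ("pelagic", "coastal"):
        sub = deviations[deviations["phase"] == phase]
        if sub["bird_id"].nunique() >= 6 and len(sub) > 50:
            stats[f"{phase}_deviation_lmm"] = inference.fit_lmm(
                sub, "deviation_deg", groups="bird_id", nested="trip_id")

    if config.run_glmm:
        _stage("behaviour GLMMs")
        fix_rows = []
        for trip in trips:
            f = trip.fixes
            ok = f["state"].notna()
            fix_rows.append(pd.DataFrame({
                "bird_id": trip.bird_id, "trip_id": trip.trip_id,
                "treatment": trip.treatment,
                "state": f.loc[ok, "state"], "night": f.loc[ok, "night"],
                "date": f.loc[ok, "time"].dt.floor("D").astype(str)}))
        fixes = pd.concat(fix_rows, ignore_index=True)
        if config.glmm_thin > 1:
            fixes = fixes.iloc[::config.glmm_thin].reset_index(drop=True)
        for state in bs.STATE_ORDER:
            for diel, is_night in (("day", False), ("night", True)):
                sub = fixes[fixes["night"] == is_night].copy()
                sub["y"] = (sub["state"] == state).astype(int)
                try:
                    stats[f"glmm_{state}_{diel}"] = glmm.glmm_treatment_test(
                        sub, "y", factors=("bird_id", "trip_id", "date"))
                except Exception as exc:  # degenerate diel class etc.
                    logger.warning("GLMM %s/%s failed: %s", state, diel, exc)

    _stage("foraging success")
    mass_records = None
    if weighings is not None and {"deploy_mass_g", "retrieve_mass_g"} <= set(metadata.columns):
        rate = inference.incubation_loss_rate(weighings)
        stats["incubation_loss_pct_per_day"] = rate
        forage_counts = {}
        for trip in trips:
            n_forage = int((trip.fixes["state"] == "forage").sum())
            forage_counts[trip.bird_id] = forage_counts.get(trip.bird_id, 0) + n_forage
        rec = metadata.copy()
        rec["foraging_fix_count"] = rec["bird_id"].map(forage_counts).fillna(0)
        if "days_incubating_before_departure" not in rec.columns:
            rec["days_incubating_before_departure"] = (
                (rec["first_departure_date"] - rec["deploy_date"]).dt.total_seconds()
                / 86400.0)
        rec = rec.dropna(subset=["deploy_mass_g", "retrieve_mass_g"])
        mass_records = inference.corrected_mass_gain(rec, rate)
        if len(mass_records) >= 8:
            stats["mass_glm"] = inference.mass_foraging_glm(mass_records)

    run_log = {
        "config": dataclasses.asdict(config),
        "colony": list(colony),
        "n_birds": int(trip_summary["bird_id"].nunique()),
        "n_trips": int(len(trip_summary)),
        "n_states": int(K),
        "state_mean_speeds": sorted(float(s) for s in model.mean_speeds),
        "versions": _versions(),
    }
    return PipelineResult(config=config, trips=trips, n_states=K,
                          state_models=models, behaviour_table=behaviour_table,
                          diurnal=diurnal, segments=segments,
                          trip_summary=trip_summary, deviations=deviations,
                          outbound_ww=ww, stats=stats,
                          mass_records=mass_records, run_log=run_log)


def _versions() -> dict:
    import scipy
    import sklearn
    import statsmodels

    from . import __version__
    return {"shearwater": __version__, "numpy": np.__version__,
            "pandas": pd.__version__, "scipy": scipy.__version__,
            "sklearn": sklearn.__version__, "statsmodels": statsmodels.__version__}


def write_outputs(result: PipelineResult) -> Path:
    """Write the report bundle (tables, statistics, run log) to out_dir."""
    out = Path(result.config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.behaviour_table.to_csv(out / "behaviour_table.csv", index=False)
    result.diurnal.to_csv(out / "diurnal_profile.csv", index=False)
    result.segments.to_csv(out / "segments.csv", index=False)
    result.trip_summary.to_csv(out / "trip_summary.csv", index=False)
    result.deviations.to_csv(out / "deviations.csv", index=False)
    trips_dir = out / "trips"
    trips_dir.mkdir(exist_ok=True)
    for trip in result.trips:
        track_io.write_trip_csv(trip, trips_dir / f"{trip.trip_id}.csv")
    stat_rows = []
    for name, res in result.stats.items():
        if isinstance(res, inference.MixedModelResult):
            for lev, row in res.estimates.iterrows():
                stat_rows.append({"analysis": name, "term": lev,
                                  "estimate": row["estimate"], "se": row["se"],
                                  "chi2": res.lr_chi2, "df": res.lr_df,
                                  "p": res.lr_p})
            if res.posthoc is not None:
                for _, r in res.posthoc.iterrows():
                    stat_rows.append({"analysis": f"{name}_tukey",
                                      "term": r["pair"], "estimate": r["diff"],
                                      "se": r["se"], "chi2": np.nan,
                                      "df": r["df"], "p": r["p_adj"]})
        elif isinstance(res, inference.CircTestResult):
            stat_rows.append({"analysis": name, "term": "p_mean",
                              "estimate": res.p_mean, "se": res.p_se,
                              "chi2": np.nan, "df": np.nan, "p": res.p_mean})
        elif isinstance(res, pd.DataFrame):
            res.to_csv(out / f"stats_{name}.csv")
        elif np.isscalar(res):
            stat_rows.append({"analysis": name, "term": "value",
                              "estimate": float(res), "se": np.nan,
                              "chi2": np.nan, "df": np.nan, "p": np.nan})
    pd.DataFrame(stat_rows).to_csv(out / "statistics.csv", index=False)
    if result.mass_records is not None:
        result.mass_records.to_csv(out / "mass_records.csv", index=False)

    def _default(o):
        if isinstance(o, (np.integer, np.floating)):
            return float(o)
        return str(o)

    with open(out / "run_log.json", "w") as fh:
        json.dump(result.run_log, fh, indent=2, default=_default)
    if result.config.make_plots:
        _plots(result, out)
    return out


def _plots(result: PipelineResult, out: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    colors = {"control": "tab:red", "magnetic": "tab:green", "anosmic": "k"}
    for trip in result.trips:
        ax.plot(trip.lon, trip.lat, lw=0.5, alpha=0.6,
                color=colors.get(trip.treatment, "gray"))
    ax.set_xlabel("longitude"); ax.set_ylabel("latitude")
    fig.savefig(out / "tracks.png", dpi=120)
    plt.close(fig)

    piv = result.diurnal.pivot_table(index="hour", columns=["treatment", "state"],
                                     values="proportion")
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharey=True)
    for ax, state in zip(axes, ("forage", "commute", "rest")):
        for treat, col in colors.items():
            key = (treat, state)
            if key in piv.columns:
                ax.plot(piv.index, piv[key], color=col, label=treat)
        ax.set_title(state); ax.set_xlabel("hour (UTC)")
    axes[0].set_ylabel("proportion of fixes")
    axes[0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out / "diurnal.png", dpi=120)
    plt.close(fig)
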