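"""Behavioural-state classification from track kinematics.

Gaussian mixture models are fitted to per-fix (speed, |turning angle|)
features pooled across all birds; the number of states is chosen by the
elbow of the log-likelihood over a range of component counts, and each fix
is assigned its maximum-posterior component.  Components are given semantic
labels by ascending mean speed — resting on the water, foraging
(slow, tortuous flight / surface feeding), and commuting (fast directed
flight) — matching how such mixtures are read in seabird tracking studies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .track_io import Trip

logger = logging.getLogger(__name__)

STATE_ORDER = ("rest", "forage", "commute")


@dataclass
class StateModel:
    """A fitted Gaussian mixture over (speed m/s, |turn| deg) features."""

    K: int
    weights: np.ndarray          # (K,) simplex
    means: np.ndarray            # (K, 2)
    covariances: np.ndarray      # (K, 2, 2)
    loglik: float                # total log-likelihood of the training data
    labels: dict[int, str]       # component index -> semantic label
    estimator: GaussianMixture = field(repr=False, default=None)

    @property
    def mean_speeds(self) -> np.ndarray:
        return self.means[:, 0]


def state_features(trip: Trip) -> pd.DataFrame:
    """Per-fix (speed, |turn|) features with a validity mask.

    Fixes without both kinematic quantities (trip endpoints) and fixes
    interpolated through long data gaps are marked invalid: gap-bridging
    splines fabricate movement and would contaminate the mixture fit.
    """
    f = trip.fixes
    if "speed" not in f or "turn" not in f:
        raise ValueError("run speed_and_turn() before extracting state features")
    feats = pd.DataFrame({
        "speed": f["speed"].to_numpy(dtype=float),
        "abs_turn": np.abs(f["turn"].to_numpy(dtype=float)),
    })
    valid = np.isfinite(feats["speed"]) & np.isfinite(feats["abs_turn"])
    if "gap" in f:
        valid &= ~f["gap"].to_numpy(dtype=bool)
    feats["valid"] = valid
    return feats


def pooled_features(trips: list[Trip]) -> np.ndarray:
    """Stack valid (speed, |turn|) rows from many trips into one array."""
    parts = []
    for trip in trips:
        ft = state_features(trip)
        parts.append(ft.loc[ft["valid"], ["speed", "abs_turn"]].to_numpy())
    X = np.vstack(parts)
    return X


def _semantic_labels(K: int, mean_speeds: np.ndarray) -> dict[int, str]:
    """Label components by ascending mean speed: rest < forage < commute."""
    order = np.argsort(mean_speeds)
    labels: dict[int, str] = {}
    for rank, comp in enumerate(order):
        if rank == 0:
            labels[int(comp)] = "rest"
        elif rank == K - 1:
            labels[int(comp)] = "commute"
        else:
            labels[int(comp)] = "forage"
    if K == 1:
        labels[int(order[0])] = "rest"
    elif K == 2:
        labels[int(order[0])], labels[int(order[1])] = "rest", "commute"
    return labels


def fit_state_models(features: np.ndarray, K_range=range(1, 11),
                     n_init: int = 10, rng_seed: int = 0,
                     reg_covar: float = 1e-6) -> list[StateModel]:
    """Fit best-of-``n_init`` full-covariance mixtures for each K.

    Degenerate fits (component collapse) are guarded by the covariance
    floor; if a fit still fails it is retried once with a larger floor.
    """
    X = np.asarray(features, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    K_range = list(K_range)
    if len(X) < 10 * max(K_range):
        raise ValueError(f"need at least {10 * max(K_range)} feature rows "
                         f"for K up to {max(K_range)}")
    models = []
    for K in K_range:
        gm = GaussianMixture(n_components=K, covariance_type="full",
                             reg_covar=reg_covar, n_init=n_init,
                             random_state=rng_seed)
        try:
            gm.fit(X)
        except Exception:  # component collapse: refit with a stronger floor
            gm = GaussianMixture(n_components=K, covariance_type="full",
                                 reg_covar=1e-3, n_init=n_init,
                                 random_state=rng_seed)
            gm.fit(X)
        loglik = float(gm.score(X) * len(X))
        models.append(StateModel(
            K=K, weights=gm.weights_.copy(), means=gm.means_.copy(),
            covariances=gm.covariances_.copy(), loglik=loglik,
            labels=_semantic_labels(K, gm.means_[:, 0]), estimator=gm))
    return models


def select_n_states(models: list[StateModel]) -> int:
    """Choose K at the elbow of the log-likelihood curve.

    The elbow is the interior K with the largest flattening, i.e. the K
    maximising 2*ll(K) - ll(K-1) - ll(K+1).  With no interior maximum
    (e.g. perfectly linear growth) the smallest K is returned with a
    warning.  Only valid for a contiguous K range of at least 3 models.
    """
    if len(models) < 3:
        raise ValueError("elbow selection needs models for at least 3 contiguous K")
    Ks = [m.K for m in models]
    if Ks != list(range(Ks[0], Ks[0] + len(Ks))):
        raise ValueError("models must cover a contiguous K range")
    ll = np.array([m.loglik for m in models])
    flattening = 2 * ll[1:-1] - ll[:-2] - ll[2:]
    if np.all(flattening <= 1e-9 * max(1.0, np.abs(ll).max())):
        warnings.warn("no elbow in log-likelihood curve; selecting smallest K")
        return Ks[0]
    return Ks[1 + int(np.argmax(flattening))]


def assign_states(model: StateModel, trip: Trip) -> Trip:
    """Assign each fix its maximum-posterior semantic state label.

    Fixes with invalid features keep a missing label.  Posterior ties are
    broken deterministically towards the lower-speed component.
    """
    ft = state_features(trip)
    out = trip.copy()
    labels = np.array([None] * len(ft), dtype=object)
    valid = ft["valid"].to_numpy()
    if valid.any():
        X = ft.loc[valid, ["speed", "abs_turn"]].to_numpy()
        post = model.estimator.predict_proba(X)
        # reorder components by ascending speed so argmax's first-wins rule
        # breaks ties towards the slower state
        order = np.argsort(model.mean_speeds)
        comp = order[np.argmax(post[:, order], axis=1)]
        labels[valid] = [model.labels[int(c)] for c in comp]
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.debug("trip %s: %d fixes left unlabelled", trip.trip_id, n_skipped)
    out.fixes["state"] = labels
    return out


def behaviour_proportions(trips: list[Trip]) -> pd.DataFrame:
    """Treatment x diel-class x state activity budget (second-order means).

    First-order proportions are computed per trip within each diel class,
    averaged to bird level, and the reported mean and s.e. are taken across
    birds within a treatment.  Trips with an empty diel class are omitted
    from that class's mean.
    """
    rows = []
    for trip in trips:
        f = trip.fixes
        if "state" not in f or "night" not in f:
            raise ValueError("states and night mask must be assigned first")
        for is_night, diel in ((False, "day"), (True, "night")):
            sub = f[(f["night"] == is_night) & f["state"].notna()]
            if sub.empty:
                logger.debug("trip %s: no %s fixes", trip.trip_id, diel)
                continue
            counts = sub["state"].value_counts()
            total = counts.sum()
            for state in STATE_ORDER:
                rows.append({"bird_id": trip.bird_id, "treatment": trip.treatment,
                             "trip_id": trip.trip_id, "diel": diel, "state": state,
                             "proportion": counts.get(state, 0) / total})
    per_trip = pd.DataFrame(rows)
    per_bird = (per_trip.groupby(["treatment", "bird_id", "diel", "state"])
                ["proportion"].mean().reset_index())
    summary = (per_bird.groupby(["treatment", "diel", "state"])["proportion"]
               .agg(mean="mean", se=lambda s: s.std(ddof=1) / np.sqrt(len(s)), n_birds="size")
               .reset_index())
    return summary


def diurnal_profile(trips: list[Trip]) -> pd.DataFrame:
    """Hourly (UTC) state proportions per treatment."""
    rows = []
    for trip in trips:
        f = trip.fixes
        sub = f[f["state"].notna()]
        if sub.empty:
            continue
        hours = sub["time"].dt.hour
        for (hour, state), n in sub.groupby([hours, sub["state"]], observed=True).size().items():
            rows.append({"treatment": trip.treatment, "hour": int(hour),
                         "state": state, "n": int(n)})
    df = pd.DataFrame(rows)
    counts = df.groupby(["treatment", "hour", "state"])["n"].sum().reset_index()
    totals = counts.groupby(["treatment", "hour"])["n"].transform("sum")
    counts["proportion"] = counts["n"] / totals
    return counts
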