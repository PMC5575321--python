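"""Circular and mixed-model inference for treatment contrasts.

Covers the statistical battery applied to trip metrics:

* Watson-Williams circular ANOVA of mean directions, and its iterated
  one-angle-per-bird resampling form that removes pseudo-replication from
  birds contributing several trips;
* linear mixed models (random intercept for bird, or trip nested in bird)
  with REML estimates for reporting, ML refits for likelihood-ratio tests,
  and Tukey-adjusted pairwise treatment contrasts;
* the incubation mass-loss correction and the corrected-mass-gain ~
  foraging-effort GLM with sequential F tests.

The binomial GLMM for per-fix behavioural states lives in
:mod:`shearwater.glmm`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

logger = logging.getLogger(__name__)

TREATMENTS = ("control", "magnetic", "anosmic")


# --------------------------------------------------------------------------
# circular statistics
# --------------------------------------------------------------------------

def circular_mean_deg(angles_deg) -> float:
    a = np.radians(np.asarray(angles_deg, dtype=float))
    return float(np.degrees(np.arctan2(np.mean(np.sin(a)), np.mean(np.cos(a)))) % 360.0)


def _kappa_ml(r: np.ndarray) -> np.ndarray:
    """Fisher's approximation to the ML von Mises concentration given r."""
    r = np.asarray(r, dtype=float)
    k = np.where(r < 0.53, 2 * r + r ** 3 + 5 * r ** 5 / 6,
                 np.where(r < 0.85, -0.4 + 1.39 * r + 0.43 / np.maximum(1 - r, 1e-12),
                          1.0 / np.maximum(r ** 3 - 4 * r ** 2 + 3 * r, 1e-12)))
    return k


def _ww_from_components(C: np.ndarray, S: np.ndarray, n: np.ndarray):
    """Watson-Williams F and p from per-group resultant components.

    ``C``, ``S``, ``n`` have shape (k, ...) — trailing axes vectorise over
    independent datasets (used by the iterated test).
    """
    R_g = np.hypot(C, S)                      # per-group resultant lengths
    N = n.sum(axis=0)
    sumR = R_g.sum(axis=0)
    R_all = np.hypot(C.sum(axis=0), S.sum(axis=0))
    k = C.shape[0]
    rw = sumR / N
    kappa = _kappa_ml(rw)
    g = 1.0 + 3.0 / (8.0 * kappa)             # concentration correction factor
    denom = N - sumR
    with np.errstate(divide="ignore", invalid="ignore"):
        F = g * ((N - k) * (sumR - R_all)) / ((k - 1) * denom)
    # identical angles in every group: 0/0 -> no difference
    F = np.where(denom <= 1e-12, 0.0, np.maximum(F, 0.0))
    p = sps.f.sf(F, k - 1, N - k)
    return F, p, rw


def watson_williams(groups: list) -> tuple[float, float]:
    """Watson-Williams test for equal mean directions across groups.

    Parameters are lists/arrays of angles in degrees, one per group.
    Returns (F, p) with p from F(k-1, N-k).  The test assumes von Mises
    samples of common, reasonably high concentration; a warning is issued
    when the pooled mean resultant length is below 0.45.
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 angles each")
    C = np.array([np.sum(np.cos(np.radians(np.asarray(g, float)))) for g in groups])
    S = np.array([np.sum(np.sin(np.radians(np.asarray(g, float)))) for g in groups])
    n = np.array([len(g) for g in groups], dtype=float)
    F, p, rw = _ww_from_components(C, S, n)
    if rw < 0.45:
        warnings.warn("low concentration (r_w = %.2f): Watson-Williams "
                      "assumptions questionable" % rw)
    return float(F), float(p)


@dataclass
class CircTestResult:
    """Distribution of Watson-Williams outcomes over per-bird resamples."""

    n_iter: int
    p_values: np.ndarray
    F_values: np.ndarray
    group_means_deg: dict[str, float]
    groups: tuple[str, ...]

    @property
    def p_mean(self) -> float:
        return float(np.mean(self.p_values))

    @property
    def p_se(self) -> float:
        if self.n_iter < 2:
            return 0.0
        return float(np.std(self.p_values, ddof=1) / np.sqrt(self.n_iter))

    def summary(self) -> str:
        lines = [f"Iterated Watson-Williams test ({self.n_iter} resamples)",
                 f"  p = {self.p_mean:.4g} +/- {self.p_se:.2g} (mean +/- s.e.)",
                 f"  F (mean) = {float(np.mean(self.F_values)):.3f}"]
        for g in self.groups:
            lines.append(f"  mean direction [{g}] = {self.group_means_deg[g]:.2f} deg")
        return "\n".join(lines)


def iterated_watson_williams(angles: pd.DataFrame, n_iter: int = 5000,
                             rng_seed: int = 0,
                             group_order=TREATMENTS) -> CircTestResult:
    """Repeated-measures Watson-Williams test by one-angle-per-bird resampling.

    ``angles`` needs columns bird_id, treatment, angle_deg (one row per
    trip).  Each iteration draws exactly one angle per bird uniformly at
    random and runs the Watson-Williams test across treatments; the
    distribution of p-values over ``n_iter`` iterations is reported as its
    mean and standard error.  A single seed governs all iterations.
    """
    groups = [g for g in group_order if g in set(angles["treatment"])]
    if len(groups) < 2:
        raise ValueError("need >= 2 treatments")
    birds = angles.groupby("bird_id", sort=True)
    bird_ids = list(birds.groups)
    bird_treat = angles.drop_duplicates("bird_id").set_index("bird_id")["treatment"]
    for g in groups:
        if (bird_treat == g).sum() < 2:
            raise ValueError(f"treatment {g!r} has fewer than 2 birds")
    rng = np.random.default_rng(rng_seed)
    rad = np.radians(angles["angle_deg"].to_numpy(dtype=float))
    cos_a, sin_a = np.cos(rad), np.sin(rad)
    # per-iteration index of the sampled angle for every bird
    C = np.zeros((len(groups), n_iter))
    S = np.zeros((len(groups), n_iter))
    n = np.zeros((len(groups), 1))
    gidx = {g: i for i, g in enumerate(groups)}
    for bird in bird_ids:
        rows = birds.groups[bird].to_numpy()
        gi = gidx[bird_treat.loc[bird]]
        pick = rows[rng.integers(0, len(rows), size=n_iter)]
        C[gi] += cos_a[angles.index.get_indexer(pick)]
        S[gi] += sin_a[angles.index.get_indexer(pick)]
        n[gi, 0] += 1
    F, p, _ = _ww_from_components(C, S, np.broadcast_to(n, C.shape))
    means = {g: circular_mean_deg(angles.loc[angles["treatment"] == g, "angle_deg"])
             for g in groups}
    return CircTestResult(n_iter=n_iter, p_values=p, F_values=F,
                          group_means_deg=means, groups=tuple(groups))


# --------------------------------------------------------------------------
# linear mixed models
# --------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Treatment contrast from a (G)LMM: estimates, LR test, post-hoc."""

    response: str
    estimates: pd.DataFrame          # index treatment, columns estimate/se
    lr_chi2: float
    lr_df: int
    lr_p: float
    posthoc: pd.DataFrame | None = None   # pair, diff, se, t, df, p_adj
    model: object = field(default=None, repr=False)
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Mixed model for {self.response!r} (cell-means treatment coding)"]
        for lev, row in self.estimates.iterrows():
            lines.append(f"  {lev}: {row['estimate']:.4g} +/- {row['se']:.3g} (s.e.)")
        lines.append(f"  LR test: chi2 = {self.lr_chi2:.3f}, df = {self.lr_df}, "
                     f"p = {self.lr_p:.4g}")
        if self.posthoc is not None:
            for _, r in self.posthoc.iterrows():
                lines.append(f"  Tukey {r['pair']}: t = {r['t']:.3f}, "
                             f"df = {r['df']:.1f}, p = {r['p_adj']:.3f}")
        return "\n".join(lines)


def _fit_mixedlm(formula, data, groups, vc_formula, reml):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.filterwarnings("ignore", message=".*[Ss]ingular.*")
        warnings.filterwarnings("ignore", message=".*boundary.*")
        model = smf.mixedlm(formula, data=data, groups=data[groups],
                            vc_formula=vc_formula, re_formula="1")
        try:
            return model.fit(reml=reml, method="lbfgs", maxiter=200)
        except Exception:
            return model.fit(reml=reml, maxiter=200)


def _healthy(fit) -> bool:
    """A usable fit: finite estimates/SEs on a sane scale, finite loglik."""
    bse = np.asarray(fit.bse, dtype=float)
    params = np.asarray(fit.params, dtype=float)
    scale = 1.0 + np.nanmax(np.abs(params))
    return bool(np.isfinite(fit.llf) and np.all(np.isfinite(bse))
                and np.nanmax(bse) < 1e4 * scale)


def fit_lmm(data: pd.DataFrame, response: str, groups: str = "bird_id",
            nested: str | None = None, levels=TREATMENTS,
            posthoc_always: bool = False) -> MixedModelResult:
    """Treatment LMM with a bird (optionally trip-in-bird) random intercept.

    REML estimates (cell-means coding: one mean per treatment level) are
    reported; the LR test compares ML refits of the treatment model against
    the intercept-only null.  When the LR test is significant at 0.05 the
    Tukey post-hoc contrasts are attached.
    """
    data = data.copy()
    levels = [l for l in levels if l in set(data["treatment"])]
    lev_term = f"C(treatment, levels={list(levels)!r})"
    full_f = f"{response} ~ 0 + {lev_term}"
    null_f = f"{response} ~ 1"
    # fallback chain for boundary/singular variance fits: drop the nested
    # intercept first, then all random effects (degenerate clusters carry no
    # information beyond the residual anyway)
    structures = []
    if nested:
        structures.append(("trip-in-bird", {"nested": f"0 + C({nested})"}))
    structures.append(("bird", None))
    reml_fit = ml_full = ml_null = None
    structure_used = "fixed-only"
    for name, vc in structures:
        reml_fit = _fit_mixedlm(full_f, data, groups, vc, reml=True)
        ml_full = _fit_mixedlm(full_f, data, groups, vc, reml=False)
        ml_null = _fit_mixedlm(null_f, data, groups, vc, reml=False)
        if _healthy(reml_fit) and np.isfinite(ml_full.llf) and np.isfinite(ml_null.llf):
            structure_used = name
            break
        logger.warning("singular random-effects fit (%s) for %s; simplifying",
                       name, response)
    else:
        reml_fit = smf.ols(full_f, data=data).fit()
        ml_full = reml_fit
        ml_null = smf.ols(null_f, data=data).fit()
    lr = max(0.0, 2.0 * (ml_full.llf - ml_null.llf))
    lr_df = len(levels) - 1
    lr_p = float(sps.chi2.sf(lr, lr_df))
    est = pd.DataFrame({
        "estimate": [reml_fit.params[f"{lev_term}[{lev}]"] for lev in levels],
        "se": [reml_fit.bse[f"{lev_term}[{lev}]"] for lev in levels],
    }, index=pd.Index(levels, name="treatment"))
    posthoc = None
    if lr_p < 0.05 or posthoc_always:
        posthoc = _tukey_posthoc_from_levels(reml_fit, data, groups, levels, lev_term)
    return MixedModelResult(response=response, estimates=est, lr_chi2=float(lr),
                            lr_df=lr_df, lr_p=lr_p, posthoc=posthoc, model=reml_fit,
                            extra={"coding": "cell-means",
                                   "random_structure": structure_used})


def _tukey_posthoc_from_levels(reml_fit, data, groups_col, levels, lev_term):
    params = reml_fit.params
    cov = reml_fit.cov_params()
    df = max(data[groups_col].nunique() - len(levels), 2)
    k = len(levels)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ca, cb = f"{lev_term}[{levels[i]}]", f"{lev_term}[{levels[j]}]"
            diff = params[ca] - params[cb]
            var = cov.loc[ca, ca] + cov.loc[cb, cb] - 2 * cov.loc[ca, cb]
            se = float(np.sqrt(max(var, 1e-12)))  # guard near-singular fits
            t = float(diff / se)
            p_adj = float(sps.studentized_range.sf(abs(t) * np.sqrt(2.0), k, df))
            rows.append({"pair": f"{levels[i]}-{levels[j]}", "diff": float(diff),
                         "se": se, "t": t, "df": float(df),
                         "p_adj": min(p_adj, 1.0)})
    return pd.DataFrame(rows)


def lmm_lr_term_tests(data: pd.DataFrame, response: str, groups: str,
                      terms: list[tuple[str, str, int]]) -> pd.DataFrame:
    """Sequential LR tests for nested fixed-effect structures.

    ``terms`` is a list of (label, full_formula_rhs, df_constrained); each
    entry is compared by ML likelihood ratio against the previous entry's
    formula.  Used for the homing-timing model (distance, then treatment,
    then interaction).
    """
    rows = []
    prev = None
    for label, rhs, df_c in terms:
        fit = _fit_mixedlm(f"{response} ~ {rhs}", data, groups, None, reml=False)
        if prev is not None:
            lr = max(0.0, 2.0 * (fit.llf - prev.llf))
            rows.append({"term": label, "chi2": lr, "df": df_c,
                         "p": float(sps.chi2.sf(lr, df_c))})
        prev = fit
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# foraging success
# --------------------------------------------------------------------------

def incubation_loss_rate(weighings: pd.DataFrame) -> float:
    """Mean percentage mass loss per day across repeat-weighed birds.

    ``weighings`` needs columns mass1_g, mass2_g, interval_days (first and
    second weighing within one incubation stint).  The per-bird rate is
    100 * (m1 - m2) / m1 / days; the reported rate is its mean over birds.
    """
    if (weighings["interval_days"] <= 0).any():
        raise ValueError("weighing intervals must be positive")
    rates = (100.0 * (weighings["mass1_g"] - weighings["mass2_g"])
             / weighings["mass1_g"] / weighings["interval_days"])
    return float(rates.mean())


def corrected_mass_gain(records: pd.DataFrame, loss_rate_pct_per_day: float) -> pd.DataFrame:
    """Correct raw mass change for pre-departure incubation mass loss.

    Departure mass is the deployment mass discounted by the loss rate over
    the days spent incubating before departure; the corrected gain is the
    retrieval mass minus that estimated departure mass.  With zero days on
    the nest the corrected gain equals the raw gain.
    """
    out = records.copy()
    out["raw_gain_g"] = out["retrieve_mass_g"] - out["deploy_mass_g"]
    depart = out["deploy_mass_g"] * (
        1.0 - loss_rate_pct_per_day * out["days_incubating_before_departure"] / 100.0)
    out["departure_mass_g"] = depart
    out["corrected_gain_g"] = out["retrieve_mass_g"] - depart
    return out


def mass_foraging_glm(records: pd.DataFrame) -> pd.DataFrame:
    """Sequential-F GLM of corrected mass gain on foraging effort.

    Predictors enter in order: foraging effort (number of fixes labelled
    foraging), treatment, and their interaction; the returned table has one
    row per term with sequential (type-I) F, df and p, mirroring how such
    models are reported for small balanced field samples.
    """
    need = {"corrected_gain_g", "foraging_fix_count", "treatment"}
    if missing := need - set(records.columns):
        raise ValueError(f"records missing columns: {sorted(missing)}")
    n = len(records)
    if n < 5:
        raise ValueError("too few birds for the mass GLM")
    if np.isclose(records["corrected_gain_g"].std(ddof=0), 0.0):
        raise ValueError("degenerate fit: response has zero variance")
    steps = [
        ("foraging_effort", "corrected_gain_g ~ foraging_fix_count"),
        ("treatment", "corrected_gain_g ~ foraging_fix_count + C(treatment)"),
        ("treatment_x_effort",
         "corrected_gain_g ~ foraging_fix_count * C(treatment)"),
    ]
    prev = smf.ols("corrected_gain_g ~ 1", data=records).fit()
    rows = []
    for label, formula in steps:
        fit = smf.ols(formula, data=records).fit()
        df_num = fit.df_model - prev.df_model
        df_den = fit.df_resid
        if df_num <= 0 or df_den <= 0 or fit.ssr <= 0:
            rows.append({"term": label, "F": np.nan, "df_num": int(df_num),
                         "df_den": int(df_den), "p": np.nan})
            prev = fit
            continue
        F = ((prev.ssr - fit.ssr) / df_num) / (fit.ssr / df_den)
        rows.append({"term": label, "F": float(F), "df_num": int(df_num),
                     "df_den": int(df_den),
                     "p": float(sps.f.sf(F, df_num, df_den))})
        prev = fit
    return pd.DataFrame(rows).set_index("term")
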