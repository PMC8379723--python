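"""Regression stages: trip-to-trip co-adjustment and age trends.

Two questions are asked of the segmented timelines.  First, does a
parent adjust the duration of its foraging trip to the duration of the
last trip its partner completed (trip-to-trip co-adjustment)?  Second,
do nest bouts shorten as the offspring grow?  Both responses are
strictly positive durations, modelled with a gamma GLM and logarithmic
link.  Full models are reported (no term dropping).

The requested random-effect structures (couple / bird / colony) are
recorded on every fit; because the fitting machinery here provides no
gamma or beta mixed models, fits are fixed-effects GLMs with
cluster-robust (sandwich) covariance grouped by the top-level requested
effect, and the report's ``fallback`` flag says so.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.othermod.betareg import BetaModel


@dataclass
class ModelFit:
    """A fitted regression: coefficients, uncertainty, provenance."""

    formula: str
    family: str
    coefficients: pd.DataFrame          # index=term; columns: estimate, se, stat, p
    random_effects_requested: tuple
    cluster_groups: str | None
    converged: bool
    fallback: str | None = None
    n_obs: int = 0
    stat_label: str = "z"

    def coef(self, term: str) -> float:
        return float(self.coefficients.loc[term, "estimate"])

    def se(self, term: str) -> float:
        return float(self.coefficients.loc[term, "se"])

    def ci(self, term: str, level: float = 0.95) -> tuple[float, float]:
        from scipy.stats import norm
        z = norm.ppf(0.5 + level / 2.0)
        est, se = self.coef(term), self.se(term)
        return est - z * se, est + z * se

    def to_dict(self) -> dict:
        return dict(
            formula=self.formula, family=self.family,
            coefficients=self.coefficients.reset_index().to_dict(orient="records"),
            random_effects_requested=list(self.random_effects_requested),
            cluster_groups=self.cluster_groups, converged=self.converged,
            fallback=self.fallback, n_obs=self.n_obs, stat_label=self.stat_label,
        )


class RankDeficiencyError(ValueError):
    pass


def _check_rank(X: pd.DataFrame) -> None:
    arr = np.asarray(X, dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        const = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (constant or collinear terms: {const})")


def _wrap_result(res, formula, family, requested, cluster_name, stat_label="z",
                 fallback=None) -> ModelFit:
    coefs = pd.DataFrame(dict(
        estimate=res.params, se=res.bse, stat=res.tvalues, p=res.pvalues))
    coefs.index.name = "term"
    converged = bool(getattr(res, "converged", True) or getattr(getattr(res, "mle_retvals", {}), "get", lambda *_: True)("converged", True))
    return ModelFit(formula, family, coefs, tuple(requested), cluster_name,
                    converged, fallback=fallback, n_obs=int(res.nobs),
                    stat_label=stat_label)


_GLMM_FALLBACK = ("random effects requested but fitted as fixed-effects GLM "
                  "with cluster-robust errors")


def cluster_gamma_fit(y, X: pd.DataFrame, groups, requested_random_effects=(),
                      formula: str = "") -> ModelFit:
    """Gamma GLM with log link and cluster-robust covariance."""
    y = np.asarray(y, dtype=float)
    if np.any(y <= 0):
        raise ValueError("gamma responses must be strictly positive")
    X = sm.add_constant(pd.DataFrame(X).astype(float), has_constant="add")
    _check_rank(X)
    model = sm.GLM(y, X, family=sm.families.Gamma(link=sm.families.links.Log()))
    codes = pd.Categorical(np.asarray(groups)).codes
    res = model.fit(cov_type="cluster", cov_kwds={"groups": codes})
    return _wrap_result(
        res, formula or "y ~ " + " + ".join(c for c in X.columns if c != "const"),
        "gamma(log)", requested_random_effects,
        getattr(groups, "name", "cluster"), stat_label="z",
        fallback=_GLMM_FALLBACK if requested_random_effects else None)


def cluster_beta_fit(y, X: pd.DataFrame, groups, requested_random_effects=(),
                     formula: str = "") -> ModelFit:
    """Beta regression (logit mean link) with cluster-robust covariance.

    The response must lie strictly inside (0, 1); shrink boundary values
    before calling.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y <= 0) | (y >= 1)):
        raise ValueError("beta responses must lie strictly in (0, 1)")
    X = sm.add_constant(pd.DataFrame(X).astype(float), has_constant="add")
    _check_rank(X)
    model = BetaModel(y, X)
    codes = pd.Categorical(np.asarray(groups)).codes
    try:
        res = model.fit(cov_type="cluster", cov_kwds={"groups": codes}, disp=False)
        fallback = _GLMM_FALLBACK if requested_random_effects else None
    except Exception:
        res = model.fit(disp=False)
        fallback = "cluster covariance unavailable; model-based SEs reported"
    return _wrap_result(
        res, formula or "y ~ " + " + ".join(c for c in X.columns if c != "const"),
        "beta(logit)", requested_random_effects,
        getattr(groups, "name", "cluster"), stat_label="z", fallback=fallback)


# ---------------------------------------------------------------------------
# trip-to-trip co-adjustment
# ---------------------------------------------------------------------------


def build_response_table(trips: pd.DataFrame, pair_of: dict[str, str],
                         sex_of: dict[str, str],
                         partner_rule: str = "ended_before") -> pd.DataFrame:
    """Match every focal trip to the partner's preceding trip.

    One row per focal trip that has a preceding partner trip: focal
    duration, the duration of the partner's most recent trip that ended
    before the focal departure (``partner_rule="ended_before"``, the
    default: a trip still in progress is not "previous"; the
    ``"started_before"`` alternative matches on start times), sex, ids
    and offspring age.  Focal trips with no prior partner trip are
    dropped.
    """
    if partner_rule not in ("ended_before", "started_before"):
        raise ValueError(f"unknown partner_rule {partner_rule!r}")
    trips = trips.sort_values(["individual_id", "start"], kind="mergesort")
    by_ind = {ind: grp for ind, grp in trips.groupby("individual_id")}
    partners: dict[str, str] = {}
    pair_members: dict[str, list] = {}
    for ind, pair in pair_of.items():
        pair_members.setdefault(pair, []).append(ind)
    for pair, members in pair_members.items():
        if len(members) == 2:
            partners[members[0]] = members[1]
            partners[members[1]] = members[0]
    rows = []
    for ind, grp in by_ind.items():
        mate = partners.get(ind)
        if mate is None or mate not in by_ind:
            continue
        mg = by_ind[mate]
        key = "end" if partner_rule == "ended_before" else "start"
        mate_times = mg[key].to_numpy()
        mate_durs = mg["duration_h"].to_numpy()
        order = np.argsort(mate_times)
        mate_times, mate_durs = mate_times[order], mate_durs[order]
        idx = np.searchsorted(mate_times, grp["start"].to_numpy(), side="left") - 1
        for (_, trip), j in zip(grp.iterrows(), idx):
            if j < 0:
                continue
            rows.append(dict(
                individual_id=ind, pair_id=pair_of[ind], sex=sex_of[ind],
                trip_id=trip.get("trip_id"),
                duration_h=trip["duration_h"],
                partner_prev_duration_h=float(mate_durs[j]),
                offspring_age=trip.get("offspring_age_at_start", np.nan),
            ))
    return pd.DataFrame(rows, columns=["individual_id", "pair_id", "sex", "trip_id",
                                       "duration_h", "partner_prev_duration_h",
                                       "offspring_age"])


def fit_trip_response(table: pd.DataFrame) -> ModelFit:
    """Gamma(log) model of focal trip duration on the partner's preceding
    trip duration, sex and their interaction; clustered by bird."""
    tab = table.dropna(subset=["duration_h", "partner_prev_duration_h"]).copy()
    sex = (tab["sex"].astype(str).str.lower().str.startswith("m")).astype(float)
    X = pd.DataFrame(dict(
        partner_prev_duration_h=tab["partner_prev_duration_h"].to_numpy(),
        sex_male=sex.to_numpy(),
        partner_prev_x_sex=tab["partner_prev_duration_h"].to_numpy() * sex.to_numpy(),
    ))
    return cluster_gamma_fit(
        tab["duration_h"], X, groups=tab["individual_id"],
        requested_random_effects=("bird", "colony"),
        formula="trip_duration ~ partner_prev_duration * sex")


def fit_bout_age(bouts: pd.DataFrame, sex_of: dict[str, str] | None = None,
                 pair_of: dict[str, str] | None = None,
                 exclude_censored: bool = True) -> ModelFit:
    """Gamma(log) model of nest-bout duration on offspring age, sex and
    their interaction; clustered by couple (falling back to bird when no
    pair mapping is given).  Censored bouts are excluded by default."""
    bo = bouts.copy()
    if exclude_censored:
        for col in ("censored_start", "censored_end"):
            if col in bo.columns:
                bo = bo[~bo[col].astype(bool)]
    bo = bo.dropna(subset=["duration_h", "offspring_age_at_start"])
    bo = bo[bo["duration_h"] > 0]
    if sex_of is not None:
        sex = bo["individual_id"].map(sex_of).astype(str).str.lower().str.startswith("m").astype(float)
    elif "sex" in bo.columns:
        sex = bo["sex"].astype(str).str.lower().str.startswith("m").astype(float)
    else:
        sex = pd.Series(np.nan, index=bo.index)
    age = bo["offspring_age_at_start"].astype(float)
    X = pd.DataFrame(dict(offspring_age=age.to_numpy()))
    if sex.notna().all():
        X["sex_male"] = sex.to_numpy()
        X["age_x_sex"] = age.to_numpy() * sex.to_numpy()
    groups = bo["individual_id"].map(pair_of) if pair_of else bo["individual_id"]
    return cluster_gamma_fit(
        bo["duration_h"], X, groups=groups,
        requested_random_effects=("couple", "bird", "colony"),
        formula="bout_duration ~ offspring_age * sex")
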