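"""Within-pair similarity of investment parameters via MRPP.

The Multiple Response Permutation Procedure compares within-group to
between-group dissimilarity.  The test statistic delta is the weighted
mean of within-group mean pairwise dissimilarities, with weights
n_g / N; a smaller observed delta than expected under random regrouping
indicates that group members (here: the two parents of a pair, each
contributing per-trip observations) resemble each other.  Significance
comes from randomly reassigning observations to groups of the original
sizes (999 permutations by default; exhaustive enumeration when the
assignment space is small), one-tailed low.

Each investment parameter — total distance (km), trip duration (h), and
hours spent resting, flying and foraging outside the colony — is tested
separately and per colony.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

INVESTMENT_PARAMETERS = (
    "total_distance_km",
    "trip_duration_h",
    "resting_h",
    "flying_h",
    "foraging_h",
)


def _multiset_permutations(items: list):
    """Yield distinct permutations of a multiset (lexicographic)."""
    items = sorted(items)
    n = len(items)
    yield tuple(items)
    while True:
        i = n - 2
        while i >= 0 and items[i] >= items[i + 1]:
            i -= 1
        if i < 0:
            return
        j = n - 1
        while items[j] <= items[i]:
            j -= 1
        items[i], items[j] = items[j], items[i]
        items[i + 1:] = reversed(items[i + 1:])
        yield tuple(items)


def _n_assignments(sizes: np.ndarray) -> float:
    from math import factorial
    total = factorial(int(sizes.sum()))
    for s in sizes:
        total //= factorial(int(s))
    return total


@dataclass
class MrppResult:
    observed_delta: float
    expected_delta: float        # mean of all pairwise dissimilarities (H0)
    within_mean: float           # mean within-pair dissimilarity, normalised scale
    between_mean: float          # mean between-pair dissimilarity, normalised scale
    p: float
    n_perm: int
    exact: bool
    n_obs: int
    n_groups: int
    a_statistic: float           # chance-corrected within-group agreement

    def to_row(self) -> dict:
        return dict(observed_delta=self.observed_delta, expected_delta=self.expected_delta,
                    within=self.within_mean, between=self.between_mean, p=self.p,
                    n_perm=self.n_perm, exact=self.exact, n_obs=self.n_obs,
                    n_groups=self.n_groups, A=self.a_statistic)


def _delta(D: np.ndarray, labels: np.ndarray, uniq: np.ndarray, weights: np.ndarray) -> float:
    val = 0.0
    for g, w in zip(uniq, weights):
        idx = np.flatnonzero(labels == g)
        sub = D[np.ix_(idx, idx)]
        m = len(idx)
        val += w * (sub.sum() / (m * (m - 1)))
    return val


def mrpp(values, groups, metric: str = "euclidean", n_perm: int = 999,
         rng: np.random.Generator | None = None, weight: str = "n",
         exact_max: int = 20000) -> MrppResult:
    """MRPP test of group structure for one parameter.

    ``values`` is (N,) or (N, d); ``groups`` the group label per
    observation.  ``weight='n'`` uses the common n_g/N group weights
    (``'n-1'`` uses (n_g - 1)/(N - k)).  The one-tailed p-value is the
    probability of a permuted delta at most as small as the observed:
    exact over all distinct assignments when their number is at most
    ``exact_max``, else Monte-Carlo with the add-one estimator.
    """
    rng = rng or np.random.default_rng()
    X = np.asarray(values, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    labels = np.asarray(groups)
    uniq, counts = np.unique(labels, return_counts=True)
    small = uniq[counts < 2]
    if small.size:
        warnings.warn(f"groups with <2 observations excluded: {list(small)}", stacklevel=2)
        keep = ~np.isin(labels, small)
        X, labels = X[keep], labels[keep]
        uniq, counts = np.unique(labels, return_counts=True)
    N = len(labels)
    k = len(uniq)
    if k < 2:
        raise ValueError("MRPP needs at least 2 groups with >=2 observations")
    D = squareform(pdist(X, metric=metric))
    if weight == "n":
        weights = counts / N
    elif weight == "n-1":
        weights = (counts - 1) / (N - k)
    else:
        raise ValueError(f"unknown weight {weight!r}")

    observed = _delta(D, labels, uniq, weights)
    # expected delta under no group structure: mean original dissimilarity
    iu = np.triu_indices(N, 1)
    expected = float(D[iu].mean())

    # within/between means on a min-max normalised scale
    rngs = X.max(axis=0) - X.min(axis=0)
    rngs[rngs == 0] = 1.0
    Dn = squareform(pdist(X / rngs, metric=metric))
    same = labels[:, None] == labels[None, :]
    within_mean = float(Dn[iu][same[iu]].mean())
    between_mean = float(Dn[iu][~same[iu]].mean())

    n_arr = _n_assignments(counts)
    exact = n_arr <= exact_max
    if exact:
        deltas = np.array([
            _delta(D, np.asarray(perm), uniq, weights)
            for perm in _multiset_permutations(list(labels))
        ])
        p = float((deltas <= observed + 1e-12).mean())
        n_used = len(deltas)
    else:
        count = 0
        lab = labels.copy()
        for _ in range(n_perm):
            rng.shuffle(lab)
            if _delta(D, lab, uniq, weights) <= observed + 1e-12:
                count += 1
        p = (1.0 + count) / (n_perm + 1.0)
        n_used = n_perm
    A = 1.0 - observed / expected if expected > 0 else float("nan")
    return MrppResult(float(observed), expected, within_mean, between_mean, p,
                      n_used, exact, N, k, float(A))


# ---------------------------------------------------------------------------
# investment table
# ---------------------------------------------------------------------------


def build_investment_table(trips: pd.DataFrame, fixes: pd.DataFrame | None = None,
                           behaviour_col: str = "pred_behaviour",
                           fix_interval_s: float = 180.0) -> pd.DataFrame:
    """Per-trip investment parameters for MRPP.

    Each trip contributes total distance (km) and duration (h) from the
    trip table, plus resting/flying/foraging hours counted as
    fix_interval x the number of the trip's fixes predicted as
    rest/commute/forage.  Without ``fixes`` (or for trips with no
    annotated fixes) the behavioural columns are left missing while
    distance and duration are still filled.
    """
    rows = []
    ann = None
    if fixes is not None and behaviour_col in fixes.columns:
        ann = fixes.sort_values(["individual_id", "timestamp"], kind="mergesort")
    per_fix_h = fix_interval_s / 3600.0
    for _, trip in trips.iterrows():
        row = dict(
            pair_id=trip.get("pair_id"),
            individual_id=trip["individual_id"],
            colony_id=trip.get("colony_id"),
            trip_id=trip.get("trip_id"),
            total_distance_km=trip["total_distance_km"],
            trip_duration_h=trip["duration_h"],
            resting_h=np.nan, flying_h=np.nan, foraging_h=np.nan,
        )
        if ann is not None:
            sub = ann[(ann["individual_id"] == trip["individual_id"])
                      & (ann["timestamp"] > trip["start"])
                      & (ann["timestamp"] < trip["end"])]
            if len(sub):
                counts = sub[behaviour_col].value_counts()
                row["resting_h"] = per_fix_h * int(counts.get("rest", 0))
                row["flying_h"] = per_fix_h * int(counts.get("commute", 0))
                row["foraging_h"] = per_fix_h * int(counts.get("forage", 0))
        rows.append(row)
    return pd.DataFrame(rows)


def mrpp_by_colony(table: pd.DataFrame, parameters=INVESTMENT_PARAMETERS,
                   n_perm: int = 999, rng: np.random.Generator | None = None,
                   metric: str = "euclidean", weight: str = "n") -> pd.DataFrame:
    """Run MRPP for every investment parameter, separately per colony,
    grouping observations by pair.  Returns a tidy results table."""
    rng = rng or np.random.default_rng()
    rows = []
    colonies = table["colony_id"].dropna().unique() if "colony_id" in table.columns else [None]
    for colony in colonies:
        sub = table if colony is None else table[table["colony_id"] == colony]
        for param in parameters:
            vals = sub[[param, "pair_id"]].dropna()
            if vals["pair_id"].nunique() < 2:
                warnings.warn(f"colony {colony!r}: fewer than 2 pairs with {param}; skipped",
                              stacklevel=2)
                continue
            res = mrpp(vals[param].to_numpy(), vals["pair_id"].to_numpy(),
                       metric=metric, n_perm=n_perm, rng=rng, weight=weight)
            rows.append(dict(colony_id=colony, parameter=param, **res.to_row()))
    return pd.DataFrame(rows)
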