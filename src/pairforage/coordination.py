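"""Temporal coordination of nest visits: statistics and randomisation null.

Four statistics summarise how a pair times its alternating foraging
trips and nest bouts:

* ``male`` / ``female`` — the proportion of the focal sex's departures
  at which the partner was inside the colony,
* ``partner`` — both sexes pooled,
* ``attendance`` — the fraction of the shared observation window during
  which at least one parent was in the colony.

The null model for uncoordinated care permutes each individual's trip
durations and bout durations as two independent multisets while keeping
the alternation order and starting state, then rebuilds the timeline
from the window start.  Because the permuted durations tile the same
window, per-individual total trip time and bout time are preserved
exactly; only the between-mate phase relationship is destroyed.  The
observed statistics are compared one-tailed against 999 such rebuilds
(coordination = observed significantly above the 95th percentile of the
null).  When the arrangement space is small enough to enumerate, the
test is run exactly over all arrangements instead of by sampling.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .models import ModelFit, cluster_beta_fit

STAT_NAMES = ("male", "female", "partner", "attendance")

_TILING_TOL_H = 1.0 / 3600.0  # one second


class DegenerateScheduleError(ValueError):
    pass


# ---------------------------------------------------------------------------
# timelines
# ---------------------------------------------------------------------------


@dataclass
class IndividualTimeline:
    """One parent's alternating trips/bouts over a window, in hours."""

    trips: np.ndarray  # (n, 2) [start, end]
    bouts: np.ndarray  # (m, 2)
    window: tuple[float, float]
    trip_censored_start: np.ndarray | None = None

    def __post_init__(self):
        self.trips = np.asarray(self.trips, dtype=float).reshape(-1, 2)
        self.bouts = np.asarray(self.bouts, dtype=float).reshape(-1, 2)
        if self.trip_censored_start is None:
            cs = np.zeros(len(self.trips), dtype=bool)
            if len(self.trips) and self.trips[0, 0] <= self.window[0] + _TILING_TOL_H and (
                not len(self.bouts) or self.bouts[0, 0] > self.trips[0, 0]
            ):
                cs[0] = True
            self.trip_censored_start = cs
        else:
            self.trip_censored_start = np.asarray(self.trip_censored_start, dtype=bool)

    @property
    def starts_with_trip(self) -> bool:
        if not len(self.trips):
            return False
        if not len(self.bouts):
            return True
        return self.trips[0, 0] < self.bouts[0, 0]

    def alternation(self) -> list[str]:
        """Interval type sequence in time order, e.g. ['b','t','b']."""
        seq = []
        ti = bi = 0
        while ti < len(self.trips) or bi < len(self.bouts):
            t_start = self.trips[ti, 0] if ti < len(self.trips) else math.inf
            b_start = self.bouts[bi, 0] if bi < len(self.bouts) else math.inf
            if t_start < b_start:
                seq.append("t")
                ti += 1
            else:
                seq.append("b")
                bi += 1
        return seq

    def check_tiling(self, tol: float = _TILING_TOL_H) -> None:
        """Trips and bouts must partition the window without gap/overlap."""
        iv = np.vstack([self.trips, self.bouts]) if len(self.trips) or len(self.bouts) else np.empty((0, 2))
        if not len(iv):
            raise DegenerateScheduleError("empty timeline")
        iv = iv[np.argsort(iv[:, 0])]
        if abs(iv[0, 0] - self.window[0]) > tol or abs(iv[-1, 1] - self.window[1]) > tol:
            raise DegenerateScheduleError("timeline does not span the window")
        gaps = iv[1:, 0] - iv[:-1, 1]
        if np.any(np.abs(gaps) > tol):
            raise DegenerateScheduleError("timeline has gaps or overlaps")

    def in_colony_fraction(self) -> float:
        L = self.window[1] - self.window[0]
        return float(np.sum(self.bouts[:, 1] - self.bouts[:, 0]) / L) if L > 0 else float("nan")

    def permutable_masks(self, overrun: str = "pin") -> tuple[np.ndarray, np.ndarray]:
        """Which trip/bout durations may be permuted under the null.

        With ``overrun="pin"`` (default) the chronologically last
        interval — whose duration is truncated by the end of
        observation and therefore not exchangeable with complete
        durations — stays in place, as does a leading censored-start
        trip.  With ``overrun="clip"`` every duration is permuted.
        """
        tmask = np.ones(len(self.trips), dtype=bool)
        bmask = np.ones(len(self.bouts), dtype=bool)
        if overrun == "clip":
            return tmask, bmask
        if overrun != "pin":
            raise ValueError(f"unknown overrun scheme {overrun!r}")
        seq = self.alternation()
        if seq and seq[-1] == "t" and len(self.trips):
            tmask[-1] = False
        elif seq and len(self.bouts):
            bmask[-1] = False
        if seq and seq[0] == "t" and len(self.trips) and self.trip_censored_start[0]:
            tmask[0] = False
        return tmask, bmask


@dataclass
class PairSchedule:
    """The merged two-parent timeline over the shared observation window."""

    pair_id: str
    male: IndividualTimeline
    female: IndividualTimeline

    @property
    def window(self) -> tuple[float, float]:
        return self.male.window

    @classmethod
    def from_simulation(cls, schedule: dict, window_h: float) -> "PairSchedule":
        """Build from a simulator truth schedule (hours already)."""
        tls = {}
        for sex in ("m", "f"):
            s = schedule[sex]
            tls[sex] = IndividualTimeline(s["trips"], s["bouts"], (0.0, window_h))
        return cls(schedule["pair_id"], tls["m"], tls["f"])

    @classmethod
    def from_frames(cls, trips: pd.DataFrame, bouts: pd.DataFrame, pair_id: str,
                    sex_of: dict[str, str]) -> "PairSchedule":
        """Build from segmented trips/bouts tables of the two pair members.

        ``sex_of`` maps individual_id to 'male'/'female'.  Timestamps are
        converted to hours since the shared window start (the later of
        the two individuals' first observations); intervals are clipped
        to the shared window.
        """
        ids = list(sex_of)
        pieces = {}
        spans = []
        for ind in ids:
            tr = trips[trips["individual_id"] == ind]
            bo = bouts[bouts["individual_id"] == ind]
            iv = pd.concat([tr[["start", "end"]], bo[["start", "end"]]])
            if not len(iv):
                raise DegenerateScheduleError(f"no intervals for {ind!r}")
            spans.append((iv["start"].min(), iv["end"].max()))
            pieces[ind] = (tr, bo)
        w0 = max(s for s, _ in spans)
        w1 = min(e for _, e in spans)
        if not w1 > w0:
            raise DegenerateScheduleError("individuals share no observation window")
        L = (w1 - w0).total_seconds() / 3600.0

        def to_hours(df, censored_col=None):
            s = (pd.to_datetime(df["start"], utc=True) - w0).dt.total_seconds().to_numpy() / 3600.0
            e = (pd.to_datetime(df["end"], utc=True) - w0).dt.total_seconds().to_numpy() / 3600.0
            clipped_start = s < 0
            s2, e2 = np.clip(s, 0.0, L), np.clip(e, 0.0, L)
            keep = e2 > s2
            cens = clipped_start
            if censored_col is not None and censored_col in df.columns:
                cens = cens | df[censored_col].to_numpy(dtype=bool)
            return np.column_stack([s2, e2])[keep], cens[keep]

        tls = {}
        for ind in ids:
            tr, bo = pieces[ind]
            tr_iv, tr_cs = to_hours(tr, "censored_start")
            bo_iv, _ = to_hours(bo)
            tls[sex_of[ind]] = IndividualTimeline(tr_iv, bo_iv, (0.0, L), trip_censored_start=tr_cs)
        return cls(pair_id, tls["male"], tls["female"])


# ---------------------------------------------------------------------------
# observed statistics
# ---------------------------------------------------------------------------


def partner_present_at_departure(focal: IndividualTimeline,
                                 partner: IndividualTimeline) -> tuple[float, int]:
    """Proportion of the focal bird's departures with the partner in the colony.

    A departure at time t counts as "partner present" when some partner
    bout [s, e) contains t with the left endpoint closed: a partner
    returning exactly at t counts, a partner departing exactly at t does
    not.  Censored-start trips (departure not observed) are excluded.
    Returns (proportion, number of eligible departures); the proportion
    is NaN when no departure is eligible.
    """
    dep = focal.trips[~focal.trip_censored_start, 0]
    if dep.size == 0:
        return float("nan"), 0
    bs, be = partner.bouts[:, 0], partner.bouts[:, 1]
    present = ((bs[None, :] <= dep[:, None]) & (dep[:, None] < be[None, :])).any(axis=1)
    return float(present.mean()), int(dep.size)


def nest_attendance(pair: PairSchedule) -> float:
    """Fraction of the shared window with at least one parent in the colony."""
    w0, w1 = pair.window
    L = w1 - w0
    if not L > 0:
        raise ValueError("empty observation window")
    a = np.sum(pair.male.bouts[:, 1] - pair.male.bouts[:, 0])
    b = np.sum(pair.female.bouts[:, 1] - pair.female.bouts[:, 0])
    inter = _interval_overlap(pair.male.bouts[None], pair.female.bouts[None])[0]
    return float((a + b - inter) / L)


def _interval_overlap(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Total overlap length between interval sets, batched over axis 0.

    A: (R, n, 2), B: (R, m, 2) -> (R,) summed pairwise intersections
    (correct when each set is internally disjoint).
    """
    if A.shape[1] == 0 or B.shape[1] == 0:
        return np.zeros(A.shape[0])
    lo = np.maximum(A[:, :, None, 0], B[:, None, :, 0])
    hi = np.minimum(A[:, :, None, 1], B[:, None, :, 1])
    return np.clip(hi - lo, 0.0, None).sum(axis=(1, 2))


@dataclass
class CoordinationStats:
    prop_male: float
    prop_female: float
    prop_partner: float
    attendance: float
    n_male: int = 0
    n_female: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.prop_male, self.prop_female, self.prop_partner, self.attendance])


def compute_stats(pair: PairSchedule) -> CoordinationStats:
    pm, nm = partner_present_at_departure(pair.male, pair.female)
    pf, nf = partner_present_at_departure(pair.female, pair.male)
    if nm + nf:
        pooled = (np.nan_to_num(pm) * nm + np.nan_to_num(pf) * nf) / (nm + nf)
    else:
        pooled = float("nan")
    return CoordinationStats(pm, pf, float(pooled), nest_attendance(pair), nm, nf)


# ---------------------------------------------------------------------------
# randomisation null
# ---------------------------------------------------------------------------


def _canonical(tl: IndividualTimeline) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Alternation sequence plus trip/bout duration multisets in time order."""
    tl.check_tiling()
    seq = tl.alternation()
    tdur = tl.trips[:, 1] - tl.trips[:, 0]
    bdur = tl.bouts[:, 1] - tl.bouts[:, 0]
    return seq, tdur, bdur


def _rebuild(seq: list[str], tdur: np.ndarray, bdur: np.ndarray, w0: float
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Boundaries of rebuilt timelines for a batch of permuted durations.

    tdur: (R, nt), bdur: (R, nb).  Returns (trip_starts, trip_ends,
    bout_starts, bout_ends) each (R, n).
    """
    R = tdur.shape[0]
    n = tdur.shape[1] + bdur.shape[1]
    out = np.empty((R, n))
    t_pos = np.array([k for k, c in enumerate(seq) if c == "t"], dtype=int)
    b_pos = np.array([k for k, c in enumerate(seq) if c == "b"], dtype=int)
    out[:, t_pos] = tdur
    out[:, b_pos] = bdur
    bounds = np.concatenate([np.full((R, 1), w0), w0 + np.cumsum(out, axis=1)], axis=1)
    return bounds[:, t_pos], bounds[:, t_pos + 1], bounds[:, b_pos], bounds[:, b_pos + 1]


def _permute_batch(dur: np.ndarray, mask: np.ndarray, R: int,
                   rng: np.random.Generator) -> np.ndarray:
    """R random rearrangements of the permutable entries of ``dur``;
    pinned entries keep their position."""
    out = np.tile(dur, (R, 1)).astype(float)
    idx = np.flatnonzero(mask)
    if idx.size > 1:
        sub = dur[idx]
        out[:, idx] = sub[np.argsort(rng.random((R, idx.size)), axis=1)]
    return out


def randomise_schedule(tl: IndividualTimeline, rng: np.random.Generator,
                       overrun: str = "pin") -> IndividualTimeline:
    """One draw from the null: permute trip and bout duration multisets,
    keep alternation order and starting state, rebuild from window start.
    Window-truncated (and censored-start) durations stay in place under
    the default ``overrun="pin"`` scheme."""
    seq, tdur, bdur = _canonical(tl)
    tmask, bmask = tl.permutable_masks(overrun)
    ts, te, bs, be = _rebuild(
        seq, _permute_batch(tdur, tmask, 1, rng), _permute_batch(bdur, bmask, 1, rng),
        tl.window[0]
    )
    return IndividualTimeline(
        np.column_stack([ts[0], te[0]]), np.column_stack([bs[0], be[0]]), tl.window
    )


def _batch_stats(seq_m, ts_m, te_m, bs_m, be_m, seq_f, ts_f, te_f, bs_f, be_f,
                 L: float) -> np.ndarray:
    """The four statistics for a batch of rebuilt pair timelines -> (R, 4)."""
    R = ts_m.shape[0]

    def presence(dep, bs, be, leading_trip: bool):
        if leading_trip and dep.shape[1]:
            dep = dep[:, 1:]  # departure of a window-leading trip is unobserved
        if dep.shape[1] == 0:
            return np.zeros(R), 0
        present = ((bs[:, None, :] <= dep[:, :, None]) & (dep[:, :, None] < be[:, None, :])).any(axis=2)
        return present.sum(axis=1), dep.shape[1]

    k_m, n_m = presence(ts_m, bs_f, be_f, seq_m[0] == "t")
    k_f, n_f = presence(ts_f, bs_m, be_m, seq_f[0] == "t")
    prop_m = k_m / n_m if n_m else np.full(R, np.nan)
    prop_f = k_f / n_f if n_f else np.full(R, np.nan)
    pooled = (k_m + k_f) / (n_m + n_f) if (n_m + n_f) else np.full(R, np.nan)
    in_m = (be_m - bs_m).sum(axis=1)
    in_f = (be_f - bs_f).sum(axis=1)
    inter = _interval_overlap(np.stack([bs_m, be_m], axis=2), np.stack([bs_f, be_f], axis=2))
    att = (in_m + in_f - inter) / L
    return np.column_stack([prop_m, prop_f, pooled, att])


@dataclass
class RandomisationResult:
    pair_id: str
    observed: CoordinationStats
    expected: CoordinationStats
    difference: np.ndarray
    p: np.ndarray                     # one per statistic, order STAT_NAMES
    n_replicates: int
    exact: bool = False
    untestable: bool = False
    null_samples: np.ndarray | None = None

    def to_row(self) -> dict:
        row = {"pair_id": self.pair_id, "untestable": self.untestable,
               "exact": self.exact, "n_replicates": self.n_replicates}
        obs, exp = self.observed.as_array(), self.expected.as_array()
        for k, name in enumerate(STAT_NAMES):
            row[f"observed_{name}"] = obs[k]
            row[f"expected_{name}"] = exp[k]
            row[f"difference_{name}"] = self.difference[k]
            row[f"p_{name}"] = self.p[k]
        return row


def _count_arrangements(nt_m, nb_m, nt_f, nb_f) -> float:
    return (math.factorial(nt_m) * math.factorial(nb_m)
            * math.factorial(nt_f) * math.factorial(nb_f))


def _exact_orderings(dur: np.ndarray, mask: np.ndarray) -> list[np.ndarray]:
    """Every rearrangement of the permutable entries (pinned stay put)."""
    idx = np.flatnonzero(mask)
    base = np.arange(len(dur))
    orders = []
    for perm in itertools.permutations(idx):
        o = base.copy()
        o[idx] = perm
        orders.append(dur[o])
    return orders


def randomisation_test(pair: PairSchedule, n_rep: int = 999,
                       rng: np.random.Generator | None = None,
                       randomise: str = "both", overrun: str = "pin",
                       exact_max: int = 25000,
                       keep_null: bool = False, chunk: int = 200) -> RandomisationResult:
    """Permutation test of the four coordination statistics for one pair.

    Each replicate independently permutes the trip-duration and
    bout-duration multisets of both pair members (``randomise='both'``,
    the default; ``'male'``/``'female'`` permute one member only) and
    recomputes all four statistics on the rebuilt pair timeline.  Under
    the default ``overrun='pin'`` scheme the window-truncated final
    interval (and a censored-start leading trip) keeps its position —
    truncated durations are not exchangeable with complete ones, and
    holding them fixed keeps the null exact for exchangeable durations;
    ``overrun='clip'`` permutes everything.  The p-value is one-tailed
    high.  When the number of distinct duration arrangements is at most
    ``exact_max`` the full arrangement space is enumerated and
    p = (#null >= observed)/N is exact; otherwise n_rep Monte-Carlo
    draws are used with the add-one estimator
    p = (1 + #null >= observed)/(n_rep + 1).
    """
    rng = rng or np.random.default_rng()
    obs = compute_stats(pair)
    if len(pair.male.trips) <= 1 or len(pair.female.trips) <= 1:
        nan4 = np.full(4, np.nan)
        return RandomisationResult(pair.pair_id, obs,
                                   CoordinationStats(*nan4), nan4, nan4,
                                   0, untestable=True)
    seq_m, tdur_m, bdur_m = _canonical(pair.male)
    seq_f, tdur_f, bdur_f = _canonical(pair.female)
    tmask_m, bmask_m = pair.male.permutable_masks(overrun)
    tmask_f, bmask_f = pair.female.permutable_masks(overrun)
    none_m = np.zeros_like(tmask_m, dtype=bool), np.zeros_like(bmask_m, dtype=bool)
    none_f = np.zeros_like(tmask_f, dtype=bool), np.zeros_like(bmask_f, dtype=bool)
    if randomise == "female":
        tmask_m, bmask_m = none_m
    elif randomise == "male":
        tmask_f, bmask_f = none_f
    elif randomise != "both":
        raise ValueError(f"unknown randomise option {randomise!r}")
    w0 = pair.window[0]
    L = pair.window[1] - pair.window[0]

    n_arr = _count_arrangements(int(tmask_m.sum()), int(bmask_m.sum()),
                                int(tmask_f.sum()), int(bmask_f.sum()))
    exact = n_arr <= exact_max

    if exact:
        arr_m = list(itertools.product(_exact_orderings(tdur_m, tmask_m),
                                       _exact_orderings(bdur_m, bmask_m)))
        arr_f = list(itertools.product(_exact_orderings(tdur_f, tmask_f),
                                       _exact_orderings(bdur_f, bmask_f)))
        combos = list(itertools.product(range(len(arr_m)), range(len(arr_f))))
        tm = np.array([arr_m[i][0] for i, _ in combos])
        bm = np.array([arr_m[i][1] for i, _ in combos])
        tf = np.array([arr_f[j][0] for _, j in combos])
        bf = np.array([arr_f[j][1] for _, j in combos])
        null = _stats_for_durations(seq_m, tm, bm, seq_f, tf, bf, w0, L, chunk)
        obs_arr = obs.as_array()
        with np.errstate(invalid="ignore"):
            p = np.nanmean(null >= obs_arr[None, :] - 1e-12, axis=0)
        n_used = len(combos)
    else:
        batches = []
        done = 0
        while done < n_rep:
            r = min(chunk, n_rep - done)
            tm = _permute_batch(tdur_m, tmask_m, r, rng)
            bm = _permute_batch(bdur_m, bmask_m, r, rng)
            tf = _permute_batch(tdur_f, tmask_f, r, rng)
            bf = _permute_batch(bdur_f, bmask_f, r, rng)
            batches.append(_stats_for_durations(seq_m, tm, bm, seq_f, tf, bf, w0, L, chunk))
            done += r
        null = np.vstack(batches)
        obs_arr = obs.as_array()
        with np.errstate(invalid="ignore"):
            k = np.nansum(null >= obs_arr[None, :] - 1e-12, axis=0)
        p = (1.0 + k) / (n_rep + 1.0)
        n_used = n_rep

    exp_arr = np.nanmean(null, axis=0)
    expected = CoordinationStats(*exp_arr, obs.n_male, obs.n_female)
    diff = obs.as_array() - exp_arr
    return RandomisationResult(pair.pair_id, obs, expected, diff, np.asarray(p, dtype=float),
                               n_used, exact=exact,
                               null_samples=null if keep_null else None)


def _stats_for_durations(seq_m, tm, bm, seq_f, tf, bf, w0, L, chunk) -> np.ndarray:
    out = []
    for k in range(0, tm.shape[0], chunk):
        sl = slice(k, k + chunk)
        ts_m, te_m, bs_m, be_m = _rebuild(seq_m, tm[sl], bm[sl], w0)
        ts_f, te_f, bs_f, be_f = _rebuild(seq_f, tf[sl], bf[sl], w0)
        out.append(_batch_stats(seq_m, ts_m, te_m, bs_m, be_m,
                                seq_f, ts_f, te_f, bs_f, be_f, L))
    return np.vstack(out)


# ---------------------------------------------------------------------------
# population summaries (Table-1-style arithmetic)
# ---------------------------------------------------------------------------


def results_to_frame(results: list[RandomisationResult]) -> pd.DataFrame:
    return pd.DataFrame([r.to_row() for r in results])


def load_published_coordination() -> pd.DataFrame:
    """Published per-pair coordination statistics for the 25 gull pairs
    (observed/expected proportions, differences and one-tailed p-values
    for the male, female, partner and attendance statistics).

    p-values printed as "<0.001" are stored as the bound 0.001 with
    ``p_*_censored`` set; they count as significant at any usual alpha.
    """
    with resources.files("pairforage.data").joinpath("pair_coordination_published.csv").open() as fh:
        df = pd.read_csv(fh, dtype={f"p_{s}": str for s in STAT_NAMES})
    for s in STAT_NAMES:
        raw = df[f"p_{s}"].astype(str).str.strip()
        df[f"p_{s}_censored"] = raw.str.startswith("<")
        df[f"p_{s}"] = raw.str.lstrip("<").astype(float)
    return df


def summarise_population(per_pair: pd.DataFrame | list, alpha: float = 0.05) -> pd.DataFrame:
    """Per-statistic population summary: means of observed, expected and
    difference, plus the count of pairs significant at ``alpha``.

    Accepts either a list of RandomisationResult or a tidy per-pair
    frame with observed_/expected_/difference_/p_ columns.
    """
    if not isinstance(per_pair, pd.DataFrame):
        per_pair = results_to_frame(per_pair)
    rows = []
    for s in STAT_NAMES:
        p = per_pair[f"p_{s}"].astype(float)
        rows.append(dict(
            statistic=s,
            mean_observed=per_pair[f"observed_{s}"].mean(),
            mean_expected=per_pair[f"expected_{s}"].mean(),
            mean_difference=per_pair[f"difference_{s}"].mean(),
            n_significant=int((p < alpha).sum()),
            n_pairs=int(p.notna().sum()),
        ))
    return pd.DataFrame(rows).set_index("statistic")


# ---------------------------------------------------------------------------
# attendance vs offspring age
# ---------------------------------------------------------------------------


def daily_attendance(pair: PairSchedule) -> pd.DataFrame:
    """Nest attendance per whole day of the shared window, with offspring
    age (days since window start = hatch day 0)."""
    w0, w1 = pair.window
    rows = []
    day = 0
    t = w0
    while t < w1 - 1e-9:
        t2 = min(t + 24.0, w1)
        sub = PairSchedule(
            pair.pair_id,
            _clip_tl(pair.male, t, t2),
            _clip_tl(pair.female, t, t2),
        )
        try:
            att = nest_attendance(sub)
        except ValueError:
            att = float("nan")
        rows.append(dict(pair_id=pair.pair_id, age=day, attendance=att))
        day += 1
        t = t2
    return pd.DataFrame(rows)


def _clip_tl(tl: IndividualTimeline, t0: float, t1: float) -> IndividualTimeline:
    def clip(iv):
        if not len(iv):
            return iv
        s = np.clip(iv[:, 0], t0, t1)
        e = np.clip(iv[:, 1], t0, t1)
        keep = e > s
        return np.column_stack([s[keep], e[keep]])

    return IndividualTimeline(clip(tl.trips), clip(tl.bouts), (t0, t1))


def attendance_vs_age(pairs: list[PairSchedule]) -> ModelFit:
    """Beta regression (logit link) of daily nest attendance on offspring age.

    Daily proportions of exactly 0 or 1 are shrunk by (y(n-1)+0.5)/n
    before fitting.  Clustering by couple is handled with cluster-robust
    standard errors (see ModelFit.fallback for the random-effect
    structure actually honoured).
    """
    df = pd.concat([daily_attendance(p) for p in pairs], ignore_index=True).dropna()
    n = len(df)
    y = (df["attendance"].to_numpy() * (n - 1) + 0.5) / n
    return cluster_beta_fit(y, df[["age"]], groups=df["pair_id"],
                            requested_random_effects=("couple", "colony"))
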