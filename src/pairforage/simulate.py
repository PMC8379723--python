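"""Synthetic paired GPS tracks with known coordination strength.

Emulates the study design this package analyses: two central-place
foraging parents per pair, tracked at 3-minute fixes over a 30-day
chick-rearing window, alternating foraging trips (gamma durations, mean
~4.4 h) with nest bouts whose expected duration declines log-linearly
with offspring age.  Temporal coordination is generated mechanistically
by *departure gating*: with probability ``coordination_prob`` a bird
about to leave waits until its partner is back in the colony (plus a
short exponential lag) before departing.  This produces coordinated
timing without any trip-to-trip duration matching.

Within trips, movement follows commute-out -> area-restricted foraging
(short steps, wide turns) -> optional rest -> commute-back kinematics,
so that trajectory features separate the three behaviours.  Each fix
carries the true behaviour label, an accelerometer class drawn through a
row-stochastic confusion matrix, and a land-cover class read from a
distance-band patch map.

All randomness flows from a single master seed; per-pair child streams
are derived by hashing (seed, pair_id), so any pair can be regenerated
independently and bit-identically.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .trackdata import (
    BOUT_COLUMNS,
    TRIP_COLUMNS,
    BroodInfo,
    ColonyGeometry,
    SECONDS_PER_HOUR,
)

BEHAVIOURS = ("rest", "commute", "forage")
ACC_CLASSES = ("acc_rest", "acc_flight", "acc_active")
HABITATS = ("colony", "urban", "agricultural", "marine")

DEG_PER_KM_LAT = 1.0 / 111.19492664455873  # spherical, radius 6371.0088 km


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Study-condition defaults for the paired-track generator.

    Durations are hours, speeds m/s, distances km.  ``coordination_prob``
    is the probability that a departure is gated on the partner's
    presence; 0 gives independent schedules, 1 guarantees the partner is
    in the colony at every (non-censored) departure.
    """

    n_pairs: int = 25
    days: float = 30.0
    fix_interval_s: float = 180.0
    colony_lat: float = 51.45
    colony_lon: float = 3.7
    colony_radius_m: float = 500.0
    # trip durations: gamma with mean ~4.4 h (observed population mean scale)
    trip_mean_h: float = 4.4
    trip_shape: float = 3.0
    # nest bouts: gamma, log-linear age trend exp(beta_age * age_days)
    bout_mean_h: float = 5.3
    bout_shape: float = 2.5
    beta_age: float = -0.0142
    coordination_prob: float = 0.6
    wait_lag_mean_h: float = 0.05
    # per-behaviour kinematics: (speed m/s, turning concentration kappa)
    speed_rest: float = 0.05
    speed_commute: float = 10.0
    speed_forage: float = 1.5
    kappa_commute: float = 200.0
    kappa_forage: float = 0.8
    p_rest_in_trip: float = 0.5
    rest_frac: float = 0.15
    # foraging-site geography: 1-3 persistent sites per pair (shared) or
    # per individual (independent); lognormal distances
    shared_sites: bool = True
    site_dist_logmean: float = np.log(15.0)
    site_dist_logsd: float = 0.4
    pair_effect_sd: float = 0.25
    acc_confusion: tuple = (
        (0.85, 0.05, 0.10),
        (0.05, 0.85, 0.10),
        (0.10, 0.10, 0.80),
    )
    start_time: str = "2016-06-01T00:00:00Z"
    seed: int = 0

    def validate(self) -> "SimConfig":
        if not 0.0 <= self.coordination_prob <= 1.0:
            raise ConfigError("coordination_prob must lie in [0, 1]")
        for name in ("trip_mean_h", "trip_shape", "bout_mean_h", "bout_shape",
                     "fix_interval_s", "days", "colony_radius_m"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        conf = np.asarray(self.acc_confusion, dtype=float)
        if conf.shape != (3, 3) or np.any(conf < 0):
            raise ConfigError("acc_confusion must be a 3x3 non-negative matrix")
        if np.any(np.abs(conf.sum(axis=1) - 1.0) > 1e-12):
            raise ConfigError("acc_confusion rows must sum to 1")
        return self

    @property
    def colony(self) -> ColonyGeometry:
        return ColonyGeometry(self.colony_lat, self.colony_lon, self.colony_radius_m)

    @property
    def window_h(self) -> float:
        return self.days * 24.0


def _pair_rng(seed: int, pair_id: str, salt: int = 0) -> np.random.Generator:
    """Deterministic child stream for one pair: hash (seed, pair_id)."""
    h = zlib.crc32(pair_id.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed & 0x7FFFFFFF, h, salt]))


# ---------------------------------------------------------------------------
# schedule layer (event-driven; fast — no per-fix work)
# ---------------------------------------------------------------------------


def simulate_pair_schedule(config: SimConfig, pair_id: str,
                           rng: np.random.Generator | None = None) -> dict:
    """Joint alternating trip/bout schedules for one pair, in hours.

    Returns ``{"m": {...}, "f": {...}, "pair_id": ...}`` where each
    individual entry holds ``trips`` and ``bouts`` as (n, 2) float
    arrays of [start, end] hours since window start, censoring flags for
    the final clipped interval, and a ``waited`` flag per trip marking
    gated departures.  Both schedules start in the colony at t=0 and are
    clipped at the window end.
    """
    config.validate()
    rng = rng or _pair_rng(config.seed, pair_id)
    T = config.window_h
    w = config.coordination_prob

    if config.shared_sites:
        mult = [float(rng.lognormal(0.0, config.pair_effect_sd))] * 2
    else:
        mult = [float(rng.lognormal(0.0, config.pair_effect_sd)) for _ in range(2)]

    def bout_draw(age_days: float) -> float:
        mean = config.bout_mean_h * np.exp(config.beta_age * age_days)
        return float(rng.gamma(config.bout_shape, mean / config.bout_shape))

    def trip_draw(i: int) -> float:
        mean = config.trip_mean_h * mult[i]
        return float(rng.gamma(config.trip_shape, mean / config.trip_shape))

    status = ["in", "in"]
    last_arrival = [0.0, 0.0]
    t_next = [bout_draw(0.0), bout_draw(0.0)]
    gate_pending: list[bool | None] = [None, None]
    deferred = [False, False]
    trips: list[list] = [[], []]
    bouts: list[list] = [[], []]
    waited: list[list] = [[], []]

    while True:
        i = 0 if t_next[0] <= t_next[1] else 1
        t = t_next[i]
        if t >= T:
            break
        j = 1 - i
        if status[i] == "in":
            if gate_pending[i] is None:
                gate_pending[i] = bool(rng.random() < w)
            if gate_pending[i] and status[j] == "out" and t_next[j] > t:
                # defer until the partner's return, plus a short lag
                t_next[i] = t_next[j] + rng.exponential(config.wait_lag_mean_h)
                deferred[i] = True
                continue
            bouts[i].append([last_arrival[i], t])
            dur = trip_draw(i)
            trips[i].append([t, t + dur])
            waited[i].append(deferred[i])
            gate_pending[i] = None
            deferred[i] = False
            status[i] = "out"
            t_next[i] = t + dur
        else:
            status[i] = "in"
            last_arrival[i] = t
            age = t / 24.0
            t_next[i] = t + bout_draw(age)

    out = {"pair_id": pair_id}
    for i, sex in enumerate(("m", "f")):
        tr = np.asarray(trips[i], dtype=float).reshape(-1, 2)
        bo = np.asarray(bouts[i], dtype=float).reshape(-1, 2)
        # clip the interval in progress at the window end
        trip_cens = np.zeros(len(tr), dtype=bool)
        if status[i] == "out" and len(tr):
            tr[-1, 1] = min(tr[-1, 1], T)
            trip_cens[-1] = True
        else:
            bo = np.vstack([bo, [last_arrival[i], T]]) if len(bo) else np.array([[last_arrival[i], T]])
        bout_cens = np.zeros(len(bo), dtype=bool)
        if status[i] == "in" and len(bo):
            bout_cens[-1] = True
        out[sex] = dict(
            trips=tr,
            bouts=bo,
            trip_censored_end=trip_cens,
            bout_censored_end=bout_cens,
            waited=np.asarray(waited[i], dtype=bool),
            trip_mult=mult[i],
        )
    return out


def schedule_to_frames(schedule: dict, config: SimConfig,
                       individual_ids: tuple[str, str] | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convert an hours-based pair schedule into trackdata-style
    trips/bouts tables with UTC timestamps and offspring ages."""
    t0 = pd.Timestamp(config.start_time)
    pair = schedule["pair_id"]
    ids = individual_ids or (f"{pair}m", f"{pair}f")
    trips_rows, bouts_rows = [], []
    for sex, ind in zip(("m", "f"), ids):
        sch = schedule[sex]
        for k, (s, e) in enumerate(sch["trips"]):
            trips_rows.append(dict(
                individual_id=ind, trip_id=f"{ind}-trip{k}",
                start=t0 + pd.Timedelta(hours=s), end=t0 + pd.Timedelta(hours=e),
                duration_h=e - s, total_distance_km=np.nan, n_fixes=0,
                censored_start=False, censored_end=bool(sch["trip_censored_end"][k]),
                offspring_age_at_start=int(np.floor(s / 24.0)),
            ))
        for k, (s, e) in enumerate(sch["bouts"]):
            bouts_rows.append(dict(
                individual_id=ind, bout_id=f"{ind}-bout{k}",
                start=t0 + pd.Timedelta(hours=s), end=t0 + pd.Timedelta(hours=e),
                duration_h=e - s,
                censored_start=bool(k == 0), censored_end=bool(sch["bout_censored_end"][k]),
                offspring_age_at_start=int(np.floor(s / 24.0)),
            ))
    trips = pd.DataFrame(trips_rows, columns=TRIP_COLUMNS)
    bouts = pd.DataFrame(bouts_rows, columns=BOUT_COLUMNS)
    return trips, bouts


# ---------------------------------------------------------------------------
# movement layer (per-fix positions, behaviours, sensors)
# ---------------------------------------------------------------------------


def _habitat_of(dist_km: np.ndarray) -> np.ndarray:
    """Land-cover class from a concentric distance-band patch map."""
    out = np.full(dist_km.shape, "marine", dtype=object)
    out[dist_km < 20.0] = "agricultural"
    out[dist_km < 5.0] = "urban"
    out[dist_km < 0.5] = "colony"
    return out


def _draw_sites(rng: np.random.Generator, config: SimConfig) -> np.ndarray:
    n = int(rng.integers(1, 4))
    d = rng.lognormal(config.site_dist_logmean, config.site_dist_logsd, size=n)
    b = rng.uniform(0.0, 2.0 * np.pi, size=n)
    return np.column_stack([d, b])


def _trip_positions(rng: np.random.Generator, config: SimConfig,
                    rel_h: np.ndarray, trip_dur: float, site: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(x, y) km offsets from the colony and behaviour labels for the
    fixes of one trip, given fix times relative to the trip start."""
    dt_h = config.fix_interval_s / SECONDS_PER_HOUR
    v_c = config.speed_commute * 3.6  # km/h
    d_site, bearing = float(site[0]), float(site[1])
    t_out = min(d_site / v_c, 0.4 * trip_dur)
    t_in = t_out
    d_eff = v_c * t_out
    t_back = trip_dur - t_in

    n = len(rel_h)
    x = np.zeros(n)
    y = np.zeros(n)
    beh = np.full(n, "forage", dtype=object)

    ux, uy = np.sin(bearing), np.cos(bearing)
    out_mask = rel_h < t_out
    back_mask = rel_h >= t_back
    mid_mask = ~out_mask & ~back_mask

    # commuting out: straight toward the site with slight cross-track noise
    r = v_c * rel_h[out_mask]
    x[out_mask] = r * ux + rng.normal(0, 0.05, out_mask.sum())
    y[out_mask] = r * uy + rng.normal(0, 0.05, out_mask.sum())
    beh[out_mask] = "commute"

    # area-restricted search around the site, with an optional rest block
    mid_idx = np.flatnonzero(mid_mask)
    rest_block = (t_out, t_out)
    if rng.random() < config.p_rest_in_trip and t_back - t_out > 4 * dt_h:
        span = t_back - t_out
        r0 = t_out + rng.uniform(0.2, 0.6) * span
        rest_block = (r0, min(r0 + config.rest_frac * trip_dur, t_back))
    px, py = d_eff * ux, d_eff * uy
    if mid_idx.size:
        m = mid_idx.size
        is_rest = (rel_h[mid_idx] >= rest_block[0]) & (rel_h[mid_idx] < rest_block[1])
        speed = np.where(is_rest, config.speed_rest, config.speed_forage) * 3.6  # km/h
        steps = speed * dt_h * rng.lognormal(0.0, 0.3, m)
        turns = rng.vonmises(0.0, config.kappa_forage, m)
        headings = bearing + np.cumsum(turns)
        dx = np.cumsum(steps * np.sin(headings))
        dy = np.cumsum(steps * np.cos(headings))
        x[mid_idx] = px + dx
        y[mid_idx] = py + dy
        beh[mid_idx] = np.where(is_rest, "rest", "forage")
        qx, qy = px + dx[-1], py + dy[-1]
    else:
        qx, qy = px, py

    # commuting back: linear glide to the colony, arriving exactly at trip end
    bk = np.flatnonzero(back_mask)
    if bk.size:
        tau = (rel_h[bk] - t_back) / max(trip_dur - t_back, 1e-9)
        x[bk] = qx * (1.0 - tau)
        y[bk] = qy * (1.0 - tau)
        beh[bk] = "commute"
    return x, y, beh


@dataclass
class SimOutput:
    """One simulated pair: fix table, ground-truth intervals, provenance."""

    pair_id: str
    fixes: pd.DataFrame
    truth_trips: pd.DataFrame
    truth_bouts: pd.DataFrame
    schedule: dict
    config: SimConfig
    seed: int


def simulate_pair(config: SimConfig, pair_id: str, colony_id: str = "COL") -> SimOutput:
    """Full simulation of one pair: schedules, per-fix positions,
    behaviour truth, accelerometer classes and habitat."""
    config.validate()
    rng = _pair_rng(config.seed, pair_id)
    schedule = simulate_pair_schedule(config, pair_id, rng)
    t0 = pd.Timestamp(config.start_time)
    dt_h = config.fix_interval_s / SECONDS_PER_HOUR
    fix_h = np.arange(0.0, config.window_h + 1e-9, dt_h)
    conf = np.asarray(config.acc_confusion, dtype=float)
    beh_index = {b: k for k, b in enumerate(BEHAVIOURS)}

    pair_sites = _draw_sites(rng, config) if config.shared_sites else None
    frames = []
    for sex_key, sex in (("m", "male"), ("f", "female")):
        ind = f"{pair_id}{sex_key}"
        sites = pair_sites if pair_sites is not None else _draw_sites(rng, config)
        n = len(fix_h)
        x = rng.normal(0.0, 0.1 * config.colony_radius_m / 1000.0, n)
        y = rng.normal(0.0, 0.1 * config.colony_radius_m / 1000.0, n)
        beh = np.full(n, "rest", dtype=object)
        for (s, e) in schedule[sex_key]["trips"]:
            k = int(rng.integers(0, len(sites)))
            in_trip = (fix_h > s) & (fix_h < e)
            idx = np.flatnonzero(in_trip)
            if not idx.size:
                continue
            tx, ty, tb = _trip_positions(rng, config, fix_h[idx] - s, e - s, sites[k])
            x[idx], y[idx], beh[idx] = tx, ty, tb
        lat = config.colony_lat + y * DEG_PER_KM_LAT
        lon = config.colony_lon + x * DEG_PER_KM_LAT / np.cos(np.radians(config.colony_lat))
        step_km = np.concatenate([[0.0], np.hypot(np.diff(x), np.diff(y))])
        speed = step_km * 1000.0 / config.fix_interval_s + np.abs(rng.normal(0, 0.05, n))
        truth_codes = np.array([beh_index[b] for b in beh])
        u = rng.random(n)
        cum = np.cumsum(conf, axis=1)[truth_codes]
        acc = np.array(ACC_CLASSES, dtype=object)[(u[:, None] < cum).argmax(axis=1)]
        habitat = _habitat_of(np.hypot(x, y))
        frames.append(pd.DataFrame(dict(
            individual_id=ind, pair_id=pair_id, sex=sex, colony_id=colony_id,
            timestamp=t0 + pd.to_timedelta(fix_h, unit="h"),
            lat=lat, lon=lon, ground_speed=speed,
            acc_class=acc, habitat=habitat, true_behaviour=beh,
        )))
    fixes = pd.concat(frames, ignore_index=True)
    fixes = fixes.sort_values(["individual_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    truth_trips, truth_bouts = schedule_to_frames(schedule, config)
    return SimOutput(pair_id, fixes, truth_trips, truth_bouts, schedule, config, config.seed)


def simulate_colony(config: SimConfig, colony_id: str = "COL",
                    schedules_only: bool = False) -> tuple[list, dict]:
    """Simulate ``n_pairs`` independent pairs plus a reproducibility manifest.

    With ``schedules_only=True`` the (cheap) schedule layer alone is run
    and the list holds schedule dicts instead of SimOutput objects.
    """
    config.validate()
    outputs = []
    pair_ids = [f"P{k + 1:03d}" for k in range(config.n_pairs)]
    for pid in pair_ids:
        if schedules_only:
            outputs.append(simulate_pair_schedule(config, pid))
        else:
            outputs.append(simulate_pair(config, pid, colony_id=colony_id))
    manifest = dict(
        seed=config.seed,
        colony_id=colony_id,
        pair_ids=pair_ids,
        child_hashes={p: zlib.crc32(p.encode()) & 0x7FFFFFFF for p in pair_ids},
        config={k: (list(map(list, v)) if k == "acc_confusion" else v)
                for k, v in asdict(config).items()},
    )
    return outputs, manifest


def write_colony(outputs: list[SimOutput], manifest: dict, out_dir: str | Path) -> None:
    """Write the standard fix table plus truth intervals and manifest."""
    from .trackdata import write_fixes, write_intervals

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    fixes = pd.concat([o.fixes for o in outputs], ignore_index=True)
    write_fixes(fixes, out_dir / "fixes.csv")
    write_intervals(pd.concat([o.truth_trips for o in outputs], ignore_index=True),
                    out_dir / "truth_trips.csv")
    write_intervals(pd.concat([o.truth_bouts for o in outputs], ignore_index=True),
                    out_dir / "truth_bouts.csv")
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
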