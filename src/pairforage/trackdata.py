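"""GPS fix tables, colony geometry, and trip/nest-bout segmentation.

Central-place foragers alternate between foraging trips away from the
breeding colony and nest bouts inside it.  This module reads per-fix GPS
tables, decides colony membership from a circle or polygon boundary, and
splices each individual's track into the alternating trip/bout timeline
that every downstream statistic is computed on.

A foraging trip starts at the last fix inside the colony boundary before
an excursion and ends at the first fix back inside; nest bouts are the
complementary in-colony intervals.  Trips shorter than 30 min or covering
less than 1 km are discarded by default because such excursions are
unlikely to be genuine foraging.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon, shape

EARTH_RADIUS_KM = 6371.0088  # IUGG mean Earth radius

#: columns every fix table must provide
REQUIRED_COLUMNS = (
    "individual_id",
    "pair_id",
    "sex",
    "colony_id",
    "timestamp",
    "lat",
    "lon",
)

#: optional per-fix annotations, kept as missing (not zero) when absent
OPTIONAL_COLUMNS = ("ground_speed", "acc_class", "habitat", "true_behaviour")

SECONDS_PER_HOUR = 3600.0
SECONDS_PER_DAY = 86400.0


class SchemaError(ValueError):
    """A fix table is missing a required column or has an invalid value."""


class TimestampError(ValueError):
    """A timestamp cell could not be parsed; carries the offending line."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def great_circle_km(lat1, lon1, lat2, lon2):
    """Great-circle (haversine) distance in km on a sphere of radius 6371.0088 km.

    Accepts scalars or numpy arrays (broadcast).  Symmetric, non-negative
    and zero only for identical points.
    """
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return EARTH_RADIUS_KM * 2.0 * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def initial_bearing_rad(lat1, lon1, lat2, lon2):
    """Initial bearing (radians, clockwise from north) from point 1 to point 2."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


@dataclass(frozen=True)
class ColonyGeometry:
    """Colony boundary: a circle (centre + radius) or a simple polygon.

    Membership uses great-circle distance <= radius for circles and
    point-in-polygon with the boundary counted inside for polygons.
    The default radius is 500 m.
    """

    centre_lat: float | None = None
    centre_lon: float | None = None
    radius_m: float = 500.0
    polygon: Polygon | None = None

    def __post_init__(self):
        if self.polygon is None:
            if self.centre_lat is None or self.centre_lon is None:
                raise ValueError("circle geometry needs centre_lat and centre_lon")
            if not self.radius_m > 0:
                raise ValueError("colony radius must be > 0")
        else:
            if not self.polygon.is_valid:
                raise ValueError("colony polygon must be simple (non-self-intersecting)")

    def contains(self, lat, lon) -> np.ndarray:
        """Vectorised membership test; returns a boolean array."""
        lat = np.atleast_1d(np.asarray(lat, dtype=float))
        lon = np.atleast_1d(np.asarray(lon, dtype=float))
        if self.polygon is not None:
            # shapely uses (x, y) = (lon, lat)
            return np.array([self.polygon.covers(Point(x, y)) for y, x in zip(lat, lon)])
        d_km = great_circle_km(self.centre_lat, self.centre_lon, lat, lon)
        return d_km * 1000.0 <= self.radius_m


def load_colony(path: str | Path) -> ColonyGeometry:
    """Load colony geometry from JSON: either ``{"type": "circle", ...}``
    or a GeoJSON Polygon (coordinates in lon/lat order)."""
    with open(path) as fh:
        obj = json.load(fh)
    if obj.get("type") == "circle":
        return ColonyGeometry(
            centre_lat=float(obj["centre"]["lat"]),
            centre_lon=float(obj["centre"]["lon"]),
            radius_m=float(obj.get("radius_m", 500.0)),
        )
    geom = shape(obj.get("geometry", obj))
    if not isinstance(geom, Polygon):
        raise ValueError(f"unsupported colony geometry type: {geom.geom_type}")
    return ColonyGeometry(polygon=geom)


@dataclass(frozen=True)
class BroodInfo:
    """Chick-rearing window of one pair: hatch day (age 0) to fledging
    (day 30) or failure."""

    pair_id: str
    hatch_date: pd.Timestamp
    end_date: pd.Timestamp

    def __post_init__(self):
        h = pd.Timestamp(self.hatch_date)
        e = pd.Timestamp(self.end_date)
        if h.tzinfo is None:
            h = h.tz_localize("UTC")
        if e.tzinfo is None:
            e = e.tz_localize("UTC")
        object.__setattr__(self, "hatch_date", h)
        object.__setattr__(self, "end_date", e)
        if not self.end_date > self.hatch_date:
            raise ValueError("brood end_date must be after hatch_date")

    def offspring_age_days(self, when: pd.Timestamp) -> int:
        """Whole days since hatching (hatch day = day 0)."""
        return int(math.floor((pd.Timestamp(when) - self.hatch_date).total_seconds() / SECONDS_PER_DAY))


# ---------------------------------------------------------------------------
# fix-table I/O
# ---------------------------------------------------------------------------


def read_fixes(path: str | Path, sep: str = ",") -> pd.DataFrame:
    """Read a delimited fix table, validate the schema and sort it.

    Returns a DataFrame sorted by (individual_id, timestamp) with UTC
    timestamps.  Optional columns that are absent stay absent; missing
    cells stay NaN rather than being filled with zeros.
    """
    df = pd.read_csv(path, sep=sep, dtype={"individual_id": str, "pair_id": str, "colony_id": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"fix table is missing required column {col!r}")
    ts = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601", errors="coerce")
    if ts.isna().any():
        line = int(np.flatnonzero(ts.isna().to_numpy())[0]) + 2  # header is line 1
        raise TimestampError(f"unparsable timestamp at line {line} of {path}")
    df["timestamp"] = ts
    bad = (df["lat"].abs() > 90) | (df["lon"].abs() > 180)
    if bad.any():
        raise SchemaError(f"{int(bad.sum())} fixes have coordinates outside valid ranges")
    if "ground_speed" in df.columns and (df["ground_speed"].dropna() < 0).any():
        raise SchemaError("ground_speed must be non-negative")
    df = df.sort_values(["individual_id", "timestamp"], kind="mergesort").reset_index(drop=True)
    return df


def write_fixes(df: pd.DataFrame, path: str | Path, sep: str = ",") -> None:
    """Write a fix table; numeric values round-trip exactly through read_fixes."""
    out = df.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

TRIP_COLUMNS = [
    "individual_id",
    "trip_id",
    "start",
    "end",
    "duration_h",
    "total_distance_km",
    "n_fixes",
    "censored_start",
    "censored_end",
    "offspring_age_at_start",
]

BOUT_COLUMNS = [
    "individual_id",
    "bout_id",
    "start",
    "end",
    "duration_h",
    "censored_start",
    "censored_end",
    "offspring_age_at_start",
]


def _empty_trips() -> pd.DataFrame:
    return pd.DataFrame(columns=TRIP_COLUMNS)


def _empty_bouts() -> pd.DataFrame:
    return pd.DataFrame(columns=BOUT_COLUMNS)


def segment(
    fixes: pd.DataFrame,
    colony: ColonyGeometry,
    brood: BroodInfo | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Splice one individual's fixes into foraging trips and nest bouts.

    Each trip runs from the last in-colony fix before an out-of-colony
    run to the first in-colony fix after it.  Bouts are the in-colony
    intervals in between; together they tile the observed window.  When a
    brood window is given, fixes outside [hatch, end] are dropped first
    and offspring age at interval start is attached.  Tracks that begin
    (end) away from the colony yield a leading (trailing) trip flagged
    ``censored_start`` (``censored_end``); edge bouts are flagged the
    same way.
    """
    if fixes["individual_id"].nunique() > 1:
        raise ValueError("segment() expects fixes of a single individual")
    ind = fixes["individual_id"].iloc[0] if len(fixes) else ""
    fixes = fixes.sort_values("timestamp", kind="mergesort").reset_index(drop=True)
    if brood is not None:
        m = (fixes["timestamp"] >= brood.hatch_date) & (fixes["timestamp"] <= brood.end_date)
        fixes = fixes.loc[m].reset_index(drop=True)
    if len(fixes) == 0:
        warnings.warn(f"no fixes inside the observation window for {ind!r}", stacklevel=2)
        return _empty_trips(), _empty_bouts()

    t = fixes["timestamp"].to_numpy()
    lat = fixes["lat"].to_numpy(dtype=float)
    lon = fixes["lon"].to_numpy(dtype=float)
    inside = colony.contains(lat, lon)
    n = len(fixes)
    step_km = great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:]) if n > 1 else np.array([])
    cum_km = np.concatenate([[0.0], np.cumsum(step_km)])

    # locate runs of out-of-colony fixes
    out_idx = np.flatnonzero(~inside)
    trips = []
    if out_idx.size:
        breaks = np.flatnonzero(np.diff(out_idx) > 1)
        run_starts = np.concatenate([[out_idx[0]], out_idx[breaks + 1]])
        run_ends = np.concatenate([out_idx[breaks], [out_idx[-1]]])
        for i, j in zip(run_starts, run_ends):
            s = i - 1 if i > 0 else i
            e = j + 1 if j < n - 1 else j
            trips.append(
                dict(
                    individual_id=ind,
                    start=t[s],
                    end=t[e],
                    duration_h=(t[e] - t[s]) / np.timedelta64(1, "s") / SECONDS_PER_HOUR,
                    total_distance_km=float(cum_km[e] - cum_km[s]),
                    n_fixes=int(e - s + 1),
                    censored_start=bool(i == 0),
                    censored_end=bool(j == n - 1),
                )
            )

    trips_df = pd.DataFrame(trips) if trips else _empty_trips().drop(columns=["trip_id", "offspring_age_at_start"])

    # complementary in-colony bouts
    bouts = []
    window_start, window_end = t[0], t[-1]
    bound_times: list[tuple] = []
    if len(trips_df):
        starts = trips_df["start"].to_numpy()
        ends = trips_df["end"].to_numpy()
        if not trips_df["censored_start"].iloc[0]:
            bound_times.append((window_start, starts[0], True, False))
        for k in range(len(trips_df) - 1):
            bound_times.append((ends[k], starts[k + 1], False, False))
        if not trips_df["censored_end"].iloc[-1]:
            bound_times.append((ends[-1], window_end, False, True))
    else:
        bound_times.append((window_start, window_end, True, True))
    for s, e, cs, ce in bound_times:
        if e > s:
            bouts.append(
                dict(
                    individual_id=ind,
                    start=s,
                    end=e,
                    duration_h=(e - s) / np.timedelta64(1, "s") / SECONDS_PER_HOUR,
                    censored_start=bool(cs),
                    censored_end=bool(ce),
                )
            )
    bouts_df = pd.DataFrame(bouts) if bouts else _empty_bouts().drop(columns=["bout_id", "offspring_age_at_start"])

    for df, prefix in ((trips_df, "trip"), (bouts_df, "bout")):
        if len(df):
            df.insert(1, f"{prefix}_id", [f"{ind}-{prefix}{k}" for k in range(len(df))])
            if brood is not None:
                df["offspring_age_at_start"] = [brood.offspring_age_days(s) for s in df["start"]]
            else:
                df["offspring_age_at_start"] = np.nan
    trips_df = trips_df.reindex(columns=TRIP_COLUMNS) if len(trips_df) else _empty_trips()
    bouts_df = bouts_df.reindex(columns=BOUT_COLUMNS) if len(bouts_df) else _empty_bouts()
    return trips_df, bouts_df


def trip_metrics(trip_fixes: pd.DataFrame) -> dict:
    """Duration (h) and cumulative point-to-point distance (km) of one trip.

    The fixes must be the trip's own ordered fixes, first and last being
    the delimiting in-colony fixes.  A single-fix trip is degenerate:
    distance 0 and flagged.
    """
    t = pd.to_datetime(trip_fixes["timestamp"], utc=True).to_numpy()
    if len(t) < 2:
        return dict(duration_h=0.0, total_distance_km=0.0, degenerate=True)
    lat = trip_fixes["lat"].to_numpy(dtype=float)
    lon = trip_fixes["lon"].to_numpy(dtype=float)
    dist = float(np.sum(great_circle_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))
    dur = float((t[-1] - t[0]) / np.timedelta64(1, "s") / SECONDS_PER_HOUR)
    return dict(duration_h=dur, total_distance_km=dist, degenerate=False)


def filter_trips(
    trips: pd.DataFrame,
    min_duration_h: float = 0.5,
    min_distance_km: float = 1.0,
    combiner: Literal["either", "both"] = "either",
) -> pd.DataFrame:
    """Drop trips too short or too close to be genuine foraging.

    With ``combiner="either"`` (default) a trip is removed when it fails
    either threshold (duration < 30 min OR distance < 1 km); with
    ``"both"`` only when it fails both.
    """
    if not len(trips):
        return trips
    short = trips["duration_h"] < min_duration_h
    near = trips["total_distance_km"] < min_distance_km
    if combiner == "either":
        drop = short | near
    elif combiner == "both":
        drop = short & near
    else:
        raise ValueError(f"unknown combiner {combiner!r}")
    return trips.loc[~drop].reset_index(drop=True)


def absorb_removed_trips(all_trips: pd.DataFrame, kept_trips: pd.DataFrame,
                         bouts: pd.DataFrame) -> pd.DataFrame:
    """Merge filtered-out excursions back into the surrounding nest bouts.

    A trip removed by the duration/distance filters is not a foraging
    trip, so the nest bout is treated as continuing across it: the bout
    before, the removed interval and the bout after coalesce into one
    bout.  Returns the new bout table, which together with
    ``kept_trips`` tiles each individual's window again.
    """
    removed = all_trips[~all_trips["trip_id"].isin(set(kept_trips["trip_id"]))]
    out = []
    for ind in pd.unique(pd.concat([bouts["individual_id"], removed["individual_id"]])
                         if len(removed) else bouts["individual_id"]):
        pieces = []
        for df in (bouts[bouts["individual_id"] == ind],
                   removed[removed["individual_id"] == ind]):
            for _, r in df.iterrows():
                pieces.append(dict(start=r["start"], end=r["end"],
                                   censored_start=bool(r.get("censored_start", False)),
                                   censored_end=bool(r.get("censored_end", False)),
                                   offspring_age_at_start=r.get("offspring_age_at_start", np.nan)))
        pieces.sort(key=lambda p: p["start"])
        merged = []
        for p in pieces:
            if merged and (p["start"] - merged[-1]["end"]) <= pd.Timedelta(seconds=1):
                merged[-1]["end"] = max(merged[-1]["end"], p["end"])
                merged[-1]["censored_end"] = p["censored_end"]
            else:
                merged.append(dict(p))
        for k, m in enumerate(merged):
            out.append(dict(
                individual_id=ind, bout_id=f"{ind}-mbout{k}",
                start=m["start"], end=m["end"],
                duration_h=(m["end"] - m["start"]).total_seconds() / SECONDS_PER_HOUR
                if hasattr(m["end"] - m["start"], "total_seconds")
                else float(m["end"] - m["start"]),
                censored_start=m["censored_start"], censored_end=m["censored_end"],
                offspring_age_at_start=m["offspring_age_at_start"],
            ))
    return pd.DataFrame(out, columns=BOUT_COLUMNS) if out else _empty_bouts()


def segment_all(
    fixes: pd.DataFrame,
    colony: ColonyGeometry,
    broods: dict[str, BroodInfo] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Segment every individual in a multi-individual fix table.

    ``broods`` maps pair_id to BroodInfo; individuals with no entry are
    segmented over their full track.
    """
    all_trips, all_bouts = [], []
    for ind, grp in fixes.groupby("individual_id", sort=True):
        pair = grp["pair_id"].iloc[0]
        brood = (broods or {}).get(pair)
        tr, bo = segment(grp, colony, brood)
        all_trips.append(tr)
        all_bouts.append(bo)
    trips = pd.concat(all_trips, ignore_index=True) if all_trips else _empty_trips()
    bouts = pd.concat(all_bouts, ignore_index=True) if all_bouts else _empty_bouts()
    return trips, bouts


def write_intervals(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for col in ("start", "end"):
        if col in out.columns and len(out):
            out[col] = pd.to_datetime(out[col], utc=True).dt.strftime("%Y-%m-%dT%H:%M:%S.%f%z")
    out.to_csv(path, index=False)


def read_intervals(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("start", "end"):
        if col in df.columns:
            df[col] = pd.to_datetime(df[col], utc=True, format="ISO8601")
    return df
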