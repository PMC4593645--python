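"""GPS track ingestion, behaviour classification and trip segmentation.

A *trajectory* is the full deployment of one logger on one bird; a
*trip* is a central-place foraging excursion: a maximal run of fixes
farther than a small buffer from the colony.  Behaviour is classified
from ground speed: fixes arriving at < 3 km/h are resting/preening on
the water, everything else is flight.

Trip metrics reported per trip: duration (days), total distance (km),
maximum distance from the colony (km), flight hours per day, and the
short/long class (long = strictly more than 3 days).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .geo import great_circle_km

logger = logging.getLogger(__name__)

SPEED_REST_THRESHOLD_KMH = 3.0  # below this a fix is resting/preening
LONG_TRIP_DAYS = 3.0            # long trip iff duration > 3 days
GAP_FLAG_MIN = 60.0             # gaps longer than this are logged, not split

REQUIRED_COLUMNS = ("individual_id", "timestamp", "lon", "lat")


class TrackFormatError(ValueError):
    """Input table is structurally unusable (missing columns, unparseable)."""


class TrackValidationError(ValueError):
    """Input table parses but violates a trajectory invariant."""


@dataclass
class Trajectory:
    """One individual's deployment: time-ordered fixes plus its colony."""

    individual_id: str
    colony: tuple[float, float]  # (lon, lat)
    fixes: pd.DataFrame  # columns: timestamp, lon, lat [, speed_kmh, behaviour]

    @property
    def n_fixes(self) -> int:
        return len(self.fixes)

    @property
    def has_behaviour(self) -> bool:
        return "behaviour" in self.fixes.columns


@dataclass
class Trip:
    """One foraging excursion (contiguous fixes outside the colony buffer)."""

    individual_id: str
    trip_id: str
    colony: tuple[float, float]
    fixes: pd.DataFrame

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]


def read_tracks(path, colony: tuple[float, float]) -> list[Trajectory]:
    """Read a track table (CSV) into one :class:`Trajectory` per individual.

    The table must have columns ``individual_id, timestamp, lon, lat``
    with ISO 8601 UTC timestamps.  Fixes are returned time-sorted;
    duplicate timestamps within an individual are rejected.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(f"{path}: missing required column(s) {missing}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise TrackFormatError(f"{path}: unparseable timestamps: {exc}") from None
    if not (df["lat"].between(-90, 90).all() and df["lon"].between(-180, 180).all()):
        bad = df.index[~(df["lat"].between(-90, 90) & df["lon"].between(-180, 180))][0]
        raise TrackValidationError(f"{path}: coordinate out of range at row {bad}")
    out = []
    for ind, sub in df.groupby("individual_id", sort=True):
        sub = sub.sort_values("timestamp").reset_index(drop=True)
        dup = sub["timestamp"].duplicated()
        if dup.any():
            row = int(sub.index[dup][0])
            raise TrackValidationError(
                f"individual {ind!r}: duplicate timestamp at sorted row {row} "
                f"({sub['timestamp'].iloc[row]})")
        out.append(Trajectory(individual_id=str(ind), colony=tuple(colony),
                              fixes=sub[["timestamp", "lon", "lat"]]))
    return out


def classify_behaviour(traj: Trajectory,
                       threshold_kmh: float = SPEED_REST_THRESHOLD_KMH) -> Trajectory:
    """Label each fix flight/rest from its incoming ground speed.

    The speed of the leg *into* a fix is assigned to that fix; the first
    fix inherits the second's label.  Rest iff speed < threshold
    (strict inequality: a fix at exactly 3 km/h is flight).
    """
    if traj.n_fixes < 2:
        raise TrackValidationError(
            f"individual {traj.individual_id!r}: cannot classify behaviour "
            "with fewer than 2 fixes")
    f = traj.fixes.copy()
    dt_h = f["timestamp"].diff().dt.total_seconds().to_numpy() / 3600.0
    leg_km = np.concatenate([
        [np.nan],
        great_circle_km(f["lon"].to_numpy()[:-1], f["lat"].to_numpy()[:-1],
                        f["lon"].to_numpy()[1:], f["lat"].to_numpy()[1:]),
    ])
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = leg_km / dt_h
    speed[0] = speed[1]
    f["speed_kmh"] = speed
    f["behaviour"] = np.where(speed < threshold_kmh, "rest", "flight")
    return replace(traj, fixes=f)


def segment_trips(traj: Trajectory, buffer_km: float = 2.0,
                  min_duration_h: float = 1.0, min_fixes: int = 5) -> list[Trip]:
    """Cut a trajectory into foraging trips.

    A trip is a maximal run of consecutive fixes farther than
    ``buffer_km`` from the colony that lasts at least ``min_duration_h``
    and contains at least ``min_fixes`` fixes.  A trajectory that never
    leaves the buffer yields an empty list.
    """
    f = traj.fixes
    if len(f) == 0:
        return []
    d = great_circle_km(f["lon"].to_numpy(), f["lat"].to_numpy(),
                        traj.colony[0], traj.colony[1])
    outside = d > buffer_km
    trips: list[Trip] = []
    edges = np.flatnonzero(np.diff(np.concatenate([[0], outside.astype(int), [0]])))
    for k, (i0, i1) in enumerate(zip(edges[::2], edges[1::2])):
        run = f.iloc[i0:i1].reset_index(drop=True)
        dur_h = (run["timestamp"].iloc[-1] - run["timestamp"].iloc[0]).total_seconds() / 3600.0
        if len(run) < min_fixes or dur_h < min_duration_h:
            continue
        gaps = run["timestamp"].diff().dt.total_seconds() / 60.0
        if (gaps > GAP_FLAG_MIN).any():
            logger.warning("individual %s trip %d: %d gap(s) > %g min retained",
                           traj.individual_id, len(trips) + 1,
                           int((gaps > GAP_FLAG_MIN).sum()), GAP_FLAG_MIN)
        trips.append(Trip(individual_id=traj.individual_id,
                          trip_id=f"{traj.individual_id}_t{len(trips) + 1:02d}",
                          colony=traj.colony, fixes=run))
    return trips


def _fix_dwell_hours(timestamps: pd.Series) -> np.ndarray:
    """Trapezoidal time attribution: half the gap to each neighbour."""
    t = timestamps.to_numpy(dtype="datetime64[ns]").astype("int64") / 3.6e12
    if len(t) == 1:
        return np.zeros(1)
    gaps = np.diff(t)
    dwell = np.zeros(len(t))
    dwell[:-1] += gaps / 2.0
    dwell[1:] += gaps / 2.0
    return dwell


def trip_metrics(trip: Trip) -> dict:
    """Per-trip summary metrics.

    Requires behaviour labels for the flight-hours metric (computed with
    trapezoidal time attribution over flight-labelled fixes).
    """
    f = trip.fixes
    duration_days = (trip.end - trip.start).total_seconds() / 86400.0
    lon, lat = f["lon"].to_numpy(), f["lat"].to_numpy()
    legs = great_circle_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
    total_km = float(np.sum(legs))
    dist_col = great_circle_km(lon, lat, trip.colony[0], trip.colony[1])
    if "behaviour" in f.columns:
        dwell = _fix_dwell_hours(f["timestamp"])
        flight_h = float(dwell[(f["behaviour"] == "flight").to_numpy()].sum())
        flight_h_per_day = flight_h / duration_days if duration_days > 0 else np.nan
    else:
        flight_h_per_day = np.nan
    return {
        "individual_id": trip.individual_id,
        "trip_id": trip.trip_id,
        "start": trip.start,
        "end": trip.end,
        "duration_days": duration_days,
        "total_distance_km": total_km,
        "max_distance_colony_km": float(dist_col.max()),
        "flight_hours_per_day": flight_h_per_day,
        "duration_class": "long" if duration_days > LONG_TRIP_DAYS else "short",
        "n_fixes": len(f),
    }


def trips_table(trips: list[Trip]) -> pd.DataFrame:
    """Stack :func:`trip_metrics` for a list of trips into a DataFrame."""
    return pd.DataFrame([trip_metrics(t) for t in trips])
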