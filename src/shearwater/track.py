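"""GPS track filtering, foraging-trip segmentation and trip metrics.

A GPS track is a :class:`pandas.DataFrame` with columns ``timestamp``
(tz-aware UTC), ``lat`` and ``lon`` (decimal degrees, WGS84, southern
latitudes negative), strictly increasing in time.  Trips are
colony-departure-to-return slices of a filtered track; for each complete
trip five parameters are computed: duration (h), total distance travelled
(km), maximum distance to the colony (km), average horizontal speed
(km/h) and average bearing from the colony (deg).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0

__all__ = [
    "EARTH_RADIUS_KM",
    "Trip",
    "TripMetrics",
    "great_circle_km",
    "initial_bearing",
    "track_speeds_kmh",
    "speed_filter",
    "segment_trips",
    "trip_metrics",
    "daily_wind_means",
    "position_at",
]


# ---------------------------------------------------------------------------
# geodesy
# ---------------------------------------------------------------------------

def great_circle_km(a, b):
    """Haversine great-circle distance in km between (lat, lon) points.

    Accepts scalars or array-likes (broadcast).  Mean Earth radius
    6371.0 km; error < 0.5% at the scales of coastal foraging trips.
    """
    lat1, lon1 = np.radians(np.asarray(a[0], float)), np.radians(np.asarray(a[1], float))
    lat2, lon2 = np.radians(np.asarray(b[0], float)), np.radians(np.asarray(b[1], float))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    return d if d.ndim else float(d)


def initial_bearing(a, b):
    """Initial great-circle bearing from point ``a`` to ``b`` in [0, 360).

    0 = north, clockwise positive.  Raises ``ValueError`` for coincident
    points, where the bearing is undefined.
    """
    lat1, lon1 = math.radians(a[0]), math.radians(a[1])
    lat2, lon2 = math.radians(b[0]), math.radians(b[1])
    if a[0] == b[0] and a[1] == b[1]:
        raise ValueError("bearing undefined for coincident points")
    dlon = lon2 - lon1
    y = math.sin(dlon) * math.cos(lat2)
    x = math.cos(lat1) * math.sin(lat2) - math.sin(lat1) * math.cos(lat2) * math.cos(dlon)
    return math.degrees(math.atan2(y, x)) % 360.0


def _bearings_from(origin, lats, lons):
    """Vectorised initial bearings (deg, [0,360)) from one origin to many points."""
    lat1 = math.radians(origin[0])
    lon1 = math.radians(origin[1])
    lat2 = np.radians(np.asarray(lats, float))
    lon2 = np.radians(np.asarray(lons, float))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = math.cos(lat1) * np.sin(lat2) - math.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.degrees(np.arctan2(y, x)) % 360.0


def _destination(lat, lon, bearing_deg, dist_km):
    """Point reached travelling ``dist_km`` on ``bearing_deg`` from (lat, lon)."""
    delta = dist_km / EARTH_RADIUS_KM
    theta = math.radians(bearing_deg)
    phi1 = math.radians(lat)
    lam1 = math.radians(lon)
    sphi2 = math.sin(phi1) * math.cos(delta) + math.cos(phi1) * math.sin(delta) * math.cos(theta)
    phi2 = math.asin(max(-1.0, min(1.0, sphi2)))
    lam2 = lam1 + math.atan2(
        math.sin(theta) * math.sin(delta) * math.cos(phi1),
        math.cos(delta) - math.sin(phi1) * sphi2,
    )
    return math.degrees(phi2), (math.degrees(lam2) + 540.0) % 360.0 - 180.0


# ---------------------------------------------------------------------------
# speed filter
# ---------------------------------------------------------------------------

def track_speeds_kmh(track: pd.DataFrame) -> np.ndarray:
    """Speeds (km/h) over consecutive fixes; length ``len(track) - 1``."""
    lat = track["lat"].to_numpy(float)
    lon = track["lon"].to_numpy(float)
    t = track["timestamp"].to_numpy()
    dt_h = np.diff(t).astype("timedelta64[ns]").astype(float) / 3.6e12
    d = great_circle_km((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(dt_h > 0, d / dt_h, np.inf)


def speed_filter(track: pd.DataFrame, vmax: float = 60.0):
    """Iterative forward/backward speed filter.

    Removes fixes implying travel speed above ``vmax`` (km/h; default 60,
    the threshold used for shearwater tracks).  Each iteration flags a fix
    forward if the speed from the previous retained fix exceeds ``vmax``
    and backward if the speed from the next retained fix exceeds it, then
    removes the earliest fix flagged in both directions (failing that, the
    earliest single-direction flag) and recomputes; the first and last
    fixes are never removed.  Iterates until no fix is flagged, hence the
    result is idempotent.

    Returns ``(filtered_track, removed_positional_indices)``.
    """
    if vmax <= 0:
        raise ValueError("vmax must be positive")
    n = len(track)
    if n < 2:
        raise ValueError("speed filter needs at least 2 fixes")
    keep = np.ones(n, bool)
    while True:
        idx = np.flatnonzero(keep)
        sub = track.iloc[idx]
        fast = track_speeds_kmh(sub) > vmax  # segment j joins kept fixes j, j+1
        m = len(idx)
        fwd = np.zeros(m, bool)
        bwd = np.zeros(m, bool)
        fwd[1:] = fast   # incoming segment too fast
        bwd[:-1] = fast  # outgoing segment too fast
        fwd[0] = fwd[-1] = bwd[0] = bwd[-1] = False  # endpoints protected
        both = fwd & bwd
        # one fix per iteration, speeds recomputed after each removal:
        # a good fix sandwiched between two outliers is flagged both ways
        # on the first pass but exonerated once its neighbours are gone
        if both.any():
            keep[idx[np.argmax(both)]] = False
        elif fwd.any():
            keep[idx[np.argmax(fwd)]] = False
        elif bwd.any():
            keep[idx[np.argmax(bwd)]] = False
        else:
            break
    removed = np.flatnonzero(~keep)
    return track.iloc[keep].reset_index(drop=True), list(removed)


# ---------------------------------------------------------------------------
# trips
# ---------------------------------------------------------------------------

@dataclass
class Trip:
    """A colony-departure-to-return slice of a GPS track."""

    fixes: pd.DataFrame
    colony: tuple
    bird_id: str | None = None
    complete: bool = True

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise ValueError("a trip needs at least 2 fixes")
        if self.duration_h <= 0:
            raise ValueError("trip duration must be positive")

    @property
    def start(self):
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self):
        return self.fixes["timestamp"].iloc[-1]

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


@dataclass
class TripMetrics:
    duration_h: float
    total_distance_km: float
    max_distance_km: float
    avg_speed_kmh: float
    avg_bearing_deg: float
    bird_id: str | None = None

    def as_dict(self) -> dict:
        return {
            "bird_id": self.bird_id,
            "duration_h": self.duration_h,
            "total_distance_km": self.total_distance_km,
            "max_distance_km": self.max_distance_km,
            "avg_speed_kmh": self.avg_speed_kmh,
            "avg_bearing_deg": self.avg_bearing_deg,
        }


def segment_trips(track: pd.DataFrame, colony, radius_km: float = 1.0,
                  bird_id: str | None = None) -> list[Trip]:
    """Cut a (filtered) track into foraging trips around a colony.

    A trip opens at the last fix inside ``radius_km`` of the colony
    before an excursion and closes at the first fix back inside.
    Excursions truncated by the start or end of the record are returned
    flagged ``complete=False``.  A track that never leaves the radius
    yields an empty list.
    """
    lat = track["lat"].to_numpy(float)
    lon = track["lon"].to_numpy(float)
    inside = great_circle_km((lat, lon), (colony[0], colony[1])) <= radius_km
    trips: list[Trip] = []
    n = len(track)
    i = 0
    while i < n:
        if inside[i]:
            i += 1
            continue
        # excursion run [i, j)
        j = i
        while j < n and not inside[j]:
            j += 1
        start = i - 1  # last inside fix before departure (may be -1)
        end = j        # first inside fix after return (may be n)
        lo = max(start, 0)
        hi = min(end, n - 1)
        complete = start >= 0 and end < n
        if hi > lo:
            trips.append(Trip(track.iloc[lo:hi + 1].reset_index(drop=True),
                              colony=(colony[0], colony[1]),
                              bird_id=bird_id, complete=complete))
        i = j
    return trips


def trip_metrics(trip: Trip, circular_bearing: bool = False) -> TripMetrics:
    """The five per-trip parameters.

    ``avg_bearing_deg`` is by default the arithmetic mean of the per-fix
    colony-to-fix bearings reduced mod 360, which is the convention the
    field's per-trip summary tables use; set ``circular_bearing=True``
    for the vector (circular) mean instead.  Fixes within 1 m of the
    colony are skipped for the bearing (undefined there).
    """
    fx = trip.fixes
    lat = fx["lat"].to_numpy(float)
    lon = fx["lon"].to_numpy(float)
    dur = trip.duration_h
    seg = great_circle_km((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    total = float(np.sum(seg))
    dcol = np.atleast_1d(great_circle_km((lat, lon), (trip.colony[0], trip.colony[1])))
    max_d = float(np.max(dcol))
    away = dcol > 1e-3  # > 1 m from colony
    if away.any():
        b = _bearings_from(trip.colony, lat[away], lon[away])
        if circular_bearing:
            rad = np.radians(b)
            avg_bearing = math.degrees(math.atan2(np.mean(np.sin(rad)),
                                                  np.mean(np.cos(rad)))) % 360.0
        else:
            avg_bearing = float(np.mean(b)) % 360.0
    else:
        avg_bearing = float("nan")
    return TripMetrics(
        duration_h=dur,
        total_distance_km=total,
        max_distance_km=max_d,
        avg_speed_kmh=total / dur,
        avg_bearing_deg=avg_bearing,
        bird_id=trip.bird_id,
    )


# ---------------------------------------------------------------------------
# wind
# ---------------------------------------------------------------------------

def daily_wind_means(wind: pd.DataFrame) -> pd.DataFrame:
    """Collapse sub-daily wind records to daily means.

    ``wind`` has columns ``timestamp``, ``speed`` (m/s) and ``direction``
    (deg).  Speed is the arithmetic mean; direction is the circular
    (unit-vector) mean reported in [0, 360).  Days without records are
    absent from the output.
    """
    if len(wind) == 0:
        return pd.DataFrame(columns=["date", "speed", "direction"])
    df = wind.copy()
    df["date"] = pd.to_datetime(df["timestamp"]).dt.date
    rad = np.radians(df["direction"].to_numpy(float))
    df["_sin"] = np.sin(rad)
    df["_cos"] = np.cos(rad)
    g = df.groupby("date", sort=True).agg(speed=("speed", "mean"),
                                          _sin=("_sin", "mean"),
                                          _cos=("_cos", "mean"))
    d = np.degrees(np.arctan2(g["_sin"], g["_cos"])) % 360.0
    g["direction"] = np.where(d > 360.0 - 1e-9, 0.0, d)
    return g.reset_index()[["date", "speed", "direction"]]


# ---------------------------------------------------------------------------
# interpolation
# ---------------------------------------------------------------------------

def _slerp(p0, p1, f):
    """Spherical linear interpolation between two (lat, lon) points, f in [0,1]."""
    v0 = _unit(p0)
    v1 = _unit(p1)
    dot = max(-1.0, min(1.0, float(np.dot(v0, v1))))
    omega = math.acos(dot)
    if omega < 1e-12:
        v = v0
    else:
        so = math.sin(omega)
        v = (math.sin((1 - f) * omega) / so) * v0 + (math.sin(f * omega) / so) * v1
    return _latlon(v)


def _unit(p):
    lat, lon = math.radians(p[0]), math.radians(p[1])
    return np.array([math.cos(lat) * math.cos(lon),
                     math.cos(lat) * math.sin(lon),
                     math.sin(lat)])


def _latlon(v):
    v = v / np.linalg.norm(v)
    return math.degrees(math.asin(max(-1.0, min(1.0, v[2])))), math.degrees(math.atan2(v[1], v[0]))


def position_at(trip: Trip, t) -> tuple[float, float]:
    """Great-circle interpolated (lat, lon) on the trip track at time ``t``.

    ``t`` must lie within the trip span.
    """
    t = pd.Timestamp(t)
    ts = trip.fixes["timestamp"]
    if t < ts.iloc[0] or t > ts.iloc[-1]:
        raise ValueError(f"time {t} outside trip span [{ts.iloc[0]}, {ts.iloc[-1]}]")
    i = int(ts.searchsorted(t, side="right")) - 1
    if i >= len(ts) - 1:
        i = len(ts) - 2
    t0, t1 = ts.iloc[i], ts.iloc[i + 1]
    f = 0.0 if t1 == t0 else (t - t0) / (t1 - t0)
    p0 = (trip.fixes["lat"].iloc[i], trip.fixes["lon"].iloc[i])
    p1 = (trip.fixes["lat"].iloc[i + 1], trip.fixes["lon"].iloc[i + 1])
    return _slerp(p0, p1, float(f))


def positions_per_second(trip: Trip) -> pd.DataFrame:
    """Interpolated position at every whole UTC second of the trip span.

    Vectorised slerp per track segment; used to attach locations and
    ground speeds to per-second behavioural records.
    """
    start = trip.start.ceil("s")
    end = trip.end.floor("s")
    secs = pd.date_range(start, end, freq="1s")
    ts = trip.fixes["timestamp"].to_numpy()
    lat = np.radians(trip.fixes["lat"].to_numpy(float))
    lon = np.radians(trip.fixes["lon"].to_numpy(float))
    v = np.stack([np.cos(lat) * np.cos(lon), np.cos(lat) * np.sin(lon), np.sin(lat)], axis=1)
    tq = secs.to_numpy()
    i = np.clip(np.searchsorted(ts, tq, side="right") - 1, 0, len(ts) - 2)
    dt = (ts[i + 1] - ts[i]).astype("timedelta64[ns]").astype(float)
    f = np.where(dt > 0, (tq - ts[i]).astype("timedelta64[ns]").astype(float) / dt, 0.0)
    v0 = v[i]
    v1 = v[i + 1]
    dot = np.clip(np.sum(v0 * v1, axis=1), -1.0, 1.0)
    omega = np.arccos(dot)
    so = np.sin(omega)
    small = so < 1e-12
    w0 = np.where(small, 1.0 - f, np.sin((1.0 - f) * omega) / np.where(small, 1.0, so))
    w1 = np.where(small, f, np.sin(f * omega) / np.where(small, 1.0, so))
    vi = w0[:, None] * v0 + w1[:, None] * v1
    vi /= np.linalg.norm(vi, axis=1, keepdims=True)
    out = pd.DataFrame({
        "timestamp": secs,
        "lat": np.degrees(np.arcsin(np.clip(vi[:, 2], -1.0, 1.0))),
        "lon": np.degrees(np.arctan2(vi[:, 1], vi[:, 0])),
    })
    return out
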