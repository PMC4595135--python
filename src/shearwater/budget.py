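"""Activity budgets, night-time exclusion and spatial foraging summaries."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .track import Trip, great_circle_km, positions_per_second

BUDGET_STATES = ("rest", "flap", "glide", "takeoff", "forage")

__all__ = [
    "BUDGET_STATES",
    "ActivityBudget",
    "SpatialForagingSummary",
    "solar_elevation",
    "night_mask",
    "budget",
    "surface_events",
    "spatial_summary",
]


# ---------------------------------------------------------------------------
# solar geometry (NOAA general solar position formulas)
# ---------------------------------------------------------------------------

def solar_elevation(timestamps, lat, lon) -> np.ndarray:
    """Solar elevation angle (deg) at UTC times and positions.

    NOAA's general solar position calculations (fractional-year Fourier
    fits for the equation of time and declination); accurate to a small
    fraction of a degree, ample for a twilight cut.  ``lat``/``lon`` may
    be scalars or arrays aligned with ``timestamps``.
    """
    ts = pd.DatetimeIndex(pd.to_datetime(timestamps, utc=True))
    lat = np.broadcast_to(np.asarray(lat, float), ts.shape)
    lon = np.broadcast_to(np.asarray(lon, float), ts.shape)
    doy = np.asarray(ts.dayofyear)
    hours = np.asarray(ts.hour + ts.minute / 60.0 + ts.second / 3600.0
                       + ts.microsecond / 3.6e9, float)
    leap = np.asarray(ts.is_leap_year)
    year_len = np.where(leap, 366.0, 365.0)
    g = 2.0 * np.pi / year_len * (doy - 1 + (hours - 12.0) / 24.0)
    eqtime = 229.18 * (0.000075 + 0.001868 * np.cos(g) - 0.032077 * np.sin(g)
                       - 0.014615 * np.cos(2 * g) - 0.040849 * np.sin(2 * g))
    decl = (0.006918 - 0.399912 * np.cos(g) + 0.070257 * np.sin(g)
            - 0.006758 * np.cos(2 * g) + 0.000907 * np.sin(2 * g)
            - 0.002697 * np.cos(3 * g) + 0.00148 * np.sin(3 * g))
    time_offset = eqtime + 4.0 * lon  # minutes; lon east-positive
    tst = hours * 60.0 + time_offset
    ha = np.radians(tst / 4.0 - 180.0)
    latr = np.radians(lat)
    sin_el = (np.sin(latr) * np.sin(decl)
              + np.cos(latr) * np.cos(decl) * np.cos(ha))
    return np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def night_mask(timestamps, lats, lons, threshold_deg: float = -6.0) -> np.ndarray:
    """True where the sun is below ``threshold_deg`` (default -6 deg,
    civil twilight) at each time and position."""
    return solar_elevation(timestamps, lats, lons) < threshold_deg


# ---------------------------------------------------------------------------
# budgets
# ---------------------------------------------------------------------------

@dataclass
class ActivityBudget:
    """Per-trip fraction of seconds in each of the five at-sea behaviours.

    ``forage`` pools surface foraging and diving (as in activity-budget
    figures); the split is reported separately.  Proportions sum to 1.
    """

    proportions: dict
    forage_surface: float
    forage_dive: float
    n_seconds: int
    night_excluded: bool

    def __post_init__(self):
        total = sum(self.proportions.values())
        if self.n_seconds and abs(total - 1.0) > 1e-9:
            raise ValueError(f"budget proportions sum to {total}, not 1")


def budget(ethogram: pd.DataFrame, trip: Trip, exclude_night: bool = False,
           night_threshold_deg: float = -6.0) -> ActivityBudget:
    """Activity budget of a trip from its per-second ethogram.

    With ``exclude_night`` the seconds whose solar elevation at the
    interpolated position is below the twilight threshold are dropped
    from both numerator and denominator; a trip with zero daylight
    seconds is an explicit error.
    """
    labels = ethogram["label"].to_numpy(dtype=object)
    secs = pd.DatetimeIndex(ethogram["second"])
    keep = np.ones(len(labels), bool)
    if exclude_night:
        pos = positions_per_second(trip).set_index("timestamp")
        pos = pos.reindex(secs).ffill().bfill()
        keep = ~night_mask(secs, pos["lat"].to_numpy(), pos["lon"].to_numpy(),
                           night_threshold_deg)
        if not keep.any():
            raise ValueError("no daylight seconds in trip; cannot exclude night")
    labels = labels[keep]
    n = len(labels)
    counts = pd.Series(labels).value_counts()
    get = lambda s: int(counts.get(s, 0))
    surface = get("forage_surface")
    dive = get("dive")
    props = {
        "rest": get("rest") / n,
        "flap": get("flap") / n,
        "glide": get("glide") / n,
        "takeoff": get("takeoff") / n,
        "forage": (surface + dive) / n,
    }
    return ActivityBudget(proportions=props, forage_surface=surface / n,
                          forage_dive=dive / n, n_seconds=n,
                          night_excluded=exclude_night)


# ---------------------------------------------------------------------------
# spatial summaries of foraging events
# ---------------------------------------------------------------------------

@dataclass
class SpatialForagingSummary:
    n_dives: int
    first_dive_km: float | None
    pct_dives_within_10km: float | None
    pct_dives_beyond_30km: float | None
    mean_dive_duration_s: float | None
    n_surface: int
    first_surface_km: float | None
    pct_surface_within_10km: float | None


@dataclass
class SurfaceEvent:
    start: pd.Timestamp
    duration_s: float
    lat: float
    lon: float
    dist_colony_km: float


def surface_events(ethogram: pd.DataFrame, trip: Trip) -> list[SurfaceEvent]:
    """Contiguous runs of surface-foraging seconds as located events."""
    from .track import position_at

    labels = ethogram["label"].to_numpy(dtype=object)
    secs = pd.DatetimeIndex(ethogram["second"])
    events = []
    i = 0
    n = len(labels)
    while i < n:
        if labels[i] != "forage_surface":
            i += 1
            continue
        j = i
        while j < n and labels[j] == "forage_surface":
            j += 1
        start = secs[i]
        t = min(max(start, trip.start), trip.end)
        la, lo = position_at(trip, t)
        events.append(SurfaceEvent(start=start, duration_s=float(j - i), lat=la,
                                   lon=lo,
                                   dist_colony_km=great_circle_km((la, lo), trip.colony)))
        i = j
    return events


def spatial_summary(dives, surface, trip: Trip, colony=None) -> SpatialForagingSummary:
    """Where foraging happened relative to the colony.

    ``dives`` and ``surface`` are located event lists (each event has a
    ``start`` and ``dist_colony_km``).  "First" events are earliest in
    time.  With no events the distance fields are None and counts zero.
    """
    colony = colony or trip.colony

    def dist(e):
        if e.dist_colony_km is not None:
            return e.dist_colony_km
        return great_circle_km((e.lat, e.lon), colony)

    out = dict(n_dives=len(dives), first_dive_km=None, pct_dives_within_10km=None,
               pct_dives_beyond_30km=None, mean_dive_duration_s=None,
               n_surface=len(surface), first_surface_km=None,
               pct_surface_within_10km=None)
    if dives:
        d = np.array([dist(e) for e in dives])
        first = min(dives, key=lambda e: e.start)
        out["first_dive_km"] = float(dist(first))
        out["pct_dives_within_10km"] = 100.0 * float(np.mean(d <= 10.0))
        out["pct_dives_beyond_30km"] = 100.0 * float(np.mean(d > 30.0))
        out["mean_dive_duration_s"] = float(np.mean([e.duration_s for e in dives]))
    if surface:
        d = np.array([dist(e) for e in surface])
        first = min(surface, key=lambda e: e.start)
        out["first_surface_km"] = float(dist(first))
        out["pct_surface_within_10km"] = 100.0 * float(np.mean(d <= 10.0))
    return SpatialForagingSummary(**out)
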