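"""Independent oracles shared across test modules.

Each implements the quantity a different way from the package code:
spherical law of cosines vs haversine, exhaustive minimal removal vs the
iterative speed filter, and the PSA solar position algorithm vs the NOAA
formulas.
"""

import itertools
import math

import numpy as np

from shearwater.track import track_speeds_kmh


def law_of_cosines_km(a, b):
    la1, lo1, la2, lo2 = map(math.radians, [a[0], a[1], b[0], b[1]])
    c = (math.sin(la1) * math.sin(la2)
         + math.cos(la1) * math.cos(la2) * math.cos(lo2 - lo1))
    return 6371.0 * math.acos(max(-1.0, min(1.0, c)))


def brute_force_minimal_removal(track, vmax):
    """Smallest interior-fix subset whose removal leaves all speeds <= vmax."""
    n = len(track)
    interior = range(1, n - 1)
    for size in range(0, n - 1):
        for combo in itertools.combinations(interior, size):
            keep = [i for i in range(n) if i not in combo]
            if (track_speeds_kmh(track.iloc[keep]) <= vmax).all():
                return set(combo)
    return set(interior)


def psa_solar_elevation(ts, lat, lon):
    """Solar elevation via the PSA ephemeris (Blanco-Muriel et al. 2001).

    Entirely different formulation (ecliptic coordinates from Julian
    date) from the NOAA fractional-year fits used by the package.
    """
    import pandas as pd

    t = pd.Timestamp(ts)
    if t.tzinfo is None:
        t = t.tz_localize("UTC")
    t = t.tz_convert("UTC")
    hour = t.hour + t.minute / 60.0 + t.second / 3600.0
    # Julian day from calendar date (Fliegel-Van Flandern)
    y, m, d = t.year, t.month, t.day
    jd = (1461 * (y + 4800 + (m - 14) // 12)) // 4 \
        + (367 * (m - 2 - 12 * ((m - 14) // 12))) // 12 \
        - (3 * ((y + 4900 + (m - 14) // 12) // 100)) // 4 + d - 32075
    jd = jd - 0.5 + hour / 24.0
    n = jd - 2451545.0
    omega = 2.1429 - 0.0010394594 * n
    mean_lon = 4.8950630 + 0.017202791698 * n
    mean_anom = 6.2400600 + 0.0172019699 * n
    ecl_lon = (mean_lon + 0.03341607 * math.sin(mean_anom)
               + 0.00034894 * math.sin(2 * mean_anom) - 0.0001134
               - 0.0000203 * math.sin(omega))
    obliquity = 0.4090928 - 6.2140e-9 * n + 0.0000396 * math.cos(omega)
    sin_el = math.sin(ecl_lon) * math.sin(obliquity)
    dec = math.asin(sin_el)
    ra = math.atan2(math.cos(obliquity) * math.sin(ecl_lon), math.cos(ecl_lon))
    ra = ra % (2 * math.pi)
    gmst = 6.6974243242 + 0.0657098283 * n + hour
    lmst = math.radians(gmst * 15 + lon)
    ha = lmst - ra
    latr = math.radians(lat)
    cos_zen = (math.cos(latr) * math.cos(ha) * math.cos(dec)
               + math.sin(dec) * math.sin(latr))
    zen = math.acos(max(-1.0, min(1.0, cos_zen)))
    # parallax correction
    zen += 6371.01 / 149597890.0 * math.sin(zen)
    return 90.0 - math.degrees(zen)
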