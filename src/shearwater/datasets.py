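"""Reference data: published per-trip parameters of short-tailed
shearwater short foraging trips at two Bass Strait colonies.

Thirteen complete short trips from ten chick-rearing birds tracked in
February 2012 at Gabo Island (37deg33'S, 149deg54'E) and Griffith Island
(38deg22'S, 142deg13'E).  Two Griffith birds were tracked over sequential
1-day trips (2 and 3 trips); one performed a 2-day trip.  These per-trip
values are the input to the colony-comparison statistics.
"""

from __future__ import annotations

import pandas as pd

GABO_COLONY = (-37.55, 149.90)
GRIFFITH_COLONY = (-38.3667, 142.2167)

_ROWS = [
    # colony, bird, body_mass_g, duration_h, total_km, max_km, speed_kmh, bearing_deg
    ("gabo", "1", 565.0, 16.3, 207.9, 37.2, 12.4, 239.1),
    ("gabo", "2", 555.0, 15.1, 118.7, 38.1, 6.4, 24.0),
    ("gabo", "3", 610.0, 15.6, 140.9, 31.3, 9.4, 211.9),
    ("gabo", "4", 565.0, 16.5, 257.9, 36.3, 15.3, 210.9),
    ("gabo", "5", 590.0, 18.4, 295.9, 49.5, 17.1, 13.6),
    ("gabo", "6", 565.0, 15.0, 152.3, 40.7, 9.0, 21.1),
    ("griffith", "7a", 625.0, 16.0, 319.1, 130.3, 22.3, 107.6),
    ("griffith", "7b", None, 15.8, 264.5, 47.3, 17.3, 206.2),
    ("griffith", "8", 595.0, 17.2, 306.7, 68.1, 19.9, 267.4),
    ("griffith", "9a", 565.0, 16.0, 195.7, 81.1, 12.4, 110.5),
    ("griffith", "9b", None, 15.8, 181.7, 71.4, 11.1, 118.3),
    ("griffith", "9c", None, 15.4, 277.9, 87.1, 18.7, 169.3),
    ("griffith", "10", 595.0, 41.5, 667.2, 122.9, 14.6, 125.6),
]


def field_trips() -> pd.DataFrame:
    """Per-trip foraging parameters of the two-colony field study."""
    return pd.DataFrame(_ROWS, columns=[
        "colony", "bird_id", "body_mass_g", "duration_h",
        "total_distance_km", "max_distance_km", "avg_speed_kmh",
        "avg_bearing_deg",
    ])
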