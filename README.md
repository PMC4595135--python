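# shearwater

Combined GPS + tri-axial accelerometry analysis of seabird foraging
trips, built around the short-tailed shearwater (*Ardenna tenuirostris*),
a small pelagic procellariiform that alternates short (1–3 day) foraging
trips near the colony with long trips to distant waters.  The package is
aimed at movement ecologists who deploy a 5-min-interval GPS logger and a
25 Hz tri-axial accelerometer on the same bird and want, from those two
text files, the bird's at-sea activity budget, its dives, and
colony-level comparisons of trip parameters.

## What it computes

**Track side.** GPS fixes are cleaned with an iterative forward/backward
speed filter (threshold 60 km·h⁻¹), segmented into complete
colony-departure-to-return trips, and summarised by five parameters per
trip: duration (h), total distance (km), maximum distance to the colony
(km), average horizontal speed (km·h⁻¹) and average bearing from the
colony (°).  Distances are haversine on a 6371 km sphere.

**Acceleration side.** Each second of the longitudinal (surge) axis is
converted into a spectrum by continuous wavelet transform (Morlet, 16
log-spaced bands 0.5–12 Hz) after splitting the signal into static
(gravity, 1-s moving average) and dynamic components.  Per-second
spectral features are clustered by k-means and the clusters mapped onto
five at-sea behaviours — resting on water, flapping flight, gliding
flight, taking off, and foraging (surface foraging + diving) — with
resting and gliding disambiguated by ground speed, since both are
low-dynamic postures.  Dives are detected from a high dynamic surge
spike during sustained negative pitch, where pitch is
atan2(surge, √(sway² + heave²)) of the static vector.

**Budgets and statistics.** Activity budgets per trip (optionally with
night-time excluded, night = solar elevation < −6°), spatial summaries
of foraging events relative to the colony, Wilcoxon rank-sum and
Kruskal–Wallis comparisons, a Yates-corrected 2×2 χ², arcsine-√ and log
transforms, and a random-intercept linear mixed model (bird as random
factor) fitted by direct REML profile optimisation.

**Synthetic data.** Because raw tracking data of this kind are rarely
deposited, `shearwater.simulate` generates fully labelled GPS +
accelerometer + wind datasets — a semi-Markov behavioural state process
with per-state acceleration signatures and state-consistent track
kinematics — so every stage of the pipeline is testable against known
truth (dive durations default to 9.0 ± 1.9 s, the value reported for
this species).

## Worked example

```python
import numpy as np
from shearwater import (SimConfig, simulate_trip, speed_filter, segment_trips,
                        classify, budget, wilcoxon_rank_sum)
from shearwater.datasets import field_trips
from shearwater.ethogram import ClassifyConfig

# colony comparison on the published per-trip table
ft = field_trips()
gabo = ft[ft.colony == "gabo"]
griffith = ft[ft.colony == "griffith"]
r = wilcoxon_rank_sum(gabo["max_distance_km"], griffith["max_distance_km"])
print(f"max distance: W = {r.W:.0f}, p = {r.p:.3f} ({r.method})")

# a labelled synthetic trip through the full pipeline
ds = simulate_trip(SimConfig(seed=1, trip_hours=4.0))
track, removed = speed_filter(ds.gps)
trip = [t for t in segment_trips(track, ds.config.colony) if t.complete][0]
eth, dives = classify(ds.accel, trip, ClassifyConfig(seed=0))
b = budget(eth, trip)
print(f"trip duration {trip.duration_h:.1f} h, {len(removed)} fixes filtered")
print(f"{len(dives)} dives, mean duration "
      f"{np.mean([d.duration_s for d in dives]):.1f} s")
print({k: round(v, 3) for k, v in b.proportions.items()})
```

prints

```
max distance: W = 1, p = 0.002 (exact)
trip duration 3.6 h, 0 fixes filtered
16 dives, mean duration 9.0 s
{'rest': 0.601, 'flap': 0.133, 'glide': 0.093, 'takeoff': 0.0, 'forage': 0.172}
```

The W = 1 / p = 0.002 line reproduces the published maximum-distance
comparison between the two colonies exactly; the budget line is the
fraction of trip seconds the classifier assigns to each behaviour
(a 4-hour trip; no take-off seconds survive rounding to three decimals
here because take-offs last only a few seconds each).

A thin CLI mirrors the library:
`shearwater simulate`, `shearwater filter`, `shearwater trips`,
`shearwater classify`, `shearwater budget`, `shearwater wilcoxon`.

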