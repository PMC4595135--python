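# Methods

## Scope and data model

The package analyses paired deployments of a GPS logger (nominal 5-min
fix interval) and a tri-axial accelerometer (25 Hz) on a central-place
foraging seabird.  Axes follow the body frame: surge = longitudinal (x),
sway = lateral, heave = dorsoventral, in g.  The mounting convention is
that level posture reads (0, 0, −1 g); pitch is
atan2(surge, √(sway² + heave²)) of the static (gravitational) component,
positive nose-up.  All timestamps are normalised to UTC on ingest; solar
geometry is evaluated per position, not per colony.  The GPS and
accelerometer clocks are assumed aligned after UTC normalisation (the
loggers share a battery in the motivating deployment); no offset
estimation is attempted.

## Track processing

* **Speed filter.** Iterative forward/backward filter with a 60 km·h⁻¹
  threshold.  Each pass flags a fix if the speed from its previous
  retained neighbour (forward) or next retained neighbour (backward)
  exceeds the threshold; the earliest doubly-flagged fix is removed and
  speeds recomputed, falling back to the earliest single flag; endpoints
  are never removed.  Removing one fix per iteration makes the filter
  agree with an exhaustive minimal-removal oracle on small tracks: a
  good fix sandwiched between two displaced fixes is flagged both ways
  on the first pass but exonerated once a neighbour is gone.  The filter
  is idempotent.
* **Trips.** A trip opens at the last fix inside the colony radius
  (default 1 km; the radius is not a reported quantity and is exposed as
  a parameter) before an excursion and closes at the first fix back
  inside.  Excursions truncated by the record edges are flagged
  incomplete and excluded from metrics by default.
* **Metrics.** Haversine distances on a sphere of radius 6371.0 km
  (< 0.5 % error at coastal-trip scales, verified against a spherical
  law-of-cosines oracle to < 1 m).  The per-trip average bearing is the
  arithmetic mean of per-fix colony-to-fix bearings reduced mod 360 —
  not the circular mean — because that is the convention under which the
  published summary row of per-trip bearings (mean 120.1° for one
  colony) reproduces; the circular mean is available as an option.
  Whether the reported per-trip bearing was fix-wise or segment-wise
  averaged is not documented anywhere we know of; fix-wise was chosen.
  Summary rows use the sample (n−1) standard deviation, which likewise
  reproduces the published SDs.
* **Wind.** Sub-daily wind records collapse to daily means: arithmetic
  for speed, circular (unit-vector) for direction.

## Behavioural classification

1. **Static/dynamic split.** Centred 1-s moving average (static) and
   residual (dynamic); the reconstruction is exact by construction.  A
   1-s boxcar attenuates a 6 Hz wingbeat by |sinc(6)| ≈ 5 %, so wingbeat
   energy stays in the dynamic component while posture stays static.
2. **Spectrum.** Morlet continuous wavelet transform of the dynamic
   surge at 16 log-spaced analysis frequencies, 0.5–12 Hz, averaged
   within each second (the convention of spectrum-based ethogram
   tools for accelerometry).
3. **Frame features.** Per second: dominant band frequency; RMS dynamic
   amplitude over the three axes; mean band amplitude below 2 Hz
   (body-lift energy of take-off bursts); mean band amplitude in the
   4–8 Hz wingbeat band; mean static surge; mean pitch.  Features are
   z-standardised for clustering.
4. **Clustering.** Lloyd's k-means, best of 10 restarts, fixed seed.
   Default k = 7.  The five behaviours occupy six natural clusters in
   feature space (resting and gliding share one low-dynamic region), and
   two spare clusters are kept: one absorbs bout-boundary transition
   seconds, one the heterogeneity of irregular surface-foraging bursts,
   which otherwise bleed into the flapping cluster.  Sweeping k over
   4–8 changes overall per-second accuracy by < 4 points on the default
   simulation (asserted in the tests).
5. **Cluster→behaviour rules** (ordered): nose-down centroid
   (pitch ≤ −30°) → dive; very high amplitude (≥ 0.9 g RMS) → take-off;
   dominant frequency in the wingbeat band (4.5–8 Hz) with amplitude
   ≥ 0.2 g → flapping; low-dynamic (≤ 0.15 g) → rest or glide by the
   cluster's median ground speed; anything else → surface foraging.
   All thresholds are exposed in `LabelRules`; none is a reported value,
   since behaviour-specific amplitude scales are never published for
   these loggers.
6. **Misclassification correction.** Resting vs gliding cannot be told
   apart from acceleration (both are low-dynamic), so every low-dynamic
   second is re-assigned by ground speed (default split 10 km·h⁻¹).
   Ground speed comes from great-circle interpolation of the 5-min
   fixes, i.e. it is piecewise constant between fixes.  This smoothing
   is the method's main known error source: seconds of resting inside a
   GPS segment that also contains flight inherit a blended speed and can
   be mislabelled gliding (and vice versa).  With multi-minute bouts the
   effect is confined to segment boundaries (≈ 5–10 % of rest seconds on
   the default simulation).
7. **Dives.** A dive opens where |dynamic surge| ≥ 1.5 g within 0.6 s of
   a window of pitch < −30°, backtracks to the start of the descent
   (pitch < −10°), and closes when pitch recovers above −10° sustained
   for 1 s; events closer than 2 s merge; events shorter than 1 s are
   discarded.  Raising the spike threshold never adds events.  Dive
   seconds override cluster labels.  The 0.6 s tolerance exists because
   the 1-s static window delays the apparent pitch drop relative to the
   instantaneous entry spike.  The spike and pitch thresholds are free
   parameters tuned on the simulator; no study publishes them.

## Budgets, night mask, spatial summaries

Budgets are per-state second counts over trip seconds; surface foraging
and diving pool into "foraging" (the split is also reported).  Night is
solar elevation < −6° (civil twilight; the threshold is configurable
because "night-time" is not formally defined in field reports), computed
with the NOAA general solar position formulas at each second's
interpolated position; with night excluded, night seconds leave both
numerator and denominator.  The implementation agrees with an
independent PSA-ephemeris oracle to well under 10 min at the twilight
boundaries.  Spatial summaries report the distance of the first dive and
first surface-foraging event from the colony and the percentage of
events within 10 km and beyond 30 km.

## Statistics

* **Wilcoxon rank-sum.** W = (rank sum of the first sample) −
  n₁(n₁+1)/2, average ranks for ties — the convention of the common
  statistical environments, verified against all three published W
  values for the two-colony trip comparisons.  P-values are exact by
  subset-sum enumeration when the pooled sample is tie-free and
  C(n₁+n₂, n₁) ≤ 10⁶, else normal approximation with tie and continuity
  corrections.  Kruskal–Wallis is provided as a thin generalisation
  (tie-corrected H, χ² reference); no published value exists to check it
  against.
* **2×2 χ².** Pearson with Yates continuity correction by default,
  matching the convention of the environment the motivating study used.
  The study's underlying nest counts are not published, so only the
  formula is verifiable (against an independent implementation), not
  the printed values.
* **Mixed model.** y = β₀ + β₁·covariate (+ site) + u_bird + ε with
  u ~ N(0, σ_u²).  The variance ratio λ = σ_u²/σ_ε² is profiled: for
  fixed λ, GLS via the closed-form block inverse (I + λJ per bird) gives
  β̂ and σ̂_ε² analytically, and −2·restricted-log-likelihood is
  minimised over log λ by a coarse grid plus golden-section refinement.
  The recorded objective trace is non-increasing.  A boundary solution
  is reported as a singular fit (σ_u² = 0), not an error, and then the
  estimates coincide with OLS.  The marginal F test for β₁ uses the
  nested (containment) denominator df: n − #birds − #slopes when the
  covariate varies within birds, #birds − 1 − #slopes otherwise.
  Published F statistics for this design cannot be reproduced (per-trip
  covariate values are not tabulated), and the published denominator df
  of 10 at n = 12 implies an effectively observation-level grouping in
  the original fit, where the variance components are not identifiable;
  correctness here is instead established by simulation — type-I error
  ≈ 5 % and ≤ 10 % median error in slope and variance components at a
  well-posed design (several trips per bird).

## The synthetic-data generator

The generator emulates the study conditions rather than any particular
dataset.  A semi-Markov chain over three macro states (rest on water,
flight, surface foraging; gamma dwell times, means 1200/600/450 s,
shape 8) produces labelled seconds; flight decomposes into alternating
flapping (mean 40 s) and gliding (mean 20 s) bouts opened by a 2–5 s
take-off burst; foraging bouts embed dives (truncated normal,
9.0 ± 1.9 s, floor 1 s — the published dive-duration distribution for
the species) separated by ~120 s surface intervals, which yields dive
counts per trip of the published order (tens per trip).  The default
16 h trip and 5-min GPS interval match the species' 1-day short trips.
Ground speeds are drawn per bout from per-state ranges (flight
25–55 km·h⁻¹, water states ≲ 4 km·h⁻¹); heading follows a wrapped-normal
random walk biased to an outbound bearing, then homes on the colony from
mid-trip (forcing flight if the time budget tightens), so the GPS track
closes a complete trip; after arrival the bird rests at the colony.
GPS outliers (default rate 0.5 %, the published speed-filter removal
rate) displace interior fixes 15–30 km.  Wind is 3-hourly, speed
N(8, 2.5²) m·s⁻¹ truncated at 0.

Acceleration signatures per state: rest — gravity plus a 0.2–0.45 Hz
swell of 0.1 g; glide — gravity plus 0.03 g noise; flap — 6 Hz sinusoid
(amplitude 1 g heave, 0.4 g surge; the wingbeat frequency is a free
parameter, not a reported value); take-off — 2.5 g wingbeat plus a
1.2 Hz body-lift component; surface foraging — irregular 0.3–0.8 s
bursts at 1.5–3.5 Hz, amplitude 0.9 g; dive — 0.25 s pitch ramp to −60°,
3 g entry spike on surge, intermittent 4 Hz underwater flapping at
0.5 g.  Amplitude scales are free parameters chosen once to resemble
published accelerometry traces of small procellariiforms; they are not
measurements.

What the generator does *not* emulate — and hence what passing tests do
not show about field data: sensor drift, mounting misalignment, sea-state
dependence of the rest signature, depth (the motivating logger had no
pressure sensor), bout-internal speed variation beyond noise, prey-patch
spatial structure (dives are placed by the state process, not by
habitat), and inter-individual variation in signal amplitudes.  Recovery
rates measured on the simulator are therefore upper bounds for field
performance; the printed-table statistics, by contrast, are exact
reproductions of published numbers.

## Numerical choices and degenerate inputs

Sample (n−1) SD throughout.  K-means is deterministic for a fixed seed
(10 restarts) and raises on all-identical frames with k > 1.  The exact
rank-sum distribution is computed by a subset-sum dynamic programme.
REML is profiled on log λ ∈ [−15, 15]; λ at the lower bound reports
σ_u² = 0.  Zero-norm static vectors make pitch undefined and raise.
Tracks that never leave the colony radius yield an empty trip list, not
an error; a trip whose seconds are all night raises when night exclusion
is requested.  Empty event lists produce summaries with counts of zero
and distance fields marked undefined.

## Problem sizes

The default test and acceptance runs use one 16 h simulated trip
(1.44 M accelerometer samples, ~190 GPS fixes, ~50 000 classified
seconds), 500 null replicates for mixed-model calibration and 200 for
parameter recovery, 10⁴ random point pairs for the geodesy check, and
minute resolution over a day for the twilight-boundary check.
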