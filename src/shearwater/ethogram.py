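"""Behavioural classification of tri-axial acceleration and dive detection.

Each second of a trip is assigned one of six labels: ``rest``, ``flap``,
``glide``, ``takeoff``, ``forage_surface`` or ``dive`` (surface foraging
and diving together constitute "foraging" in the five-state activity
budget).  The pipeline is:

1. split the trace into static (gravitational, low-pass) and dynamic
   (movement) components;
2. compute the body pitch angle from the static vector;
3. continuous-wavelet transform of the dynamic surge into per-second
   spectral frames;
4. unsupervised k-means clustering of standardised frame features;
5. rule-based mapping of clusters onto behaviours, then a per-second
   correction distinguishing resting from gliding by ground speed
   (the two are indistinguishable from acceleration alone: both are
   low-dynamic postures);
6. dive events from the dynamic surge spike + sustained negative pitch,
   overriding the cluster labels on the seconds they cover.

Axis convention (shared with the simulator): surge = longitudinal x
(positive forward/nose-up contribution), heave reads -1 g in level
posture.  Pitch = atan2(surge_static, sqrt(sway^2 + heave^2)), positive
nose-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pywt
from sklearn.cluster import KMeans

from .io_formats import AccelTrace
from .track import Trip, great_circle_km, position_at, positions_per_second

__all__ = [
    "LabelRules",
    "DiveParams",
    "DiveEvent",
    "split_static_dynamic",
    "pitch_angle",
    "cwt_spectrum",
    "frame_features",
    "kmeans_frames",
    "label_clusters",
    "correct_rest_glide",
    "detect_dives",
    "classify",
    "speeds_per_second",
]


# ---------------------------------------------------------------------------
# static / dynamic split and pitch
# ---------------------------------------------------------------------------

def split_static_dynamic(trace: AccelTrace, cutoff_s: float = 1.0):
    """Separate gravitational (static) and movement (dynamic) acceleration.

    Static = centred moving average over ``cutoff_s`` (default 1 s);
    dynamic = trace - static, so static + dynamic reconstructs the input
    exactly.  Returns two :class:`AccelTrace` objects.
    """
    if cutoff_s <= 2.0 / trace.rate:
        raise ValueError("cutoff window must exceed two samples")
    w = int(round(cutoff_s * trace.rate))
    if len(trace) < w:
        raise ValueError("trace shorter than the smoothing window")

    def smooth(x):
        c = np.cumsum(np.concatenate([[0.0], x]))
        half = w // 2
        idx = np.arange(len(x))
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + (w - half), len(x))
        return (c[hi] - c[lo]) / (hi - lo)

    static = {ax: smooth(getattr(trace, ax)) for ax in ("surge", "sway", "heave")}
    dynamic = {ax: getattr(trace, ax) - static[ax] for ax in ("surge", "sway", "heave")}
    mk = lambda d: AccelTrace(trace.start_time, trace.rate, d["surge"], d["sway"], d["heave"])
    return mk(static), mk(dynamic)


def pitch_angle(surge, sway, heave):
    """Body pitch (deg, [-90, 90], positive nose-up) from static acceleration.

    Works on scalars or arrays.  Raises on zero-norm vectors.
    """
    surge = np.asarray(surge, float)
    sway = np.asarray(sway, float)
    heave = np.asarray(heave, float)
    norm = np.sqrt(surge**2 + sway**2 + heave**2)
    if np.any(norm == 0):
        raise ValueError("zero-norm static vector: pitch undefined")
    p = np.degrees(np.arctan2(surge, np.sqrt(sway**2 + heave**2)))
    return p if p.ndim else float(p)


# ---------------------------------------------------------------------------
# wavelet spectrum and per-second frames
# ---------------------------------------------------------------------------

def default_bands(rate: float, n_bands: int = 16,
                  fmin: float = 0.5, fmax: float = 12.0) -> np.ndarray:
    """Log-spaced wavelet analysis frequencies within (0, rate/2]."""
    fmax = min(fmax, rate / 2.0)
    return np.geomspace(fmin, fmax, n_bands)


def cwt_spectrum(signal, rate: float, bands=None):
    """Per-second Morlet continuous-wavelet spectrum of a 1-D signal.

    Returns ``(bands, amps)`` where ``amps[s, j]`` is the mean absolute
    wavelet coefficient of band ``j`` during second ``s``.
    """
    signal = np.asarray(signal, float)
    if bands is None:
        bands = default_bands(rate)
    bands = np.asarray(bands, float)
    if np.any(bands <= 0) or np.any(bands > rate / 2.0):
        raise ValueError("bands must lie within (0, rate/2]")
    n_sec = int(len(signal) // rate)
    if n_sec < 1:
        raise ValueError("trace shorter than one second")
    fc = pywt.central_frequency("morl")
    scales = fc * rate / bands
    per = int(round(rate))
    n_use = n_sec * per
    amps = np.empty((n_sec, len(bands)))
    for j, sc in enumerate(scales):  # band-by-band keeps memory flat
        coef, _ = pywt.cwt(signal[:n_use], [sc], "morl", method="fft")
        amps[:, j] = np.abs(coef[0]).reshape(n_sec, per).mean(axis=1)
    return bands, amps


def frame_features(trace: AccelTrace, cutoff_s: float = 1.0, bands=None) -> pd.DataFrame:
    """Per-second feature table used for clustering.

    Columns: ``second`` (index), ``dom_freq`` (Hz, band of maximum mean
    wavelet amplitude of the dynamic surge), ``total_amp`` (g, RMS of the
    three dynamic axes), ``low_amp`` (g, mean wavelet amplitude below
    2 Hz, separating broadband take-off bursts from pure wingbeats),
    ``flap_amp`` (g, mean wavelet amplitude in the 4-8 Hz wingbeat band),
    ``static_surge`` (g) and ``pitch`` (deg), plus the raw band
    amplitudes ``amp_<freq>``.
    """
    static, dynamic = split_static_dynamic(trace, cutoff_s)
    rate = trace.rate
    bands, amps = cwt_spectrum(dynamic.surge, rate, bands)
    n_sec = amps.shape[0]
    per = int(round(rate))
    n_use = n_sec * per

    def per_second(x):
        return x[:n_use].reshape(n_sec, per)

    dyn_sq = (per_second(dynamic.surge) ** 2 + per_second(dynamic.sway) ** 2
              + per_second(dynamic.heave) ** 2)
    total_amp = np.sqrt(dyn_sq.mean(axis=1) / 3.0)
    st_surge = per_second(static.surge).mean(axis=1)
    st_sway = per_second(static.sway).mean(axis=1)
    st_heave = per_second(static.heave).mean(axis=1)
    pitch = pitch_angle(st_surge, st_sway, st_heave)
    low = bands < 2.0
    flap_band = (bands >= 4.0) & (bands <= 8.0)
    feats = pd.DataFrame({
        "second": np.arange(n_sec),
        "dom_freq": bands[np.argmax(amps, axis=1)],
        "total_amp": total_amp,
        "low_amp": amps[:, low].mean(axis=1) if low.any() else np.zeros(n_sec),
        "flap_amp": amps[:, flap_band].mean(axis=1) if flap_band.any() else np.zeros(n_sec),
        "static_surge": st_surge,
        "pitch": pitch,
    })
    for j, f in enumerate(bands):
        feats[f"amp_{f:.3g}"] = amps[:, j]
    return feats


FEATURE_COLUMNS = ("dom_freq", "total_amp", "low_amp", "flap_amp",
                   "static_surge", "pitch")


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def kmeans_frames(frames: pd.DataFrame, k: int = 6, seed: int = 0,
                  n_restarts: int = 10, feature_columns=FEATURE_COLUMNS):
    """K-means over standardised frame features; best of ``n_restarts``.

    Returns ``(cluster_ids, centroids)`` with centroids reported in raw
    feature units.  Deterministic for a fixed seed.  All-identical frames
    with k > 1 are a degeneracy error.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    X = frames.loc[:, list(feature_columns)].to_numpy(float)
    if len(X) < k:
        raise ValueError("fewer frames than clusters")
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.all(sd == 0):
        raise ValueError("degenerate input: all frames identical")
    sd = np.where(sd == 0, 1.0, sd)
    Z = (X - mu) / sd
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed, algorithm="lloyd")
    ids = km.fit_predict(Z)
    centroids = km.cluster_centers_ * sd + mu
    cent = pd.DataFrame(centroids, columns=list(feature_columns))
    return ids, cent


# ---------------------------------------------------------------------------
# cluster -> behaviour mapping
# ---------------------------------------------------------------------------

@dataclass
class LabelRules:
    """Thresholds for mapping k-means centroids onto behaviours.

    The flap band and the amplitude splits are free parameters (loggers
    are uncalibrated per behaviour); defaults suit wingbeat frequencies
    around 6 Hz and g-scale accelerometers.
    """

    flap_band: tuple = (4.5, 8.0)
    min_flap_amp: float = 0.2      # g: below this nothing is "flight flapping"
    takeoff_min_amp: float = 0.9   # g: take-off bursts dwarf cruising wingbeats
    low_dynamic_max: float = 0.15  # g: resting / gliding ceiling
    speed_split_kmh: float = 10.0  # rest vs glide ground-speed criterion
    dive_pitch_max: float = -30.0  # deg: nose-down centroid marks diving


def label_clusters(centroids: pd.DataFrame, cluster_ids, speed_per_second,
                   rules: LabelRules | None = None) -> dict:
    """Assign every cluster a behaviour from its centroid and typical speed.

    Ordered rules: nose-down centroid -> dive; very high amplitude ->
    takeoff; periodic centroid in the flap band -> flap; low-dynamic
    clusters -> rest or glide by the cluster's median ground speed;
    anything else (moderate, irregular, slow) -> forage_surface.  The
    mapping is total; an exhaustive-but-unmatched centroid raises with
    its features listed.
    """
    rules = rules or LabelRules()
    cluster_ids = np.asarray(cluster_ids)
    speed = np.asarray(speed_per_second, float)
    mapping: dict[int, str] = {}
    for c in range(len(centroids)):
        row = centroids.iloc[c]
        members = cluster_ids == c
        med_speed = float(np.median(speed[members])) if members.any() else 0.0
        if row["pitch"] <= rules.dive_pitch_max:
            mapping[c] = "dive"
        elif row["total_amp"] >= rules.takeoff_min_amp:
            mapping[c] = "takeoff"
        elif (rules.flap_band[0] <= row["dom_freq"] <= rules.flap_band[1]
              and row["total_amp"] >= rules.min_flap_amp):
            mapping[c] = "flap"
        elif row["total_amp"] <= rules.low_dynamic_max:
            mapping[c] = "glide" if med_speed >= rules.speed_split_kmh else "rest"
        elif row["total_amp"] > rules.low_dynamic_max:
            mapping[c] = "forage_surface"
        else:  # pragma: no cover - reachable only with inconsistent custom rules
            raise ValueError(f"unmapped cluster {c}: {row.to_dict()}")
    return mapping


def correct_rest_glide(labels, speed_per_second, rules: LabelRules | None = None):
    """Per-second misclassification correction: rest vs glide by speed.

    The two low-dynamic behaviours are separated by travel speed; returns
    the corrected labels and a boolean mask of seconds that changed.
    """
    rules = rules or LabelRules()
    labels = np.asarray(labels, dtype=object).copy()
    speed = np.asarray(speed_per_second, float)
    lowdyn = (labels == "rest") | (labels == "glide")
    want = np.where(speed >= rules.speed_split_kmh, "glide", "rest")
    changed = lowdyn & (labels != want)
    labels[lowdyn] = want[lowdyn]
    return labels, changed


# ---------------------------------------------------------------------------
# dive detection
# ---------------------------------------------------------------------------

@dataclass
class DiveParams:
    """Thresholds for surge-spike + negative-pitch dive identification."""

    spike_g: float = 1.5        # |dynamic surge| opening a dive
    pitch_max: float = -30.0    # deg: spike must occur this nose-down
    pitch_end: float = -10.0    # deg: dive closes once pitch recovers past this
    end_sustain_s: float = 1.0  # recovery must hold this long
    merge_gap_s: float = 2.0    # events closer than this merge
    min_duration_s: float = 1.0
    window_s: float = 0.6       # spike may lead/lag the nose-down window this much


@dataclass
class DiveEvent:
    start: pd.Timestamp
    duration_s: float
    lat: float | None = None
    lon: float | None = None
    dist_colony_km: float | None = None

    @property
    def start_offset_s(self):
        return self._offset

    _offset: float = field(default=0.0, repr=False)


def detect_dives(static: AccelTrace, dynamic: AccelTrace,
                 params: DiveParams | None = None) -> list[DiveEvent]:
    """Identify dives from a high dynamic surge spike during nose-down pitch.

    A dive opens at the start of the nose-down window containing a surge
    spike (|dynamic surge| >= ``spike_g`` while pitch < ``pitch_max``)
    and closes when pitch recovers above ``pitch_end`` sustained for
    ``end_sustain_s``.  Events separated by less than ``merge_gap_s``
    merge.  Raising ``spike_g`` never adds events.
    """
    params = params or DiveParams()
    rate = static.rate
    pitch = pitch_angle(static.surge, static.sway, static.heave)
    pitch = np.asarray(pitch, float)
    spike = np.abs(dynamic.surge) >= params.spike_g
    nose_down = pitch < params.pitch_max
    # the 1-s static window delays the apparent pitch drop relative to the
    # entry spike, so allow the spike to sit within window_s of nose-down
    w = max(1, int(round(params.window_s * rate)))
    near_nose_down = np.convolve(nose_down.astype(float), np.ones(2 * w + 1),
                                 mode="same") > 0
    candidates = np.flatnonzero(spike & near_nose_down)
    descending = pitch < params.pitch_end
    recovered = pitch >= params.pitch_end
    sustain = max(1, int(round(params.end_sustain_s * rate)))
    # run-length of consecutive recovered samples starting at each index
    rev = recovered[::-1]
    idx = np.arange(len(rev))
    last_false = np.maximum.accumulate(np.where(~rev, idx, -1))
    runlen = np.zeros(len(pitch) + 1, dtype=np.int64)
    runlen[:-1] = (idx - last_false)[::-1]
    events = []
    pos = 0
    for c in candidates:
        if events and c < events[-1][1]:
            continue
        if c < pos:
            continue
        # backtrack to the start of the descent (<= 2 s)
        o = c
        floor = max(0, c - int(round(2.0 * rate)))
        while o > floor and descending[o - 1]:
            o -= 1
        # find close: first sustained recovery after the spike
        j = c
        while j < len(pitch) and runlen[j] < sustain:
            j += 1
        close = min(j, len(pitch))
        events.append([o, close])
        pos = close
    # merge events separated by less than merge_gap_s
    merged = []
    gap = params.merge_gap_s * rate
    for ev in events:
        if merged and ev[0] - merged[-1][1] < gap:
            merged[-1][1] = ev[1]
        else:
            merged.append(ev)
    out = []
    for o, cl in merged:
        dur = (cl - o) / rate
        if dur < params.min_duration_s:
            continue
        start = static.start_time + pd.Timedelta(seconds=o / rate)
        e = DiveEvent(start=start, duration_s=dur)
        e._offset = o / rate
        out.append(e)
    return out


# ---------------------------------------------------------------------------
# speeds and the full pipeline
# ---------------------------------------------------------------------------

def speeds_per_second(trip: Trip) -> pd.DataFrame:
    """Ground speed (km/h) at every whole second, from interpolated fixes.

    Positions come from great-circle interpolation of the 5-min fixes, so
    the speed is piecewise constant between fixes - an acknowledged
    smoothing; only the low/high discrimination is used downstream.
    """
    pos = positions_per_second(trip)
    lat = pos["lat"].to_numpy()
    lon = pos["lon"].to_numpy()
    d = great_circle_km((lat[:-1], lon[:-1]), (lat[1:], lon[1:]))
    v = np.concatenate([d, d[-1:]]) * 3600.0
    pos["speed_kmh"] = v
    return pos


@dataclass
class ClassifyConfig:
    k: int = 7
    seed: int = 0
    n_restarts: int = 10
    cutoff_s: float = 1.0
    bands: object = None
    rules: LabelRules = field(default_factory=LabelRules)
    dive_params: DiveParams = field(default_factory=DiveParams)


def classify(trace: AccelTrace, trip: Trip,
             config: ClassifyConfig | None = None):
    """Full per-second classification of a trip's acceleration record.

    Returns ``(ethogram, dive_events)``.  The ethogram is a DataFrame
    with one row per overlapping second: ``second`` (UTC), ``label``,
    ``cluster`` and ``corrected``; dive seconds override cluster labels.
    Dive events carry interpolated locations and colony distances.
    Deterministic for a fixed seed.
    """
    config = config or ClassifyConfig()
    t0 = max(trace.start_time, trip.start)
    t1 = min(trace.start_time + pd.Timedelta(seconds=trace.duration_s), trip.end)
    if t1 <= t0:
        raise ValueError("acceleration trace and trip do not overlap in time")

    feats = frame_features(trace, config.cutoff_s, config.bands)
    seconds = trace.start_time + pd.to_timedelta(feats["second"].to_numpy(), unit="s")
    in_trip = (seconds >= trip.start) & (seconds < trip.end)
    feats = feats.loc[in_trip].reset_index(drop=True)
    seconds = seconds[in_trip]
    if len(feats) < config.k:
        raise ValueError("too few overlapping seconds to classify")

    ids, centroids = kmeans_frames(feats, k=config.k, seed=config.seed,
                                   n_restarts=config.n_restarts)

    sp = speeds_per_second(trip).set_index("timestamp")["speed_kmh"]
    speed = sp.reindex(seconds).ffill().bfill().to_numpy(float)

    mapping = label_clusters(centroids, ids, speed, config.rules)
    labels = np.array([mapping[c] for c in ids], dtype=object)
    labels, changed = correct_rest_glide(labels, speed, config.rules)

    static, dynamic = split_static_dynamic(trace, config.cutoff_s)
    dives = detect_dives(static, dynamic, config.dive_params)
    dives = [d for d in dives if trip.start <= d.start < trip.end]
    sec_offset = (seconds - trace.start_time).total_seconds().to_numpy()
    dive_mask = np.zeros(len(labels), bool)
    for d in dives:
        o = d.start_offset_s
        dive_mask |= (sec_offset + 1.0 > o) & (sec_offset < o + d.duration_s)
        la, lo = position_at(trip, d.start)
        d.lat, d.lon = la, lo
        d.dist_colony_km = great_circle_km((la, lo), trip.colony)
    labels[dive_mask] = "dive"

    ethogram = pd.DataFrame({
        "second": seconds,
        "label": labels,
        "cluster": ids,
        "corrected": changed | dive_mask,
    }).reset_index(drop=True)
    return ethogram, dives
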