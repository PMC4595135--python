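"""Synthetic GPS + tri-axial accelerometer datasets with known truth.

Emulates the biologging regime of a central-place foraging shearwater on
a short trip: 25 Hz tri-axial acceleration, one GPS fix every 5 min, and
3-hourly wind records.  The behavioural state process is a semi-Markov
chain over three macro states (resting on water, flight, surface
foraging), with flight composed of alternating flapping/gliding bouts
opened by a short take-off burst, and foraging bouts containing dives
whose durations are drawn from a truncated normal (default 9.0 +- 1.9 s,
floor 1 s).  Every second carries a truth label from
``{rest, flap, glide, takeoff, forage_surface, dive}``.

Acceleration signatures per state (axes: surge = longitudinal x,
sway = lateral, heave = dorsoventral; heave reads -1 g in level posture):

* rest - gravity plus a low-frequency (< 0.5 Hz) swell oscillation;
* flap - sinusoid at the wingbeat frequency on heave and surge;
* glide - gravity plus small noise;
* takeoff - 2-5 s very-high-amplitude burst mixing wingbeat and
  low-frequency body-lift components;
* forage_surface - irregular moderate bursts at near-zero ground speed;
* dive - an entry surge spike, pitch held nose-down at the configured
  dive pitch, and intermittent underwater flapping.

Amplitude scales are free parameters of the generator (field loggers are
not calibrated per behaviour); defaults were chosen once to look like
published accelerometry traces of small procellariiforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io_formats import AccelTrace
from .track import _destination, great_circle_km, initial_bearing

STATES = ("rest", "flap", "glide", "takeoff", "forage_surface", "dive")
MACRO_STATES = ("rest", "flight", "forage")

__all__ = ["STATES", "MACRO_STATES", "SimConfig", "LabelledDataset",
           "simulate_trip", "inject_speed_outliers"]


def _default_transition():
    # rows: from rest / flight / forage; columns in MACRO_STATES order
    return np.array([[0.0, 0.7, 0.3],
                     [0.5, 0.0, 0.5],
                     [0.4, 0.6, 0.0]])


def _default_dwells():
    return {"rest": 1200.0, "flight": 600.0, "forage": 450.0,
            "flap": 40.0, "glide": 20.0, "surface_gap": 120.0}


def _default_speeds():
    return {"rest": (0.0, 3.0), "flap": (35.0, 55.0), "glide": (25.0, 45.0),
            "takeoff": (5.0, 15.0), "forage_surface": (0.0, 4.0), "dive": (0.0, 2.0)}


@dataclass
class SimConfig:
    """Parameters of the synthetic foraging trip.

    ``state_transition`` is a stochastic matrix over the macro states
    (rest, flight, forage); ``dwell_means`` are mean bout lengths in
    seconds (gamma-distributed with shape ``dwell_shape`` for macro
    bouts); ``state_speeds`` are ground-speed ranges in km/h per
    fine-grained state.
    """

    seed: int = 0
    accel_rate: float = 25.0
    gps_interval: float = 300.0
    colony: tuple = (-37.56, 149.91)
    trip_hours: float = 16.0
    start_time: str = "2012-02-09T18:00:00+00:00"
    state_transition: np.ndarray = field(default_factory=_default_transition)
    dwell_means: dict = field(default_factory=_default_dwells)
    dwell_shape: float = 8.0
    takeoff_range_s: tuple = (2.0, 5.0)
    flap_freq: float = 6.0
    flap_amp: float = 1.0
    takeoff_amp: float = 2.5
    forage_burst_amp: float = 0.9
    swell_amp: float = 0.1
    dive_duration_mean: float = 9.0
    dive_duration_sd: float = 1.9
    dive_pitch: float = -60.0
    surge_spike_amp: float = 3.0
    underwater_flap_amp: float = 0.5
    state_speeds: dict = field(default_factory=_default_speeds)
    heading_sd: float = 3.0
    outlier_rate: float = 0.005
    outlier_km: tuple = (15.0, 30.0)
    wind_speed_mean: float = 8.0
    wind_speed_sd: float = 2.5
    wind_interval_s: float = 10800.0

    def validate(self) -> None:
        if self.trip_hours <= 0:
            raise ValueError("trip_hours must be positive")
        if self.accel_rate <= 0:
            raise ValueError("accel_rate must be positive")
        if self.dive_duration_sd < 0:
            raise ValueError("dive_duration_sd must be non-negative")
        if not (0 <= self.outlier_rate < 1):
            raise ValueError("outlier_rate must be in [0, 1)")
        m = np.asarray(self.state_transition, float)
        if m.shape != (3, 3) or (m < 0).any() or not np.allclose(m.sum(axis=1), 1.0):
            raise ValueError("state_transition must be a 3x3 stochastic matrix")

    def to_flat(self) -> dict:
        """Flat key=value representation (round-trips through text config files)."""
        flat = {
            "seed": self.seed, "accel_rate": self.accel_rate,
            "gps_interval": self.gps_interval,
            "colony_lat": self.colony[0], "colony_lon": self.colony[1],
            "trip_hours": self.trip_hours, "start_time": self.start_time,
            "dwell_shape": self.dwell_shape,
            "takeoff_min_s": self.takeoff_range_s[0], "takeoff_max_s": self.takeoff_range_s[1],
            "flap_freq": self.flap_freq, "flap_amp": self.flap_amp,
            "takeoff_amp": self.takeoff_amp, "forage_burst_amp": self.forage_burst_amp,
            "swell_amp": self.swell_amp,
            "dive_duration_mean": self.dive_duration_mean,
            "dive_duration_sd": self.dive_duration_sd,
            "dive_pitch": self.dive_pitch, "surge_spike_amp": self.surge_spike_amp,
            "underwater_flap_amp": self.underwater_flap_amp,
            "heading_sd": self.heading_sd, "outlier_rate": self.outlier_rate,
            "outlier_min_km": self.outlier_km[0], "outlier_max_km": self.outlier_km[1],
            "wind_speed_mean": self.wind_speed_mean, "wind_speed_sd": self.wind_speed_sd,
            "wind_interval_s": self.wind_interval_s,
        }
        m = np.asarray(self.state_transition, float)
        for i, a in enumerate(MACRO_STATES):
            for j, b in enumerate(MACRO_STATES):
                flat[f"trans.{a}.{b}"] = m[i, j]
        for k, v in self.dwell_means.items():
            flat[f"dwell.{k}"] = v
        for k, (lo, hi) in self.state_speeds.items():
            flat[f"speed.{k}.min"] = lo
            flat[f"speed.{k}.max"] = hi
        return flat

    @classmethod
    def from_flat(cls, flat: dict) -> "SimConfig":
        m = np.zeros((3, 3))
        for i, a in enumerate(MACRO_STATES):
            for j, b in enumerate(MACRO_STATES):
                m[i, j] = float(flat[f"trans.{a}.{b}"])
        dwells = {k.split(".", 1)[1]: float(v) for k, v in flat.items()
                  if k.startswith("dwell.")}
        speeds = {}
        for k in flat:
            if k.startswith("speed.") and k.endswith(".min"):
                st = k[len("speed."):-len(".min")]
                speeds[st] = (float(flat[f"speed.{st}.min"]), float(flat[f"speed.{st}.max"]))
        return cls(
            seed=int(flat["seed"]), accel_rate=float(flat["accel_rate"]),
            gps_interval=float(flat["gps_interval"]),
            colony=(float(flat["colony_lat"]), float(flat["colony_lon"])),
            trip_hours=float(flat["trip_hours"]), start_time=str(flat["start_time"]),
            state_transition=m, dwell_means=dwells, dwell_shape=float(flat["dwell_shape"]),
            takeoff_range_s=(float(flat["takeoff_min_s"]), float(flat["takeoff_max_s"])),
            flap_freq=float(flat["flap_freq"]), flap_amp=float(flat["flap_amp"]),
            takeoff_amp=float(flat["takeoff_amp"]),
            forage_burst_amp=float(flat["forage_burst_amp"]),
            swell_amp=float(flat["swell_amp"]),
            dive_duration_mean=float(flat["dive_duration_mean"]),
            dive_duration_sd=float(flat["dive_duration_sd"]),
            dive_pitch=float(flat["dive_pitch"]),
            surge_spike_amp=float(flat["surge_spike_amp"]),
            underwater_flap_amp=float(flat["underwater_flap_amp"]),
            state_speeds=speeds, heading_sd=float(flat["heading_sd"]),
            outlier_rate=float(flat["outlier_rate"]),
            outlier_km=(float(flat["outlier_min_km"]), float(flat["outlier_max_km"])),
            wind_speed_mean=float(flat["wind_speed_mean"]),
            wind_speed_sd=float(flat["wind_speed_sd"]),
            wind_interval_s=float(flat["wind_interval_s"]),
        )


@dataclass
class LabelledDataset:
    """A simulated trip with full ground truth."""

    accel: AccelTrace
    gps: pd.DataFrame
    truth_labels: np.ndarray          # one state label per second
    truth_dives: list                 # (start_second, duration_s) pairs
    wind: pd.DataFrame
    config: SimConfig
    truth_positions: pd.DataFrame     # per-second lat/lon actually flown
    truth_path_km: float              # integrated path length
    outlier_indices: list             # GPS fix indices displaced as outliers
    arrival_second: int | None        # second the bird regained the colony
    return_start_second: int          # second homing behaviour began


def _angdiff(a, b):
    """Signed smallest angle a-b in degrees."""
    return (a - b + 180.0) % 360.0 - 180.0


def _dwell(rng, mean, shape):
    return max(1.0, rng.gamma(shape, mean / shape))


def _truncnorm_s(rng, mean, sd, lo=1.0):
    if sd == 0:
        return max(lo, mean)
    a = (lo - mean) / sd
    return float(truncnorm.rvs(a, np.inf, loc=mean, scale=sd, random_state=rng))


def _plan_bouts(rng, config, macro, prev_macro):
    """Expand one macro bout into fine (state, seconds) bouts."""
    d = config.dwell_means
    dur = _dwell(rng, d[macro], config.dwell_shape)
    bouts = []
    if macro == "rest":
        bouts.append(["rest", int(round(dur))])
    elif macro == "flight":
        if prev_macro in ("rest", "forage", None):
            bouts.append(["takeoff", int(round(rng.uniform(*config.takeoff_range_s)))])
        t, flapping = 0.0, True
        while t < dur:
            sub = "flap" if flapping else "glide"
            b = _dwell(rng, d[sub], 3.0)
            bouts.append([sub, int(round(b))])
            t += b
            flapping = not flapping
    else:  # forage: surface gaps with embedded dives
        t = 0.0
        while t < dur:
            gap = _dwell(rng, d["surface_gap"], 2.0)
            bouts.append(["forage_surface", int(round(gap))])
            t += gap
            if t >= dur:
                break
            dd = _truncnorm_s(rng, config.dive_duration_mean, config.dive_duration_sd)
            bouts.append(["dive", max(1, int(round(dd)))])
            t += dd
    return [b for b in bouts if b[1] >= 1]


def simulate_trip(config: SimConfig) -> LabelledDataset:
    """Simulate one foraging trip; deterministic for a fixed seed.

    The bird departs the colony, drifts outward along a smoothly varying
    heading (wrapped-normal random walk biased to the outbound bearing),
    and from mid-trip homes on the colony, forcing flight when the time
    budget gets tight.  Once back within 150 m it rests at the colony for
    the remainder of the record, so the GPS track closes a complete trip.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sec = int(round(config.trip_hours * 3600))
    if n_sec < 10:
        raise ValueError("trip too short to simulate")
    trans = np.asarray(config.state_transition, float)

    labels = np.empty(n_sec, dtype=object)
    lat = np.empty(n_sec + 1)
    lon = np.empty(n_sec + 1)
    speeds = np.empty(n_sec)
    lat[0], lon[0] = config.colony
    heading = float(rng.uniform(0.0, 360.0))
    out_bearing = heading
    return_start = int(0.45 * n_sec)
    arrival = None
    path_km = 0.0

    macro = None
    pending: list = []           # fine bouts [state, seconds remaining]
    bout_speed = None

    t = 0
    while t < n_sec:
        if not pending:
            prev = macro
            if macro is None:
                macro, pending = "rest", [["rest", 60]]  # pre-departure at colony
            else:
                nxt = MACRO_STATES[rng.choice(3, p=trans[MACRO_STATES.index(macro)])]
                if t >= return_start:
                    dist = great_circle_km((lat[t], lon[t]), config.colony)
                    remaining_h = (n_sec - t) / 3600.0
                    if dist / 20.0 > 0.8 * remaining_h:
                        nxt = "flight"  # running out of time: fly home
                macro = nxt
                pending = _plan_bouts(rng, config, macro, prev)
            bout_speed = None
        state, _ = pending[0]
        lo, hi = config.state_speeds[state]
        if bout_speed is None:
            bout_speed = rng.uniform(lo, hi)
        # per-second kinematics
        v = float(np.clip(bout_speed + rng.normal(0.0, 0.3), lo, hi))
        if state in ("flap", "glide", "takeoff"):
            target = out_bearing if t < return_start else initial_bearing(
                (lat[t], lon[t]), config.colony)
            heading = heading + 0.08 * _angdiff(target, heading) + rng.normal(0, config.heading_sd)
        else:
            heading += rng.normal(0.0, 10.0)
        heading %= 360.0
        step = v / 3600.0
        lat[t + 1], lon[t + 1] = _destination(lat[t], lon[t], heading, step)
        path_km += step
        speeds[t] = v
        labels[t] = state
        pending[0][1] -= 1
        if pending[0][1] == 0:
            pending.pop(0)
            bout_speed = None
        t += 1
        # arrival check during homing
        if arrival is None and t > return_start:
            if great_circle_km((lat[t], lon[t]), config.colony) < 0.15:
                arrival = t
                labels[t:] = "rest"
                lat[t:] = config.colony[0]
                lon[t:] = config.colony[1]
                speeds[t:] = 0.0
                break

    # dive bookkeeping from the label sequence (contiguous runs)
    dives = []
    for s0, s1, st in _runs(labels):
        if st == "dive":
            dives.append((s0, float(s1 - s0)))

    start = pd.Timestamp(config.start_time)
    if start.tzinfo is None:
        start = start.tz_localize("UTC")

    accel = _synth_accel(rng, config, labels, n_sec, start)

    # GPS: sample the flown positions every gps_interval
    fix_idx = np.arange(0, n_sec + 1, int(round(config.gps_interval)))
    gps = pd.DataFrame({
        "timestamp": start + pd.to_timedelta(fix_idx, unit="s"),
        "lat": lat[fix_idx],
        "lon": lon[fix_idx],
    })
    outlier_idx: list = []
    if config.outlier_rate > 0:
        gps, outlier_idx = inject_speed_outliers(
            gps, config.outlier_rate, seed=int(rng.integers(2**31)),
            displacement_km=config.outlier_km)

    wind = _synth_wind(rng, config, start, n_sec)

    positions = pd.DataFrame({
        "timestamp": start + pd.to_timedelta(np.arange(n_sec + 1), unit="s"),
        "lat": lat, "lon": lon,
    })
    return LabelledDataset(
        accel=accel, gps=gps, truth_labels=labels, truth_dives=dives,
        wind=wind, config=replace(config), truth_positions=positions,
        truth_path_km=path_km, outlier_indices=outlier_idx,
        arrival_second=arrival, return_start_second=return_start,
    )


def _runs(labels):
    """Yield (start, stop, state) for contiguous runs of a label array."""
    n = len(labels)
    s0 = 0
    for i in range(1, n + 1):
        if i == n or labels[i] != labels[s0]:
            yield s0, i, labels[s0]
            s0 = i


def _synth_accel(rng, config, labels, n_sec, start) -> AccelTrace:
    rate = config.accel_rate
    n = int(round(n_sec * rate))
    surge = rng.normal(0.0, 0.02, n)
    sway = rng.normal(0.0, 0.02, n)
    heave = rng.normal(0.0, 0.02, n)
    pitch = np.zeros(n)

    for s0, s1, st in _runs(labels):
        a = int(round(s0 * rate))
        b = min(n, int(round(s1 * rate)))
        m = b - a
        if m <= 0:
            continue
        tt = np.arange(m) / rate
        if st == "rest":
            f = rng.uniform(0.2, 0.45)
            ph = rng.uniform(0, 2 * math.pi)
            heave[a:b] += config.swell_amp * np.sin(2 * math.pi * f * tt + ph)
            surge[a:b] += rng.normal(0.0, 0.03, m)
            heave[a:b] += rng.normal(0.0, 0.03, m)
        elif st == "glide":
            surge[a:b] += rng.normal(0.0, 0.03, m)
            heave[a:b] += rng.normal(0.0, 0.03, m)
        elif st == "flap":
            ph = rng.uniform(0, 2 * math.pi)
            carrier = np.sin(2 * math.pi * config.flap_freq * tt + ph)
            heave[a:b] += config.flap_amp * carrier + rng.normal(0.0, 0.05, m)
            surge[a:b] += 0.4 * config.flap_amp * np.sin(
                2 * math.pi * config.flap_freq * tt + ph + 1.0) + rng.normal(0.0, 0.05, m)
            sway[a:b] += rng.normal(0.0, 0.05, m)
        elif st == "takeoff":
            ph = rng.uniform(0, 2 * math.pi)
            wing = np.sin(2 * math.pi * (config.flap_freq + 1.0) * tt + ph)
            lift = np.sin(2 * math.pi * 1.2 * tt + ph / 2)
            heave[a:b] += config.takeoff_amp * wing + 0.5 * config.takeoff_amp * lift \
                + rng.normal(0.0, 0.4, m)
            surge[a:b] += 0.6 * config.takeoff_amp * wing + 0.3 * config.takeoff_amp * lift \
                + rng.normal(0.0, 0.4, m)
            sway[a:b] += rng.normal(0.0, 0.3, m)
            pitch[a:b] = 10.0
        elif st == "forage_surface":
            f = rng.uniform(1.5, 3.5)
            ph = rng.uniform(0, 2 * math.pi)
            env = _burst_envelope(rng, m, rate)
            carrier = np.sin(2 * math.pi * f * tt + ph)
            heave[a:b] += config.forage_burst_amp * env * carrier + rng.normal(0.0, 0.08, m)
            surge[a:b] += 0.55 * config.forage_burst_amp * env * np.sin(
                2 * math.pi * f * tt + ph + 0.7) + rng.normal(0.0, 0.08, m)
            sway[a:b] += rng.normal(0.0, 0.08, m)
        elif st == "dive":
            ramp = max(1, int(round(0.25 * rate)))
            p = np.full(m, config.dive_pitch)
            p[:ramp] = np.linspace(0.0, config.dive_pitch, ramp)
            tail = min(max(1, int(round(0.2 * rate))), m)
            p[-tail:] = np.linspace(config.dive_pitch, 0.0, tail)
            pitch[a:b] = p + rng.normal(0.0, 2.0, m)
            # entry surge spike inside the nose-down window
            c = min(m - 1, int(round(0.35 * rate)))
            width = max(1.0, 0.1 * rate)
            spike = config.surge_spike_amp * np.exp(-0.5 * ((np.arange(m) - c) / width) ** 2)
            env = _burst_envelope(rng, m, rate, duty=0.4)
            uw = config.underwater_flap_amp * env * np.sin(2 * math.pi * 4.0 * tt)
            surge[a:b] += spike + 0.6 * uw + rng.normal(0.0, 0.08, m)
            heave[a:b] += uw + rng.normal(0.0, 0.08, m)

    prad = np.radians(pitch + rng.normal(0.0, 1.0, n))
    static_surge = np.sin(prad)
    static_heave = -np.cos(prad)
    return AccelTrace(start_time=start, rate=rate,
                      surge=surge + static_surge,
                      sway=sway,
                      heave=heave + static_heave)


def _burst_envelope(rng, m, rate, duty=0.6):
    """0/1 envelope of irregular bursts in ~0.4 s blocks, lightly smoothed."""
    block = max(1, int(round(0.4 * rate)))
    nb = m // block + 1
    on = (rng.uniform(size=nb) < duty).astype(float)
    env = np.repeat(on, block)[:m]
    k = max(1, int(round(0.06 * rate)))
    kernel = np.ones(k) / k
    return np.convolve(env, kernel, mode="same")


def _synth_wind(rng, config, start, n_sec) -> pd.DataFrame:
    n = max(2, int(n_sec // config.wind_interval_s) + 2)
    ts = start.floor("D") + pd.to_timedelta(np.arange(n) * config.wind_interval_s, unit="s")
    speed = np.clip(rng.normal(config.wind_speed_mean, config.wind_speed_sd, n), 0.0, None)
    direction = (rng.uniform(0, 360) + np.cumsum(rng.normal(0, 20, n))) % 360.0
    return pd.DataFrame({"timestamp": ts, "speed": speed, "direction": direction})


def inject_speed_outliers(gps: pd.DataFrame, rate: float, seed: int,
                          displacement_km=(15.0, 30.0)):
    """Displace a random fraction of interior fixes to create speed outliers.

    Each selected fix is moved 15-30 km (default) on a random bearing,
    which at a 5-min fix interval implies apparent speeds far above the
    60 km/h filter threshold.  Returns ``(track, injected_indices)``;
    ``rate=0`` returns the track unchanged.
    """
    if not (0 <= rate < 1):
        raise ValueError("rate must be in [0, 1)")
    if len(gps) == 0:
        raise ValueError("empty track")
    if rate == 0 or len(gps) < 3:
        return gps.copy().reset_index(drop=True), []
    rng = np.random.default_rng(seed)
    interior = np.arange(1, len(gps) - 1)
    pick = interior[rng.uniform(size=len(interior)) < rate]
    # keep outliers isolated so each creates a clean teleport
    chosen = []
    for i in pick:
        if not chosen or i - chosen[-1] > 1:
            chosen.append(int(i))
    out = gps.copy().reset_index(drop=True)
    for i in chosen:
        d = rng.uniform(*displacement_km)
        brg = rng.uniform(0.0, 360.0)
        la, lo = _destination(out.at[i, "lat"], out.at[i, "lon"], brg, d)
        out.at[i, "lat"] = la
        out.at[i, "lon"] = lo
    return out, chosen
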