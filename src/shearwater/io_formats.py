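"""Readers and writers for the logger file dialects and derived products.

All files are delimited text (comma, UTF-8) with ISO-8601 timestamps.
Timestamps are normalised to UTC on ingest; local solar computations
convert per position downstream.  Coordinates are decimal degrees,
southern latitudes negative.

Dialects
--------
``generic``
    ``timestamp,lat,lon`` columns.
``igotu``
    Vendor-style ``Date,Time,Latitude,Longitude`` columns (separate UTC
    date and time fields), mapped onto the generic names on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger("shearwater.io")

__all__ = [
    "AccelTrace",
    "read_gps",
    "write_gps",
    "read_accel",
    "write_accel",
    "read_wind",
    "write_wind",
    "read_ethogram",
    "write_ethogram",
    "write_trip_report",
    "read_truth_labels",
    "write_truth_labels",
    "read_flat_config",
    "write_flat_config",
    "write_gpx",
]


@dataclass
class AccelTrace:
    """Tri-axial acceleration at a fixed rate.

    Axes follow the body frame: ``surge`` = longitudinal (x), ``sway`` =
    lateral, ``heave`` = dorsoventral.  Values in g.  Convention: in
    level posture heave reads -1 g (gravity), surge and sway read 0.
    """

    start_time: pd.Timestamp
    rate: float
    surge: np.ndarray
    sway: np.ndarray
    heave: np.ndarray

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        self.start_time = pd.Timestamp(self.start_time)
        if self.start_time.tzinfo is None:
            self.start_time = self.start_time.tz_localize("UTC")
        self.surge = np.asarray(self.surge, float)
        self.sway = np.asarray(self.sway, float)
        self.heave = np.asarray(self.heave, float)
        lens = {"surge": len(self.surge), "sway": len(self.sway), "heave": len(self.heave)}
        if len(set(lens.values())) != 1:
            short = min(lens, key=lens.get)
            raise ValueError(f"axis lengths differ: shortest is {short} ({lens})")
        for name in ("surge", "sway", "heave"):
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"non-finite values in {name} axis")

    def __len__(self):
        return len(self.surge)

    @property
    def duration_s(self) -> float:
        return len(self) / self.rate

    def times(self) -> pd.DatetimeIndex:
        return self.start_time + pd.to_timedelta(np.arange(len(self)) / self.rate, unit="s")


class InputFormatError(ValueError):
    """A file could not be parsed; the message names the offending line."""


_GPS_DIALECTS = {
    "generic": {"timestamp": "timestamp", "lat": "lat", "lon": "lon"},
    "igotu": {"Latitude": "lat", "Longitude": "lon"},
}


def _to_utc(series: pd.Series, path, col="timestamp") -> pd.Series:
    ts = pd.to_datetime(series, errors="coerce", utc=True, format="ISO8601")
    bad = ts.isna()
    if bad.any():
        line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
        raise InputFormatError(f"{path}: unparseable {col} on line {line}")
    return ts


def read_gps(path, dialect: str = "generic") -> pd.DataFrame:
    """Read a GPS fix table; returns columns ``timestamp, lat, lon``.

    Fixes are sorted by time and duplicate timestamps dropped (first
    kept, count logged).  Rejects NaN coordinates and unparseable rows
    with the line number; an empty file is an explicit error.
    """
    if dialect not in _GPS_DIALECTS:
        raise ValueError(f"unknown GPS dialect {dialect!r}")
    df = pd.read_csv(path)
    if len(df) == 0:
        raise InputFormatError(f"{path}: no GPS fixes in file")
    if dialect == "igotu":
        df = df.rename(columns=_GPS_DIALECTS["igotu"])
        if "Date" in df.columns and "Time" in df.columns:
            df["timestamp"] = df["Date"].astype(str) + "T" + df["Time"].astype(str)
    missing = {"timestamp", "lat", "lon"} - set(df.columns)
    if missing:
        raise InputFormatError(f"{path}: missing columns {sorted(missing)}")
    df["timestamp"] = _to_utc(df["timestamp"], path)
    for col in ("lat", "lon"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise InputFormatError(f"{path}: invalid {col} on line {line}")
        df[col] = vals
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        raise InputFormatError(f"{path}: coordinate out of range")
    df = df.sort_values("timestamp", kind="stable")
    before = len(df)
    df = df.drop_duplicates(subset="timestamp", keep="first")
    dropped = before - len(df)
    if dropped:
        logger.warning("%s: dropped %d duplicate-timestamp fixes", path, dropped)
    return df[["timestamp", "lat", "lon"]].reset_index(drop=True)


def write_gps(path, track: pd.DataFrame) -> None:
    out = track.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).dt.strftime(
        "%Y-%m-%dT%H:%M:%S.%f%z")
    out["lat"] = out["lat"].map(lambda v: f"{v:.6f}")
    out["lon"] = out["lon"].map(lambda v: f"{v:.6f}")
    out[["timestamp", "lat", "lon"]].to_csv(path, index=False)


def read_accel(path) -> AccelTrace:
    """Read a tri-axial acceleration table.

    Two layouts are accepted: a metadata header (comment lines
    ``# start_time=...`` and ``# rate_hz=...`` followed by
    ``surge,sway,heave`` columns), or a ``timestamp,surge,sway,heave``
    table from which the rate is inferred from the first two timestamps.
    """
    meta = {}
    with open(path, "r", encoding="utf-8") as fh:
        pos = 0
        for line in fh:
            if line.startswith("#"):
                pos += 1
                if "=" in line:
                    k, v = line[1:].split("=", 1)
                    meta[k.strip()] = v.strip()
            else:
                break
    df = pd.read_csv(path, skiprows=pos, float_precision="round_trip")
    if len(df) == 0:
        raise InputFormatError(f"{path}: no acceleration samples in file")
    if "timestamp" in df.columns:
        ts = _to_utc(df["timestamp"], path)
        if len(ts) < 2:
            raise InputFormatError(f"{path}: cannot infer rate from a single sample")
        dt = (ts.iloc[1] - ts.iloc[0]).total_seconds()
        if dt <= 0:
            raise InputFormatError(f"{path}: non-increasing timestamps")
        rate = 1.0 / dt
        start = ts.iloc[0]
    else:
        if "rate_hz" not in meta or "start_time" not in meta:
            raise InputFormatError(f"{path}: missing rate_hz/start_time header")
        rate = float(meta["rate_hz"])
        start = pd.Timestamp(meta["start_time"])
    for col in ("surge", "sway", "heave"):
        if col not in df.columns:
            raise InputFormatError(f"{path}: missing column {col}")
    return AccelTrace(start_time=start, rate=rate,
                      surge=df["surge"].to_numpy(float),
                      sway=df["sway"].to_numpy(float),
                      heave=df["heave"].to_numpy(float))


def write_accel(path, trace: AccelTrace) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# start_time={trace.start_time.isoformat()}\n")
        fh.write(f"# rate_hz={trace.rate!r}\n")
        fh.write("surge,sway,heave\n")
        np.savetxt(fh, np.column_stack([trace.surge, trace.sway, trace.heave]),
                   fmt="%.17g", delimiter=",")


def read_wind(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df) == 0:
        raise InputFormatError(f"{path}: no wind records in file")
    df["timestamp"] = _to_utc(df["timestamp"], path)
    if (df["speed"] < 0).any():
        raise InputFormatError(f"{path}: negative wind speed")
    df["direction"] = df["direction"].astype(float) % 360.0
    return df[["timestamp", "speed", "direction"]]


def write_wind(path, wind: pd.DataFrame) -> None:
    out = wind.copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"], utc=True).map(pd.Timestamp.isoformat)
    out.to_csv(path, index=False)


def write_ethogram(path, ethogram: pd.DataFrame) -> None:
    """One row per second: UTC second, label, cluster id, corrected flag."""
    out = ethogram.copy()
    if len(out):
        out["second"] = pd.to_datetime(out["second"], utc=True).map(pd.Timestamp.isoformat)
        out["corrected"] = out["corrected"].astype(int)
    else:
        out = pd.DataFrame(columns=["second", "label", "cluster", "corrected"])
    out[["second", "label", "cluster", "corrected"]].to_csv(path, index=False)


def read_ethogram(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if len(df):
        df["second"] = pd.to_datetime(df["second"], utc=True)
        df["corrected"] = df["corrected"].astype(bool)
    return df


def write_trip_report(path, metrics_list) -> None:
    """One CSV row per trip with the five trip parameters."""
    rows = [m.as_dict() for m in metrics_list]
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6f")


def write_truth_labels(path, labels) -> None:
    """Two-column (second-index, state) text file of simulator truth labels."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("second,state\n")
        for i, lab in enumerate(labels):
            fh.write(f"{i},{lab}\n")


def read_truth_labels(path) -> list[str]:
    df = pd.read_csv(path)
    return df["state"].astype(str).tolist()


def write_flat_config(path, flat: dict) -> None:
    """Flat ``key=value`` file (one per line)."""
    with open(path, "w", encoding="utf-8") as fh:
        for k in sorted(flat):
            fh.write(f"{k}={flat[k]}\n")


def read_flat_config(path) -> dict:
    out = {}
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise InputFormatError(f"{path}: malformed line {lineno}")
            k, v = line.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def write_gpx(path, track: pd.DataFrame, name: str = "track") -> None:
    """Minimal GPX 1.1 export of a GPS track."""
    import xml.etree.ElementTree as ET

    gpx = ET.Element("gpx", version="1.1", creator="shearwater",
                     xmlns="http://www.topografix.com/GPX/1/1")
    trk = ET.SubElement(gpx, "trk")
    ET.SubElement(trk, "name").text = name
    seg = ET.SubElement(trk, "trkseg")
    for _, row in track.iterrows():
        pt = ET.SubElement(seg, "trkpt", lat=f"{row['lat']:.6f}", lon=f"{row['lon']:.6f}")
        ET.SubElement(pt, "time").text = pd.Timestamp(row["timestamp"]).isoformat()
    ET.ElementTree(gpx).write(path, encoding="unicode", xml_declaration=True)
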