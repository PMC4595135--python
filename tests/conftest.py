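"""Shared fixtures: one default simulated trip, classified once per session."""

import numpy as np
import pandas as pd
import pytest

from shearwater.ethogram import ClassifyConfig, classify
from shearwater.simulate import SimConfig, simulate_trip
from shearwater.track import segment_trips, speed_filter


@pytest.fixture(scope="session")
def sim16():
    """Default-condition 16 h trip, fixed seed."""
    return simulate_trip(SimConfig(seed=1))


@pytest.fixture(scope="session")
def trip16(sim16):
    filtered, _ = speed_filter(sim16.gps)
    trips = [t for t in segment_trips(filtered, sim16.config.colony, 1.0)
             if t.complete]
    assert len(trips) == 1
    return trips[0]


@pytest.fixture(scope="session")
def classified16(sim16, trip16):
    """(ethogram, dive events) of the default trip at default settings."""
    return classify(sim16.accel, trip16, ClassifyConfig(seed=0))


@pytest.fixture(scope="session")
def sim2():
    """Short 2 h trip without GPS outliers, for cheap unit tests."""
    return simulate_trip(SimConfig(seed=3, trip_hours=2.0, outlier_rate=0.0))


def truth_for(eth: pd.DataFrame, ds) -> np.ndarray:
    """Simulator truth labels aligned with an ethogram's seconds."""
    idx = ((eth["second"] - ds.accel.start_time).dt.total_seconds()).astype(int)
    return ds.truth_labels[idx.to_numpy()]


def merge_forage(labels) -> np.ndarray:
    a = np.asarray(labels, dtype=object)
    return np.where((a == "forage_surface") | (a == "dive"), "forage", a)


@pytest.fixture(scope="session")
def truth_ethogram16(sim16, trip16):
    """Per-second truth-label ethogram over the default trip span."""
    sec = pd.date_range(trip16.start.ceil("s"), trip16.end.floor("s"), freq="1s")
    idx = ((sec - sim16.accel.start_time).total_seconds()).astype(int)
    return pd.DataFrame({
        "second": sec,
        "label": sim16.truth_labels[idx],
        "cluster": 0,
        "corrected": False,
    })
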