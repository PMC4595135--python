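"""Classifier components: split, pitch, wavelet frames, clustering,
cluster labelling and dive detection."""

import itertools

import numpy as np
import pandas as pd
import pytest

from shearwater.ethogram import (ClassifyConfig, DiveParams, LabelRules,
                                 classify, correct_rest_glide, cwt_spectrum,
                                 detect_dives, frame_features, kmeans_frames,
                                 label_clusters, pitch_angle,
                                 split_static_dynamic)
from shearwater.io_formats import AccelTrace
from shearwater.simulate import _runs
from shearwater.track import Trip

RATE = 25.0


def make_trace(surge, sway=None, heave=None, rate=RATE):
    n = len(surge)
    sway = np.zeros(n) if sway is None else sway
    heave = -np.ones(n) if heave is None else heave
    return AccelTrace("2012-02-10T00:00:00Z", rate, surge, sway, heave)


class TestSplit:
    def test_constant_trace_is_all_static(self):
        tr = make_trace(np.full(100, 0.3))
        static, dynamic = split_static_dynamic(tr)
        np.testing.assert_allclose(static.surge, 0.3)
        np.testing.assert_allclose(dynamic.surge, 0.0, atol=1e-12)

    def test_pure_6hz_sinusoid_passes_to_dynamic(self):
        t = np.arange(1000) / RATE
        x = np.sin(2 * np.pi * 6.0 * t)
        static, dynamic = split_static_dynamic(make_trace(x))
        core = slice(25, -25)  # away from edge effects
        resid = dynamic.surge[core] - x[core]
        # 1-s boxcar attenuates a 6 Hz tone by |sinc(6)| < 5%
        assert np.sqrt(np.mean(resid**2)) < 0.05 * np.sqrt(np.mean(x[core]**2))

    def test_reconstruction_identity_exact(self):
        rng = np.random.default_rng(0)
        tr = make_trace(rng.normal(size=500))
        static, dynamic = split_static_dynamic(tr)
        np.testing.assert_allclose(static.surge + dynamic.surge, tr.surge,
                                   atol=1e-12)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            split_static_dynamic(make_trace(np.zeros(10)))


class TestPitch:
    def test_level_posture_zero(self):
        assert pitch_angle(0.0, 0.0, -1.0) == pytest.approx(0.0)

    def test_vertical_climb_plus_90(self):
        assert pitch_angle(1.0, 0.0, 0.0) == pytest.approx(90.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError):
            pitch_angle(0.0, 0.0, 0.0)

    def test_simulated_dive_pitch_recovered(self, sim2):
        static, _ = split_static_dynamic(sim2.accel)
        pitch = pitch_angle(static.surge, static.sway, static.heave)
        vals = []
        for s, d in sim2.truth_dives:
            a = int((s + 1.5) * RATE)  # interior, past the entry ramp
            b = int((s + d - 1.0) * RATE)
            if b > a:
                vals.append(np.mean(pitch[a:b]))
        assert vals
        assert np.mean(vals) == pytest.approx(sim2.config.dive_pitch, abs=3.0)


class TestCwt:
    def test_zero_signal_zero_amplitudes(self):
        bands, amps = cwt_spectrum(np.zeros(250), RATE)
        np.testing.assert_allclose(amps, 0.0, atol=1e-12)

    @pytest.mark.parametrize("f0", [1.0, 3.0, 6.0, 10.0])
    def test_sinusoid_dominant_band_matches_dft_oracle(self, f0):
        t = np.arange(2500) / RATE
        x = np.sin(2 * np.pi * f0 * t)
        bands, amps = cwt_spectrum(x, RATE)
        dom = bands[np.argmax(amps.mean(axis=0))]
        # DFT oracle for the true peak
        freqs = np.fft.rfftfreq(len(x), 1.0 / RATE)
        peak = freqs[np.argmax(np.abs(np.fft.rfft(x)))]
        i_dom = int(np.argmin(np.abs(bands - dom)))
        i_true = int(np.argmin(np.abs(bands - peak)))
        assert abs(i_dom - i_true) <= 1

    def test_amplitude_scales_linearly(self):
        t = np.arange(500) / RATE
        x = np.sin(2 * np.pi * 4.0 * t)
        _, a1 = cwt_spectrum(x, RATE)
        _, a3 = cwt_spectrum(3.0 * x, RATE)
        np.testing.assert_allclose(a3, 3.0 * a1, rtol=1e-9)

    def test_out_of_range_bands_rejected(self):
        with pytest.raises(ValueError):
            cwt_spectrum(np.zeros(250), RATE, bands=[0.5, 20.0])


def frames_from_points(X):
    df = pd.DataFrame(X, columns=["dom_freq", "total_amp", "low_amp",
                                  "flap_amp", "static_surge", "pitch"][:X.shape[1]])
    for c in ("dom_freq", "total_amp", "low_amp", "flap_amp",
              "static_surge", "pitch"):
        if c not in df:
            df[c] = 0.0
    df.insert(0, "second", np.arange(len(df)))
    return df


class TestKmeans:
    def test_two_separated_blobs_partitioned(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, (20, 2))
        b = rng.normal(5, 0.1, (20, 2))
        ids, _ = kmeans_frames(frames_from_points(np.vstack([a, b])), k=2, seed=0)
        assert len(set(ids[:20])) == 1
        assert len(set(ids[20:])) == 1
        assert ids[0] != ids[-1]

    def test_k_equals_n_zero_wcss(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(6, 2))
        frames = frames_from_points(X)
        ids, cent = kmeans_frames(frames, k=6, seed=0)
        assert sorted(ids) == list(range(6))

    def test_matches_exhaustive_bipartition_oracle(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(10, 2))
        frames = frames_from_points(X)
        ids, _ = kmeans_frames(frames, k=2, seed=0, n_restarts=20)
        # standardise exactly as the implementation does
        cols = ["dom_freq", "total_amp", "low_amp", "flap_amp",
                "static_surge", "pitch"]
        Z = frames[cols].to_numpy(float)
        Z = (Z - Z.mean(0)) / np.where(Z.std(0) == 0, 1, Z.std(0))

        def wcss(assign):
            tot = 0.0
            for c in (0, 1):
                pts = Z[np.asarray(assign) == c]
                if len(pts):
                    tot += ((pts - pts.mean(0))**2).sum()
            return tot

        best = min(wcss([int(i in combo) for i in range(10)])
                   for r in range(1, 10)
                   for combo in itertools.combinations(range(10), r))
        assert wcss(ids) == pytest.approx(best, rel=1e-9)

    def test_degenerate_frames_rejected(self):
        frames = frames_from_points(np.zeros((10, 2)))
        with pytest.raises(ValueError, match="degenerate"):
            kmeans_frames(frames, k=2, seed=0)

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(3)
        frames = frames_from_points(rng.normal(size=(50, 2)))
        ids1, c1 = kmeans_frames(frames, k=3, seed=5)
        ids2, c2 = kmeans_frames(frames, k=3, seed=5)
        np.testing.assert_array_equal(ids1, ids2)
        pd.testing.assert_frame_equal(c1, c2)


class TestLabelRules:
    def test_all_resting_trace_maps_every_cluster_to_rest(self):
        rng = np.random.default_rng(4)
        n = 600 * int(RATE)
        t = np.arange(n) / RATE
        heave = -1.0 + 0.1 * np.sin(2 * np.pi * 0.3 * t) + rng.normal(0, 0.03, n)
        tr = make_trace(rng.normal(0, 0.03, n), rng.normal(0, 0.02, n), heave)
        feats = frame_features(tr)
        ids, cent = kmeans_frames(feats, k=3, seed=0)
        mapping = label_clusters(cent, ids, np.full(len(feats), 1.0))
        assert set(mapping.values()) == {"rest"}

    def test_speed_correction_splits_rest_and_glide(self):
        labels = np.array(["rest", "rest", "glide", "flap"], dtype=object)
        speeds = np.array([2.0, 30.0, 2.0, 50.0])
        out, changed = correct_rest_glide(labels, speeds)
        assert list(out) == ["rest", "glide", "rest", "flap"]
        assert list(changed) == [False, True, True, False]

    def test_kmeans_seed_does_not_change_final_labels(self, sim2):
        trips = _trips_for(sim2)
        e1, _ = classify(sim2.accel, trips[0], ClassifyConfig(seed=0))
        e2, _ = classify(sim2.accel, trips[0], ClassifyConfig(seed=1234))
        assert (e1["label"] == e2["label"]).mean() > 0.99


def _trips_for(ds):
    from shearwater.track import segment_trips, speed_filter
    filtered, _ = speed_filter(ds.gps)
    trips = [t for t in segment_trips(filtered, ds.config.colony, 1.0)
             if t.complete]
    assert trips
    return trips


class TestDetectDives:
    def level_flap_trace(self):
        rng = np.random.default_rng(5)
        n = 120 * int(RATE)
        t = np.arange(n) / RATE
        surge = 0.4 * np.sin(2 * np.pi * 6 * t) + rng.normal(0, 0.05, n)
        heave = -1.0 + np.sin(2 * np.pi * 6 * t) + rng.normal(0, 0.05, n)
        return make_trace(surge, None, heave)

    def test_level_flapping_yields_no_dives(self):
        static, dynamic = split_static_dynamic(self.level_flap_trace())
        assert detect_dives(static, dynamic) == []

    def test_monotone_in_spike_threshold(self, sim2):
        static, dynamic = split_static_dynamic(sim2.accel)
        counts = [len(detect_dives(static, dynamic, DiveParams(spike_g=g)))
                  for g in (0.8, 1.2, 1.5, 2.0, 3.0, 5.0)]
        assert counts == sorted(counts, reverse=True)

    def test_recovers_simulated_dives(self, sim2):
        static, dynamic = split_static_dynamic(sim2.accel)
        events = detect_dives(static, dynamic)
        truth = sim2.truth_dives
        matched = sum(1 for e in events
                      if any(s - 2 <= e.start_offset_s <= s + d for s, d in truth))
        assert matched >= 0.9 * len(truth)
        assert len(events) - matched <= 0.05 * max(1, len(events))


class TestClassify:
    def test_ethogram_partitions_trip_seconds(self, classified16):
        eth, _ = classified16
        gaps = eth["second"].diff().dropna().unique()
        assert list(gaps) == [pd.Timedelta(seconds=1)]
        assert eth["label"].isin(["rest", "flap", "glide", "takeoff",
                                  "forage_surface", "dive"]).all()

    def test_rerun_identical(self, sim2):
        trip = _trips_for(sim2)[0]
        e1, d1 = classify(sim2.accel, trip, ClassifyConfig(seed=7))
        e2, d2 = classify(sim2.accel, trip, ClassifyConfig(seed=7))
        pd.testing.assert_frame_equal(e1, e2)
        assert [x.duration_s for x in d1] == [x.duration_s for x in d2]

    def test_disjoint_times_error(self, sim2):
        fixes = sim2.gps.copy()
        fixes["timestamp"] = fixes["timestamp"] + pd.Timedelta(days=30)
        trip = Trip(fixes, sim2.config.colony)
        with pytest.raises(ValueError, match="overlap"):
            classify(sim2.accel, trip)

    def test_cluster_count_robustness(self, sim16, trip16, classified16):
        """Overall 6-way accuracy varies < 5 points across k in 4..8."""
        from conftest import truth_for

        accs = []
        for k in (4, 5, 6, 7, 8):
            if k == 7:
                eth, _ = classified16
            else:
                eth, _ = classify(sim16.accel, trip16, ClassifyConfig(seed=0, k=k))
            truth = truth_for(eth, sim16)
            accs.append((truth == eth["label"].to_numpy()).mean())
        assert max(accs) - min(accs) < 0.05
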