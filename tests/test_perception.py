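"""Matched filtering, peak detection, interaural matching, localization."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import echonav as en
from echonav.acoustics import BinauralRecording, synthesize_echoes
from echonav.perception import (
    CorrelationTrace,
    EchoPeak,
    MatchedPair,
    detect_peaks,
    localize,
    match_interaural,
    matched_filter,
    process_acquisition,
)
from tests.conftest import localization_sweep, three_reflector_scene


def _make_trace(envelope, fs=250_000.0, ear="left"):
    return CorrelationTrace(envelope=np.asarray(envelope, float),
                            emission_index=0, noise_floor=0.0,
                            sample_rate=fs, ear=ear, raw=np.zeros(len(envelope)))


class TestMatchedFilter:
    def test_echo_peak_within_one_sample_of_delay(self, run_config, chirp):
        scene = en.make_single_reflector_scene(2.0, 0.0)
        rec = synthesize_echoes(scene, (0, 0, 0), 0.0, run_config.sonar, seed=1)
        lt, _ = matched_filter(rec, chirp, run_config.detection)
        peak = int(np.argmax(lt.envelope))
        expected = 2 * 2.0 / 343.0 * 250_000
        assert abs(peak - expected) <= 1.5

    def test_all_zero_recording_rejected(self, run_config, chirp):
        rec = BinauralRecording(left=np.zeros(8750), right=np.zeros(8750),
                                sample_rate=250_000.0, pose=(0, 0, 0),
                                heading_offset_deg=0.0)
        with pytest.raises(ValueError):
            matched_filter(rec, chirp, run_config.detection)

    def test_noise_only_never_detects(self, run_config, chirp):
        # Monte-Carlo false-alarm check: pure-noise recordings produce no
        # echo peaks that survive the absolute noise-floor guard
        rng = np.random.default_rng(0)
        for _ in range(20):
            noise = rng.normal(0, 1e-3, (8750, 2))
            noise[:2500, 0] += chirp  # emission present
            noise[:2500, 1] += chirp
            rec = BinauralRecording(left=noise[:, 0], right=noise[:, 1],
                                    sample_rate=250_000.0, pose=(0, 0, 0),
                                    heading_offset_deg=0.0)
            dets = process_acquisition([rec], chirp, run_config.sonar,
                                       run_config.detection)
            assert dets == []


class TestDetectPeaks:
    def test_threshold(self, run_config):
        env = np.zeros(8750)
        env[3000] = 1.0
        env[4000] = 0.29   # below the 0.3 amplitude threshold
        env[5000] = 0.35
        peaks = detect_peaks(_make_trace(env), run_config.detection)
        assert [round(p.lag * 250_000) for p in peaks] == [3000, 5000]

    def test_min_peak_distance_keeps_larger(self, run_config):
        env = np.zeros(8750)
        env[3000] = 0.8
        env[3250] = 1.0    # 1 ms away: closer than the 2 ms minimum distance
        peaks = detect_peaks(_make_trace(env), run_config.detection)
        assert len(peaks) == 1
        assert round(peaks[0].lag * 250_000) == 3250

    def test_three_separated_echoes(self, run_config):
        env = np.zeros(8750)
        for i in (2000, 3000, 4000):   # 4 ms apart
            env[i] = 0.5
        peaks = detect_peaks(_make_trace(env), run_config.detection)
        assert len(peaks) == 3
        assert peaks[0].lag < peaks[1].lag < peaks[2].lag


class TestMatchInteraural:
    def test_identical_echo_accepted_with_r_near_one(self, run_config, chirp):
        scene = en.make_single_reflector_scene(1.5, 0.0)
        rec = synthesize_echoes(scene, (0, 0, 0), 0.0, run_config.sonar, seed=2)
        lt, rt = matched_filter(rec, chirp, run_config.detection)
        pairs = match_interaural(detect_peaks(lt, run_config.detection),
                                 detect_peaks(rt, run_config.detection),
                                 lt, rt, run_config.detection, len(chirp))
        assert len(pairs) == 1
        assert pairs[0].pearson_r > 0.97
        assert abs(pairs[0].left_peak.lag - pairs[0].right_peak.lag) < 1e-4

    def test_single_ear_echo_dropped(self, run_config, chirp):
        # conservative by design: an echo present in one ear only is no object
        scene = en.make_single_reflector_scene(1.5, 0.0)
        rec = synthesize_echoes(scene, (0, 0, 0), 0.0, run_config.sonar, seed=2)
        lt, rt = matched_filter(rec, chirp, run_config.detection)
        pairs = match_interaural(detect_peaks(lt, run_config.detection), [],
                                 lt, rt, run_config.detection, len(chirp))
        assert pairs == []

    def test_nearest_lag_candidate_chosen(self, run_config):
        fs = 250_000.0
        env = np.zeros(8750)
        env[3000] = 1.0
        lt = _make_trace(env)
        renv = np.zeros(8750)
        renv[3010] = 1.0    # 40 us away (nearest)
        renv[3150] = 1.0    # 600 us away
        rt = _make_trace(renv, ear="right")
        lp = [EchoPeak(3000 / fs, 1.0, "left")]
        rp = [EchoPeak(3010 / fs, 1.0, "right"), EchoPeak(3150 / fs, 1.0, "right")]
        pairs = match_interaural(lp, rp, lt, rt, run_config.detection, 2500)
        assert len(pairs) == 1
        assert pairs[0].right_peak.lag == pytest.approx(3010 / fs)


class TestLocalize:
    def test_equal_lags_mean_broadside(self, run_config):
        pair = MatchedPair(EchoPeak(0.01, 1.0, "left"), EchoPeak(0.01, 1.0, "right"), 0.99)
        obj = localize(pair, run_config.sonar, run_config.detection)
        assert obj.azimuth_deg == pytest.approx(0.0)
        assert obj.range_m == pytest.approx(343.0 * 0.01 / 2)

    def test_itd_at_baseline_maps_to_ninety_degrees(self, run_config):
        itd = run_config.sonar.ear_baseline / 343.0  # ~204 us
        pair = MatchedPair(EchoPeak(0.01, 1.0, "left"),
                           EchoPeak(0.01 + itd, 1.0, "right"), 0.99)
        obj = localize(pair, run_config.sonar, run_config.detection)
        assert obj.azimuth_deg == pytest.approx(90.0, abs=1e-6)

    def test_window_edge_range(self, run_config):
        # a mean lag just inside the window maps to just under 6 m...
        pair = MatchedPair(EchoPeak(0.03495, 1.0, "left"),
                           EchoPeak(0.03495, 1.0, "right"), 0.99)
        obj = localize(pair, run_config.sonar, run_config.detection)
        assert obj.range_m == pytest.approx(5.99, abs=0.01)
        # ...and anything beyond the 6 m maximum is discarded
        far = MatchedPair(EchoPeak(0.036, 1.0, "left"),
                          EchoPeak(0.036, 1.0, "right"), 0.99)
        assert localize(far, run_config.sonar, run_config.detection) is None

    def test_impossible_itd_rejected(self, run_config):
        pair = MatchedPair(EchoPeak(0.0100, 1.0, "left"),
                           EchoPeak(0.0108, 1.0, "right"), 0.99)  # 800 us ITD
        assert localize(pair, run_config.sonar, run_config.detection) is None


class TestProcessAcquisition:
    def test_three_reflectors_in_one_beam(self, run_config, chirp):
        scene = three_reflector_scene()
        rec = synthesize_echoes(scene, (0, 0, 0), 0.0, run_config.sonar, seed=5)
        dets = process_acquisition([rec], chirp, run_config.sonar,
                                   run_config.detection)
        assert len(dets) == 3
        got = sorted((d.range_m, d.azimuth_deg) for d in dets)
        for (r, az), (er, eaz) in zip(got, [(1.0, 0.0), (1.8, 5.0), (2.6, -5.0)]):
            assert r == pytest.approx(er, abs=0.02)
            assert az == pytest.approx(eaz, abs=0.5)

    def test_duplicate_across_headings_merged(self, run_config, chirp):
        scene = en.make_single_reflector_scene(1.2, 20.0)
        recs = en.acquire_three_headings(scene, (0, 0, 0), run_config.sonar, seed=6)
        dets = process_acquisition(recs, chirp, run_config.sonar,
                                   run_config.detection)
        assert len(dets) == 1
        assert dets[0].range_m == pytest.approx(1.2, abs=0.02)
        assert dets[0].azimuth_deg == pytest.approx(20.0, abs=1.0)

    def test_every_detection_is_binaural(self, run_config, chirp):
        # C is a real Pearson value above the acceptance threshold for all
        scene = three_reflector_scene()
        rec = synthesize_echoes(scene, (0, 0, 0), 0.0, run_config.sonar, seed=5)
        for d in process_acquisition([rec], chirp, run_config.sonar,
                                     run_config.detection):
            assert d.C > run_config.detection.min_pearson_r
            assert d.T == "unknown" and d.P == 0.0


class TestRoundTrip:
    @settings(max_examples=12, deadline=None, derandomize=True)
    @given(r=st.floats(0.4, 2.8), az=st.floats(-45.0, 45.0),
           seed=st.integers(0, 10_000))
    def test_single_reflector_recovery(self, r, az, seed, run_config, chirp):
        scene = en.make_single_reflector_scene(r, az)
        rec = synthesize_echoes(scene, (0, 0, 0), 0.0, run_config.sonar, seed=seed)
        dets = process_acquisition([rec], chirp, run_config.sonar,
                                   run_config.detection)
        assert len(dets) >= 1
        best = min(dets, key=lambda d: abs(d.range_m - r))
        assert abs(best.range_m - r) < 0.013      # 1.3 cm
        assert abs(best.azimuth_deg - az) < 1.2   # degrees

    def test_sweep_statistics(self, run_config):
        trials, misses = localization_sweep(run_config, n_trials=30, seed=3)
        assert misses == 0
        report = en.localization_report(trials)
        assert report["range_error_mean_cm"] <= 1.3
        assert report["azimuth_error_mean_deg"] <= 1.2
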