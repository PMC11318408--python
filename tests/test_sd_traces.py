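"""Nernst conversion, SD onset detection, feature extraction, unit helpers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sliceox import (
    FeatureConfig,
    NernstCalibration,
    OnsetConfig,
    TraceSet,
    ValidationError,
    detect_sd_onset,
    extract_sd_features,
    isoflurane_vol_percent_to_mM,
    potassium_to_voltage,
    voltage_to_potassium,
)


class TestNernst:
    def test_zero_delta_reads_baseline(self):
        k = voltage_to_potassium(np.zeros(5), NernstCalibration(), reference_mv=0.0)
        np.testing.assert_allclose(k, 3.0)

    def test_one_decade_per_slope_unit(self):
        calib = NernstCalibration()
        k = voltage_to_potassium(np.array([calib.slope]), calib, reference_mv=0.0)
        assert k[0] == pytest.approx(30.0, rel=1e-12)

    def test_voltage_round_trip_is_algebraic_inverse(self):
        calib = NernstCalibration(slope=58.0)
        rng = np.random.default_rng(5)
        v = rng.uniform(-10.0, 80.0, size=200)
        back = potassium_to_voltage(voltage_to_potassium(v, calib, reference_mv=0.0), calib)
        np.testing.assert_allclose(back, v, atol=1e-9)

    def test_output_strictly_positive(self):
        k = voltage_to_potassium(np.array([-300.0, 0.0, 300.0]), NernstCalibration(),
                                 reference_mv=0.0)
        assert np.all(k > 0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValidationError):
            voltage_to_potassium(np.array([]), NernstCalibration())


class TestOnsetDetection:
    def test_flat_trace_reports_no_sd(self):
        assert detect_sd_onset(np.zeros(1000), 10.0) is None

    def test_generator_onset_detected_within_one_second(self, noiseless_episode):
        traces, truth = noiseless_episode
        onset = detect_sd_onset(traces.dc, traces.sampling_rate)
        assert onset == pytest.approx(truth.scenario.onset, abs=1.0)

    def test_trace_without_baseline_rejected(self):
        # a recording that starts mid-event is shorter than the baseline window
        with pytest.raises(ValidationError, match="baseline"):
            detect_sd_onset(np.full(100, -10.0), 10.0, OnsetConfig(baseline_window_s=30.0))

    def test_brief_artifact_not_detected(self):
        dc = np.zeros(1000)
        dc[500:505] = -10.0  # 0.5 s deflection, below the 2-s sustain requirement
        assert detect_sd_onset(dc, 10.0) is None


class TestFeatureExtraction:
    def test_noiseless_round_trip_recovers_generator_parameters(self, noiseless_episode):
        traces, truth = noiseless_episode
        feats = extract_sd_features(traces)
        sc = truth.scenario
        dt = 1.0 / sc.sampling_rate
        assert feats is not None
        assert feats.delta_k == pytest.approx(sc.delta_k, rel=0.02)
        assert feats.t1_50 == pytest.approx(sc.t1_50, abs=dt)
        assert feats.t2_50 == pytest.approx(sc.t2_50, abs=dt)
        assert feats.dc_duration == pytest.approx(sc.dc_duration, abs=dt)
        assert feats.dc_amplitude == pytest.approx(sc.dc_amplitude, rel=0.02)
        assert feats.t1_50 <= feats.t2_50
        assert not feats.t1_50_censored and not feats.t2_50_censored

    def test_invariant_to_dc_offset_and_time_shift(self, noiseless_episode):
        traces, _ = noiseless_episode
        ref = extract_sd_features(traces)
        shifted = TraceSet(
            time=traces.time + 100.0,
            dc=traces.dc + 37.5,
            sampling_rate=traces.sampling_rate,
            po2=traces.po2,
            k_voltage=traces.k_voltage,
        )
        out = extract_sd_features(shifted)
        assert out.onset == pytest.approx(ref.onset + 100.0, abs=1e-9)
        assert out.dc_amplitude == pytest.approx(ref.dc_amplitude, abs=1e-9)
        assert out.dc_duration == pytest.approx(ref.dc_duration, abs=1e-9)
        assert out.delta_k == pytest.approx(ref.delta_k, abs=1e-9)

    @pytest.mark.parametrize("core_min,expected", [(7.5, True), (8.5, False)])
    def test_hypoxia_flag_straddles_threshold(self, core_min, expected):
        n = 1200
        t = np.arange(n) / 10.0
        dc = np.zeros(n)
        dc[600:1100] = -15.0
        k = np.full(n, 3.0)
        k[600:700] = 20.0
        core = np.full(n, 30.0)
        core[650:700] = core_min
        traces = TraceSet(time=t, dc=dc, sampling_rate=10.0, k=k,
                          po2={160.0: core, 40.0: np.full(n, 60.0)})
        feats = extract_sd_features(traces)
        assert feats.hypoxia is expected
        assert feats.min_po2[160.0] == core_min

    def test_no_sd_returns_none(self):
        n = 600
        traces = TraceSet(
            time=np.arange(n) / 10.0, dc=np.zeros(n), sampling_rate=10.0,
            k=np.full(n, 3.0), po2={160.0: np.full(n, 20.0)},
        )
        assert extract_sd_features(traces) is None

    def test_unrecovered_potassium_reported_censored(self, slice_params):
        from sliceox import SdScenarioParams, generate_sd_episode

        # decay far slower than the recording: 10% landmark never reached
        scenario = SdScenarioParams(
            t1_50=120.0, t2_50=1200.0, noise_sd_po2=0.0, noise_sd_dc=0.0,
            noise_sd_k_voltage=0.0, sampling_rate=2.0,
        )
        traces, _ = generate_sd_episode(scenario, slice_params, duration_s=300.0)
        feats = extract_sd_features(traces, config=FeatureConfig(post_window_s=200.0))
        assert feats.t2_50_censored
        assert np.isnan(feats.t2_50)

    def test_csv_round_trip(self, tmp_path, noiseless_episode):
        traces, _ = noiseless_episode
        path = tmp_path / "traces.csv"
        traces.to_csv(path)
        back = TraceSet.from_csv(path)
        assert back.sampling_rate == pytest.approx(traces.sampling_rate)
        np.testing.assert_allclose(back.dc, traces.dc)
        assert sorted(back.po2) == sorted(traces.po2)


class TestIsofluraneConversion:
    @pytest.mark.parametrize("percent,expected", [(1.0, 0.24), (3.0, 0.72), (0.0, 0.0)])
    def test_reference_conversions_at_two_decimals(self, percent, expected):
        assert isoflurane_vol_percent_to_mM(percent, decimals=2) == pytest.approx(expected)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0.0, max_value=10.0), st.floats(min_value=0.1, max_value=10.0))
    def test_conversion_strictly_proportional(self, percent, factor):
        base = isoflurane_vol_percent_to_mM(percent)
        scaled = isoflurane_vol_percent_to_mM(percent * factor)
        assert scaled == pytest.approx(base * factor, rel=1e-12, abs=1e-15)

    def test_negative_percent_rejected(self):
        with pytest.raises(ValidationError):
            isoflurane_vol_percent_to_mM(-1.0)
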