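"""CMRO2 inverse fitting: round trips, oracle agreement, series and AUC."""

import numpy as np
import pytest

from sliceox import (
    Cmro2Series,
    DepthProfile,
    FitConfig,
    SliceModelParams,
    TraceSet,
    ValidationError,
    excess_cmro2_auc,
    fit_cmro2,
    fit_cmro2_timeseries,
    generate_depth_profile,
    solve_planar_steady_state,
)


class TestFitCmro2:
    @pytest.mark.parametrize(
        "true_cmro2,depths",
        [
            (40.0, np.arange(20.0, 161.0, 20.0)),  # multi-step design
            (92.0, [40.0, 100.0, 160.0]),  # three-point design
            (34.4, [40.0, 100.0, 160.0]),
        ],
    )
    def test_noiseless_round_trip_within_tenth_percent(self, slice_params, true_cmro2, depths):
        profile, _ = generate_depth_profile(true_cmro2, slice_params, depths, noise_sd=0.0)
        fit = fit_cmro2(profile, slice_params)
        assert fit.estimate == pytest.approx(true_cmro2, rel=1e-3)
        assert fit.sse < 1e-3
        assert fit.converged and not fit.boundary_hit

    def test_multistep_shallowest_as_dirichlet_round_trip(self, slice_params):
        profile, _ = generate_depth_profile(
            50.0, slice_params, np.arange(20.0, 161.0, 20.0), noise_sd=0.0
        )
        fit = fit_cmro2(profile, use_shallowest_as_surface=True)
        assert fit.estimate == pytest.approx(50.0, rel=1e-3)

    def test_noisy_fit_matches_grid_search_oracle(self, slice_params, three_depths):
        """Brent minimum coincides with an exhaustive 0.01-resolution scan."""
        profile, _ = generate_depth_profile(
            92.0, slice_params, three_depths, noise_sd=1.0, seed=42
        )
        fit = fit_cmro2(profile, slice_params)

        def sse(m):
            f = solve_planar_steady_state(slice_params, m)
            return float(np.sum((f.sample(profile.depths) - profile.po2) ** 2))

        # two-stage exhaustive scan over [0, 500] at 0.01 resolution
        coarse = np.arange(0.0, 500.01, 0.5)
        i = int(np.argmin([sse(m) for m in coarse]))
        fine = np.arange(max(0.0, coarse[i] - 0.5), min(500.0, coarse[i] + 0.5) + 1e-9, 0.01)
        best = fine[int(np.argmin([sse(m) for m in fine]))]
        assert abs(fit.estimate - best) <= 0.01

    def test_sse_is_unimodal_in_candidate_cmro2(self, slice_params, three_depths):
        profile, _ = generate_depth_profile(34.4, slice_params, three_depths, noise_sd=0.0)

        def sse(m):
            f = solve_planar_steady_state(slice_params, m)
            return float(np.sum((f.sample(profile.depths) - profile.po2) ** 2))

        vals = np.array([sse(m) for m in np.arange(0.0, 200.0, 2.0)])
        sign_changes = np.sum(np.abs(np.diff(np.sign(np.diff(vals))))) / 2
        assert sign_changes <= 1  # one interior minimum

    def test_fitted_sd_to_baseline_ratio(self, slice_params, three_depths):
        p_lo, _ = generate_depth_profile(34.4, slice_params, three_depths, noise_sd=0.0)
        p_hi, _ = generate_depth_profile(92.0, slice_params, three_depths, noise_sd=0.0)
        ratio = fit_cmro2(p_hi, slice_params).estimate / fit_cmro2(p_lo, slice_params).estimate
        assert ratio == pytest.approx(2.674, abs=0.01)

    def test_requires_three_points(self):
        with pytest.raises(ValidationError):
            DepthProfile(depths=[40.0, 160.0], po2=[100.0, 50.0], core_depth=160.0)

    def test_three_point_fit_requires_surface_value(self, slice_params, three_depths):
        profile, _ = generate_depth_profile(34.4, slice_params, three_depths, noise_sd=0.0)
        stripped = DepthProfile(
            depths=profile.depths, po2=profile.po2, core_depth=profile.core_depth
        )
        with pytest.raises(ValidationError, match="surface_po2"):
            fit_cmro2(stripped)

    def test_csv_round_trip(self, tmp_path, slice_params, three_depths):
        profile, _ = generate_depth_profile(34.4, slice_params, three_depths, noise_sd=0.0)
        path = tmp_path / "profile.csv"
        profile.to_csv(path)
        back = DepthProfile.from_csv(path, surface_po2=150.0)
        np.testing.assert_allclose(back.po2, profile.po2)
        assert back.core_depth == profile.core_depth


class TestTimeseries:
    def test_constant_channels_give_constant_series(self, slice_params, three_depths):
        f = solve_planar_steady_state(slice_params, 34.4)
        vals = f.sample(three_depths)
        n = 200
        t = np.arange(n) / 10.0
        traces = TraceSet(
            time=t,
            dc=np.zeros(n),
            sampling_rate=10.0,
            po2={d: np.full(n, v) for d, v in zip(three_depths, vals)},
            k=np.full(n, 3.0),
        )
        series = fit_cmro2_timeseries(
            traces, FitConfig(surface_po2=150.0, baseline_window=(0.0, 5.0), stride=10)
        )
        np.testing.assert_allclose(series.estimates, 34.4, atol=0.01)
        assert series.baseline == pytest.approx(34.4, abs=0.01)

    def test_recovers_generator_peak_ratio(self, slice_params):
        from sliceox import SdScenarioParams, generate_sd_episode

        scenario = SdScenarioParams(
            noise_sd_po2=0.0, noise_sd_dc=0.0, noise_sd_k_voltage=0.0,
            sampling_rate=2.0, seed=11,
        )
        traces, _ = generate_sd_episode(scenario, slice_params, duration_s=240.0)
        series = fit_cmro2_timeseries(
            traces, FitConfig(surface_po2=150.0, baseline_window=(0.0, 55.0))
        )
        ratio = series.estimates.max() / series.baseline
        assert ratio == pytest.approx(scenario.peak_ratio, abs=0.05)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValidationError):
            TraceSet(time=np.array([]), dc=np.array([]), sampling_rate=10.0, k=np.array([]))

    def test_nonuniform_time_base_rejected(self, three_depths):
        t = np.array([0.0, 0.1, 0.25, 0.3])
        with pytest.raises(ValidationError):
            TraceSet(
                time=t, dc=np.zeros(4), sampling_rate=10.0,
                po2={d: np.zeros(4) for d in three_depths}, k=np.ones(4) * 3,
            )


class TestExcessAuc:
    def _series(self, times, estimates, baseline, onset=0.0):
        return Cmro2Series(
            times=times, estimates=estimates, baseline=baseline,
            window=(0.0, onset), onset=onset,
        )

    def test_baseline_series_has_zero_auc(self):
        t = np.arange(0.0, 301.0, 1.0)
        s = self._series(t, np.full_like(t, 34.4), 34.4)
        assert excess_cmro2_auc(s) == 0.0

    def test_rectangular_excess_area(self):
        t = np.arange(0.0, 301.0, 0.1)
        est = np.where((t >= 10.0) & (t < 70.0), 44.4, 34.4)
        s = self._series(t, est, 34.4)
        assert excess_cmro2_auc(s) == pytest.approx(600.0, rel=0.01)

    def test_auc_linear_in_excess_scaling(self, slice_params):
        t = np.arange(0.0, 361.0, 0.5)
        excess = 20.0 * np.exp(-np.maximum(t - 60.0, 0.0) / 80.0) * (t >= 60.0)
        full = self._series(t, 34.4 + excess, 34.4, onset=60.0)
        half = self._series(t, 34.4 + 0.5 * excess, 34.4, onset=60.0)
        assert excess_cmro2_auc(half) == pytest.approx(0.5 * excess_cmro2_auc(full), rel=0.01)

    def test_short_series_error_names_shortfall(self):
        t = np.arange(0.0, 100.0, 1.0)
        s = self._series(t, np.full_like(t, 40.0), 34.4)
        with pytest.raises(ValidationError, match="short"):
            excess_cmro2_auc(s, horizon=300.0)
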