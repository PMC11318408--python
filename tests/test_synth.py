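"""Synthetic-data generators: determinism, noise model, cross-module consistency."""

import numpy as np
import pytest

from sliceox import (
    SdScenarioParams,
    SliceModelParams,
    ValidationError,
    generate_depth_profile,
    generate_paired_cohort,
    generate_sd_episode,
    solve_planar_steady_state,
)
from sliceox.synth import solve_decay_constants


class TestDepthProfileGenerator:
    def test_noiseless_profile_equals_forward_solution(self, slice_params, three_depths):
        profile, truth = generate_depth_profile(34.4, slice_params, three_depths, noise_sd=0.0)
        f = solve_planar_steady_state(slice_params, 34.4)
        np.testing.assert_allclose(profile.po2, f.sample(three_depths), atol=1e-12)
        np.testing.assert_allclose(profile.po2, truth["clean_po2"], atol=1e-12)

    def test_identical_seeds_identical_profiles(self, slice_params, three_depths):
        a, _ = generate_depth_profile(34.4, slice_params, three_depths, noise_sd=1.0, seed=3)
        b, _ = generate_depth_profile(34.4, slice_params, three_depths, noise_sd=1.0, seed=3)
        np.testing.assert_array_equal(a.po2, b.po2)

    def test_empirical_noise_sd_matches_nominal(self, slice_params, three_depths):
        """Monte-Carlo check of the Gaussian noise model: residual SD = 1 +- 0.1."""
        clean = solve_planar_steady_state(slice_params, 34.4).sample(three_depths)
        residuals = []
        for rep in range(1000):
            p, _ = generate_depth_profile(
                34.4, slice_params, three_depths, noise_sd=1.0, seed=rep
            )
            residuals.append(p.po2 - clean)
        sd = float(np.std(np.concatenate(residuals)))
        assert sd == pytest.approx(1.0, abs=0.1)

    def test_depth_outside_domain_rejected(self, slice_params):
        with pytest.raises(ValidationError):
            generate_depth_profile(34.4, slice_params, [40.0, 100.0, 200.0])


class TestDecayConstants:
    def test_landmarks_reproduced_exactly(self):
        tau, beta = solve_decay_constants(20.0, 65.0)
        assert np.exp(-((20.0 / tau) ** beta)) == pytest.approx(0.5, abs=1e-12)
        assert np.exp(-((65.0 / tau) ** beta)) == pytest.approx(0.1, abs=1e-12)

    @pytest.mark.parametrize("t1,t2", [(20.0, 65.0), (38.3, 235.7), (5.0, 400.0)])
    def test_family_covers_fast_and_slow_tails(self, t1, t2):
        tau, beta = solve_decay_constants(t1, t2)
        assert tau > 0 and beta > 0

    def test_inverted_landmarks_rejected(self):
        with pytest.raises(ValidationError, match="t2_50 must exceed t1_50"):
            solve_decay_constants(65.0, 20.0)


class TestEpisodeGenerator:
    def test_quasi_steady_po2_respects_slice_model_exactly(self, noiseless_episode,
                                                           slice_params):
        """At zero noise every time sample solves the planar forward model."""
        traces, truth = noiseless_episode
        for i in (0, 700, 1200, 4000):  # baseline, rise, peak-decay, late recovery
            f = solve_planar_steady_state(slice_params, float(truth.cmro2_t[i]))
            expected = f.sample(np.array(sorted(traces.po2)))
            observed = np.array([traces.po2[d][i] for d in sorted(traces.po2)])
            np.testing.assert_allclose(observed, expected, atol=1e-6)

    def test_cmro2_waveform_peak_ratio(self, noiseless_episode):
        _, truth = noiseless_episode
        # sampled maximum sits within one time step of the continuous peak
        ratio = truth.cmro2_t.max() / truth.scenario.baseline_cmro2
        assert ratio == pytest.approx(truth.scenario.peak_ratio, abs=1e-3)

    def test_fixed_seed_reproducibility(self, slice_params):
        sc = SdScenarioParams(seed=9, sampling_rate=2.0)
        a, _ = generate_sd_episode(sc, slice_params, duration_s=120.0)
        b, _ = generate_sd_episode(sc, slice_params, duration_s=120.0)
        np.testing.assert_array_equal(a.dc, b.dc)
        np.testing.assert_array_equal(a.k_voltage, b.k_voltage)
        for d in a.po2:
            np.testing.assert_array_equal(a.po2[d], b.po2[d])

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValidationError):
            SdScenarioParams(t1_50=65.0, t2_50=20.0)
        with pytest.raises(ValidationError):
            SdScenarioParams(peak_ratio=0.5)


class TestPairedCohort:
    def test_requested_pair_count(self):
        df, truth = generate_paired_cohort(
            SdScenarioParams(), SdScenarioParams(delta_k=16.5), n_slices=13, seed=1
        )
        assert len(df) == 26
        assert set(df["condition"]) == {"control", "treated"}
        assert df.groupby("condition").size().eq(13).all()

    def test_slice_effects_shared_within_pairs(self):
        # with no episode-level noise, paired log-differences are exactly the
        # scenario contrast (slice effect cancels)
        control = SdScenarioParams()
        treated = SdScenarioParams(delta_k=16.5)
        df, _ = generate_paired_cohort(
            control, treated, n_slices=8, seed=2, episode_effect_sd=0.0
        )
        piv = df.pivot(index="slice_id", columns="condition", values="delta_k")
        ratios = piv["treated"] / piv["control"]
        np.testing.assert_allclose(ratios, 16.5 / 22.6, rtol=1e-12)

    def test_zero_slices_rejected(self):
        with pytest.raises(ValidationError):
            generate_paired_cohort(SdScenarioParams(), SdScenarioParams(), n_slices=0)

    def test_synthesized_cohort_measures_features(self, slice_params):
        sc = SdScenarioParams(sampling_rate=2.0, noise_sd_po2=0.5)
        df, _ = generate_paired_cohort(
            sc, sc, n_slices=2, seed=4, synthesize=True,
            slice_params=slice_params, duration_s=240.0,
        )
        assert len(df) == 4
        assert df["delta_k"].between(5.0, 80.0).all()

    def test_null_effect_type_one_error_calibrated(self):
        """Wilcoxon on null cohorts rejects at ~alpha (exact-test size at n=13
        is 0.048, so the rate sits just under 0.05)."""
        from sliceox import wilcoxon_signed_rank

        sc = SdScenarioParams()
        rejections = 0
        n_cohorts = 500
        for rep in range(n_cohorts):
            df, _ = generate_paired_cohort(sc, sc, n_slices=13, seed=10_000 + rep)
            piv = df.pivot(index="slice_id", columns="condition", values="delta_k")
            p = wilcoxon_signed_rank((piv["treated"] - piv["control"]).to_numpy()).p_raw
            rejections += p <= 0.05
        rate = rejections / n_cohorts
        se = np.sqrt(0.05 * 0.95 / n_cohorts)
        assert abs(rate - 0.05) < 2 * se + 0.01

    def test_power_against_reduced_potassium_stable_across_seeds(self):
        """Detection rate of a 22.6 -> 16.5 mM contrast at n=13 is seed-stable."""
        from sliceox import wilcoxon_signed_rank

        control = SdScenarioParams()
        treated = SdScenarioParams(delta_k=16.5)
        rates = []
        for seed0 in (1, 2):
            rej = 0
            n_cohorts = 200
            for rep in range(n_cohorts):
                df, _ = generate_paired_cohort(
                    control, treated, n_slices=13, seed=seed0 * 100_000 + rep,
                    slice_effect_sd=0.45, episode_effect_sd=0.15,
                )
                piv = df.pivot(index="slice_id", columns="condition", values="delta_k")
                p = wilcoxon_signed_rank((piv["treated"] - piv["control"]).to_numpy()).p_raw
                rej += p <= 0.05
            rates.append(rej / n_cohorts)
        assert abs(rates[0] - rates[1]) < 0.12
        assert min(rates) > 0.05  # the contrast is detectable above chance
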