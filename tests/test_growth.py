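import numpy as np
import pytest

from lacmem import (
    AgeGrowthModel,
    AgeSample,
    GrowthTrace,
    LagRecoveryModel,
    SynthesisConfig,
    bin_and_average,
    fit_lag_recovery,
    gen_age_sample,
    gen_speed_trace,
    growth_rate_from_ages,
)
from lacmem.growth import _grid_search_lag, lag_recovery_profile


class TestBinAndAverage:
    def test_constant_trace_gives_unit_means_and_zero_sem(self):
        t = np.arange(0.0, 50.0)
        trace = GrowthTrace(t, np.ones((5, len(t))))
        binned = bin_and_average(trace, 5.0)
        np.testing.assert_allclose(binned.mean, 1.0)
        np.testing.assert_allclose(binned.sem, 0.0, atol=1e-12)

    def test_sem_matches_closed_form_for_chamber_offsets(self):
        t = np.arange(0.0, 20.0)
        offsets = np.array([0.9, 0.95, 1.0, 1.05, 1.1])
        trace = GrowthTrace(t, np.tile(offsets[:, None], (1, len(t))))
        binned = bin_and_average(trace, 5.0)
        expected = np.std(offsets, ddof=1) / np.sqrt(5)
        np.testing.assert_allclose(binned.sem, expected, rtol=1e-12)
        np.testing.assert_allclose(binned.mean, offsets.mean(), rtol=1e-12)

    def test_window_spanning_everything_yields_global_mean(self):
        t = np.arange(0.0, 30.0)
        rng = np.random.default_rng(0)
        sp = rng.uniform(0.5, 1.5, size=(3, len(t)))
        binned = bin_and_average(GrowthTrace(t, sp), 1000.0)
        assert len(binned.times) == 1
        assert binned.mean[0] == pytest.approx(sp.mean())

    def test_idempotent_at_existing_bin_width(self):
        t = np.arange(0.0, 100.0)
        rng = np.random.default_rng(1)
        trace = GrowthTrace(t, rng.normal(1.0, 0.1, size=(5, len(t))))
        once = bin_and_average(trace, 5.0)
        again = bin_and_average(
            GrowthTrace(once.times, once.chamber_means, bin_width=5.0), 5.0
        )
        np.testing.assert_allclose(again.mean, once.mean, rtol=1e-12)

    def test_empty_bins_marked_missing_not_zero(self):
        t = np.concatenate([np.arange(0.0, 10.0), np.arange(20.0, 30.0)])
        trace = GrowthTrace(t, np.ones((2, len(t))))
        binned = bin_and_average(trace, 5.0)
        assert np.isnan(binned.mean[2]) and np.isnan(binned.mean[3])

    def test_window_below_native_sampling_rejected(self):
        trace = GrowthTrace(np.arange(0.0, 10.0, 2.0), np.ones((1, 5)))
        with pytest.raises(ValueError):
            bin_and_average(trace, 1.0)


class TestLagRecoveryFit:
    def test_noiseless_planted_lag_recovered_exactly(self):
        """35-min lag / 55-min total structure returns exactly from its own
        noiseless profile."""
        cfg = SynthesisConfig(seed=0, noise_sd=0.0, duration=300.0)
        fit = fit_lag_recovery(gen_speed_trace(60.0, 35.0, 55.0, cfg), 60.0)
        assert fit.lag_duration == pytest.approx(35.0, abs=1e-6)
        assert fit.total_lag_recovery == pytest.approx(55.0, abs=1e-6)
        assert fit.plateau_level == pytest.approx(1.0, abs=1e-9)
        assert not fit.no_dip

    def test_time_translation_and_plateau_scale_equivariance(self):
        cfg = SynthesisConfig(seed=3, noise_sd=0.05, duration=300.0)
        base = fit_lag_recovery(gen_speed_trace(60.0, 30.0, 50.0, cfg), 60.0)
        trace = gen_speed_trace(60.0, 30.0, 50.0, cfg)
        shifted = GrowthTrace(trace.times + 37.0, trace.speeds * 2.5)
        moved = fit_lag_recovery(shifted, 97.0)
        assert moved.lag_duration == pytest.approx(base.lag_duration, abs=1e-6)
        assert moved.total_lag_recovery == pytest.approx(
            base.total_lag_recovery, abs=1e-6
        )
        assert moved.plateau_level == pytest.approx(
            2.5 * base.plateau_level, rel=1e-9
        )

    def test_flat_trace_flagged_as_no_dip(self):
        t = np.arange(0.0, 200.0)
        fit = fit_lag_recovery(GrowthTrace(t, np.ones((5, len(t)))), 60.0)
        assert fit.no_dip
        assert fit.lag_duration == 0.0 and fit.total_lag_recovery == 0.0

    def test_refined_fit_at_least_as_good_as_grid_oracle(self):
        """Joint optimizer must beat (or match) brute-force grid search."""
        cfg = SynthesisConfig(seed=11, noise_sd=0.1, duration=300.0)
        trace = gen_speed_trace(60.0, 35.0, 55.0, cfg)
        binned = bin_and_average(trace, 5.0)
        t, y = binned.times, binned.mean
        step = 2.5
        _, _, _, sse_grid = _grid_search_lag(
            t, y, 60.0, np.arange(0, 150, step), np.arange(step, 240, step)
        )
        fit = fit_lag_recovery(binned, 60.0)
        assert fit.sse <= sse_grid + 1e-9
        assert fit.lag_duration == pytest.approx(35.0, abs=step)

    def test_noisy_replicates_cover_planted_truth(self):
        """Over seeded replicates the 2-SE interval of the regressed lag
        contains the planted value at close to the nominal rate."""
        hits, n = 0, 120
        for seed in range(n):
            cfg = SynthesisConfig(seed=seed, noise_sd=0.1, duration=300.0)
            binned = bin_and_average(gen_speed_trace(60.0, 35.0, 55.0, cfg), 5.0)
            fit = fit_lag_recovery(binned, 60.0)
            se = fit.standard_errors.get("lag_duration", np.nan)
            if np.isfinite(se) and abs(fit.lag_duration - 35.0) <= 2 * se:
                hits += 1
        assert 0.88 <= hits / n <= 1.0

    def test_model_front_end(self):
        cfg = SynthesisConfig(seed=0, noise_sd=0.0, duration=200.0)
        trace = gen_speed_trace(50.0, 20.0, 40.0, cfg)
        fit = LagRecoveryModel(trace, 50.0).fit()
        assert "lag_duration" in fit.summary()

    def test_trace_must_span_switch(self):
        t = np.arange(100.0, 200.0)
        trace = GrowthTrace(t, np.ones((1, len(t))))
        with pytest.raises(ValueError):
            fit_lag_recovery(trace, 50.0)


class TestAgeGrowthRate:
    def test_zero_age_fraction_zero_growth(self):
        sample = AgeSample(np.arange(3.0), [np.array([10.0, 20.0])] * 3, 1.0)
        fit = growth_rate_from_ages(sample)
        assert fit.growth_rate == 0.0
        assert np.isinf(fit.generation_time) and fit.zero_growth

    def test_recovers_planted_generation_time(self):
        """Mean over seeds matches the 64.7-min planted doubling time (the
        estimator's O(lambda*dt) discretization bias is under 1%)."""
        gens = []
        for seed in range(25):
            cfg = SynthesisConfig(seed=seed, duration=200.0, frame_interval=1.0,
                                  n_chambers=5)
            sample = gen_age_sample(64.7, cfg, cells_per_frame=50)
            gens.append(growth_rate_from_ages(sample, n_bootstrap=10).generation_time)
        assert np.mean(gens) == pytest.approx(64.7, rel=0.015)

    def test_estimate_stable_under_frame_rebinning(self):
        cfg = SynthesisConfig(seed=5, duration=400.0, frame_interval=1.0)
        sample = gen_age_sample(60.0, cfg, cells_per_frame=100)
        fine = growth_rate_from_ages(sample, n_bootstrap=50, seed=1)
        coarse = growth_rate_from_ages(
            AgeSample(sample.frame_times, sample.ages, dt=2.0),
            n_bootstrap=50,
            seed=1,
        )
        tol = 3 * np.hypot(fine.se_growth_rate, coarse.se_growth_rate)
        # rebinning doubles the age-zero window; first-order bias only
        assert abs(coarse.growth_rate - fine.growth_rate) < max(
            tol, 0.02 * fine.growth_rate
        )

    def test_model_front_end_summary(self):
        cfg = SynthesisConfig(seed=2, duration=50.0)
        fit = AgeGrowthModel(gen_age_sample(60.0, cfg)).fit(n_bootstrap=20)
        assert "generation time" in fit.summary()


def test_lag_profile_shape():
    t = np.array([-10.0, 0.0, 5.0, 10.0, 15.0, 20.0, 30.0])
    y = lag_recovery_profile(t, 0.0, 10.0, 20.0, 2.0)
    np.testing.assert_allclose(y, [2.0, 0.0, 0.0, 0.0, 1.0, 2.0, 2.0])
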