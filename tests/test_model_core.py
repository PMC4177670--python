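import numpy as np
import pytest

from lacmem import (
    BASE,
    GLUCOSE,
    LACTOSE,
    MEMORY,
    EnvironmentSchedule,
    IntegrationError,
    LacOperonModel,
    VariantConfig,
    derivatives,
    periodic_equilibrium,
    simulate,
    steady_state,
)
from lacmem.validate import measure_crossing_half_life, measure_decay_half_life

UNIT_SCALE = VariantConfig(response_memory=True,
                           glucose_phase_allolactose_turnover_scale=1.0)


class TestDerivatives:
    def test_zero_state_in_glucose_has_only_basal_mrna_inflow(self, params):
        sched = EnvironmentSchedule.constant(GLUCOSE, 100.0)
        d = derivatives(np.zeros(4), 0.0, params, sched)
        assert d[0] == 0.0 and d[1] == 0.0  # no substrate, no transport
        assert d[2] == pytest.approx(
            params.basal_fraction * params.mrna_transcription_rate
        )
        assert d[3] == 0.0  # no mRNA yet, no protein production

    def test_vanish_at_induced_fixed_point(self, params, lactose_ss):
        sched = EnvironmentSchedule.constant(LACTOSE, 100.0)
        d = derivatives(lactose_ss, 50.0, params, sched)
        scale = np.abs(lactose_ss) + 1.0
        assert np.max(np.abs(d) / scale) < 1e-8
        assert lactose_ss[3] == pytest.approx(34286.0, rel=0.01)

    def test_unit_scale_memory_variant_is_base_model(self, params):
        rng = np.random.default_rng(7)
        sched = EnvironmentSchedule.alternating(60.0, 1, first_phase=GLUCOSE)
        for _ in range(5):
            y = rng.uniform(0, 1e4, size=4)
            d_base = derivatives(y, 30.0, params, sched, BASE)
            d_unit = derivatives(y, 30.0, params, sched, UNIT_SCALE)
            np.testing.assert_array_equal(d_base, d_unit)

    def test_rejects_negative_state_and_out_of_horizon_time(self, params):
        sched = EnvironmentSchedule.constant(GLUCOSE, 10.0)
        with pytest.raises(ValueError):
            derivatives(np.array([-1.0, 0, 0, 0]), 0.0, params, sched)
        with pytest.raises(ValueError):
            derivatives(np.zeros(4), 11.0, params, sched)

    def test_variant_scale_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            VariantConfig(response_memory=True,
                          glucose_phase_allolactose_turnover_scale=1.5)


class TestSteadyStates:
    def test_constant_glucose_fixed_point_is_basal_level(self, params, glucose_ss):
        assert glucose_ss[3] == pytest.approx(params.basal_bgal_level, rel=1e-6)
        assert glucose_ss[0] == 0.0 and glucose_ss[1] == 0.0

    def test_constant_lactose_fixed_point_is_induced_level(self, params, lactose_ss):
        assert lactose_ss[3] == pytest.approx(params.induced_bgal_level, rel=0.01)

    def test_long_integration_agrees_with_root_finding(self, params, lactose_ss):
        """Independent check of the 0.1% integration/root agreement."""
        sched = EnvironmentSchedule.constant(LACTOSE, 3000.0)
        traj = simulate(params, sched, output_step=50.0)
        np.testing.assert_allclose(traj.states[-1], lactose_ss, rtol=1e-3)

    def test_no_production_gives_all_zero_fixed_point(self, params):
        dead = params.with_(mrna_transcription_rate=0.0, basal_bgal_level=0.0)
        ss = steady_state(dead, GLUCOSE)
        np.testing.assert_allclose(ss, 0.0, atol=1e-6)

    def test_unknown_environment_rejected(self, params):
        with pytest.raises(ValueError):
            steady_state(params, "maltose")


class TestSimulate:
    def test_protein_decays_toward_basal_with_generation_time_half_life(
        self, params
    ):
        half_life = measure_decay_half_life(params)
        assert half_life == pytest.approx(params.generation_time, rel=0.01)

    def test_direct_crossing_includes_short_mrna_transient(self, params):
        """The raw half-crossing sits slightly above the dilution half-life
        while residual mRNA clears."""
        crossing = measure_crossing_half_life(params)
        assert params.generation_time < crossing < 1.05 * params.generation_time

    def test_output_step_changes_sampling_not_solution(self, params, lactose_ss):
        sched = EnvironmentSchedule.alternating(45.0, 1)
        fine = simulate(params, sched, init=lactose_ss, output_step=1.0)
        coarse = simulate(params, sched, init=lactose_ss, output_step=3.0)
        idx = np.searchsorted(fine.times, coarse.times)
        np.testing.assert_allclose(
            fine.states[idx], coarse.states, rtol=1e-6, atol=1e-8
        )

    def test_trajectories_stay_non_negative(self, params, lactose_ss):
        sched = EnvironmentSchedule.alternating(20.0, 4, first_phase=GLUCOSE)
        for variant in (BASE, MEMORY):
            traj = simulate(params, sched, variant, init=lactose_ss)
            assert np.min(traj.states) >= 0.0

    @pytest.mark.parametrize(
        "scales",
        [
            {"permease_import_turnover": 0.3},
            {"bgal_lactose_turnover": 3.0},
            {"bgal_allolactose_turnover": 0.5},
            {"mrna_degradation_rate": 2.0},
        ],
    )
    def test_non_negativity_robust_to_rate_perturbations(self, params, scales):
        pert = params.with_(
            **{k: getattr(params, k) * v for k, v in scales.items()}
        )
        sched = EnvironmentSchedule.alternating(30.0, 2)
        traj = simulate(pert, sched, MEMORY)
        assert np.min(traj.states) >= 0.0

    def test_invalid_output_step_rejected(self, params):
        sched = EnvironmentSchedule.constant(GLUCOSE, 10.0)
        with pytest.raises(ValueError):
            simulate(params, sched, output_step=0.0)

    def test_environment_labels_follow_schedule(self, params):
        sched = EnvironmentSchedule.alternating(10.0, 1, first_phase=LACTOSE)
        traj = simulate(params, sched, output_step=5.0)
        assert list(traj.environment_labels) == [
            LACTOSE, LACTOSE, GLUCOSE, GLUCOSE, GLUCOSE
        ]


class TestPeriodicEquilibrium:
    def test_cycle_map_fixed_point(self, params):
        eq = periodic_equilibrium(params, 45.0, MEMORY)
        from lacmem.model import _propagate_cycle

        y0 = eq.cycle.states[0]
        y1, _, _ = _propagate_cycle(params, MEMORY, y0, 45.0, LACTOSE,
                                    1e-8, 1e-14)
        assert np.max(np.abs(y1 - y0) / (np.abs(y0) + 1e-9)) < 1e-5

    def test_limit_cycle_independent_of_initial_state(self, params, lactose_ss):
        eq_a = periodic_equilibrium(params, 60.0, BASE)
        eq_b = periodic_equilibrium(params, 60.0, BASE, init=lactose_ss)
        assert eq_a.Bmin == pytest.approx(eq_b.Bmin, rel=1e-4)
        assert eq_a.Bmax_cycle == pytest.approx(eq_b.Bmax_cycle, rel=1e-4)

    def test_long_period_limit_reaches_both_constant_steady_states(
        self, params, glucose_ss, lactose_ss
    ):
        eq = periodic_equilibrium(params, 24 * 60.0, BASE)
        assert eq.Bmin == pytest.approx(glucose_ss[3], rel=1e-3)
        assert eq.Bmax_cycle == pytest.approx(lactose_ss[3], rel=1e-3)

    def test_residual_protein_at_90_minute_duration(self, params):
        """Sub-generation-scale cycling leaves cells far above basal level."""
        eq = periodic_equilibrium(params, 90.0, BASE)
        assert eq.Bmin > 10 * params.basal_bgal_level
        assert eq.Bmin < eq.Bmax_cycle

    def test_non_convergence_reports_discrepancy(self, params):
        with pytest.raises(IntegrationError, match="relative change"):
            periodic_equilibrium(params, 10.0, BASE, max_cycles=2)


def test_model_object_mirrors_functional_api(params):
    model = LacOperonModel(params, MEMORY)
    ss = model.steady_state(GLUCOSE)
    np.testing.assert_allclose(ss[3], params.basal_bgal_level, rtol=1e-6)
    sched = EnvironmentSchedule.alternating(30.0, 1)
    traj = model.simulate(sched, output_step=10.0)
    assert len(traj.times) == 7
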