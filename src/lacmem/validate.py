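"""Self-validation suite: model fixed points, half-life, and estimator
round-trips on planted synthetic truths."""

from __future__ import annotations

import numpy as np

from .environment import GLUCOSE, LACTOSE, EnvironmentSchedule
from .expression import fit_decay, fit_induction, phase_delay
from .growth import bin_and_average, fit_lag_recovery, growth_rate_from_ages
from .model import BASE, MEMORY, simulate, steady_state
from .params import ModelParameters
from .synth import (
    SynthesisConfig,
    gen_age_sample,
    gen_decay_trace,
    gen_induction_trace,
    gen_periodic_reporter_trace,
    gen_speed_trace,
)


def measure_decay_half_life(
    params: ModelParameters,
    window: tuple[float, float] = (60.0, 360.0),
    horizon: float = 600.0,
) -> float:
    """Half-life of the above-basal protein excess after a switch from the
    induced state to glucose, from a log-linear fit of B(t) - B0 over the
    post-transient window (the paper-style exponential-decay measurement)."""
    init = steady_state(params, LACTOSE)
    traj = simulate(
        params,
        EnvironmentSchedule.constant(GLUCOSE, horizon),
        init=init,
        output_step=1.0,
    )
    excess = traj.protein - params.basal_bgal_level
    m = (traj.times >= window[0]) & (traj.times <= window[1]) & (excess > 0)
    slope = np.polyfit(traj.times[m], np.log(excess[m]), 1)[0]
    return float(np.log(2.0) / -slope)


def measure_crossing_half_life(params: ModelParameters, horizon: float = 300.0) -> float:
    """First time at which B - B0 falls to half its initial excess (includes
    the short mRNA-clearance transient)."""
    init = steady_state(params, LACTOSE)
    traj = simulate(
        params,
        EnvironmentSchedule.constant(GLUCOSE, horizon),
        init=init,
        output_step=0.25,
    )
    excess = traj.protein - params.basal_bgal_level
    half = 0.5 * excess[0]
    i = int(np.argmax(excess <= half))
    # linear interpolation across the crossing sample
    t1, t0 = traj.times[i], traj.times[i - 1]
    e1, e0 = excess[i], excess[i - 1]
    return float(t0 + (e0 - half) / (e0 - e1) * (t1 - t0))


def run_validation(seed: int = 0) -> dict:
    """Run the check table; returns {checks: {...}, all_passed: bool}."""
    params = ModelParameters()
    checks: dict = {}

    def add(name, value, target, rtol):
        ok = abs(value - target) <= rtol * abs(target)
        checks[name] = {
            "passed": bool(ok),
            "detail": f"value {value:.6g} vs target {target:.6g}, rtol {rtol}",
        }

    b_glc = steady_state(params, GLUCOSE)[3]
    b_lac = steady_state(params, LACTOSE)[3]
    add("basal_steady_state_nM", b_glc, params.basal_bgal_level, 0.01)
    add("induced_steady_state_nM", b_lac, params.induced_bgal_level, 0.01)
    add("decay_half_life_min", measure_decay_half_life(params),
        params.generation_time, 0.01)

    # base-model equivalence of the unit-scale memory variant
    from .model import VariantConfig

    sched = EnvironmentSchedule.alternating(45.0, 2)
    unit = VariantConfig(response_memory=True,
                         glucose_phase_allolactose_turnover_scale=1.0)
    t_base = simulate(params, sched, BASE, output_step=5.0)
    t_unit = simulate(params, sched, unit, output_step=5.0)
    dev = float(np.max(np.abs(t_base.states - t_unit.states)))
    checks["unit_scale_variant_equivalence"] = {
        "passed": dev < 1e-6 * float(np.max(t_base.states)),
        "detail": f"max state deviation {dev:.3g} nM",
    }

    # noiseless estimator round trips on planted truths
    cfg0 = SynthesisConfig(seed=seed, noise_sd=0.0, duration=300.0)
    lag_fit = fit_lag_recovery(gen_speed_trace(60.0, 35.0, 55.0, cfg0), 60.0)
    add("lag_round_trip_min", lag_fit.lag_duration, 35.0, 0.01)
    add("total_lag_recovery_round_trip_min", lag_fit.total_lag_recovery, 55.0, 0.01)

    ind = fit_induction(gen_induction_trace(25.0, 21.0, cfg0), 0.0)
    add("induction_onset_round_trip_min", ind.onset_lag, 25.0, 0.01)
    add("induction_half_rise_round_trip_min", ind.half_life, 21.0, 0.01)

    dec = fit_decay(gen_decay_trace(60.0, cfg0), 0.0)
    add("decay_fit_round_trip_min", dec.half_life, 60.0, 0.01)

    trace, sched90 = gen_periodic_reporter_trace(90.0, 13.8, 5, cfg0)
    add("phase_delay_round_trip_min",
        phase_delay(trace, sched90, 5).delay, 13.8, 0.05)

    cfg_age = SynthesisConfig(seed=seed, noise_sd=0.0, duration=200.0,
                              frame_interval=1.0, n_chambers=5)
    age = growth_rate_from_ages(gen_age_sample(64.7, cfg_age), seed=seed)
    add("age_generation_time_min", age.generation_time, 64.7, 0.05)

    return {"checks": checks, "all_passed": all(c["passed"] for c in checks.values()),
            "seed": seed}
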