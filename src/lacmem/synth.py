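"""Seeded synthetic-data generators with the structure the estimators assume.

Each generator is a pure function of (planted truth, config): the same seed
and configuration reproduce identical output, with a single explicit RNG
stream per call and no global state.  Noise is additive i.i.d. Gaussian and
may go negative; downstream estimators must tolerate that (no clipping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .environment import LACTOSE, EnvironmentSchedule
from .expression import FluorescenceTrace
from .growth import AgeSample, GrowthTrace, lag_recovery_profile


@dataclass(frozen=True)
class SynthesisConfig:
    """Common knobs for the generators (minutes / dimensionless)."""

    seed: int = 0
    noise_sd: float = 0.0  # on the signal's natural scale
    n_chambers: int = 5
    frame_interval: float = 1.0
    duration: float = 300.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.duration <= 0 or self.frame_interval <= 0:
            raise ValueError("duration and frame_interval must be positive")
        if self.n_chambers < 1:
            raise ValueError("need at least one chamber")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def time_grid(self, t0: float = 0.0) -> np.ndarray:
        n = int(np.floor(self.duration / self.frame_interval))
        return t0 + np.arange(n + 1) * self.frame_interval


def make_schedule(
    T: float, n_cycles: int, first_phase: str = LACTOSE
) -> EnvironmentSchedule:
    """Alternating square-wave schedule (external lactose = Le during lactose
    phases, 0 during glucose phases, by construction of the model)."""
    return EnvironmentSchedule.alternating(T, n_cycles, first_phase=first_phase)


def gen_speed_trace(
    switch_time: float,
    lag: float,
    total: float,
    config: SynthesisConfig,
    plateau: float = 1.0,
    chamber_offset_sd: float = 0.0,
) -> GrowthTrace:
    """Replicate-chamber lateral-speed traces around a nutrient switch.

    Each chamber carries the same zero/ramp/plateau profile plus independent
    Gaussian noise per frame; ``chamber_offset_sd`` optionally adds a constant
    chamber-level offset to stress the across-chamber SEM.
    """
    if not 0 <= lag <= total:
        raise ValueError("need 0 <= lag <= total")
    rng = config.rng()
    t = config.time_grid()
    truth = lag_recovery_profile(t, switch_time, lag, total, plateau)
    speeds = np.tile(truth, (config.n_chambers, 1))
    if chamber_offset_sd > 0:
        speeds += rng.normal(0.0, chamber_offset_sd, size=(config.n_chambers, 1))
    if config.noise_sd > 0:
        speeds = speeds + rng.normal(0.0, config.noise_sd, size=speeds.shape)
    return GrowthTrace(times=t, speeds=speeds)


def _first_order_filter(t: np.ndarray, x: np.ndarray, rate: float,
                        init: float | None = None) -> np.ndarray:
    """Exact response of dF/dt = rate * (x(t) - F) to piecewise-linear input."""
    if not np.isfinite(rate):
        return x.copy()
    if rate <= 0:
        raise ValueError("maturation rate must be positive")
    F = np.empty_like(x)
    F[0] = x[0] if init is None else init
    for i in range(len(t) - 1):
        h = t[i + 1] - t[i]
        b = (x[i + 1] - x[i]) / h
        e = np.exp(-rate * h)
        # F(t+h) for input x(s) = x_i + b (s - t_i)
        F[i + 1] = x[i + 1] - b / rate + (F[i] - x[i] + b / rate) * e
    return F


def gen_fluorescence_trace(
    source_times: np.ndarray,
    source_values: np.ndarray,
    maturation_rate: float,
    config: SynthesisConfig,
    scale: float = 1.0,
    schedule: EnvironmentSchedule | None = None,
) -> FluorescenceTrace:
    """Reporter intensity from a protein signal through first-order maturation
    kinetics, scaled to arbitrary units, plus Gaussian noise.

    ``maturation_rate = inf`` makes the intensity directly proportional to the
    source; for a step input the half-crossing of the filtered output lags the
    step by ln(2)/maturation_rate.  Noise sd is ``config.noise_sd`` times the
    signal range (relative noise).
    """
    t = np.asarray(source_times, dtype=float)
    p = np.asarray(source_values, dtype=float)
    matured = _first_order_filter(t, p, maturation_rate)
    sig = scale * matured
    if config.noise_sd > 0:
        rng = config.rng()
        span = float(np.max(sig) - np.min(sig)) or 1.0
        sig = sig + rng.normal(0.0, config.noise_sd * span, size=sig.shape)
    return FluorescenceTrace(times=t, intensity=sig, schedule=schedule)


def trapezoid_wave(
    t: np.ndarray,
    T: float,
    delay: float,
    ramp_halfwidth: float,
    lo: float,
    hi: float,
    first_phase: str = LACTOSE,
) -> np.ndarray:
    """Periodic trapezoid whose half-crossings sit exactly ``delay`` minutes
    after each environment switch (period 2T; rises after the lactose switch)."""
    if not 0 < ramp_halfwidth <= min(delay, T - delay):
        raise ValueError("need 0 < ramp_halfwidth <= min(delay, T - delay)")
    period = 2.0 * T
    ph = np.asarray(t, dtype=float) % period
    if first_phase != LACTOSE:
        ph = (ph + T) % period  # shift so the rise starts at phase 0
    ramp_up = np.clip((ph - (delay - ramp_halfwidth)) / (2 * ramp_halfwidth), 0, 1)
    ramp_dn = np.clip((ph - (T + delay - ramp_halfwidth)) / (2 * ramp_halfwidth), 0, 1)
    return lo + (hi - lo) * (ramp_up - ramp_dn)


def gen_periodic_reporter_trace(
    T: float,
    delay: float,
    n_periods: int,
    config: SynthesisConfig,
    ramp_halfwidth: float = 8.0,
    lo: float = 0.1,
    hi: float = 1.0,
    first_phase: str = LACTOSE,
) -> tuple[FluorescenceTrace, EnvironmentSchedule]:
    """Periodically driven reporter trace with a planted phase delay.

    Returns the trace and the matching schedule; noise sd is
    ``config.noise_sd * (hi - lo)``.
    """
    schedule = make_schedule(T, n_periods, first_phase=first_phase)
    n = int(round(2 * T * n_periods / config.frame_interval))
    t = np.arange(n) * config.frame_interval
    sig = trapezoid_wave(t, T, delay, ramp_halfwidth, lo, hi, first_phase)
    if config.noise_sd > 0:
        sig = sig + config.rng().normal(0.0, config.noise_sd * (hi - lo), size=sig.shape)
    return FluorescenceTrace(times=t, intensity=sig, schedule=schedule), schedule


def gen_induction_trace(
    onset_lag: float,
    half_rise: float,
    config: SynthesisConfig,
    induction_start: float = 0.0,
    baseline: float = 0.05,
    amplitude: float = 1.0,
) -> FluorescenceTrace:
    """Delayed saturating-exponential induction trace; ``half_rise`` is the
    post-onset time to half-maximum (tau = half_rise / ln 2)."""
    tau = half_rise / np.log(2.0)
    t = config.time_grid(induction_start)
    t0 = induction_start + onset_lag
    sig = np.where(
        t >= t0, baseline + amplitude * (1.0 - np.exp(-(t - t0) / tau)), baseline
    )
    if config.noise_sd > 0:
        sig = sig + config.rng().normal(0.0, config.noise_sd * amplitude,
                                        size=sig.shape)
    return FluorescenceTrace(times=t, intensity=sig)


def gen_decay_trace(
    half_life: float,
    config: SynthesisConfig,
    start: float = 0.0,
    baseline: float = 0.1,
    amplitude: float = 1.0,
) -> FluorescenceTrace:
    """Exponential decay trace with the given half-life (tau = t_half / ln 2)."""
    tau = half_life / np.log(2.0)
    t = config.time_grid(start)
    sig = baseline + amplitude * np.exp(-(t - start) / tau)
    if config.noise_sd > 0:
        sig = sig + config.rng().normal(0.0, config.noise_sd * amplitude,
                                        size=sig.shape)
    return FluorescenceTrace(times=t, intensity=sig)


def steady_state_age_density(a: np.ndarray, doubling_time: float) -> np.ndarray:
    """p(a) = 2 lambda exp(-lambda a) on [0, doubling_time], lambda = ln2/Td.

    This is the age distribution of an exponentially growing population with
    deterministic division age; it integrates to exactly 1 on the support.
    """
    lam = np.log(2.0) / doubling_time
    a = np.asarray(a, dtype=float)
    return np.where((a >= 0) & (a <= doubling_time), 2 * lam * np.exp(-lam * a), 0.0)


def gen_age_sample(
    doubling_time: float,
    config: SynthesisConfig,
    cells_per_frame: int = 50,
) -> AgeSample:
    """Cell-cycle ages drawn per frame from the steady-state age density via
    inverse-CDF sampling: a = -ln(1 - u/2)/lambda, u ~ U(0,1)."""
    if doubling_time <= 0:
        raise ValueError("doubling_time must be positive")
    lam = np.log(2.0) / doubling_time
    rng = config.rng()
    # one set of frames per chamber, pooled into a single sample
    frame_times = np.tile(config.time_grid(), config.n_chambers)
    ages = [
        -np.log(1.0 - rng.random(cells_per_frame) / 2.0) / lam
        for _ in frame_times
    ]
    return AgeSample(frame_times=frame_times, ages=ages, dt=config.frame_interval)
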