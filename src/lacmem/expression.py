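"""Fluorescence-trajectory estimators for reporter dynamics.

Covers the measurement procedures used on LacY-Venus-like reporter traces:
exponential decay fits (dilution-driven loss), delayed saturating-exponential
induction fits, the post-removal overshoot timing, and the phase delay of a
periodically driven signal obtained by folding onto a single period and
locating half-crossings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .environment import LACTOSE, EnvironmentSchedule

LN2 = np.log(2.0)


@dataclass
class FluorescenceTrace:
    """Reporter intensity (arbitrary units) over time."""

    times: np.ndarray
    intensity: np.ndarray
    schedule: EnvironmentSchedule | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must align")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"time_min": self.times, "intensity_au": self.intensity})
        if self.schedule is not None:
            df["env"] = self.schedule.labels_for(self.times)
        return df


@dataclass
class ExpFit:
    """Exponential fit record: baseline + amplitude * f((t - onset)/tau)."""

    baseline: float
    amplitude: float
    tau: float
    onset_lag: float = 0.0  # induction fits only
    kind: str = "decay"
    standard_errors: dict = field(default_factory=dict)
    flag: str = "ok"
    residual_sd: float = np.nan
    n_obs: int = 0

    @property
    def half_life(self) -> float:
        """tau * ln 2: decay half-life, or post-onset half-rise time."""
        return self.tau * LN2

    def summary(self) -> str:
        se = self.standard_errors
        lines = [f"Exponential {self.kind} fit (n = {self.n_obs}, flag = {self.flag})"]
        for name in ("baseline", "amplitude", "tau", "onset_lag"):
            val = getattr(self, name)
            s = se.get(name)
            s_txt = f" +/- {s:.3g}" if s is not None and np.isfinite(s) else ""
            lines.append(f"  {name:10s} {val:10.4g}{s_txt}")
        lines.append(f"  half-{'life' if self.kind == 'decay' else 'rise'} "
                     f"= {self.half_life:.4g} min")
        return "\n".join(lines)


class FitError(RuntimeError):
    """Raised when a fit precondition fails (no decay / no rise detected)."""


def _stderr_from_jac(res, n, p):
    sse = float(2 * res.cost)
    try:
        cov = np.linalg.inv(res.jac.T @ res.jac) * (sse / max(n - p, 1))
        return np.sqrt(np.diag(cov)), sse
    except np.linalg.LinAlgError:
        return np.full(p, np.nan), sse


def fit_decay(trace: FluorescenceTrace, start: float) -> ExpFit:
    """Least-squares fit of baseline + amplitude * exp(-(t-start)/tau) for
    t >= start.  The implied half-life is tau * ln 2."""
    mask = trace.times >= start
    t = trace.times[mask] - start
    y = trace.intensity[mask]
    if len(t) < 4:
        raise ValueError("not enough points after start")
    scale = float(np.max(y) - np.min(y))
    if scale <= 1e-12 * max(abs(float(np.mean(y))), 1.0):
        # constant trace: amplitude 0, timescale unidentifiable
        return ExpFit(float(np.mean(y)), 0.0, np.nan, kind="decay",
                      flag="no_decay", n_obs=len(t))
    slope = np.polyfit(t, y, 1)[0]
    if slope >= 0:
        raise FitError("trace is not decreasing on average after start")

    base0 = float(np.min(y))
    amp0 = float(y[0] - base0)
    # crude tau from the 1/e crossing of the excess
    excess = (y - base0) / max(amp0, 1e-12)
    below = np.nonzero(excess < np.exp(-1.0))[0]
    tau0 = float(t[below[0]]) if len(below) else float(t[-1] / 2)
    tau0 = max(tau0, 1e-3)

    def resid(x):
        base, amp, tau = x
        return base + amp * np.exp(-t / tau) - y

    res = least_squares(resid, [base0, amp0, tau0],
                        bounds=([-np.inf, 0.0, 1e-6], [np.inf, np.inf, np.inf]))
    se, sse = _stderr_from_jac(res, len(t), 3)
    base, amp, tau = res.x
    return ExpFit(
        baseline=float(base),
        amplitude=float(amp),
        tau=float(tau),
        kind="decay",
        standard_errors={"baseline": se[0], "amplitude": se[1], "tau": se[2]},
        residual_sd=float(np.sqrt(sse / max(len(t) - 3, 1))),
        n_obs=len(t),
    )


def _induction_profile(t, base, amp, tau, t0):
    out = np.full(t.shape, base, dtype=float)
    after = t >= t0
    out[after] = base + amp * (1.0 - np.exp(-(t[after] - t0) / tau))
    return out


def fit_induction(trace: FluorescenceTrace, induction_start: float) -> ExpFit:
    """Fit baseline + amplitude * (1 - exp(-(t-t0)/tau)) for t >= t0, with a
    free onset t0 >= induction_start.  ``onset_lag`` = t0 - induction_start;
    the post-onset half-rise time is tau * ln 2."""
    mask = trace.times >= induction_start
    t = trace.times[mask]
    y = trace.intensity[mask]
    if len(t) < 5:
        raise ValueError("not enough points after induction start")
    scale = float(np.max(y) - np.min(y))
    level = max(abs(float(np.mean(y))), 1.0)
    if scale <= 1e-12 * level:
        return ExpFit(float(np.mean(y)), 0.0, np.nan, onset_lag=0.0,
                      kind="induction", flag="no_rise", n_obs=len(t))
    if np.polyfit(t, y, 1)[0] <= 0:
        raise FitError("no rise detected after induction start")

    span = t[-1] - t[0]
    # coarse profile search over (t0, tau) with (baseline, amplitude) linear
    t0_grid = t[0] + np.linspace(0.0, 0.7 * span, 36)
    tau_grid = np.geomspace(max(span / 200.0, 0.5), span, 24)
    best = (np.inf, None)
    for t0g in t0_grid:
        for taug in tau_grid:
            g = _induction_profile(t, 0.0, 1.0, taug, t0g)
            X = np.column_stack([np.ones_like(t), g])
            coef, sse_arr, *_ = np.linalg.lstsq(X, y, rcond=None)
            sse = float(sse_arr[0]) if len(sse_arr) else float(
                np.sum((y - X @ coef) ** 2)
            )
            if sse < best[0]:
                best = (sse, (coef[0], coef[1], taug, t0g))
    base0, amp0, tau0, t00 = best[1]

    def resid(x):
        base, amp, tau, t0 = x
        return _induction_profile(t, base, amp, tau, t0) - y

    res = least_squares(
        resid,
        [base0, max(amp0, 1e-9), tau0, t00],
        bounds=([-np.inf, 0.0, 1e-6, induction_start],
                [np.inf, np.inf, np.inf, t[-1]]),
        diff_step=1e-4,
    )
    se, sse = _stderr_from_jac(res, len(t), 4)
    base, amp, tau, t0 = res.x
    return ExpFit(
        baseline=float(base),
        amplitude=float(amp),
        tau=float(tau),
        onset_lag=float(t0 - induction_start),
        kind="induction",
        standard_errors={"baseline": se[0], "amplitude": se[1], "tau": se[2],
                         "onset_lag": se[3]},
        residual_sd=float(np.sqrt(sse / max(len(t) - 4, 1))),
        n_obs=len(t),
    )


class ExponentialDecayModel:
    def __init__(self, trace: FluorescenceTrace, start: float):
        self.trace, self.start = trace, start

    def fit(self) -> ExpFit:
        return fit_decay(self.trace, self.start)


class DelayedInductionModel:
    def __init__(self, trace: FluorescenceTrace, induction_start: float):
        self.trace, self.induction_start = trace, induction_start

    def fit(self) -> ExpFit:
        return fit_induction(self.trace, self.induction_start)


# ----------------------------------------------------------------------------
# overshoot timing


@dataclass
class PeakDelay:
    """Time from inducer removal to the (smoothed) intensity peak."""

    delay: float  # minutes
    peak_time: float
    censored: bool = False  # peak at the trace boundary


def time_to_peak_after_removal(
    trace: FluorescenceTrace,
    removal_time: float,
    smooth_window: float = 10.0,
) -> PeakDelay:
    """Argmax time of the moving-average-smoothed intensity at/after the
    inducer removal, minus the removal time.  A peak at the final sample is
    flagged as censored."""
    t, y = trace.times, trace.intensity
    if t[0] > removal_time or t[-1] <= removal_time:
        raise ValueError("trace must span the removal time")
    if smooth_window > 0:
        dt = float(np.median(np.diff(t)))
        w = max(int(round(smooth_window / dt)), 1)
        kernel = np.ones(w) / w
        pad = w // 2
        ypad = np.concatenate([np.full(pad, y[0]), y, np.full(w - 1 - pad, y[-1])])
        ys = np.convolve(ypad, kernel, mode="valid")
    else:
        ys = y
    after = t >= removal_time
    i_rel = int(np.argmax(ys[after]))
    peak_time = float(t[after][i_rel])
    censored = i_rel == int(np.sum(after)) - 1
    return PeakDelay(delay=peak_time - removal_time, peak_time=peak_time,
                     censored=censored)


# ----------------------------------------------------------------------------
# phase delay


@dataclass
class PhaseFit:
    """Delay between environment switches and reporter half-crossings."""

    delay: float  # minutes, mean of rising and falling transitions
    rise_delay: float
    fall_delay: float
    per_period_delays: np.ndarray
    n_periods: int
    folded_phase: np.ndarray
    folded_intensity: np.ndarray

    def summary(self) -> str:
        return (
            "Phase-delay measurement (fold + half-crossing)\n"
            f"  periods folded: {self.n_periods}\n"
            f"  rising-transition delay : {self.rise_delay:.2f} min\n"
            f"  falling-transition delay: {self.fall_delay:.2f} min\n"
            f"  mean delay: {self.delay:.2f} min"
        )


def _upcross(phase, sig, thr, direction, period):
    """Interpolated crossing phases of ``thr`` in the requested direction on a
    circular signal; returns sorted array of phases."""
    s = sig - thr
    s_next = np.roll(s, -1)
    ph_next = np.roll(phase, -1)
    ph_next = np.where(ph_next < phase, ph_next + period, ph_next)
    if direction > 0:
        hit = (s < 0) & (s_next >= 0)
    else:
        hit = (s > 0) & (s_next <= 0)
    out = []
    for i in np.nonzero(hit)[0]:
        denom = s_next[i] - s[i]
        frac = -s[i] / denom if denom != 0 else 0.0
        out.append((phase[i] + frac * (ph_next[i] - phase[i])) % period)
    return np.sort(out)


def _delay_after(crossings, switch_phase, period):
    if len(crossings) == 0:
        return np.nan
    d = (crossings - switch_phase) % period
    return float(np.min(d))


def phase_delay(
    trace: FluorescenceTrace,
    schedule: EnvironmentSchedule,
    n_periods: int,
) -> PhaseFit:
    """Fold the trace onto one full 2T period, average across periods, and
    measure the delay between each environment switch and the corresponding
    half-crossing (midpoint of folded min and max), averaged over rising and
    falling transitions.  Invariant under intensity scaling and offsets."""
    T = schedule.environmental_duration
    if T is None:
        raise ValueError("phase delay needs an alternating schedule")
    period = 2.0 * T
    t0 = schedule.t_start
    dt = float(np.median(np.diff(trace.times)))
    # each sample covers one sampling interval
    span = trace.times[-1] - max(trace.times[0], t0) + dt
    n_avail = int(np.floor(span / period + 1e-9))
    if n_avail < n_periods:
        raise ValueError(f"only {n_avail} complete periods available, "
                         f"{n_periods} requested")
    # use the last n_periods complete periods (closest to periodic equilibrium)
    t_hi = max(trace.times[0], t0) + n_avail * period
    t_lo = t_hi - n_periods * period
    sel = (trace.times >= t_lo) & (trace.times < t_hi)
    tt, yy = trace.times[sel], trace.intensity[sel]

    n_bins = max(int(round(period / dt)), 4)
    ph = (tt - t0) % period
    idx = np.minimum((ph / period * n_bins).astype(int), n_bins - 1)
    sums = np.bincount(idx, weights=yy, minlength=n_bins)
    counts = np.bincount(idx, minlength=n_bins)
    folded = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    # support each fold bin at the mean phase of its samples, so folding a
    # trace sampled commensurately with the period stays exact
    ph_sums = np.bincount(idx, weights=ph, minlength=n_bins)
    centers = np.where(
        counts > 0,
        ph_sums / np.maximum(counts, 1),
        (np.arange(n_bins) + 0.5) / n_bins * period,
    )
    good = np.isfinite(folded)
    centers_g, folded_g = centers[good], folded[good]

    thr = 0.5 * (np.min(folded_g) + np.max(folded_g))
    # signal rises when the inducer (lactose) phase begins
    rise_switch = 0.0 if schedule.labels[0] == LACTOSE else T
    fall_switch = T if rise_switch == 0.0 else 0.0

    def _wrap(d):
        # a crossing marginally before its switch (noise) wraps to ~period
        return d - period if d > 0.75 * period else d

    rise = _wrap(_delay_after(_upcross(centers_g, folded_g, thr, +1, period),
                              rise_switch, period))
    fall = _wrap(_delay_after(_upcross(centers_g, folded_g, thr, -1, period),
                              fall_switch, period))

    per_period = []
    for k in range(n_periods):
        m = (tt >= t_lo + k * period) & (tt < t_lo + (k + 1) * period)
        if np.sum(m) < 4:
            per_period.append(np.nan)
            continue
        phk = (tt[m] - t0) % period
        order = np.argsort(phk)
        r = _delay_after(_upcross(phk[order], yy[m][order], thr, +1, period),
                         rise_switch, period)
        f = _delay_after(_upcross(phk[order], yy[m][order], thr, -1, period),
                         fall_switch, period)
        per_period.append(np.nanmean([_wrap(r), _wrap(f)]))

    delay = float(np.nanmean([rise, fall]))
    return PhaseFit(
        delay=delay,
        rise_delay=rise,
        fall_delay=fall,
        per_period_delays=np.asarray(per_period),
        n_periods=n_periods,
        folded_phase=centers_g,
        folded_intensity=folded_g,
    )


class PhaseDelayModel:
    def __init__(self, trace, schedule, n_periods: int):
        self.trace, self.schedule, self.n_periods = trace, schedule, n_periods

    def fit(self) -> PhaseFit:
        return phase_delay(self.trace, self.schedule, self.n_periods)
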