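"""Growth-rate statistics from lateral-speed traces and cell-age samples.

Three estimators:

* :func:`bin_and_average` -- time-window binning within replicate growth
  chambers followed by mean and SEM across chambers (the error bar is the
  chamber-to-chamber SEM, not a within-trace one).
* :func:`fit_lag_recovery` -- piecewise zero/ramp/plateau least-squares
  regression of the relative speed around a nutrient switch, yielding the lag
  duration and the total lag+recovery time with standard errors.
* :func:`growth_rate_from_ages` -- the age-zero-fraction statistic: in a
  steadily growing population each division yields two age-zero cells, so the
  fraction of cells younger than one frame interval is twice the growth rate
  per frame, lambda = f0 / (2 * dt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares


@dataclass
class GrowthTrace:
    """Relative lateral-speed series for replicate chambers.

    ``speeds`` has shape (n_chambers, n_times); speed 1 corresponds to the
    glucose-equilibrium growth speed.
    """

    times: np.ndarray
    speeds: np.ndarray
    bin_width: float | None = None  # minutes; None = native sampling

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.speeds = np.atleast_2d(np.asarray(self.speeds, dtype=float))
        if self.speeds.shape[1] != len(self.times):
            raise ValueError("speeds must align with times")
        if not np.all(np.isfinite(self.times)):
            raise ValueError("times must be finite")

    @property
    def n_chambers(self) -> int:
        return self.speeds.shape[0]

    def mean_speed(self) -> np.ndarray:
        return np.nanmean(self.speeds, axis=0)

    def to_frame(self):
        import pandas as pd

        frames = [
            pd.DataFrame(
                {
                    "time_min": self.times,
                    "chamber_id": i,
                    "relative_speed": self.speeds[i],
                }
            )
            for i in range(self.n_chambers)
        ]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_frame(cls, df, bin_width=None) -> "GrowthTrace":
        piv = df.pivot_table(
            index="chamber_id", columns="time_min", values="relative_speed"
        )
        return cls(piv.columns.to_numpy(float), piv.to_numpy(float), bin_width)


@dataclass
class BinnedGrowthTrace:
    """Per-bin chamber means plus across-chamber mean and SEM.

    ``times`` are the nominal window centers; ``time_centroids`` are the mean
    sample times actually contributing to each bin, which is where a fitted
    model should be evaluated when the native sampling is not symmetric about
    the window center.
    """

    times: np.ndarray  # bin centers
    chamber_means: np.ndarray  # (n_chambers, n_bins); NaN for empty bins
    mean: np.ndarray
    sem: np.ndarray
    bin_width: float
    time_centroids: np.ndarray | None = None

    @property
    def n_chambers(self) -> int:
        return self.chamber_means.shape[0]

    @property
    def eval_times(self) -> np.ndarray:
        return self.times if self.time_centroids is None else self.time_centroids


def bin_and_average(trace: GrowthTrace, window: float = 5.0) -> BinnedGrowthTrace:
    """Bin each chamber over ``window``-minute intervals, then average across
    chambers; the SEM is computed across chambers per bin.  Empty bins are
    NaN, never zero."""
    if window <= 0:
        raise ValueError("window must be positive")
    dt = np.min(np.diff(np.sort(trace.times))) if len(trace.times) > 1 else window
    if window < dt - 1e-12:
        raise ValueError("window smaller than the native sampling interval")
    t0 = trace.times.min()
    idx = np.floor((trace.times - t0) / window).astype(int)
    n_bins = idx.max() + 1
    centers = t0 + (np.arange(n_bins) + 0.5) * window
    counts = np.bincount(idx, minlength=n_bins)
    ch_means = np.full((trace.n_chambers, n_bins), np.nan)
    for c in range(trace.n_chambers):
        sums = np.bincount(idx, weights=trace.speeds[c], minlength=n_bins)
        with np.errstate(invalid="ignore"):
            ch_means[c] = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    n_ch = np.sum(~np.isnan(ch_means), axis=0)
    mean = np.where(n_ch > 0, np.nansum(ch_means, axis=0) / np.maximum(n_ch, 1),
                    np.nan)
    with np.errstate(invalid="ignore"):
        ss = np.nansum((ch_means - mean) ** 2, axis=0)
        sem = np.sqrt(ss / np.maximum(n_ch - 1, 1)) / np.sqrt(np.maximum(n_ch, 1))
    sem = np.where(n_ch > 1, sem, np.nan if trace.n_chambers > 1 else 0.0)
    if trace.n_chambers == 1:
        sem = np.zeros_like(mean)
    t_sums = np.bincount(idx, weights=trace.times, minlength=n_bins)
    centroids = np.where(counts > 0, t_sums / np.maximum(counts, 1), centers)
    return BinnedGrowthTrace(centers, ch_means, mean, sem, window, centroids)


# ----------------------------------------------------------------------------
# lag + recovery regression


def lag_recovery_profile(
    t: np.ndarray, switch_time: float, lag: float, total: float, plateau: float
) -> np.ndarray:
    """Piecewise speed profile: plateau / 0 during the lag / linear ramp back
    to plateau, completing ``total`` minutes after the switch."""
    t = np.asarray(t, dtype=float)
    u = t - switch_time
    rec = total - lag
    out = np.full(t.shape, plateau, dtype=float)
    in_lag = (u >= 0) & (u < lag)
    out[in_lag] = 0.0
    if rec > 0:
        in_ramp = (u >= lag) & (u < total)
        out[in_ramp] = plateau * (u[in_ramp] - lag) / rec
    return out


@dataclass
class LagFit:
    """Result of the piecewise lag+recovery regression."""

    switch_time: float
    lag_duration: float
    total_lag_recovery: float
    plateau_level: float
    recovery_slope: float  # plateau units per minute
    standard_errors: dict = field(default_factory=dict)
    no_dip: bool = False
    sse: float = np.nan
    n_obs: int = 0

    def summary(self) -> str:
        se = self.standard_errors
        rows = [
            ("lag_duration [min]", self.lag_duration, se.get("lag_duration")),
            ("total_lag_recovery [min]", self.total_lag_recovery,
             se.get("total_lag_recovery")),
            ("plateau_level", self.plateau_level, se.get("plateau_level")),
            ("recovery_slope [1/min]", self.recovery_slope, None),
        ]
        lines = ["Lag+recovery piecewise regression",
                 f"  switch at t = {self.switch_time:g} min, n = {self.n_obs}"]
        if self.no_dip:
            lines.append("  flag: no post-switch dip detected")
        for name, val, s in rows:
            s_txt = f" +/- {s:.3g}" if s is not None and np.isfinite(s) else ""
            lines.append(f"  {name:26s} {val:10.4g}{s_txt}")
        return "\n".join(lines)


def _grid_search_lag(t, y, switch_time, lag_grid, total_grid):
    """Profile-plateau brute-force search; returns best (lag, total, plateau, sse)."""
    best = (0.0, 0.0, float(np.mean(y)), np.inf)
    for lag in lag_grid:
        for total in total_grid:
            if total < lag:
                continue
            g = lag_recovery_profile(t, switch_time, lag, total, 1.0)
            denom = g @ g
            plateau = (y @ g) / denom if denom > 0 else 0.0
            r = y - plateau * g
            sse = float(r @ r)
            if sse < best[3]:
                best = (float(lag), float(total), float(plateau), sse)
    return best


def fit_lag_recovery(
    trace: GrowthTrace | BinnedGrowthTrace,
    switch_time: float,
    grid_step: float | None = None,
) -> LagFit:
    """Fit the zero/ramp/plateau model around a nutrient switch.

    Accepts a raw :class:`GrowthTrace` (fitted on the across-chamber mean at
    native resolution) or a :class:`BinnedGrowthTrace`.  Lag and total
    lag+recovery are optimized jointly: a coarse profile-plateau grid search
    avoids local minima, then bounded least squares refines and supplies
    standard errors from the Jacobian.
    """
    if isinstance(trace, BinnedGrowthTrace):
        t, y = trace.eval_times, trace.mean
        native = trace.bin_width
    else:
        t, y = trace.times, trace.mean_speed()
        native = float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    ok = np.isfinite(y)
    t, y = t[ok], y[ok]
    if len(t) < 6:
        raise ValueError("not enough data points to fit")
    if t.min() >= switch_time or t.max() <= switch_time:
        raise ValueError("trace must span the switch time")
    span = t.max() - switch_time

    pre = y[t < switch_time]
    plateau_pre = float(np.mean(pre))
    post_min = float(np.min(y[t >= switch_time]))
    if plateau_pre > 0 and post_min > 0.5 * plateau_pre:
        # no post-switch dip: degenerate fit, flagged
        return LagFit(
            switch_time=switch_time,
            lag_duration=0.0,
            total_lag_recovery=0.0,
            plateau_level=float(np.mean(y)),
            recovery_slope=np.nan,
            no_dip=True,
            sse=float(np.sum((y - np.mean(y)) ** 2)),
            n_obs=len(y),
        )

    step = grid_step if grid_step is not None else max(native / 2.0, 0.5)
    lag_grid = np.arange(0.0, 0.8 * span, step)
    total_grid = np.arange(step, span, step)
    lag0, total0, plat0, _ = _grid_search_lag(t, y, switch_time, lag_grid, total_grid)

    def resid(x):
        lag, rec, plateau = x
        return lag_recovery_profile(t, switch_time, lag, lag + rec, plateau) - y

    x0 = np.array([lag0, max(total0 - lag0, step / 2), plat0])
    res = least_squares(
        resid,
        x0,
        bounds=([0.0, 1e-9, 0.0], [span, span, np.inf]),
        diff_step=1e-3,
    )
    lag, rec, plateau = res.x
    total = lag + rec
    n, p = len(y), 3
    sse = float(2 * res.cost)
    se = {}
    try:
        J = res.jac
        cov = np.linalg.inv(J.T @ J) * (sse / max(n - p, 1))
        se["lag_duration"] = float(np.sqrt(cov[0, 0]))
        se["total_lag_recovery"] = float(np.sqrt(cov[0, 0] + cov[1, 1] + 2 * cov[0, 1]))
        se["plateau_level"] = float(np.sqrt(cov[2, 2]))
    except np.linalg.LinAlgError:
        pass
    return LagFit(
        switch_time=float(switch_time),
        lag_duration=float(lag),
        total_lag_recovery=float(total),
        plateau_level=float(plateau),
        recovery_slope=float(plateau / rec) if rec > 1e-9 else np.nan,
        standard_errors=se,
        sse=sse,
        n_obs=n,
    )


class LagRecoveryModel:
    """statsmodels-style front end: ``LagRecoveryModel(trace, switch).fit()``."""

    def __init__(self, trace, switch_time: float):
        self.trace = trace
        self.switch_time = switch_time

    def fit(self, **kw) -> LagFit:
        return fit_lag_recovery(self.trace, self.switch_time, **kw)


# ----------------------------------------------------------------------------
# age-distribution growth rate


@dataclass
class AgeSample:
    """Cell-cycle ages observed per imaging frame.

    ``ages`` is a list of arrays, one per frame; age 0 means the cell divided
    within the current frame interval (age < dt).
    """

    frame_times: np.ndarray
    ages: list
    dt: float

    def __post_init__(self) -> None:
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if self.dt <= 0:
            raise ValueError("frame interval dt must be positive")
        if len(self.ages) != len(self.frame_times):
            raise ValueError("one age array per frame required")
        for a in self.ages:
            if np.any(np.asarray(a) < 0):
                raise ValueError("ages must be non-negative")

    def pooled(self) -> np.ndarray:
        return np.concatenate([np.asarray(a, dtype=float) for a in self.ages])


@dataclass
class AgeGrowthFit:
    """Growth rate from the age-zero fraction, with bootstrap uncertainty."""

    growth_rate: float  # 1/min
    generation_time: float  # min
    f0: float
    n_cells: int
    n_frames: int
    se_growth_rate: float = np.nan
    se_generation_time: float = np.nan
    zero_growth: bool = False

    def summary(self) -> str:
        lines = [
            "Age-distribution growth-rate estimate",
            f"  pooled cells: {self.n_cells} over {self.n_frames} frames",
            f"  age-zero fraction f0 = {self.f0:.4f}",
            f"  growth rate = {self.growth_rate:.5f} /min"
            f" +/- {self.se_growth_rate:.2g}",
            f"  generation time = {self.generation_time:.2f} min"
            f" +/- {self.se_generation_time:.2g}",
        ]
        if self.zero_growth:
            lines.append("  flag: f0 = 0, generation time unbounded")
        return "\n".join(lines)


def growth_rate_from_ages(
    sample: AgeSample, n_bootstrap: int = 200, seed: int = 0
) -> AgeGrowthFit:
    """Estimate lambda = f0 / (2 dt), f0 being the fraction of pooled cell
    observations with age below one frame interval; the standard error is a
    bootstrap over frames."""
    pooled = sample.pooled()
    if len(pooled) == 0:
        raise ValueError("empty age sample")
    f0 = float(np.mean(pooled < sample.dt))
    lam = f0 / (2.0 * sample.dt)
    if f0 == 0.0:
        return AgeGrowthFit(0.0, np.inf, 0.0, len(pooled), len(sample.ages),
                            zero_growth=True)
    rng = np.random.default_rng(seed)
    n_frames = len(sample.ages)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        pick = rng.integers(0, n_frames, size=n_frames)
        ages_b = np.concatenate([np.asarray(sample.ages[i]) for i in pick])
        boots[b] = np.mean(ages_b < sample.dt) / (2.0 * sample.dt)
    se_lam = float(np.std(boots, ddof=1))
    gen = np.log(2.0) / lam
    return AgeGrowthFit(
        growth_rate=float(lam),
        generation_time=float(gen),
        f0=f0,
        n_cells=len(pooled),
        n_frames=n_frames,
        se_growth_rate=se_lam,
        se_generation_time=float(gen * se_lam / lam),
    )


class AgeGrowthModel:
    """statsmodels-style front end for the age-fraction estimator."""

    def __init__(self, sample: AgeSample):
        self.sample = sample

    def fit(self, **kw) -> AgeGrowthFit:
        return growth_rate_from_ages(self.sample, **kw)
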