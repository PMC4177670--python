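"""Lactose-hydrolysis fitness metric and environmental-duration sweeps.

The per-cycle fitness proxy is the lactose hydrolyzed per unit time at
periodic equilibrium, integrated over one complete glucose/lactose cycle of
duration 2T.  The instantaneous rate is

    Phi(t) = (1 - phi) * b * B * L/(L+K_L) + c_eff * B * A/(A+K_A)

i.e. the direct hydrolysis branch of beta-gal lactose turnover plus the
allolactose turnover term (allolactose is itself hydrolyzed), so that at
equilibrium the cycle integral equals the lactose imported minus dilution
losses.  The reference implementation integrates Phi as an auxiliary ODE
state alongside the model; post-hoc quadrature of Phi over the sampled cycle
is used as an independent cross-check in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .environment import GLUCOSE
from .model import (
    BASE,
    MEMORY,
    IntegrationError,
    PeriodicEquilibrium,
    VariantConfig,
    periodic_equilibrium,
)
from .params import ModelParameters


def hydrolysis_rate(
    state: np.ndarray,
    params: ModelParameters,
    allolactose_scale: float = 1.0,
) -> np.ndarray | float:
    """Instantaneous lactose hydrolysis rate (nM/min) for state(s) (L,A,M,B).

    Accepts a single 4-vector or an (n, 4) array.  ``allolactose_scale``
    rescales the allolactose turnover term (0 during glucose phases of the
    response-memory variant).
    """
    y = np.asarray(state, dtype=float)
    squeeze = y.ndim == 1
    y = np.atleast_2d(y)
    if y.shape[1] < 4:
        raise ValueError("state must have 4 components")
    if np.any(y[:, :4] < -1e-9):
        raise ValueError("negative state components")
    L, A, B = y[:, 0], y[:, 1], y[:, 3]
    phi = params.lactose_to_allolactose_branching
    b = params.bgal_lactose_turnover
    c = params.bgal_allolactose_turnover * allolactose_scale
    rate = (1.0 - phi) * b * B * L / (L + params.bgal_lactose_Km) + c * B * A / (
        A + params.bgal_allolactose_Km
    )
    return float(rate[0]) if squeeze else rate


def cycle_hydrolysis(
    params: ModelParameters,
    T: float,
    variant: VariantConfig = BASE,
    equilibrium: PeriodicEquilibrium | None = None,
    **kwargs,
) -> float:
    """Lactose hydrolyzed per unit time (nM/min) over a full 2T cycle at
    periodic equilibrium, normalized by the full cycle duration."""
    if equilibrium is None:
        equilibrium = periodic_equilibrium(params, T, variant, **kwargs)
    return equilibrium.cycle_hydrolysis_total / (2.0 * T)


def excess_activity(
    params: ModelParameters,
    T: float,
    memory_variant: VariantConfig = MEMORY,
    **kwargs,
) -> float:
    """Percent excess hydrolysis of the response-memory variant over the base
    model at environmental duration T."""
    base_rate = cycle_hydrolysis(params, T, BASE, **kwargs)
    mem_rate = cycle_hydrolysis(params, T, memory_variant, **kwargs)
    if base_rate <= 0:
        raise ZeroDivisionError("base-model hydrolysis rate is zero; excess undefined")
    return 100.0 * (mem_rate - base_rate) / base_rate


def default_T_grid(
    params: ModelParameters,
    lo_generations: float = 0.05,
    hi_generations: float = 10.0,
    n_points: int = 30,
) -> np.ndarray:
    """Logarithmic grid of environmental durations (minutes)."""
    gen = params.generation_time
    return np.geomspace(lo_generations * gen, hi_generations * gen, n_points)


@dataclass
class SweepResult:
    """Environmental-duration sweep of the protein envelope and fitness.

    Protein envelope (Bmin/Bmax) refers to the base model; the hydrolysis
    rates are reported for both variants with ``excess_percent`` =
    100 * (memory - base) / base.  Failed grid points carry NaN and an entry
    in ``failures``.
    """

    T_minutes: np.ndarray
    T_generations: np.ndarray
    Bmin_nM: np.ndarray
    Bmax_nM: np.ndarray
    phi_rate_memory: np.ndarray  # nM lactose hydrolyzed / min
    phi_rate_base: np.ndarray
    excess_percent: np.ndarray
    failures: dict = field(default_factory=dict)

    @property
    def max_excess_percent(self) -> float:
        return float(np.nanmax(self.excess_percent))

    @property
    def T_at_max_excess(self) -> float:
        return float(self.T_minutes[np.nanargmax(self.excess_percent)])

    def max_excess_below(self, T_generations_cut: float = 1.0) -> float:
        """Maximum excess over environmental durations below the cut."""
        mask = self.T_generations < T_generations_cut
        if not np.any(mask):
            raise ValueError("no grid points below the requested cut")
        return float(np.nanmax(self.excess_percent[mask]))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "T_min": self.T_minutes,
                "T_generations": self.T_generations,
                "Bmin_nM": self.Bmin_nM,
                "Bmax_nM": self.Bmax_nM,
                "phi_memory": self.phi_rate_memory,
                "phi_base": self.phi_rate_base,
                "excess_percent": self.excess_percent,
            }
        )

    def summary(self) -> str:
        lines = [
            "Environmental-duration sweep",
            f"  grid: {len(self.T_minutes)} points, "
            f"{self.T_generations[0]:.3g}-{self.T_generations[-1]:.3g} generations",
            f"  max excess: {self.max_excess_percent:.1f}% at "
            f"T = {self.T_at_max_excess:.1f} min "
            f"({self.T_at_max_excess / self.T_minutes[0] * self.T_generations[0]:.2f} gen)",
            f"  failures: {len(self.failures)}",
        ]
        return "\n".join(lines)


def sweep_environmental_duration(
    params: ModelParameters,
    T_list: np.ndarray | None = None,
    memory_variant: VariantConfig = MEMORY,
    cycle_tolerance: float = 1e-6,
    max_cycles: int = 500,
    rtol: float = 1e-8,
    atol: float = 1e-14,
) -> SweepResult:
    """Run both variants to periodic equilibrium on a grid of environmental
    durations; per-T failures are recorded and the sweep continues."""
    if T_list is None:
        T_list = default_T_grid(params)
    T_list = np.asarray(T_list, dtype=float)
    if np.any(T_list <= 0):
        raise ValueError("all environmental durations must be positive")
    gen = params.generation_time
    n = len(T_list)
    out = {k: np.full(n, np.nan) for k in ("bmin", "bmax", "mem", "base")}
    failures: dict = {}
    kw = dict(
        cycle_tolerance=cycle_tolerance, max_cycles=max_cycles, rtol=rtol, atol=atol
    )
    for i, T in enumerate(T_list):
        try:
            eq_base = periodic_equilibrium(params, T, BASE, **kw)
            eq_mem = periodic_equilibrium(params, T, memory_variant, **kw)
        except IntegrationError as exc:  # record and continue
            failures[float(T)] = str(exc)
            continue
        out["bmin"][i] = eq_base.Bmin
        out["bmax"][i] = eq_base.Bmax_cycle
        out["base"][i] = eq_base.cycle_hydrolysis_total / (2 * T)
        out["mem"][i] = eq_mem.cycle_hydrolysis_total / (2 * T)
    with np.errstate(invalid="ignore", divide="ignore"):
        excess = 100.0 * (out["mem"] - out["base"]) / out["base"]
    return SweepResult(
        T_minutes=T_list,
        T_generations=T_list / gen,
        Bmin_nM=out["bmin"],
        Bmax_nM=out["bmax"],
        phi_rate_memory=out["mem"],
        phi_rate_base=out["base"],
        excess_percent=excess,
        failures=failures,
    )


def plot_sweep(result: SweepResult, path=None):
    """Render the protein-envelope and excess-activity panels (optional)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.6))
    ax1.loglog(result.T_generations, result.Bmax_nM, "k--", label="max")
    ax1.loglog(result.T_generations, result.Bmin_nM, "b--", label="min")
    ax1.set_xlabel("environmental duration (generations)")
    ax1.set_ylabel("lac protein (nM)")
    ax1.legend()
    ax2.semilogx(result.T_generations, result.excess_percent, "r-")
    ax2.set_xlabel("environmental duration (generations)")
    ax2.set_ylabel("excess hydrolysis (%)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
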