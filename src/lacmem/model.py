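"""Four-variable ODE model of lac operon induction under switching environments.

State (all nM): intracellular lactose L, allolactose A, lac mRNA M, LacZ
protein B (LacY is proportional to B).  Dynamics::

    dL/dt = a * B * Le(t)/(Le(t)+K_Le) - b * B * L/(L+K_L) - mu * L
    dA/dt = phi * b * B * L/(L+K_L) - c_eff * B * A/(A+K_A) - mu * A
    dM/dt = alpha_M * [rho + (1-rho) * A^n/(A^n+K_half^n)] - gamma_M * M
    dB/dt = k_B * M - mu * B

with a, b, c the permease / beta-gal lactose / beta-gal allolactose turnover
numbers, rho = B0/Bmax the basal transcription fraction and k_B the lumped
translation rate (see :mod:`lacmem.params`).  Protein is lost only by
dilution, which is what makes the basal-ward decay half-life equal the
generation time.

The *response memory* variant rescales the allolactose turnover c by a factor
in [0, 1] during glucose phases (0 by default), so residual intracellular
inducer persists and expression continues after external lactose is removed.
Hysteresis then emerges with no change to any other rate.

Integration restarts at every phase boundary so the piecewise-constant forcing
is resolved exactly at switch times.  A cumulative-hydrolysis auxiliary state
(the Eq-5 style rate integrated in time) rides along as a fifth component.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import root

from .environment import GLUCOSE, LACTOSE, EnvironmentSchedule
from .params import ModelParameters

#: tolerance below which a negative concentration is treated as an
#: integration failure rather than roundoff (nM); clipping is never applied
NEGATIVITY_TOL = 1e-9

STATE_NAMES = ("lactose", "allolactose", "mrna", "protein")


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces invalid states."""


@dataclass(frozen=True)
class VariantConfig:
    """Response-memory switch for the allolactose turnover in glucose.

    ``glucose_phase_allolactose_turnover_scale = 1`` reproduces the base model
    identically; 0 (default when ``response_memory`` is on) freezes allolactose
    degradation during glucose phases.
    """

    response_memory: bool = False
    glucose_phase_allolactose_turnover_scale: float = 0.0

    def __post_init__(self) -> None:
        s = self.glucose_phase_allolactose_turnover_scale
        if not 0.0 <= s <= 1.0:
            raise ValueError("turnover scale must lie in [0, 1]")

    def allolactose_scale(self, phase: str) -> float:
        if self.response_memory and phase == GLUCOSE:
            return self.glucose_phase_allolactose_turnover_scale
        return 1.0


BASE = VariantConfig(response_memory=False)
MEMORY = VariantConfig(response_memory=True)


@dataclass
class Trajectory:
    """Time-stamped model states with environment annotation.

    ``states`` has shape (n_times, 4) ordered (L, A, M, B); ``hydrolysis`` is
    the cumulative lactose hydrolyzed (nM) since the trajectory start.
    """

    times: np.ndarray
    states: np.ndarray
    environment_labels: np.ndarray
    hydrolysis: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ValueError("times and states must align")
        if np.any(np.diff(self.times) <= 0) and len(self.times) > 1:
            raise ValueError("times must be strictly increasing")

    @property
    def protein(self) -> np.ndarray:
        return self.states[:, 3]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_min": self.times,
                "env": self.environment_labels,
                "L_nM": self.states[:, 0],
                "A_nM": self.states[:, 1],
                "M_nM": self.states[:, 2],
                "B_nM": self.states[:, 3],
                "hydrolyzed_nM": self.hydrolysis,
            }
        )


# ----------------------------------------------------------------------------
# right-hand side


def _rhs_factory(params: ModelParameters, Le: float, allo_scale: float):
    """RHS for one constant-environment segment, incl. cumulative hydrolysis."""
    a = params.permease_import_turnover
    b = params.bgal_lactose_turnover
    c = params.bgal_allolactose_turnover * allo_scale
    phi = params.lactose_to_allolactose_branching
    mu = params.growth_rate
    KL = params.bgal_lactose_Km
    KA = params.bgal_allolactose_Km
    Kh = params.half_max_induction
    n = params.hill_number
    alphaM = params.mrna_transcription_rate
    gammaM = params.mrna_degradation_rate
    rho = params.basal_fraction
    kB = params.translation_rate
    import_sat = Le / (Le + params.permease_Km) if Le > 0 else 0.0

    def rhs(t, y):
        L, A, M, B = y[0], y[1], y[2], y[3]
        uptake = a * B * import_sat
        lac_conv = b * B * L / (L + KL) if L > 0 else 0.0
        allo_conv = c * B * A / (A + KA) if A > 0 else 0.0
        hill = 0.0
        if A > 0:
            An = A**n
            hill = An / (An + Kh**n)
        dL = uptake - lac_conv - mu * L
        dA = phi * lac_conv - allo_conv - mu * A
        dM = alphaM * (rho + (1.0 - rho) * hill) - gammaM * M
        dB = kB * M - mu * B
        # Eq-5 hydrolysis: direct lactose hydrolysis branch plus allolactose
        # turnover (allolactose is itself hydrolyzed by beta-gal), so the
        # cycle integral accounts for all lactose consumed.
        dH = (1.0 - phi) * lac_conv + allo_conv
        return (dL, dA, dM, dB, dH)

    return rhs


def derivatives(
    state: np.ndarray,
    t: float,
    params: ModelParameters,
    schedule: EnvironmentSchedule,
    variant: VariantConfig = BASE,
) -> np.ndarray:
    """Instantaneous rates (nM/min) of (L, A, M, B) at time ``t``.

    Rejects negative state components and times outside the schedule horizon.
    """
    y = np.asarray(state, dtype=float)
    if y.shape != (4,):
        raise ValueError("state must have 4 components (L, A, M, B)")
    if np.any(y < -NEGATIVITY_TOL):
        raise ValueError(f"negative state components: {y}")
    phase = schedule.phase_at(t)  # raises outside horizon
    Le = params.external_lactose if phase == LACTOSE else 0.0
    rhs = _rhs_factory(params, Le, variant.allolactose_scale(phase))
    return np.asarray(rhs(t, np.concatenate([np.maximum(y, 0.0), [0.0]]))[:4])


# ----------------------------------------------------------------------------
# integration


def _check_nonnegative(y: np.ndarray) -> None:
    if np.min(y) < -NEGATIVITY_TOL:
        raise IntegrationError(
            f"negative concentration {np.min(y):.3e} nM beyond tolerance; "
            "tighten integrator tolerances"
        )


def _integrate_segment(rhs, y0, t0, t1, rtol, atol, t_eval=None, method="LSODA"):
    if np.isscalar(atol) and len(y0) == 5:
        # loose tolerance on the cumulative-hydrolysis auxiliary state only
        atol = np.array([atol] * 4 + [1e-6])
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
        dense_output=t_eval is None,
    )
    if not sol.success:
        raise IntegrationError(f"integrator failed on [{t0}, {t1}]: {sol.message}")
    if not np.all(np.isfinite(sol.y)):
        raise IntegrationError(f"non-finite state on [{t0}, {t1}]")
    _check_nonnegative(sol.y[:4])
    return sol


def simulate(
    params: ModelParameters,
    schedule: EnvironmentSchedule,
    variant: VariantConfig = BASE,
    init: np.ndarray | None = None,
    output_step: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-14,
) -> Trajectory:
    """Integrate the model across the schedule, restarting at phase switches.

    ``init`` is the 4-component initial state; by default the uninduced
    (constant-glucose) steady state.  Output is sampled every ``output_step``
    minutes, with every phase boundary included exactly.
    """
    if output_step <= 0:
        raise ValueError("output_step must be positive")
    if init is None:
        init = steady_state(params, GLUCOSE, variant)
    y = np.concatenate([np.asarray(init, dtype=float), [0.0]])
    if y.shape != (5,):
        raise ValueError("init must have 4 components")
    if np.any(y < -NEGATIVITY_TOL):
        raise ValueError("initial state has negative components")
    y = np.maximum(y, 0.0)

    all_t: list[np.ndarray] = []
    all_y: list[np.ndarray] = []
    for start, end, phase in schedule.segments():
        Le = params.external_lactose if phase == LACTOSE else 0.0
        rhs = _rhs_factory(params, Le, variant.allolactose_scale(phase))
        n_pts = max(int(round((end - start) / output_step)), 1)
        t_eval = np.linspace(start, end, n_pts + 1)
        sol = _integrate_segment(rhs, y, start, end, rtol, atol, t_eval=t_eval)
        y = sol.y[:, -1]
        # drop the duplicated segment-start sample except for the first segment
        keep = slice(None) if not all_t else slice(1, None)
        all_t.append(sol.t[keep])
        all_y.append(sol.y[:, keep].T)
    times = np.concatenate(all_t)
    ys = np.vstack(all_y)
    return Trajectory(
        times=times,
        states=np.maximum(ys[:, :4], 0.0),
        environment_labels=schedule.labels_for(times),
        hydrolysis=ys[:, 4],
    )


def _propagate_cycle(params, variant, y4, T, first_phase, rtol, atol):
    """Advance the 4-state across one full 2T cycle; return end state and the
    lactose hydrolyzed during the cycle."""
    y = np.concatenate([y4, [0.0]])
    t = 0.0
    second = GLUCOSE if first_phase == LACTOSE else LACTOSE
    end_of_phase = {}
    for phase in (first_phase, second):
        Le = params.external_lactose if phase == LACTOSE else 0.0
        rhs = _rhs_factory(params, Le, variant.allolactose_scale(phase))
        sol = _integrate_segment(rhs, y, t, t + T, rtol, atol, t_eval=[t + T])
        y = sol.y[:, -1]
        end_of_phase[phase] = y[:4].copy()
        t += T
    return y[:4], y[4], end_of_phase


# ----------------------------------------------------------------------------
# fixed points


def steady_state(
    params: ModelParameters,
    environment: str,
    variant: VariantConfig = BASE,
    horizon: float = 6000.0,
    rtol: float = 1e-10,
    atol: float = 1e-14,
    agreement_rtol: float = 1e-3,
) -> np.ndarray:
    """Fixed point (L*, A*, M*, B*) under a constant environment.

    Found by long integration and confirmed by root-finding; the two must
    agree to ``agreement_rtol`` on every component (relative to scale).
    """
    if environment not in (GLUCOSE, LACTOSE):
        raise ValueError(f"unknown environment {environment!r}")
    Le = params.external_lactose if environment == LACTOSE else 0.0
    allo_scale = variant.allolactose_scale(environment)
    rhs = _rhs_factory(params, Le, allo_scale)

    # start from basal expression with no internal sugars
    rho = params.basal_fraction
    y0 = np.array(
        [0.0, 0.0, rho * params.mrna_transcription_rate / params.mrna_degradation_rate,
         params.basal_bgal_level, 0.0]
    )
    sol = _integrate_segment(rhs, y0, 0.0, horizon, rtol, atol, t_eval=[horizon])
    y_int = np.maximum(sol.y[:4, -1], 0.0)

    res = root(lambda y: np.asarray(rhs(0.0, np.concatenate([y, [0.0]]))[:4]),
               y_int, method="hybr", tol=1e-12)
    if not res.success:
        raise IntegrationError(f"root-finding failed: {res.message}")
    y_root = res.x
    scale = np.abs(y_root) + 1.0
    if np.max(np.abs(y_root - y_int) / scale) > agreement_rtol:
        raise IntegrationError(
            "long integration and root-finding disagree: "
            f"{y_int} vs {y_root}"
        )
    if np.any(y_root < -NEGATIVITY_TOL):
        raise IntegrationError(f"negative fixed point {y_root}")
    return np.maximum(y_root, 0.0)


@dataclass
class PeriodicEquilibrium:
    """Limit cycle of the periodically forced model.

    ``Bmin`` is the protein level immediately before the glucose-to-lactose
    switch (end of the glucose phase); ``Bmax_cycle`` immediately before the
    lactose-to-glucose switch (end of the lactose phase).
    """

    cycle: Trajectory
    Bmin: float
    Bmax_cycle: float
    T: float
    n_cycles: int
    residual: float
    cycle_hydrolysis_total: float  # nM of lactose hydrolyzed over the 2T cycle


def periodic_equilibrium(
    params: ModelParameters,
    T: float,
    variant: VariantConfig = BASE,
    cycle_tolerance: float = 1e-6,
    max_cycles: int = 500,
    init: np.ndarray | None = None,
    output_step: float | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-14,
) -> PeriodicEquilibrium:
    """Iterate full lactose->glucose cycles until the cycle-start state repeats.

    Convergence: max_i |dy_i| / (|y_i| + 1e-9) < ``cycle_tolerance`` between
    consecutive cycle starts.  The returned cycle is re-integrated with dense
    output once equilibrated.
    """
    if T <= 0:
        raise ValueError("environmental duration T must be positive")
    if init is None:
        init = steady_state(params, GLUCOSE, variant)
    y = np.asarray(init, dtype=float)
    resid = np.inf
    for k in range(1, max_cycles + 1):
        y_next, _, _ = _propagate_cycle(params, variant, y, T, LACTOSE, rtol, atol)
        resid = float(np.max(np.abs(y_next - y) / (np.abs(y) + 1e-9)))
        y = y_next
        if resid < cycle_tolerance:
            break
    else:
        raise IntegrationError(
            f"no periodic equilibrium within {max_cycles} cycles at T={T}; "
            f"last cycle-start relative change {resid:.3e}"
        )

    step = output_step if output_step is not None else max(T / 200.0, 1e-3)
    schedule = EnvironmentSchedule.alternating(T, 1, first_phase=LACTOSE)
    cycle = simulate(
        params, schedule, variant, init=y, output_step=step, rtol=rtol, atol=atol
    )
    # protein immediately before the switches
    i_switch = int(np.searchsorted(cycle.times, T))
    Bmax_cycle = float(cycle.states[i_switch, 3])
    Bmin = float(cycle.states[-1, 3])
    return PeriodicEquilibrium(
        cycle=cycle,
        Bmin=Bmin,
        Bmax_cycle=Bmax_cycle,
        T=T,
        n_cycles=k,
        residual=resid,
        cycle_hydrolysis_total=float(cycle.hydrolysis[-1]),
    )


class LacOperonModel:
    """Convenience object bundling parameters and variant.

    Mirrors the functional API: ``simulate``, ``steady_state``,
    ``periodic_equilibrium`` and ``derivatives`` with the bound configuration.
    """

    def __init__(
        self,
        params: ModelParameters | None = None,
        variant: VariantConfig = BASE,
    ) -> None:
        self.params = params if params is not None else ModelParameters()
        self.variant = variant

    def derivatives(self, state, t, schedule):
        return derivatives(state, t, self.params, schedule, self.variant)

    def simulate(self, schedule, **kw):
        return simulate(self.params, schedule, self.variant, **kw)

    def steady_state(self, environment, **kw):
        return steady_state(self.params, environment, self.variant, **kw)

    def periodic_equilibrium(self, T, **kw):
        return periodic_equilibrium(self.params, T, self.variant, **kw)
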