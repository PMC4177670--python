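# Methods

## The induction model

The model is a deterministic, population-average description of *lac* operon
induction in a cell growing at a fixed rate μ.  It tracks intracellular
lactose *L*, allolactose *A*, *lac* mRNA *M* and LacZ protein *B* (all nM);
LacY permease is assumed proportional to LacZ, so one protein variable drives
both import and catalysis.  Per minute:

* import:            `a · B · Le/(Le + K_Le)`
* lactose turnover:  `b · B · L/(L + K_L)`, a fraction φ converted to
  allolactose, the remainder hydrolyzed to glucose + galactose
* allolactose turnover: `c · B · A/(A + K_A)` (hydrolysis by β-gal)
* transcription:     `α_M · [ρ + (1−ρ) · Aⁿ/(Aⁿ + K_½ⁿ)]`, first-order mRNA
  loss at γ_M
* translation:       `k_B · M`, protein loss **only** by dilution at μ

All sugars are additionally diluted at μ.  The environment is a square wave:
`Le = 11,700 nM` during lactose phases and 0 during glucose phases, switching
every *environmental duration* `T` (full cycle `2T`); integration restarts at
every switch so the discontinuous forcing is resolved exactly.

Assumptions worth keeping in mind: no catabolite-repression dynamics beyond
the on/off inducer abstraction, no stringent response, no stochastic
single-cell effects, and a growth rate that does not feed back on expression.

## Parameter values and two closure conditions

Defaults (shipped in `data/lac_parameters.cfg`):

| symbol | meaning | default | unit |
|---|---|---|---|
| μ | growth/dilution rate | ln 2 / 60 ≈ 0.01155 | 1/min |
| a | permease import turnover | 2,400 | 1/min |
| b | β-gal lactose turnover | 600 | 1/min |
| φ | lactose→allolactose branching | 0.448 | – |
| c | β-gal allolactose turnover | 25 | 1/min |
| B₀ | basal LacZ level | 34.2 | nM |
| B_max | fully induced LacZ level | 34,286 | nM |
| Le | external lactose (lactose phase) | 11,700 | nM |
| K_Le | permease Michaelis constant | 5×10⁵ | nM |
| K_L | β-gal lactose Michaelis constant | 2,530 | nM |
| K_A | β-gal allolactose Michaelis constant | 1,200 | nM |
| K_½ | half-maximal induction (allolactose) | 1,000 | nM |
| α_M | maximal transcription rate | 20 | nM/min |
| γ_M | mRNA loss rate (1.5-min lifetime) | 0.667 | 1/min |
| n | Hill coefficient | 2 | – |

Two constants are **derived**, not free, anchoring the model to the two
measured expression levels:

* basal transcription fraction `ρ = B₀ / B_max`, so the uninduced fixed point
  (L = A = 0) is exactly `B₀ = 34.2 nM`;
* translation rate `k_B = μ · γ_M · B_max / α_M`, so the fully induced fixed
  point approaches `B_max = 34,286 nM` (the Hill function saturates at
  ~99.98% under constant lactose, leaving the fixed point within 0.03% of
  B_max).

This closure makes the two steady states and the 60-minute dilution half-life
structural properties rather than fitted outcomes, and it renders the mRNA
scale α_M a pure bookkeeping choice (changing α_M rescales M and k_B
together without moving any protein trajectory).

Under these defaults the induced allolactose level (~67 μM) sits far above
K_½, so induction under lactose is monostable and fast; in glucose the base
model clears allolactose within seconds (turnover `c·B` ≫ 1/min), while the
memory variant retains it with only dilution loss (half-life one generation).
That separation of scales is exactly what produces the ~100% hydrolysis
advantage at sub-generation `T` and its disappearance once `T` exceeds a few
generations.

## Response-memory variant

Residual intracellular inducer is modelled by multiplying the allolactose
turnover `c` by a scale in [0, 1] during glucose phases only; the default
scale 0 freezes allolactose degradation, and scale 1 reproduces the base
model bit-for-bit (a regression-tested identity).  Intermediate scales model
"slower but non-zero" degradation.

## Fitness metric

The instantaneous hydrolysis rate is
`Φ = (1−φ)·b·B·L/(L+K_L) + c(t)·B·A/(A+K_A)`; the allolactose term is
included because allolactose is itself hydrolyzed by β-gal, so at periodic
equilibrium the cycle integral of Φ equals the lactose imported minus the
(negligible) dilution loss of internal sugar pools.  Φ is integrated as a
fifth ODE state (the reference implementation) and normalized by the full
cycle duration `2T`; Simpson quadrature of Φ over the sampled cycle is the
independent cross-check, agreeing to <0.1%.

Periodic equilibrium is found by iterating full cycles (lactose first,
starting from the uninduced glucose steady state) until the cycle-start state
repeats to `|Δy|/(|y|+10⁻⁹) < 10⁻⁶` per component (≤500 cycles; a mixed
tolerance because intracellular lactose underflows to 0 each glucose phase).
The protein immediately before the glucose→lactose switch is the cycle
minimum, immediately before the lactose→glucose switch the maximum.  The
default sweep grid is logarithmic, 0.05–10 generations, 30 points.

## Numerical choices

* LSODA with `rtol = 10⁻⁸`, `atol = 10⁻¹⁴` on concentrations (10⁻⁶ on the
  cumulative-hydrolysis state).  Concentrations are never clipped: any value
  below −10⁻⁹ nM aborts the run as an integration failure; roundoff-scale
  negatives are sanitized only in the returned trajectory.
* Steady states are obtained by long integration **and** Powell root-finding;
  disagreement beyond 0.1% per component is an error.
* The post-removal protein half-life is measured from a log-linear fit of
  `B(t) − B₀` over t ∈ [60, 360] min after the switch.  The first crossing of
  half the initial excess sits ~2.5% later (≈61.5 min) because mRNA takes a
  few lifetimes to clear; the tail fit reports the dilution-limited
  exponential that the decay actually follows, mirroring how reporter decays
  are fitted in practice.

## Estimators

* **bin_and_average** — per-chamber means over fixed time windows, then mean
  and SEM **across chambers** (N = number of chambers), the error model used
  for replicate growth chambers.  Reported timestamps are window centers; the
  fitted model is evaluated at each bin's sample-time centroid so asymmetric
  sampling inside a window does not bias changepoints.
* **fit_lag_recovery** — joint least squares of (lag, total, plateau) for the
  piecewise plateau/zero/linear-ramp/plateau profile, continuity enforced at
  the ramp ends.  A coarse profile-plateau grid search (plateau solved in
  closed form per changepoint pair) supplies the start; bounded
  Levenberg–Marquardt refines and the Jacobian supplies standard errors.
  Lag and recovery are fitted jointly rather than sequentially; the choice is
  validated by parameter recovery (35/55-min truths recovered exactly
  noiselessly and to ±0.5 min in the mean over 100 noisy replicates, with
  ~95% 2-SE coverage).  A trace whose post-switch minimum stays above half
  the pre-switch plateau is flagged `no_dip` and returned with zero lag.
* **growth_rate_from_ages** — λ = f₀ / (2Δt) with f₀ the pooled fraction of
  cells younger than one frame interval ("age 0" = divided within the current
  frame); the uncertainty is a bootstrap over frames.  The estimator carries
  an O(λΔt/2) discretization bias (≈ +0.5% on the generation time at 1-min
  frames), well inside the reported uncertainty.
* **fit_decay / fit_induction** — ordinary least squares on intensities (not
  logs, since traces cross baseline-dominated regimes) of
  `base + amp·e^(−(t−t₀)/τ)` and `base + amp·(1 − e^(−(t−t₀)/τ))` with a free
  onset t₀ for induction (coarse (t₀, τ) grid with the linear pair profiled,
  then refinement).  Flat traces return flagged zero-amplitude fits;
  wrong-signed trends raise.
* **time_to_peak_after_removal** — argmax of a centered moving average
  (default 10-min window) at/after the removal time; a boundary peak is
  flagged censored.
* **phase_delay** — fold the trace onto one `2T` period (support points at
  the per-bin mean phase, keeping commensurate sampling exact), threshold at
  the midpoint of the folded min/max, and average the delays of the rising
  crossing after the lactose switch and the falling crossing after the
  glucose switch.  The symmetric rise/fall average is a design choice
  validated by recovery of planted shifts; the midpoint threshold makes the
  estimate invariant under intensity scaling and offsets.

## Synthetic data

Generators are pure functions of (planted truth, config) with one explicit
RNG stream per call.  They emulate: replicate-chamber relative-speed traces
(zero/ramp/plateau plus i.i.d. Gaussian noise, optional chamber offsets);
reporter fluorescence as a protein signal passed through exact first-order
maturation kinetics (a configurable rate; a step input's half-crossing lags
by ln 2/rate); trapezoid periodic reporter waves whose half-crossings sit
exactly at a planted delay; and cell-age samples drawn by inverse CDF from
the steady-state age density `p(a) = 2λe^(−λa)` truncated at one doubling
time (deterministic division age; the density integrates to exactly 1).

Default noise levels — sd 0.1 on relative speed, 2% of range on fluorescence
— are fixture choices on the scale of the published error bars, not measured
values.  What the generators do **not** emulate: correlated noise, cell
packing and flow artifacts, photobleaching, gamma-distributed division ages,
or growth-rate feedback on expression.  Passing round-trip tests therefore
demonstrates estimator correctness and calibration under the assumed noise
model, not robustness to every failure mode of real microscopy data.

Problem sizes used in the shipped tests and in `scripts/acceptance.py`
(100 replicates per estimator; 21–30 point sweep grids; 200–400-minute
traces) were chosen to keep Monte-Carlo error well below the assertion
tolerances while the full suite runs in about a minute.

## Known limitations

* The Michaelis constants for β-gal (K_L, K_A) are used at their nM-scale
  values; β-gal is therefore effectively substrate-saturated during lactose
  phases, which strengthens the import-limited regime.
* The cycle-map iteration converges linearly (rate e^(−2μT)), so
  sub-generation durations need ~10² cycles; a Newton accelerator would be
  faster but is unnecessary at this system size.
* `EnvironmentSchedule` requires strictly positive phase durations; a
  zero-length horizon is rejected rather than returning a single-state
  trajectory.
* The overshoot decomposition into reporter-maturation, residual-inducer and
  repressor-rebinding contributions is out of scope; the package measures the
  total timing only.
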