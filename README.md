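# lacmem

Kinetic modelling and trace analysis for *lac* operon **memory** in
fluctuating glucose/lactose environments.

When *E. coli* alternates between glucose and lactose, two non-genetic memory
mechanisms shape its fitness: *phenotypic memory* — stable Lac proteins are
diluted only by growth, so an induced state survives several generations of
glucose — and *response memory* — expression keeps running for tens of
minutes after the external inducer disappears, because residual intracellular
allolactose keeps the operon de-repressed.  `lacmem` implements a
deterministic population-average model of both effects, a lactose-hydrolysis
fitness metric over nutrient cycles, and the estimators used to quantify
memory in growth-speed and fluorescence-reporter time series, together with
seeded synthetic-data generators so every estimator is testable end to end.

## Model

Four intracellular concentrations (nM): lactose *L*, allolactose *A*, mRNA
*M*, LacZ protein *B* (LacY is proportional to *B*):

```
dL/dt = a·B·Le(t)/(Le(t)+K_Le) − b·B·L/(L+K_L) − μL
dA/dt = φ·b·B·L/(L+K_L) − c(t)·B·A/(A+K_A) − μA
dM/dt = α_M·[ρ + (1−ρ)·Aⁿ/(Aⁿ+K_½ⁿ)] − γ_M·M
dB/dt = k_B·M − μB
```

with permease import turnover *a*, β-gal lactose turnover *b* (fraction φ
branched to allolactose, the rest hydrolyzed), β-gal allolactose turnover
*c*, Hill-type induction by allolactose and protein loss by dilution only
(μ = ln 2 / 60 min⁻¹).  The external lactose `Le(t)` is a square wave with
*environmental duration* `T` per phase (full cycle `2T`).  The
**response-memory variant** multiplies *c* by a factor in [0, 1] (default 0)
during glucose phases, so residual inducer persists.  Fitness is the
lactose hydrolyzed per unit time at the periodic equilibrium of a full cycle,

```
Φ = (1−φ)·b·B·L/(L+K_L) + c(t)·B·A/(A+K_A)
```

integrated over `2T` as an auxiliary ODE state.

The estimator suite provides piecewise zero/ramp/plateau lag+recovery
regression of relative growth-speed traces, the age-zero-fraction growth-rate
statistic (λ = f₀ / 2Δt), exponential decay and delayed-exponential induction
fits, overshoot (time-to-peak after inducer removal), and the fold-and-
half-crossing phase-delay measurement for periodic driving.  Each estimator
is exposed both as a function and as a model class with `.fit()` returning a
results object with `summary()`.

## Worked example

```python
from lacmem import (ModelParameters, steady_state, GLUCOSE, LACTOSE,
                    periodic_equilibrium, excess_activity, BASE)
from lacmem.validate import measure_decay_half_life

p = ModelParameters()                    # defaults: 60-min generation time
print(steady_state(p, GLUCOSE)[3])       # 34.2       (basal protein, nM)
print(steady_state(p, LACTOSE)[3])       # 34278.4    (induced protein, nM)
print(measure_decay_half_life(p))        # 60.0       (post-removal half-life, min)

eq = periodic_equilibrium(p, T=90.0, variant=BASE)
print(eq.Bmin, eq.Bmax_cycle)            # 9153, 25178  nM
print(excess_activity(p, 30.0))          # 100.3      (% extra hydrolysis)
```

Reading: under constant glucose the protein sits at its basal 34.2 nM; under
constant lactose at its fully induced ~34,286 nM; after removing lactose the
above-basal excess halves every 60 minutes — one generation — because the
protein is lost only by dilution.  With 90-minute alternation the protein
never falls below ~9,000 nM (phenotypic memory), and at a 30-minute
environmental duration the response-memory variant hydrolyzes ~100% more
lactose per unit time than the memoryless model.

The same operations are scriptable from the shell:

```bash
lacmem simulate --T 240 --cycles 3 --out run.csv     # trajectory + metadata
lacmem sweep --points 30 --out sweep.csv             # memory-vs-base sweep
lacmem gen --kind speed --seed 3 --out speed.csv     # synthetic fixture
lacmem fit-lag --switch-time 60 --out fit.json speed.csv
lacmem validate                                      # self-check table
```

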