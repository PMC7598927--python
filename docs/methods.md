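# Methods

## Model and assumptions

A cell is a two-pool ODE system: functional protein `P` and damaged protein
`D` (both non-dimensional, `D ∈ [0, 1]`).  Between events,

    dP/dt = g·P·(1 − S) − k1·P + r(D),    S = P + Q·D,
    dD/dt = k1·P − r(D),                  r(D) = k2·R·sin(D/R).

Growth is logistic in the damage-weighted size `S`, so damaged proteins slow
growth with weight `Q` ("resilience").  Damage formation converts functional
to damaged protein at rate `k1`; repair converts it back through `r(D)`.
Formation and repair only move mass between the two pools: `dP + dD` equals
the pure growth flux identically, which the test suite asserts as an
invariant.  The repair capacity `R ∈ [π⁻¹, ∞]` shapes the repair profile:
as `R → ∞`, `r → k2·D` (constant *rate* of repair over life, "unlimited"
capacity); at the lower end `R = π⁻¹`, `r = (k2/π)·sin(πD)` rises like
`k2·D` for young, low-damage cells but collapses to exactly zero at full
damage load ("decline" in capacity).  Intermediate `R` interpolates.

Cell division and death are instantaneous events: division at the first
upward crossing of `P` through `P_div`, death at the first upward crossing of
`D` through `D_death`.  At division the mother keeps `s·P` and
`(s + re·(1−s))·D`; the daughter receives the exact complements, so both
pools are conserved to the last bit (the complements are computed by
subtraction).  `s` and `re` are constant over a cell's life; cells are
independent after birth (full nutrients, no signalling or competition).

Cell-to-cell variability follows a log-normal mixed-effects scheme on the
two rates: `k_i = k̄_i·exp(η_i)`, `η_i ~ N(0, σ²)` i.i.d. per newborn, which
keeps rates strictly positive and reduces to identical cells at `σ = 0`.

## Parameters, units and defaults

All quantities are non-dimensional; time is in units of the rescaled model.

| name | meaning | default |
|---|---|---|
| `g` | growth factor | 2.0 |
| `k1` | damage formation rate (population fixed effect) | 0.4 |
| `k2` | damage repair rate (population fixed effect) | 0.138 decline / 0.092 unlimited |
| `Q` | resilience: weight of `D` in the size `S` | 0.5 |
| `R` | repair capacity | `π⁻¹` (decline) or `inf` (unlimited) |
| `re` | retention factor | 0.2957 |
| `s` | size proportion kept by the mother | 0.64 |
| `P_div` | division threshold on `P` | 0.5 |
| `D_death` | death threshold on `D` | 1.0 |
| `D_health` | health-span threshold on `D` | 0.5 |
| `σ` | random-effect standard deviation | 0.005 |

`s = 0.64` is pinned by the no-retention division split (64% of damage to
the mother); `re = 0.2957` is the retention wildtype anchor; `k1 = 0.4` is
the reference damage-formation rate, small enough that retention and
no-retention lineages can be compared yet short-lived enough to simulate
cheaply.  `D_health = 0.5` sits midway through the damage range; thresholds
near 0 or 1 degenerate (every cell looks healthy or none does).

The remaining base values — `g = 2.0`, `Q = 0.5`, `P_div = 0.5`, and the
pairing of `D_death = 1.0` with the domain of `r` — are **repository
calibration**: they were fixed, once, so that the wildtype surface behaves
correctly at the anchor point, namely (i) a damage-free founder at
`k1 = 0.4` reaches the wildtype lifespan of 24 divisions for retention
factors inside `(0, 1)` in both capacity regimes, (ii) cells with neither
repair nor retention are mortal (rls 8), so no-retention arms are finite and
comparable, and (iii) the calibrated repair rates at `re = 0.2957` land at
`k2 = 0.133` (decline) and `k2 = 0.091` (unlimited), close to the shipped
anchors 0.138 / 0.092.  With the shipped anchors the calibrated retention
factors are `re* = 0.312` (decline) and `re* = 0.300` (unlimited), each
giving exactly 24 divisions.

A founder with *average initial conditions* is the damage-free newborn of an
average division: `P₀ = (1−s)·P_div`, `D₀ = 0`.

## Wildtype calibration

`simulate_rls` counts the divisions of one damage-free founder at `σ = 0`;
a founder that outlives the caps (1000 divisions or 10⁴ time units) returns
an immortal sentinel, which orders above every finite lifespan.  The rls is
non-increasing in `re` (retaining damage loads the mother) and
non-decreasing in `k2`; both monotonicities are checked, not assumed, and
violations are logged as anomalies.  Because rls is integer-valued, the set
of `re` attaining the target is an interval; `calibrate_re` bisects both
edges of that plateau (tolerance 1e-7, ≤ 60 iterations per edge) and returns
the midpoint — representative and reproducible.  `calibrate_k2` is the
orthogonal mode, adapting the repair rate at fixed retention.
`build_wildtype_grid` tabulates `re*` over a `(k1, k2)` grid with spacing
0.005, marking infeasible points rather than raising.  Feasible-region
comparison on the shipped window (`k1 ∈ [0.4, 0.5]`) shows the decline
regime covering more grid points than the unlimited regime; note that at
any *single* shared `(k1, k2)` point decline repair is pointwise weaker
(`sin x ≤ x`), so the robustness gain is about the extent of the surface
(its reach into high `k2` and high `k1`), not set inclusion.

## Population engine

Lineages grow through a birth-time-ordered event queue (equivalent to the
recursive definition, bounded memory).  Every born cell is simulated to
death or cap; caps are a maximum pedigree generation (daughters beyond it
are not spawned), a spawn-time horizon (for growth-rate snapshots), a cell
budget, and per-cell division/lifetime caps.  Cells still alive at a cap are
flagged censored, and lifespan-based metrics exclude them.  Each cell's
random effects come from an RNG substream keyed by (seed, founder index,
lineage position), so results are invariant to traversal order, reruns are
byte-identical, and experiment arms sharing a seed use common random
numbers — a stress arm multiplies `k̄1` by its factor while every cell's
`η` draw is unchanged, so sampled rates scale exactly.

## Experiment defaults

Experiment arms always sit on the wildtype surface ("matched rls"): at each
retention factor the repair rate is re-calibrated to the 24-division target
for its regime, so arms differ in strategy, not founder lifespan.  Infeasible
(re, regime) pairings are skipped with a log entry.  Shipped designs use
5 founders (10 for stress and division-age protocols, 20 single-founder
populations for growth-rate distributions), `σ = 0.005`, a snapshot time of
8.0, a stress multiplier of 1.01 on `k̄1`, and a default pedigree depth of
2 generations — deep enough for grandmother-resolved `(i, j)` grouping while
keeping a five-founder population near ~3·10³ cells; founder counts and caps
are recorded in every output's manifest.

## Numerical choices

- Reference integration: scipy `solve_ivp` (RK45, rtol 1e-8, atol 1e-10)
  with event functions for division, death and the first health-threshold
  crossing; event times are root-refined by the solver.
- Production engine: a numba-compiled Dormand–Prince 5(4) loop with the same
  tolerances.  Events are located on the cubic Hermite interpolant of an
  accepted step, but only after the step size has been shrunk to ≤ 1e-6
  around the crossing, so interpolation error is negligible; the two engines
  agree to ~1e-5 in event times over a full 24-division life and exactly in
  rls (pinned by tests against a fixed-step RK4 oracle at dt = 1e-4).
- Tie-break: if division and death are located within 1e-9 of each other,
  death wins (instantaneous events cannot meaningfully co-occur).
- The sine argument `D/R` is clamped to `[0, π]`: on the admissible domain
  it exceeds π only by floating-point overshoot, and the clamp pins the
  boundary value `r(1; R = π⁻¹)` to exactly 0 while keeping repair
  non-negative under solver overshoot.
- Health span of a sterile cell (rls = 0): the division factor `rls_c/rls`
  is defined as 1, leaving `h` the pure time fraction.
- The mean rls scaling the rejuvenation index is taken over uncensored cells
  including founders (configurable).
- Sizes entering growth-per-cycle are the *pre-split* sizes at each division.
- A cell born at or above a threshold has that event at birth (health: `t_c
  = t_0`; death: immediate, rls 0).

## What the simulations do and do not emulate

The generator reproduces the study conditions — wildtype-calibrated
founders, log-normal rate variability, asymmetric division with retention,
the two capacity regimes, mild stress — and the qualitative population
behaviour that follows (larger, less variable populations with retention;
shorter generation times and longer health spans under declining capacity).
It does not model mechanistic retention (aggregate transport, bud-neck
diffusion), nutrient limitation, cell–cell interaction, variable `s` or `re`
within a life, or death causes other than damage.  Passing tests therefore
certify the model's internal logic and this parameterisation's behaviour,
not quantitative agreement with any particular wet-lab dataset; the
non-dimensional base here is the package's own calibration, and lifespans,
times and sizes are in model units, not minutes or femtolitres.

## Known limitations

- The two-parameter tuning goal (both regimes' calibrated `k2` exactly at
  0.138/0.092 with `re* = 0.2957`) is met approximately (0.133/0.091); the
  mapping between this base and any other non-dimensionalisation of the same
  dynamics is not unique.
- Directional population claims are regression-tested on shipped seeds and
  the shipped configuration; they are properties of this parameter region,
  not theorems.
- Near the immortality boundary (high `k2` at low retention) lifespans are
  steep in the parameters; censoring caps keep runs finite but mean-lifespan
  statistics there are cap-sensitive.
- The Newick export marks censored lives with a bracket comment; readers
  that strip comments lose the censoring flag (the CSV table retains it).
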