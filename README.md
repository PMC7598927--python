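# rejuvasim

Replicative ageing in budding yeast (*Saccharomyces cerevisiae*), simulated
from single-cell protein-damage dynamics up to whole, explicitly pedigreed
cell lineages.  The package is aimed at systems-biology work on ageing:
it lets you ask how a cell's damage *repair* strategy and its damage
*retention* at division shape lifespans, rejuvenation and health across an
entire population, with every mother–daughter relation known — something
wet-lab lineage tracking cannot currently deliver at depth.

## Model

Each cell carries functional protein `P(t)` and damaged protein `D(t)`
(non-dimensional, `D ∈ [0, 1]`), evolving between events as

```
dP/dt = g·P·(1 − S) − k1·P + r(D)        S = P + Q·D
dD/dt = k1·P − r(D)                      r(D) = k2·R·sin(D/R)
```

with growth factor `g`, damage formation rate `k1`, resilience `Q`
(how strongly damage inflates the growth-inhibiting size `S`), repair rate
`k2` and repair capacity `R ∈ [π⁻¹, ∞]`.  `R → ∞` gives damage-proportional
repair (`r = k2·D`, *unlimited* capacity); `R = π⁻¹` gives repair that is
efficient at low damage but collapses to zero as `D → 1` (*decline* in
capacity).  Division fires when `P` reaches `P_div` and instantaneously
splits both pools: the mother keeps the size fraction `s` of `P` and the
fraction `s + re·(1−s)` of `D`, where `re ∈ [0, 1]` is the retention factor.
Death fires when `D` reaches `D_death`.  Daughters recursively found their
own branches; each newborn draws individual rates
`k1 = k̄1·exp(η1)`, `k2 = k̄2·exp(η2)` with `η ~ N(0, σ²)` (log-normal mixed
effects).

Per cell the package computes the replicative lifespan (rls), lifetime,
generation times, growth per cycle `S(t_n)/S(t_{n−1})`, cumulative growth,
the rejuvenation index `rej = Δrls / mean rls` (daughter minus mother), and
the health span `h = [(t_c−t_0)/(t_d−t_0)]·[rls_c/rls]`, where `t_c` is the
first time damage reaches a health threshold.  Per population: size, rls
mean/dispersion, fractions of rejuvenated and healthy cells, and an early
growth proxy (cells born by a snapshot time).

*Wildtype* parameter sets are calibrated so an initially damage-free founder
divides exactly 24 times: on a `(k1, k2)` grid with spacing 0.005 the
retention factor is adapted by bisection (`calibrate_re`), or, holding `re`
fixed, the repair rate is adapted instead (`calibrate_k2`).

## Worked example

```python
import rejuvasim as rj
from rejuvasim.metrics import population_summary

params = rj.wildtype_params("decline")            # k1=0.4, k2=0.138, R=1/pi
re_star = rj.calibrate_re(0.4, params.k2, params.R)
print("re* = %.4f" % re_star)                     # re* = 0.3118
print("rls =", rj.simulate_rls(params.with_updates(re=re_star)))   # rls = 24

design = rj.ExperimentDesign(n_founders=5, seed=1)
table = rj.run_wildtype_population(design, regime="decline", re=0.2957)
pop = population_summary(table, h_c=0.5, snapshot_time=8.0)
print(pop.population_size)            # 2817
print("%.2f" % pop.mean_rls)          # 22.30
print("%.3f" % pop.fraction_rejuvenated)  # 0.443
print(pop.growth_rate_proxy)          # 230 cells born by t = 8.0
```

The calibration says: at damage formation rate 0.4 under declining repair
capacity, a retention factor of 0.312 pins the founder lifespan at 24
divisions.  The five-founder retention population (2817 cells to pedigree
depth 2) keeps a high mean lifespan (22.3) and 44% of its cells outlive
their mothers — run the same lines with `re=0.0` and the population shrinks
to ~2500 cells with a wider lifespan spread, the signature benefit of
damage retention.

The same machinery is scriptable from a shell:

```
rejuvasim simulate  --out runs/wt --seed 1
rejuvasim calibrate --k1-range 0.4 0.45 --k2-range 0.10 0.16 --regime decline --out runs/grid
rejuvasim metrics   --lineage runs/wt/lineage.csv --out runs/wt
rejuvasim experiment retention-sweep --seed 1 --out runs/sweep
```

All outputs are plain delimited text (lineage tables, Newick trees, metric
tables) plus a JSON run manifest with the config snapshot and seed.

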