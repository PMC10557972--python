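# aedplace

Spatio-temporal placement of automated external defibrillators (AEDs) —
or any point facility — when demand moves over the day.

## The problem

Out-of-hospital cardiac arrest is survivable largely to the extent that a
defibrillator can be fetched within minutes, so AEDs should sit where
people actually are. But "where people are" changes by the hour: a
placement tuned to the 14:00 crowd can serve the 6:00 crowd poorly.
`aedplace` treats placement as a *maximal covering location problem*
(MCLP) solved once per time period and then stress-tests every period's
solution against every other period's demand, selecting the site set
that is most robust across the whole day.

For each period *h* with demand points *i ∈ I_h* (weights *a_i*) and
candidate sites *j ∈ J*, the per-period program is

```
max  z_h = Σ_i a_i y_i
s.t. Σ_{j ∈ N_i} x_j ≥ y_i        N_i = { j : d_ij ≤ S }
     Σ_j x_j = k,   x_j, y_i ∈ {0,1}
```

where *S* is the service distance (default 100 m, the on-foot retrieval
distance used in AED guidance) and *k* the budget. The overlay stage
computes the coverage rate *R[h, h′]* of period *h′*'s solution on period
*h*'s demand, averages each column into an *average performance*
*N[h′] = mean_h R[h, h′]*, and selects *ĥ = argmax N*. A cost–coverage
analysis then re-optimizes on period *ĥ* over a grid of budgets and
reports the marginal coverage gain per added facility.

The exact solver is HiGHS branch-and-bound (`scipy.optimize.milp`) with
zero optimality gap; a greedy heuristic with the (1 − 1/e) submodular
guarantee scales to large instances. Demand can be built from
POI-visit tables either as count-weighted points or by spreading each
visit uniformly into a walking circle (default radius 414.3 m: five
minutes at a comfortable 138.10 cm/s gait). Spatial-clustering
diagnostics (kernel density surfaces, standard deviational ellipses)
explain *why* some hours cover better than others, and a synthetic-city
generator produces realistic test data with a diurnal visit curve and
hour-varying spatial concentration.

## Worked example

```python
from aedplace.synth import SynthConfig, generate_city
from aedplace.model import SpatioTemporalPlacement

cand, visits = generate_city(SynthConfig(
    n_pois=60, n_candidates=25, periods=6, mean_visits=5.0,
    extent=(4000.0, 4000.0), core_dispersion=500.0, seed=7))
model = SpatioTemporalPlacement.from_tables(
    visits, cand, S=400.0, k=3, jitter=False, projected=True)
res = model.fit()
print(res.summary())
```

```
Spatio-temporal facility placement
==================================================
periods:            6
candidate sites:    25
budget k:           3
service distance S: 400.0 m
solver:             exact
--------------------------------------------------
period  own_rate  avg_performance  perf_se
     0    0.3226           0.4381   0.0473
     1    0.3399           0.4700   0.0622 <- selected
     2    0.5365           0.4700   0.0622
     3    0.7074           0.4700   0.0622
     4    0.5466           0.4700   0.0622
     5    0.3843           0.4381   0.0473
--------------------------------------------------
selected period:    1
avg performance:    0.4700
sites: site00001, site00011, site00014
```

`own_rate` is each period's own optimized coverage (the overlay
diagonal): period 3, the synthetic afternoon peak with the most
concentrated demand, covers 70.7% of its own visitors, but several
periods share the identical, more dispersed site set and tie on the
cross-period average of 47.0%; the tie resolves to the earliest period.
Note the peak hour is *not* selected — clustered demand yields a high
own-hour rate but a site set that travels poorly to other hours.

```python
print(res.cost_curve([1, 2, 3, 4, 5]).to_frame().to_string(index=False))
```

```
 k  performance  increment
 1     0.204551        NaN
 2     0.350458   0.145907
 3     0.469966   0.119507
 4     0.535556   0.065590
 5     0.586236   0.050680
```

Each row re-optimizes at budget *k* on the selected period's demand and
averages coverage over all periods; the shrinking increments show the
diminishing return per added device.

A command-line interface mirrors the library
(`aedplace synth | optimize | osto | curve | diagnose | relocate`);
`aedplace relocate` evaluates an existing facility file's average
performance and re-optimizes with the same number of sites.

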