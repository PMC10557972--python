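# Methods

## Model

Coverage is binary and distance-based: a facility at candidate site *j*
covers demand point *i* exactly when the planar Euclidean distance
*d_ij ≤ S*, boundary inclusive. Each period *h* contributes a weighted
point set *I_h*; the per-period problem is the classic maximal covering
location problem (MCLP): choose exactly *k* of the candidate sites *J*
to maximize the covered weight *Σ a_i y_i* subject to
*Σ_{j∈N_i} x_j ≥ y_i* and *Σ x_j = k* with binary variables, where
*N_i = {j : d_ij ≤ S}*.

The two-stage overlay procedure then (1) solves the MCLP once per
period, and (2) evaluates every period's solution on every period's
demand, producing a T×T rate table *R* whose rows index demand periods
and whose columns index solutions. A solution's *average performance*
is the unweighted mean of its column, and the selected solution is the
column argmax. The diagonal of *R* holds each period's own optimized
rate; with an exact solver every row must attain its maximum on the
diagonal (the diagonal entry is the row's optimum), and the package
asserts this on every exact run. The cross-solution spread of
performances is necessarily no larger than the worst within-row spread
of rates, since each performance is a mean of one row entry per row.

Euclidean distance is a deliberate simplification: street networks,
building interiors and vertical travel all lengthen real retrieval
paths, so reported coverage rates are optimistic upper bounds.
Road-network distances are out of scope.

## Solvers and determinism

The exact backend formulates the integer program sparsely and solves it
with HiGHS branch-and-bound (`scipy.optimize.milp`) at zero relative MIP
gap. Demand points sharing an identical cover set *N_i* are aggregated
into one coverage variable with summed weight before solving; this is
an exact reduction and is what makes jittered unit-weight instances
(thousands of points, few distinct cover sets) tractable. Points with
empty *N_i* are uncoverable; they are excluded from the program but
retained in totals, so they depress attainable rates rather than
disappearing.

MCLP optima are frequently non-unique. For reproducibility the package
reports the lexicographically smallest optimal site set whenever
enumerating C(|J|, k) subsets is affordable (up to 20,000 combinations);
beyond that the solver incumbent is returned flagged `canonical=False`.
The brute-force oracle enumerates subsets in the same lexicographic
order, so exact and oracle solutions agree site-for-site on small
instances, not merely in objective. Greedy ties also resolve to the
smallest site id. Average-performance ties select the earliest period
label.

The greedy solver runs *k* rounds of maximum-marginal-gain selection;
by submodularity of coverage its objective is at least (1 − 1/e) ≈ 0.632
of the optimum, and along its own trajectory marginal gains are
non-increasing. No such concavity claim is made for a sequence of
independent exact optima, where only monotonicity in *k* and in *S*
holds.

Empty-demand periods are handled by convention: an MCLP over no demand
returns the k smallest site ids with objective 0 and a warning, and an
empty period's coverage rate is vacuously 1.0. By default such periods
stay in the performance mean (the mean is unconditional over periods);
an option excludes them.

## Demand construction

A POI visit table (`poi_id, x/lon, y/lat, hour, visits`) becomes
per-period demand in one of two ways. *Jitter* mode emits one
unit-weight point per visit, placed uniformly by area
(r = R√u, θ = 2πu′) in the closed walking circle around the POI — the
circle's default radius, 414.3 m, is five minutes at a comfortable adult
gait of 138.10 cm/s, reported at 0.1 m resolution. *Aggregate* mode
keeps one point per POI weighted by its count; it is exactly the jitter
model with radius 0 up to point multiplicity and is the cheaper default
in the tests. Jittered instances can be thinned by a uniform
without-replacement sample (default fraction 1/6 in the run
configuration); the companion `compute_sample_size` helper turns an
annual visit total into a daily one-in-six sample size by truncating
toward zero. Whether such a sample should be drawn once from average
daily visits or day-by-day is ambiguous in general; the package exposes
a single-draw fraction sampler and leaves day-stratified schemes to the
caller.

Longitude/latitude inputs are projected to a local spherical
transverse-Mercator frame centered at the data centroid (hand-rolled
closed form; the sphere inverse is exact, so round-trips are at machine
precision and planar distances are faithful to well under 1% at city
scale). Inputs may declare themselves already projected. Period labels
are serialized 0–23; one-based hour labels map down by one.

## Diagnostics

The kernel density surface sums unit-mass Gaussian kernels on a regular
grid (default spacing 250 m, default bandwidth Silverman's rule on the
pooled coordinates, grid padded four bandwidths beyond the data extent
so mass is conserved within 1%). The implementation evaluates the
separable kernel product; tests verify it against direct per-cell
summation to 1e-9.

The standard deviational ellipse uses the Yuill closed form with
denominator *n*: center at the coordinate means, semi-axes equal to the
square roots of the eigenvalues of the scatter matrix of centered
coordinates, rotation the major-axis direction in [0, π), axes scaled
linearly by an `n_std` multiplier. Under this convention the 1-SD
ellipse of a bivariate normal contains 1 − e^(−1/2) ≈ 39.35% of the
mass — not the one-dimensional 68% sometimes quoted for such ellipses —
so the package reports the empirical inclusion fraction rather than
asserting any nominal level. Collinear inputs are rejected.

## Synthetic cities

The generator emulates the structure of mobility-derived POI visit
data. POI locations are drawn once per city — a compact Gaussian core
(default SD 1 km, 35% of POIs) over a uniform background in a
10 km × 10 km extent — and held fixed across periods. Hourly totals
follow a fixed 24-value diurnal profile with its maximum at 14:00 and
local minima at 06:00 and 22:00; hourly spatial concentration follows a
parallel profile moving between 25% (night) and 80% (afternoon) of
expected visits onto core POIs. Counts are Poisson around these rates.
Candidate sites are drawn uniformly, with half placed on POI locations.
Defaults (500 POIs, 300 candidates, mean 20 visits/POI-period) keep
exact MCLP at small budgets interactive.

What the generator does *not* emulate: real magnitudes (hundreds of
millions of annual visits, tens of thousands of candidates), street
networks, land-use exclusions, weekday/weekend structure, or
heavy-tailed venue popularity (counts are Poisson, not gamma-Poisson).
Passing tests therefore demonstrate correctness of the optimization and
overlay machinery under controlled spatiotemporal heterogeneity, not
calibrated predictions for any real city.

A deterministic worked example (four collinear demand points, three
candidates, two periods) ships with fully hand-computed expectations —
cover sets, optima at k = 1 and 2, the 2×2 overlay matrix
{1.0, 1/3; 0.0, 2/3}, performances (2/3, 1/3) — and anchors the
end-to-end tests.

## Cost–coverage analysis

For a budget grid, the site set is re-optimized on the selected
period's demand at each *k* and its coverage averaged over all periods;
increments are successive performance differences divided by Δk. The
selected period is recomputed per budget on request rather than assumed
budget-invariant. A penalized cubic smoothing spline
(`scipy.interpolate.make_smoothing_spline`) is offered for presentation
only — smoothing never feeds selection — with the documented limits
(penalty → 0 interpolates, penalty → ∞ tends to the least-squares
line). The plateau budget is reported as the smallest *k* whose forward
increment falls below a configurable threshold (default 1e-4 per
facility). Budget steps are configurable; analyses of real stocks
typically step by 100 devices, toy tests by 1.

## Problem sizes in the checked runs

The solver-equivalence suite uses 100 random instances with up to 30
demand points, 10 candidates and k ≤ 3, where exhaustive enumeration is
exact and cheap. The overlay-dominance sweep uses twenty 24-period
cities of 30 POIs and 12 candidates at k = 3 and S = 400 m with the
exact solver, chosen so each city solves in well under a second while
exercising the full T×T overlay. Ellipse recovery uses n = 5,000
points (rotation within 2°) and n = 100,000 for the inclusion-mass
check.

## Known limitations

Binary coverage ignores partial or gradual accessibility; the model is
uncapacitated (a site serves unlimited demand); Euclidean distance
overstates coverage relative to network travel; selection maximizes the
mean across periods (a utilitarian criterion) — min-gap or equity-aware
selection rules are not implemented; and the sampling helper does not
stratify by day.
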