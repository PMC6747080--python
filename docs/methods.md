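# Methods

`netpatterns` analyzes point events that are constrained to a road
network — health care facilities, patients, and similar urban phenomena —
using shortest-path (network) distances throughout. This note documents the
models, the parameter choices, the synthetic data generator, and the
numerical conventions.

## The network metric space

Road centerlines become an undirected planar graph: polyline endpoints
within a snap tolerance (default 0.5 m) merge into nodes; each polyline is
one edge with its geometric length. Edges carry no direction, travel time,
or capacity — all segments are treated equally, which is a deliberate
simplification (one-way streets and traffic weighting are out of scope).
Events are linear references `(edge, offset)`; off-network points are
projected to the nearest edge and excluded beyond a maximum snap distance
(default 500 m), with counts reported. Both tolerances are design defaults,
configurable per call, since no canonical rule exists for them.

Distances between interior points are exact: a shortest path either stays
on a shared edge or leaves through one of the two endpoints of each point's
edge, so the distance is the minimum of the direct along-edge path and the
four endpoint routings through the cached all-pairs node distance matrix
(Dijkstra on the edge-length-weighted graph). This makes Monte Carlo
re-evaluation cheap: after one matrix computation per network, each
realization costs a vectorized minimum over four index lookups. Ties
(equidistant snaps, equal-length components) resolve to the lowest id for
determinism.

Density is evaluated on *lixels*: each edge split into
`ceil(length / lixel_length)` equal pieces (default nominal length 100 m,
matching the raster cell size), so no evaluation unit exceeds the nominal
resolution and lixel lengths sum exactly to the network total.

## Network kernel density estimation

The intensity at a lixel center `s` is

    lambda(s) = sum_i (1/r) * (1/sqrt(2 pi)) * exp(-dis_i^2 / (2 r^2)) * w_i

over events with network distance `dis_i <= r`; events beyond the bandwidth
contribute exactly zero. At `dis = 0` the kernel takes its continuous limit
so an event contributes at its own location. Three conventions to be aware
of:

* **No renormalization.** The estimator is a truncated kernel sum, not a
  probability density; its integral depends on bandwidth and weights.
* **No intersection correction.** There is no equal-split of kernel mass at
  junctions, so density near high-degree nodes is biased upward relative to
  corrected estimators. This is the estimator as specified; the bias is
  known and documented rather than patched.
* **Weights.** Hospitals are weighted by bed number; community health
  centers, clinics and pharmacies carry fixed tier weights 20 / 10 / 1
  reflecting service capacity. Default bandwidths are 1000 m for hospitals
  (wide catchment) and 500 m for the primary-care tiers.

Fields are evaluated on lixels and then transferred to a regular raster
(default 100 m cells) by the length-weighted mean of intersecting lixel
portions, which conserves the field's scale; cells touching no lixel are
nodata. Display classification uses five Jenks natural-breaks classes.
Whether to evaluate on lixels first and rasterize after (our choice) or to
evaluate directly on near-road cells is genuinely open; lixel-first keeps
the analysis intrinsically one-dimensional on the network and makes the
community aggregation resolution-independent.

## Network K-functions and CSR envelopes

With `n` points on a network of total length `S`, the pointwise K-function
is `K(t|p_i) = n(t|p_i) / rho`, `rho = (n-1)/S`. We report the global curve
as the average of the pointwise values (standard network-K practice), so
auto-K is nondecreasing and saturates exactly at `S` beyond the network
diameter. Cross-K counts target points within `t` of each base point with
`rho = n_target / S` and no self-exclusion. Point weights are ignored: the
K analysis concerns locations only.

The null is complete spatial randomness on the network: points i.i.d.
uniform over the union of edges (edge chosen proportional to length, offset
uniform). Envelopes are pointwise empirical `alpha/2` and `1 - alpha/2`
quantiles over Monte Carlo realizations (default 200 for tests, 1000 for
production runs; `alpha = 0.05`). For cross-K the base set stays fixed and
only targets are randomized — the question posed is whether patients
cluster around the (given) facilities. Observed K above the upper bound
reads as clustered, below the lower as dispersed, inside as random; the
summary label is the regime covering the largest measure of the t-range.

Two limitations are intentional: envelopes are pointwise, not global rank
envelopes, so the significance level does not control the familywise error
over all `t`; and the band width converges to the true interquantile
distance as simulations grow — more simulations stabilize the bounds, they
do not narrow them. The default distance grid is 50 equal steps from 0 to
`min(10 km, half the network diameter)`.

Per-district analyses clip the network at district polygons, keeping split
edge fragments; the clipped network may be disconnected, and distances
across components are infinite (such pairs are simply never counted).

## Geodetector

For a response `Y` over `N` units stratified into `L` strata,

    q = 1 - sum_h N_h sigma_h^2 / (N sigma^2)

with population variances (denominators `N_h` and `N`), under which the
sum-of-squares and variance forms of q coincide to machine precision. q is
0 under no stratified heterogeneity, 1 under full stratification, and is
invariant under affine rescaling of `Y`. Significance uses a label
permutation test, `p = (1 + #{q* >= q}) / (n_perm + 1)` — an explicit
substitute for the classical noncentral-F reference distribution, and
labelled as such in outputs. Note the permutation p-value has a floor at
small `N` (with 4 units and 2 balanced strata it cannot drop below ~1/3).

Continuous covariates are stratified with exact Fisher–Jenks natural
breaks: an `O(k n^2)` dynamic program minimizing total within-class sum of
squared deviations (not a heuristic). Breaks are reported as ascending
class maxima; intervals are `(lower, upper]` with the lowest class closed
below, and values above the training maximum fall into the top class with
a warning.

The interaction detector compares `q` of the intersection stratification
(distinct label pairs; empty pairs drop out) with the two factor q values:
below the minimum is nonlinear weakening, between minimum and maximum
uni-factor weakening, above the maximum but below the sum bi-enhancement,
equal to the sum independence, above the sum nonlinear enhancement.
Equalities are resolved by exact comparison at 1e-12; equality with the
maximum is reported as non-enhancing (a refinement that adds nothing). For
true intersections `q(A ∩ B) >= max(q_A, q_B)` always — the intersection
refines both partitions — so only the enhancing categories can occur there.

## Community aggregation

Per community polygon: area, population density (per km²), road length
(edge geometry intersected and apportioned at boundaries) and road density
(m per km², the default reading of "road density"; raw length is also in
the table), plus the sum of per-lixel NetKDE values apportioned by the
length fraction inside the polygon. Lixel-based aggregation avoids
raster-resolution artifacts and conserves partition sums exactly; summing
raster cells instead is possible by rasterizing first. Overlapping
community polygons are rejected.

## The synthetic city

No real facility registry, patient records, or road network ship with the
package, so every analysis is exercised on a seeded synthetic city:

* **Network**: a jittered grid (default 30x30 nodes, 400 m spacing, 30 m
  jitter) with edges kept with probability 0.85, reduced to its largest
  connected component — a city-block street fabric with gaps.
* **Communities**: a square tiling (default 1.2 km cells, about 100
  communities) with log-normal populations (log-mean 10.4, log-sd 0.6)
  boosted by Gaussian bumps around two hot-spot centers (amplitude 3,
  decay 2.5 km) — a dense core and sparse periphery.
* **Facilities**: four tiers with counts 20 / 43 / 118 / 319 (hospitals /
  CHCs / clinics / pharmacies, about 500 total, preserving the tier
  proportions of a large hierarchical system at roughly 1/17 scale). Edge
  selection mixes length-uniform and population-proportional components
  (mixing weight `population_coupling`, default 0.7). Hospital bed numbers
  come from a two-part mixture — a configured count of tertiary hospitals
  (>= 1000 beds, default 2) plus log-normal small hospitals — and, when
  coupling is on, the largest bed counts are assigned to the
  highest-density locations, mirroring the concentration of tertiary
  hospitals in real urban cores. With coupling 0 facilities are CSR and
  beds are placed at random.
* **Patients** (default 2000): with probability `background_fraction`
  (default 0.2) CSR on the network; otherwise anchored at a uniformly
  chosen facility and displaced by a network random walk of exponential
  length (mean `clustering_decay`, default 200 m), turning uniformly at
  intersections. Displacement is along the network, not planar, so the
  clustering signal specifically tests the network metric. The walk length
  upper-bounds the shortest-path distance to the anchor, making the decay
  parameter an upper bound on the induced clustering scale.

Each generator stage draws from its own stream derived from the config
seed, so outputs are reproducible stage-by-stage. What the generator does
*not* emulate: realistic street morphology (no arterials, no curvature),
within-community population gradients, facility capacity constraints, or
any health-seeking behavior — so passing recovery tests demonstrate that
the estimators detect the *kind* of structure they target (network-scale
clustering, population-coupled intensity), not that they reproduce any
particular city's numbers.

Problem sizes in the test suite are scaled-down versions of the default
city (10x10 grids, hundreds of points, 99–200 Monte Carlo realizations,
199 permutations), chosen so the full suite completes in a few minutes;
the recovery checks that need statistical power (the geodetector
seed-fraction test) run at the default city scale with 50 seeds per arm.

## Known limitations

* Kernel density carries the uncorrected intersection bias described above.
* Pointwise envelopes invite multiple-testing over the t-grid; treat per-t
  labels as descriptive and the summary label as the headline.
* The permutation test replaces, and does not approximate, the noncentral-F
  geodetector test; p-values differ especially at small stratum counts.
* Geographic (lon/lat) input is rejected by a coordinate-range heuristic,
  not a CRS database; supply projected meter coordinates.
* Very large networks are limited by the dense all-pairs node distance
  matrix (memory grows with the node count squared).
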