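# Methods

`foodexposure` implements a household-level food-environment exposure
analysis of the kind used in spatial epidemiology: exposure areas are
delineated on a street network, food-outlet indicators are computed inside
them, survey weights are calibrated by raking, and weighted regression
models relate exposure to household characteristics — once for a
conventional home-centric measure and once for an activity-space measure, so
the two can be compared. Because survey microdata of this kind are never
public, the package ships a synthetic-city generator that reproduces the
statistical structure the analysis assumes, and the whole pipeline runs
end-to-end on it.

## Exposure areas

**Home buffer.** The service area within 500 m of network travel distance
from the home. The home is snapped to the nearest edge (tolerance 30 m,
`SnapError` beyond); shortest-path distances from the snapped point are
computed by Dijkstra; every edge point within the radius is retained,
truncating partial edges at the exact residual distance. GIS tools
polygonize service areas in tool-specific ways; here the reachable
sub-network is buffered at a configurable half-width (`edge_halfwidth_m`,
default 25 m) and unioned, which is reproducible and resolution-controlled.
Buffer areas are therefore monotone in both the radius and the half-width.

**Activity space (daily path area).** The union of:

1. the home service area;
2. a 500 m network service area around every anchor point (a weekly activity
   location reported with its usual transport mode, at most two per adult);
3. a Euclidean corridor around the fastest route from home to each
   non-transit anchor — half-width 100 m for walking/cycling, 300 m for
   car/motorcycle/scooter;
4. the same corridor between the two anchors of one adult when both are
   visited by the same non-transit mode.

Public-transit trips contribute no route corridor (the traversed route is
unknown) but their endpoint service areas are retained: the visited
neighborhood is exposure regardless of how it is reached. Anchor points are
equally weighted; no time weighting is applied. With this composition the
activity space always geometrically contains the home buffer, which the
tests assert, and downstream count/diversity indicators are monotone
between the two measures.

"Fastest path" reduces to shortest path: all modes share one uniform-speed
network, and without a speed model per-mode routing would not change the
geometry. A per-edge `length_m` attribute is the single routing weight, so a
travel-time weighting can be substituted by rescaling it.

Numerical choices: route/corridor buffers use 32 arc segments per quadrant
(cap-area discretization error ~1e-4 relative); polygons are repaired with a
zero-width buffer after every union; shortest-path ties are resolved
deterministically by the traversal order of the stored graph, which is fixed
by construction order; points on a polygon boundary count as inside (closed
region).

## Indicators and coding

Ten outlet categories: eight store types (butcher, bakery, drive-through
supermarket, fish shop, greengrocer, grocery store, market, supermarket) and
two restaurant groups (traditional, fast food; cafeterias are fast food).
Fruit-and-vegetable (F&V) sellers are the five produce-stocking store types
(drive-through supermarket, greengrocer, grocery store, market,
supermarket).

Per household × area kind, five indicators: number of food stores, number
of restaurants, diversity (distinct store categories, 0–8), relative F&V
density (F&V stores / all stores), relative fast-food density (fast-food /
all restaurants). A ratio with an empty denominator is undefined and is
coded into the *below 50 %* class.

Codings: store and restaurant counts are cut at the sample's 1/3 and 2/3
quantiles, computed on the unweighted sample and separately per area kind
(the two distributions differ by an order of magnitude); intervals are
right-closed, so a value equal to a boundary falls in the lower class.
Diversity uses fixed bands 0–2 / 3–5 / 6–8. Ratios are cut at 50 % with the
upper class closed (≥ 0.5). A constant count column (e.g. a city with no
outlets) yields a single class rather than an error; a non-constant column
that still produces an empty tertile raises `DegenerateDistributionError`.

## Survey weights

Raking ratio (iterative proportional fitting) over two calibration
variables: income per consumption unit (four quartiles plus a retained
"refuse to answer" category) and household composition crossed with the age
group of the household head (4 × 3 cells). Defaults: tolerance 1e-6 on every
weighted marginal proportion, 200 iteration cycles, no trimming or bounding.
Weights are normalized to mean 1 so the weighted sample size equals the raw
n and model degrees of freedom stay comparable. A margin category with a
positive target but no sample members raises `EmptyCellError` — with 12
cross cells this effectively requires samples of a few hundred households,
which is why test fixtures use n ≥ 200.

## Regression stage

`ExposureModel.from_dataframe(...).fit()` returns an `ExposureResults` with
tidy estimates, Wald 95 % CIs, GVIF diagnostics and a `summary()` table.
Families by outcome: 3-class coded counts/diversity → weighted
baseline-category multinomial logit (baseline = lowest class); binary coded
densities → weighted logistic regression; exposure-area size in km² →
weighted least squares with a Shapiro–Wilk residual-normality statistic in
place of a visual qq-plot.

The weighted multinomial MLE is implemented in-package (Newton–Raphson with
analytic gradient and Hessian, backtracking line search, covariance from the
observed information) because no installed library fits a multinomial logit
with continuous case weights; it is cross-checked against statsmodels
`MNLogit` at unit weights in the tests. Quasi-separation (|log-odds| > 30)
raises `SeparationError`; the pipeline then refits with a tiny L2 penalty
(1e-4) and warns.

Covariate screening is a weighted likelihood-ratio test of the
single-covariate model against intercept-only, keeping covariates with
p < 0.2. The LR statistic was chosen over score/Wald alternatives for
consistency with the multivariate likelihood. An empty outcome × covariate
cell triggers the penalized fallback (flagged `penalized`); a constant
covariate is dropped (`degenerate`).

Reference levels follow the convention that the presumptively advantaged or
most common category anchors the contrast: age < 35, education "high school
or lower", employed, one adult, lowest income quartile, no car, city-center
home. Significance is read at p < 0.05 with no multiple-testing correction.
Variances are model-based (the calibration weights are treated as frequency
weights); design-based sandwich variances are deliberately not used, so CIs
describe the weighted-sample fit rather than full design-based uncertainty —
a known limitation.

GVIF follows the determinant-ratio definition on the centered dummy design:
`GVIF_j = det(R_j) det(R_-j) / det(R)`, with the adjusted value
`GVIF^(1/(2 df))` flagged acceptable below 5. For single-df covariates this
equals the classical `1/(1-R²)` VIF, which the tests verify by auxiliary
regressions.

`compare_measures` aligns the home-buffer and activity-space estimate tables
and flags *flips*: covariate levels significant under one exposure measure
but not the other — the phenomenon the two-measure comparison is designed to
surface.

## Synthetic city

The generator states a world; its defaults are not tuned to test outcomes.

* **Network**: perturbed square grid, half-width 3000 m, node spacing 250 m,
  node jitter 10 m. Edge lengths equal endpoint distances.
* **Outlets**: inhomogeneous Poisson process by thinning, intensity
  40/km² at the center decaying as `exp(-d/1500 m)` (decay scale = half the
  grid extent, planting a center-rich periphery-poor gradient). Categories
  i.i.d. from a mix shaped like a French city-region register (bakeries most
  common, one-in-four outlets a traditional restaurant, 10 % fast food).
  Outlets farther than 30 m from the network are moved to the nearest edge.
* **Households**: n = 699. Home-location zones from two radii (1000 m,
  2000 m) with zone shares 0.19/0.41/0.40; car ownership by zone
  (0.55/0.80/0.92, marginally ≈ 0.81); composition (0.33/0.38/0.05/0.24) and
  head's age (0.34/0.30/0.36) independent; education and employment
  conditional on age only; income quartiles 0.2325 each plus 7 % refusal.
  These marginals echo the published descriptive table of the survey this
  design emulates. Each adult reports 0/1/2 anchors with probabilities
  0.2/0.4/0.4 (no canonical value exists; exposed as a parameter), anchor
  locations decay toward the center like outlets (commuting into the dense
  core), and modes are drawn conditionally on car ownership (motorized modes
  only for car owners).
* **Margins**: `true_margins` returns the *generating* distribution of the
  two calibration variables, so raking recovery is exactly testable.
* **Determinism**: one RNG stream per layer (`seed+0/1/2`), bit-identical
  outputs for a given seed and config.

What the generator does *not* emulate: road hierarchies and transit
timetables, selection bias between sample and population (margins equal the
generating distribution, so weights hover near 1 at large n), spatial
autocorrelation of covariates beyond the zone → car → mode chain, and real
French sociodemography beyond category labels. A green end-to-end test
therefore establishes that the pipeline recovers structure that is truly
present, not that any real city behaves this way.

## Scaled-down simulations

To keep the default test run inside a CI budget, two simulation-based tests
run at reduced size with unchanged tolerances: the screening type-I-rate
check uses 300 replicates at n = 800, and the multinomial null-coverage
check uses 200 replicates at n = 300 (the logistic null-coverage acceptance
check keeps its full 500 replicates). The end-to-end gradient-recovery check
runs the full 20 seeds at n = 699 with home-buffer delineation.

## Known limitations

* Model-based (not design-based) variances on a weighted sample, as noted.
* The service-area polygonization half-width is a stand-in for GIS-tool
  output; absolute polygon areas depend on it, though containment and
  monotonicity do not.
* Transit routes are omitted by construction; households relying on transit
  have their exposure along those routes undercounted.
* The linear area-size model uses all covariates without screening (the
  screening test is defined for categorical outcomes).
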