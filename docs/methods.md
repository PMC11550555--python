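# Methods

`zonecast` forecasts the growth of hot-food takeaway outlets inside
school-centred management zones and converts those forecasts into
population-level exposure. This note records the models, the defaults and
their rationale, the numerical choices, and what the synthetic tests do and
do not demonstrate.

## Stage 1: time-series model of zone outlet counts

Quarterly counts of outlets within the (deduplicated, boundary-clipped)
union of 400 m school buffers form the series. Gaps from unobserved quarters
are filled by linear interpolation, flagged, and rejected when they fall at a
series endpoint (no anchor).

**Differencing.** The degree d ∈ {0, 1, 2} is the smallest at which a KPSS
level-stationarity test (short lag truncation `4·(n/100)^0.25`, α = 0.05)
fails to reject. A series still rejecting at d = 2 is used with d = 2 and a
warning — the model is then knowingly misspecified rather than silently
over-differenced. A constant series is accepted as stationary without
testing (the test statistic is 0/0).

**Variance stabilisation.** A Box-Cox transform is applied only when the
standard deviation of the last third of the series exceeds that of the first
third by a factor above 2; λ is chosen by Guerrero's method on blocks of
four quarters. Non-positive values are shifted up first and the shift
recorded. Forecast intervals are back-transformed as quantiles, with no bias
adjustment of the central value — the reported "mean" is then a median. This
keeps lower ≤ centre ≤ upper exactly.

**Estimation and selection.** Every ARMA(p, q) with p, q ∈ 0…5, with and
without a constant (the constant on a differenced scale is drift; it is
excluded at d = 2), is fitted to the d-times differenced series by exact
Gaussian maximum likelihood. The likelihood is computed in the Harvey
state-space representation with stationary initial covariance and the
innovation variance concentrated out; AR/MA coefficients are optimised
through the partial-autocorrelation transform, which keeps the search
unconstrained while every candidate stays stationary and invertible. The
filter loop is numba-compiled: a 72-candidate grid takes ~1.5 s, which is
what makes the 200-replicate recovery experiment and full-protocol
cross-validation refits practical on one CPU. Tests pin this engine to
statsmodels: log-likelihoods agree at identical parameters to 1e-6 and AICc
at the optimum to 1e-3. Selection minimises
`AICc = AIC + 2k(k+1)/(n−k−1)` with k counting all estimated parameters
including the innovation variance; ties break to fewer parameters, then
lower p, then lower q. Candidates the sample cannot identify (n−k−1 ≤ 0)
are skipped, so selection on an 8-observation training set (the shortest the
cross-validation produces) still runs over the estimable orders.

**Diagnostics.** Ljung-Box at lags = min(10, n/5) with degrees of freedom
lags − p − q, floored at one (with a warning when the floor binds); constant
residuals short-circuit to an undefined result with a warning.

**Forecasting.** Point forecasts iterate the transition matrix on the final
predicted state and are integrated d times; variances use the psi-weight
expansion of the integrated process, conditional on estimated parameters (no
parameter-uncertainty inflation — the convention of standard forecasting
software). For the random walk with drift this reduces to the closed form
`ŷ_{n+h} = y_n + h·ĉ` with variance `h·σ̂²`, which tests assert to 1e-8.
Annual reporting extracts the second calendar quarter of each year.

**Cross-validation.** Rolling origin: every observation after the first
`min_train = 8` is a one-off test set; the forecaster is refitted on all
prior observations and scored at horizons 1…min(8, remaining). Errors are
pooled across origins and horizons (a per-horizon breakdown is also
returned); RMSE is the pooled root mean square, and MASE divides the pooled
mean absolute error by the full-series mean absolute first difference. The
pooled convention is a documented choice — averaging per horizon first would
weight origins unequally. The ETS benchmark (additive error; no trend,
additive, or damped additive trend; AICc-selected via statsmodels) runs
through the identical harness.

## Growth transfer

The baseline year is the adoption year minus two, excluding anticipation
effects between announcement and enforcement. Cumulative growth at year y is
`count_y / count_baseline − 1`, applied identically to the estimate and both
95% bounds; adopter projections multiply the adopter's own baseline count by
(1 + rate). The transfer is exactly invertible (tested to 1e-9) and applied
uniformly to every zone in an area — the method deliberately does not model
within-area heterogeneity in growth.

## Stage 2: exposure

**Non-overlapping zones.** A quartic (biweight) kernel density surface of
the baseline-year Q2 outlet snapshot is built on a 100 m grid with an 800 m
bandwidth; each point's kernel integrates to one, and outlets up to 2 km
beyond the study boundary contribute, suppressing edge distortion. The
kernel and bandwidth are package choices: the quartic is the common
desktop-GIS default, and a bandwidth of twice the buffer distance resolves
density contrast between neighbouring schools; both are configurable. Cell
values are classified into three classes by exact Fisher-Jenks natural
breaks (dynamic programming, verified against exhaustive search; ties at a
threshold fall to the lower class). Each school's zone takes the class at
its site's representative interior point (guaranteed inside the site, unlike
a centroid of a concave polygon), same-class zones dissolve together, and
the result is clipped to the boundary.

Residual overlaps between classes are split by the centre-line rule,
implemented as nearest-region allocation: the shared region is rasterised at
10 m and every cell joins the class whose exclusive (non-shared) territory
is nearest, ties to the lower class. A zone wholly contained in others has
no exclusive territory; it keeps its full geometry and the enclosing zones
lose the hole — a high-density island must not be absorbed by its
surroundings, and for two partially overlapping equal discs the rule reduces
to the perpendicular bisector. Union area is preserved within 0.1% (tested
against a 10⁵-sample Monte-Carlo oracle), and point counts are conserved for
points off shared boundaries.

**Exposure spaces.** Home and work domains are 1-mile (1609.344 m) discs
around the population-weighted OA centroids. Routes are shortest
street-network paths between the centroids' nearest nodes, buffered 500 m
for car/motorcycle and 100 m for bicycle/walking. Public-transport
commuters (bus, tram/underground — rail access points, if supplied, are
treated identically through the stops layer) accrue no on-board exposure:
only the walks between home/work and the network-nearest stop, buffered
100 m, count. Shortest paths use Dijkstra keyed on (distance, node id), so
tie-breaking is lexicographic and reproducible regardless of graph insertion
order; nearest stops are chosen by network distance with ties to the lower
stop id. People working from home or within their origin OA have no route
and their home-domain exposure is double-counted. Domains overlap freely
and are summed without de-duplication or time weighting.

**Exposure equation.** Raw OA-pair flows are split by the origin's
parent-LSOA mode shares (OAs are assumed to inherit their LSOA's mode
distribution), keeping fractional counts. Each (flow, zone, domain) term is
`population × count_k × area_intersected / area_k`; totals sum over all
indices and per-capita divides by the total commuting population. The
equation is linear in each zone's count and each flow's population, and
re-partitioning a zone with counts apportioned by area leaves totals
unchanged — the property that makes the non-overlapping-zone derivation
matter; both are tested. Growth projection multiplies baseline per-capita
exposure by (1 + rate), exact because geometry is fixed and the equation is
linear in counts.

## Synthetic data

The generator emulates the study conditions end to end: a square region
(8 km default) with a 500 m lattice street network; 12 disjoint square
school sites, half pulled toward attractor points; a cumulative outlet point
process whose quarterly count follows `baseline + drift·t + N(0, σ)`
(defaults 200 + 2t, σ = 3, 41 quarters — the length of a decade of quarterly
snapshots) with 70% of placements clustered around attractors so the density
surface has genuine high/mid/low structure; 50 OA centroids on network nodes
nested in 10 LSOAs; and gravity-decay commuter flows (weight `exp(−d/2 km)`,
largest-remainder rounding so each OA's workforce of 30 is conserved
exactly). Mode shares default to a census-like split (60% car/van, 12% walk,
11% work-from-home, …) applied uniformly across LSOAs. All layers derive
from one seed through independent RNG streams; identical configuration gives
byte-identical files.

What the synthetic tests show: the selection protocol recovers a known
generating model and its drift; the geometry operations conserve area and
counts; the exposure arithmetic satisfies its invariants; the pipeline is
deterministic. What they do not show: behaviour under real spatial
autocorrelation of outlets with streets, irregular zone geographies,
census-flow sparsity patterns, or outlet churn driven by economics — the
synthetic process is a stylised stand-in, so passing tests validate the
method's mechanics, not its empirical adequacy for any particular area.

## Problem sizes and runtime

The acceptance script uses 200 replicate series of length 41 for parameter
recovery (the modal selected model stabilises well below 200 replicates),
10⁵ Monte-Carlo samples for area oracles, and the default synthetic
configuration (41 quarters, 50 OAs, ~1100 OA pairs) run twice for the
reproducibility check; the whole script completes in a few minutes on one
CPU, dominated by the 200 × 72-candidate ARIMA grids.

## Known limitations

- Non-seasonal models only; no regression-with-ARIMA-errors or saturation
  (tipping-point) dynamics, so long-horizon growth is unbounded.
- Adopter projections inherit the comparison area's interval width; the
  adopter's own baseline-count sampling uncertainty is not propagated.
- Interval transfer and exposure projection assume growth scales every
  zone's count by the same factor.
- The centre-line rule is a geometric convention; other GIS implementations
  (e.g. edge Voronoi) can differ on exotic overlap topologies, though both
  must conserve area.
- Egress stops are chosen nearest the workplace independently of the
  ingress stop; no check that both serve one transit line.
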