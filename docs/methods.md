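# Methods

This note records the model, the declared conventions behind every
configurable choice, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Spatial frame

All computation happens in a planar metric frame; every threshold in the
method (30 m sampling, 500 m access, 1000 m catchments, 250 m lattices)
is metric. Geographic inputs must be projected first. Because the only
geographic coordinates the pipeline itself meets are GTFS stop locations,
the package ships a local equirectangular projection (`projection.py`)
anchored at a per-run reference origin: over a single city's extent the
distortion is far below a metre, which is negligible against a 500 m
threshold. Users with cross-hemisphere data should project externally
with a proper CRS before loading.

## Study region and lattices

The study region is the polygon intersection of an administrative
boundary with an urbanised-extent polygon; empty intersections are an
error, not a warning. Two deterministic lattices hang off the region's
bounding box (anchored at its SW corner, so identical inputs give
identical cell ids):

- a 250 m axis-aligned square grid carrying population counts (cell area
  0.0625 km²); every cell whose square intersects the region is kept;
- a 250 m hexagon layer used as "neighbourhoods". The stated width is
  interpreted as the **flat-to-flat distance of flat-topped hexagons**,
  giving cell area (√3/2)·250² ≈ 54 127 m² — deliberately comparable to
  a grid cell so hexagon and grid summaries are on similar support. Hex
  orientation and anchoring are conventions of this package, not facts
  about the method it reimplements, and are documented so runs reproduce.

## Network model and sample points

The walking network is undirected. Edges are stored with `u ≤ v` and
geometry oriented from the lower node id, so offsets along an edge do not
depend on digitisation direction and sample-point output is invariant
under re-ordering of the input tables. Parallel duplicate edges collapse
to the shortest for routing.

Sample points sit at offsets `k·30 m` with `k = 1..floor((L−ε)/30)`,
ε = 1 mm, so an edge whose length is an exact multiple of the interval
does not put a point on its end node; edges shorter than 30 m get a
single midpoint sample. Points inside zero-population grid cells are
dropped when a population mask is active, restricting indicators to
places where people live. The phasing of points along edges is a declared
convention (the method's source material does not state one).

Shortest distances from a mid-edge origin treat the origin as splitting
its edge into two half-edges; distances are exact Dijkstra results, and
the reachable network at cutoff *d* consists of per-edge intervals merged
from both endpoints (so loops reached from both ends are never double
counted) and trimmed at exactly *d*.

## Catchments

A catchment is the set of grid cells intersected (closed-set semantics)
by the reached sub-segments. Closed semantics matter: a street running
exactly along a cell boundary belongs to both adjacent cells. Population
is the **whole-cell sum** over member cells — no areal interpolation —
which biases catchment population slightly upward for frontier cells;
this mirrors the tractable grid approximation of the sausage buffer and
is accepted as a documented bias source. Intersections are nodes of
degree ≥ 3 in the cleaned network whose network distance from the origin
is within the cutoff; the far endpoint of a partially reached edge does
not count. Both densities divide by the cell-union area.

## Access

Destinations snap to the nearest point on any edge (ties to the lower
edge id); points farther than the snap tolerance (default 500 m) are
excluded with a warning. Nearest distances use one multi-source Dijkstra
per destination layer over a routing graph in which destination-bearing
edges are split at the destination offsets — equivalent to, and tested
against, a per-destination brute-force minimum. Distances beyond the
search cap (default 3200 m) are censored at the cap and always score 0;
"within 500 m" is inclusive (exactly 500.0 scores 1). Open-space entry
points are generated every 20 m along each polygon's exterior ring
starting at its first vertex; the large class is strictly `> 1.5 ha`, so
a polygon of exactly 1.5 ha is excluded. Cap, tolerance and spacing are
package defaults, configurable, and not claims about the original method.

## Transit service frequency

The daytime window is 07:00–19:00 local, inclusive at both ends, on a
representative weekday: the Mon–Fri day with the most scheduled
departures (ties to the earliest day). All services active on that day
count. `frequencies.txt` blocks are expanded to explicit departures over
`[start, end)`; times past 24:00 are kept in service-day seconds, which
automatically excludes them from the daytime window.
`calendar_dates.txt` exceptions flip a service's weekday activity only
when they affect the majority of that weekday's dates in the feed span —
a rule chosen so isolated holidays do not redefine a city's typical
weekday. A stop's headway is the mean of consecutive gaps between its
pooled departures, **deduplicated by clock time**, so re-publishing the
same schedule under a second route id cannot halve the measured headway.
The alternative estimator (window length ÷ departures) was rejected
because it understates gaps at the window edges. Stops with fewer than
two windowed departures have undefined headway and belong to neither
frequency class.

## Composite indicators and thresholds

Daily living = sum of the three binary scores (food, convenience, any
PT). Walkability = sum of z-scores of catchment population density,
intersection density and daily living; z-scores use the
population-size (n) denominator SD, a declared convention. Zero-variance
reference sets produce all-zero z-scores with a warning rather than NaNs.
Between-city standardisation pools hexagon-level records of all supplied
cities, unweighted; computing it over hexes (not sample points or city
means) is this package's default and is exposed as a choice, since the
aggregation unit is genuinely open.

Scenario thresholds default to the lower bounds of the published 95%
CIs — scenario A (80% probability of walking for transport):
4790 persons/km², 90 intersections/km²; scenario B (WHO's ≥ 15% relative
reduction in insufficient physical activity): 5677 and 106. "Reaching or
exceeding" is inclusive (≥). Point estimates may be supplied instead via
`ThresholdScenario`.

## Aggregation and summaries

Hexagon summaries are unweighted means of member points; hexes without
points are omitted. Large-open-space access at hexagon level follows the
at-least-half rule: 1 iff ≥ 50% of member points have it. Hexagon
populations are areal-assigned from grid cells (cell count split in
proportion to overlap area; population is conserved). City percentages
weight hexagon means by hexagon population; scenario exposure classifies
hexagons by their mean densities. Group summaries over cities are
unweighted means with n-denominator SDs, excluding missing indicators
per column (a city without machine-readable transit schedules simply
does not enter the service-frequency means). Published group SDs are not
asserted against because their original denominator convention is
unstated.

The bundled 25-city benchmark tables are consumed as printed inputs
(one-decimal percent scale). Recomputing a summary row from rounded
cells can differ from a value computed on unrounded data in the last
digit (the high-income convenience mean recomputes to 43.4 against a
printed 43.3); tests allow exactly that rounding slack and no more.
Summary figures that are not reproducible as unweighted means of the
printed city cells are not asserted.

## Synthetic cities

The generator emulates the structural features the pipeline is sensitive
to: connected planar networks (square lattice; "organic" = interior
nodes jittered by ≤ 0.3·block and a seeded fraction of edges removed
bridge-safely), radially exponential population allocated by a seeded
multinomial that conserves the total exactly, amenities placed on the
network with ≤ 15 m perpendicular jitter and tunable clustering,
axis-aligned rectangular open spaces of exact requested area, and
weekday fixed-headway GTFS feeds (06:00–22:00 inclusive; one route
serving all stops in a nearest-neighbour order at 6 m/s). One named RNG
stream per layer hangs off the single seed, so regenerating one layer
never perturbs another and equal specs give byte-identical outputs.

It does **not** emulate: realistic degree distributions or dead-end
hierarchies of real street networks, land-use correlation between
amenities and population, multi-route transit interlining, schedule
irregularity, or OSM tagging noise. Passing tests therefore demonstrate
the correctness of the computational chain under controlled conditions,
not the empirical accuracy of any real city's indicator values — which
additionally depend on data completeness (informal food vendors and
transit are systematically missing from open data, a limitation this
package inherits by design).

The planted-access construction used for recovery tests places markets
at every street node of a western zone, separates east from west by a
750 m unpopulated band (wider than a hexagon, so no neighbourhood
straddles both regimes and no populated point sits within 500 m of the
other side's regime), and splits the population so the west holds
exactly fraction *p*: the population-weighted access fraction is then
*p* by construction, independent of the engine under test.

## Problem sizes and numerical choices

Default test and acceptance runs use compact cities (1–4 km extents,
≤ 300 nodes, hundreds to a few thousand sample points) — large enough to
exercise every code path including partial edges, loop merging and
boundary hexes, small enough that the brute-force oracles (Bellman-Ford
relaxation, 0.25 m edge labelling, exhaustive cell-segment tests) remain
exact references. Interval merging uses a 1 mm tolerance; GeoJSON output
rounds coordinates to millimetres so identical runs are byte-identical.
The per-metre labelling oracle has inherent quantisation of one step per
reached-interval boundary, and the equivalence tests budget exactly that
resolution.

## Known limitations

- Whole-cell catchment population (no areal weighting) overstates
  population for frontier cells.
- The grid-cell catchment is an area approximation; true sausage-buffer
  polygons are intentionally out of scope.
- One-way and access restrictions, slopes and crossings are ignored:
  distances are idealised pedestrian network distances.
- GTFS handling covers calendars, calendar-date exceptions (majority
  rule) and frequencies, but not trip-level realtime or seasonal variants.
- The local equirectangular projection is suitable for single-city
  extents only.
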