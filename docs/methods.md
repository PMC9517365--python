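# Methods

## Scope and model

`patchscape` treats a landscape as a single-band categorical raster: an
integer class code per square cell, a nodata code outside the mapped
extent, and a cell size in metres. A *patch* is a maximal connected
region of same-class cells; all structure metrics are functions of the
patch mosaic (geometry) and of the class composition (proportions). The
intended use case is multi-decadal series of co-registered land-cover
maps — e.g. six-class Landsat-derived maps (croplands, forests,
grasslands, water, settlements, others) of a forest-dominated protected
basin — analysed per epoch and cross-tabulated between epochs.

## Conventions that define the numbers

These choices are deliberate contracts; the brute-force oracles in the
test suite encode the same contracts independently.

* **Connectivity.** Patch delineation defaults to the 8-neighbour rule
  (the convention of the widely used landscape-analysis desktop
  software), switchable to 4. Like-adjacency counting for AI always uses
  unordered rook (4-neighbour) pairs counted once, regardless of patch
  connectivity.
* **Perimeter.** Every cell edge adjoining a different class, nodata, or
  the lattice boundary counts ("landscape without border"). Boundary and
  nodata edges therefore inflate the perimeter of classes touching the
  study-area edge; this is stated rather than hidden because PAFRAC and
  COHESION inherit it.
* **Area accounting.** $Z$ is the number of valid cells,
  $A = Z \cdot \text{cell}^2$; nodata contributes no area. Class CA
  values in hectares therefore sum exactly to $A/10^4$.
* **max g.** The maximum single-count like-adjacency total for $a$ cells
  uses the largest-integer-square construction: with
  $n=\lfloor\sqrt a\rfloor$, $m=a-n^2$: $2n(n-1)$ if $m=0$;
  $+\,2m-1$ if $0<m\le n$; $+\,2m-2$ if $m>n$. The tests verify this
  against pair counts on the explicitly constructed packing.
* **AI edge cases.** A class occupying one cell has $\max g = 0$; its AI
  is 100 by convention (a single cell is maximally aggregated).
  Landscape AI is the area-weighted mean of class AI values; percent
  scaling throughout.
* **COHESION.** The standard percolation-motivated form with perimeter
  and area in cell units,
  $[1-\sum p^*/\sum p^*\sqrt{a^*}]\,[1-1/\sqrt Z]^{-1}\times100$. A
  variant with denominator $\sum p^* a^*$ and correction $[1-1/Z]^{-1}$
  circulates in some typeset sources; it is available behind the
  `literal_cohesion` flag but off by default, because only the standard
  form yields the familiar near-100 values for nearly contiguous
  dominant classes.
* **PAFRAC.** Twice the least-squares slope of $\ln p$ on $\ln a$ over a
  class's patches (equivalently the closed-form moment ratio). Undefined
  (reported `N/A`) below `min_patches` patches (default 10 — a
  perimeter–area regression on a handful of patches is noise) or when
  the log-areas are numerically constant (variance < 1e-12).
* **SHDI/SHEI.** $\mathrm{SHDI}=-\sum p_i\ln p_i$ over classes present;
  $\mathrm{SHEI}=\mathrm{SHDI}/\ln m$ with $m$ the number of classes
  actually present in the grid (not the legend size); 0 for a one-class
  landscape.
* **Rounding.** All computation is full precision. The formatted report
  mode rounds like the field's published tables: class level — integer
  CA and NP, one decimal for PLAND/PD/LPI/COHESION/AI, two for PAFRAC;
  landscape level — integer NP, three decimals elsewhere; `N/A` for
  undefined values.

## Transitions and succession

Epoch pairs must be co-registered (same shape, cell size, nodata code);
a cell enters a pair's matrix only if valid in both epochs (intersection
mask). Entries are areas in hectares; row sums equal the t1 class areas
and column sums the t2 class areas over the jointly valid region,
exactly in cell units.

Flow classification is legend-driven. Each class carries an ecological
role (`natural`, `anthropogenic`, `water`) and natural classes carry a
succession rank ordering them toward the climax community (default:
settlements = croplands (0) < others (0) < grasslands (1) < forests
(2); water is handled by role). Off-diagonal flows into anthropogenic
classes are `anthropogenic_disturbance`; into water,
`hydrological_conversion`; between ranked classes, `progressive` on a
rank increase and `regressive` on a decrease; flows from an unranked
source (water) into natural cover count as progressive recovery. The
scheme is configuration, not hard-coded ecology: a different study
system supplies a different legend.

The Sankey export chains epochs left-to-right with a deterministic node
order (legend order within each epoch column), drops the diagonal
(no-succession) flows, and writes plain JSON; rendering is out of scope.

## The synthetic generator

`generate_random_cluster` implements a modified-random-clusters neutral
landscape model: (1) mark cells i.i.d. with probability `aggregation`;
(2) label marked clusters with the rook neighbourhood; (3) hand whole
clusters to classes — one of the smallest clusters is first reserved per
class, smallest target first, so a rare class can never be starved by a
large-cluster overshoot, then clusters are drawn in seeded random order
and given to the class furthest below its target cell share; (4) each
unmarked cell takes the majority class among its cluster-assigned
8-neighbours (ties broken by legend order), and cells with no assigned
neighbour draw from the target distribution.

`aggregation` must stay below 0.59, just under the rook site-percolation
threshold (~0.5927), so marked clusters remain sub-spanning and the
realized composition can track its targets. At the defaults used in the
tests (200×200 cells, 30 m, 82%-forest composition, aggregation 0.5)
the realized class shares land within about ±1 percentage point of
target across seeds, and increasing `aggregation` monotonically raises
mean AI and LPI while lowering mean NP — the fragmentation gradient the
indices are meant to detect. One caveat, verified empirically: when one
class's share exceeds the patch-percolation regime (the 82% forest
case), its patch spans the lattice at any aggregation level and
landscape LPI saturates near the class share; the monotone-trend test
therefore uses a composition whose largest class holds 30%.

What the generator does *not* emulate: topography-conditioned class
layouts, river networks and linear features, spatially structured
classification error, or temporally autocorrelated change. Passing tests
demonstrate correctness of the measurement pipeline on realistic
composition/aggregation regimes, not realism of any particular map.

`evolve_series` converts a stated fraction of a class's cells to another
class, sampling patch-boundary cells before interior ones (land-cover
change nibbles at edges); rules apply in order, later rules seeing
earlier edits, so chained rules can compose within one epoch. The
conversion count is `round(fraction × class cells)`, which the
transition matrix recovers exactly to one cell's area.

## Problem sizes and numerics

The test suite and the acceptance script run on synthetic lattices
between 3×3 (exhaustive enumeration of all 512 binary grids against
brute-force oracles) and 200×200 with 20 seeds for Monte-Carlo checks;
these sizes give stable means while keeping the full suite in the
seconds range. Patch labelling uses two-pass connected-component
labelling on boolean masks per class with deterministic renumbering in
raster scan order of each patch's first cell, so identical inputs yield
byte-identical outputs. All randomness flows from a single integer seed
per generated object.

## Known limitations

* GeoTIFF support carries cell size (pixel-scale tag) and nodata only;
  full CRS/affine georeferencing is passed through untouched and unused.
* Metrics assume square cells; rectangular pixels are not supported.
* The 2018-epoch class table is the only published reference table whose
  landscape-level densities are arithmetically consistent with its class
  columns; cross-checks in `patchscape.datasets` anchor on it.
* No corridor/least-cost connectivity analysis; COHESION is the only
  connectedness measure provided.
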