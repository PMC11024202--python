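# Methods

This note records the models implemented in `econet`, the conventions and
parameter defaults that matter, and the design choices made where the
methods literature leaves room.

## Rasters and legend

All stages operate on in-memory square-cell grids (`RasterGrid`), with a
fixed six-class land-use legend: farmland, forest, grassland, water,
construction, unused. The default cell size is 30 m, matching the
resolution of GlobeLand30-class land-cover products. Raster files are
single-band TIFFs with the grid metadata (cell size, origin, nodata,
legend) serialised as JSON in the TIFF description tag; the analysis never
depends on projection information, only on co-registered equal-resolution
grids.

## Synthetic landscapes

The generator is a neutral-landscape model: Gaussian-smoothed white noise
thresholded at the quantiles of the requested class proportions. This
gives exact control of composition (realised proportions match requests up
to quantile granularity), spatial clustering controlled by one smoothing
length (default 8 cells), and bit-reproducibility from a single seed.
Slabs are assigned in a fixed order — construction, farmland, forest,
grassland, water, unused — so that class adjacencies are plausible:
built-up cores sit inside farmland, which grades into the vegetated
classes. Because classes only border their slab neighbours, the mosaic is
smoother and more nested than real land cover; fine-grained interspersion,
linear features (roads, rivers) and registration error are *not* emulated,
so passing tests demonstrate correctness of the operations, not realism of
any particular landscape.

Default composition (fractions of the extent) is farmland 0.65, forest
0.10, grassland 0.02, water 0.03, construction 0.19, unused 0.01 — the
farmland-dominated mix typical of an east-Chinese planning area. Date
series are produced by applying prescribed conversions; the
`near_urban_seed` rule grows construction by region growing out of the
largest existing construction patch (contiguous expansion), ordered by
distance to that seed with a reproducible random tie-break, and
`near_class_boundary` converts the source-class cells nearest to the
target class. DEMs are smoothed fields rescaled so a requested fraction of
cells (default 10%) rises above the plains level (default 30 m, hills up
to +170 m); NDVI is piecewise-constant by class (forest 0.75 > grassland
0.55 > farmland 0.40 > construction 0.08 ≥ water 0.02) plus Gaussian noise
(default sd 0.05), clipped to [−1, 1].

## Change accounting

Areas are cell counts × cell area; composition ratios divide by the sum of
the six classified class areas, not by any external administrative total —
the convention that makes the published area and ratio columns mutually
consistent. The dynamic degree is reported in % per year; it is undefined
for a zero early-date area and raises. The transition matrix is the exact
cell-wise cross-tabulation converted to km²; cells that are nodata at
either date are excluded from both marginals, so row sums equal early-date
areas and column sums late-date areas by construction.

## Landscape pattern metrics

Patches are maximal 8-connected components of one class (4-connectivity is
available). A patch perimeter counts cell edges facing a different class,
nodata or the raster border. Conventions:

- **LSI** includes the landscape boundary in total edge length (the
  common raster convention); class LSI is `0.25·E_i/√A_i` in cell units,
  so a solid square patch scores exactly 1. Users comparing against
  tools that exclude the boundary should expect slightly lower values
  there.
- **AI** uses single-counted rook like-adjacencies against the
  near-square maximum for the class area; a checkerboard class scores 0,
  a solid block 100.
- **CONTAG** uses double-counted rook adjacencies over the classes
  present; a one-class landscape is defined as 100.
- **FRAC_AM** evaluates `2·ln(0.25·p)/ln(a)` with p in metres and a in
  m², area-weighted; a patch with `ln a = 0` is assigned the square limit
  1 to avoid division by zero (with 30 m cells a single-cell patch
  evaluates to exactly 1 anyway).
- **SHDI/SHEI** depend only on composition; SHEI divides by `ln m` with m
  the number of classes present and is defined as 0 for m = 1. The suite
  checks the cross-module identity that raster SHDI equals SHDI computed
  from the area table.

## MSPA

The foreground is forest + grassland + water; everything else (plus
nodata) is background. Foreground connectivity is 8, background
connectivity 4 — the standard duality that avoids touching diagonal
structures being simultaneously connected and disconnected. The edge
width defaults to 1 cell (30 m). Per-cell classes:

- **core**: survives Chebyshev erosion by the edge width (the area beyond
  the raster border counts as background for the erosion, and as exterior
  background for the edge/perforation split);
- **islet**: foreground component containing no core;
- **edge / perforation**: non-core cells within the edge width of a core,
  split by whether exterior background (4-connected to the border) or
  only an interior hole is within reach; cells near both are edge;
- **bridge / loop / branch**: the remaining cells, classified per
  connected component: bridge if the component attaches (directly or
  through the edge/perforation ring) to ≥ 2 distinct core patches, loop
  if it re-attaches to a single core patch at ≥ 2 separated contact
  zones, branch otherwise. Where a connector meets the ring around a
  core, the cell stays with the ring.

These per-cell definitions are the specification of correctness; the test
suite checks them against an independent plain-Python implementation on
random binaries. They follow the classical morphological segmentation but
are not bit-compatible with any particular desktop tool's speed-optimised
variant.

## Habitat quality

Threats (defaults): farmland (max distance 4 km, weight 0.5, linear
decay), construction (10 km, weight 1, exponential), bare/unused land
(2 km, weight 3, linear). The unusually high bare-land weight is kept as
published. Exponential decay uses `exp(−2.99·d/d_max)` (≈5% influence at
the maximum distance); both decays cut to zero beyond `d_max`; distances
are Euclidean between cell centres, evaluated by FFT convolution of the
threat mask with the decay kernel.

Each threat's summed influence at a cell is divided by the number of that
threat's source cells within `d_max` (density normalisation), keeping the
per-threat contribution in [0, 1]; threat weights are normalised by their
sum, so rescaling all weights together changes nothing. One consequence,
worth stating plainly: degradation is *not* monotone under adding an
arbitrary threat cell — a weak distant source inside the radius dilutes
the within-radius mean. Monotonicity does hold in each sensitivity, and
switching a threat on from none can only lower quality; those are the
properties the suite asserts. The accessibility factor of the full
habitat-quality model is fixed at 1 (never mentioned in the source
parameterisation). Quality uses `z = 2.5` and half-saturation `k = 0.5`
(the conventional defaults; both configurable). Grading into five levels
is equal-interval over [0, 1] by default (level 1 = best), with a
quantile option that collapses to a single level on constant rasters.

## Source selection (PC / dPC)

Candidates are the 30 largest core patches with mean habitat quality ≥
0.5 (both configurable; the quality floor is a package choice — the
source material names no number). Area ties break by higher mean quality,
then lower patch id. Dispersal is negative-exponential on edge-to-edge
Euclidean distances between patch cell sets, with probability 0.5 at the
median dispersal distance (default 2.5 km — an ecologically moderate
mammal/bird dispersal scale; the source material states none). `p*` is
exact: Dijkstra on `−log p` edge weights; an optional distance cutoff
removes direct edges between far pairs (paths may still chain through
stepping stones — without a cutoff, a memoryless exponential kernel gains
nothing from collinear stepping stones, which is why the cutoff exists).
dPC > 1 marks sources, dPC > 3 important sources. Node/connection files
can be round-tripped in the Conefor two-file text format.

## Resistance surface and corridors

Six factors graded 1 (permeable) to 5: habitat quality by equal intervals
of Q (best = 1); land use forest 1, grassland 2, farmland/unused 3, water
4, construction 5; NDVI by descending quantile bins; elevation at breaks
30/60/100/200 m; slope (Horn 8-neighbour method, degrees) at breaks
5/10/20/35°; topographic relief amplitude (max − min over an 11×11
window) at breaks 24/44/76/120, treated as a unitless graded quantity
because the published grading prints degree-like breakpoints for what is
dimensionally a length. Weights 0.18/0.35/0.20/0.09/0.08/0.08 are used as
printed (sum 0.98); renormalisation to 1 is opt-in.

Corridors are least-cost 8-connected grid paths: step cost = step length
(diagonals ×√2) × mean resistance of the two cells. Source patches enter
the graph as zero-cost super-nodes attached to their cells, so corridors
run boundary to boundary. Pairs to link default to Delaunay neighbours of
source centroids (approximating adjacent-core linking), with an all-pairs
mode; unreachable pairs are reported with infinite cost, never
fabricated. The tier rule is a package choice (the published tiering
criterion is undefined): a corridor is important iff both endpoint
sources are important, with a lowest-cost-quantile alternative; the rule
never alters geometry.

## Network structure and robustness

The corridor map becomes a graph whose nodes are source attachment points
plus corridor crossing points (snap tolerance 1 cell); edges are corridor
segments split at crossings, parallels collapsed, self-loops dropped.
α/β/γ follow the classical formulas; α and γ are undefined (reported
absent) below 3 nodes; reporting precision is 2 decimals for α/β and 3
for γ. On the published per-year source/corridor counts these formulas
reproduce the published indices for four of five years; the published
2000 alpha (0.85) is not arithmetically consistent with its own counts
(31/37 ≈ 0.838) and is documented rather than reproduced.

Attacks are site percolation: removing a node removes its incident edges.
Random attacks average n_trials = 100 uniformly random removal orders
(per-trial seeds derived from one master seed; a single noisy trajectory
is n_trials = 1); targeted attacks remove by descending initial degree or
betweenness with ties broken by node id. Curves report mean and sd of S
and R per removal step; R is undefined once every node is removed. The
collapse point is the smallest positive number of removals with mean S at
or below the threshold (default 0.1).

## Problem sizes and determinism

The end-to-end suite exercises a 200×200-cell, five-date scenario — large
enough for dozens of cores and a hundred-edge corridor network, and the
scale at which the full pipeline completes in well under a minute on one
CPU. Every stochastic component draws from `numpy.random.default_rng`
seeded from explicit configuration, and pipeline reruns with the same
seed are byte-identical (the output manifest hashes every artifact).

## Known limitations

- The synthetic mosaic's nested slab geometry understates class
  interspersion; metrics like CONTAG and AI will look smoother than on
  real land cover.
- MSPA is defined per-cell as above, not as a clone of any desktop tool.
- Corridors are single least-cost polylines; current-density (circuit
  theory) maps, pinch points and barriers are out of scope.
- The published per-year source/corridor counts and the raster-dependent
  pattern indices of the case study require the original rasters and are
  not reproduced; the packaged tables serve as inputs and reference
  values for the arithmetic that *is* reproducible.
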