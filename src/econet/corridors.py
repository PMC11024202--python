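"""Resistance surface and least-cost ecological corridors.

The comprehensive resistance surface is a weighted sum of six graded
factors — habitat quality, land-use type, NDVI, elevation, slope and
topographic relief amplitude — each mapped onto resistance levels 1
(most permeable) to 5 (least).  Default weights (0.18, 0.35, 0.20, 0.09,
0.08, 0.08) are used as printed (sum 0.98); renormalisation to 1 is
opt-in.

Corridors follow the minimum-cumulative-resistance model: the cost of a
path is the sum over steps of step length times the mean resistance of the
two cells, minimised over 8-connected grid paths (diagonal steps weighted
by sqrt 2).  Each source patch enters the path graph as a zero-cost super
node attached to its cells, so traversal inside a source is free and the
corridor runs boundary to boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.csgraph import dijkstra

from .habitat import quality_grade
from .raster import LandUseRaster, RasterGrid
from .sources import SourcePatch

__all__ = [
    "DEFAULT_WEIGHTS",
    "LANDUSE_LEVELS",
    "ELEVATION_BREAKS",
    "SLOPE_BREAKS",
    "RELIEF_BREAKS",
    "Corridor",
    "derive_terrain",
    "grade_factors",
    "resistance_surface",
    "least_cost_corridors",
    "classify_corridors",
]

#: Factor weights as printed (sum 0.98).
DEFAULT_WEIGHTS = {
    "habitat_quality": 0.18,
    "landuse": 0.35,
    "ndvi": 0.20,
    "elevation": 0.09,
    "slope": 0.08,
    "relief": 0.08,
}

#: Land-use class -> resistance level.
LANDUSE_LEVELS = {
    "forest": 1, "grassland": 2, "farmland": 3, "unused": 3,
    "water": 4, "construction": 5,
}

#: Upper bounds of levels 1..4 (level 5 above the last bound).
ELEVATION_BREAKS = (30.0, 60.0, 100.0, 200.0)   # metres
SLOPE_BREAKS = (5.0, 10.0, 20.0, 35.0)          # degrees
RELIEF_BREAKS = (24.0, 44.0, 76.0, 120.0)       # graded relief units


@dataclass
class Corridor:
    """A least-cost linkage between two source patches."""

    source_a: int
    source_b: int
    path: np.ndarray = field(repr=False)  # (n, 2) of (row, col)
    cost: float = 0.0       # accumulated km x resistance
    length_km: float = 0.0
    tier: str = "general"


def derive_terrain(
    dem: RasterGrid, relief_window: int = 11
) -> tuple[RasterGrid, RasterGrid]:
    """Slope (degrees, Horn 8-neighbour method) and relief amplitude
    (max - min elevation over a square moving window)."""
    z = np.asarray(dem.values, dtype=float)
    if min(z.shape) < 2:
        raise ValueError("DEM must have at least 2 cells per axis")
    zp = np.pad(z, 1, mode="edge")
    a = zp[:-2, :-2]; b = zp[:-2, 1:-1]; c = zp[:-2, 2:]
    d = zp[1:-1, :-2];                   f = zp[1:-1, 2:]
    g = zp[2:, :-2];  h = zp[2:, 1:-1];  i = zp[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dem.cell_size)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * dem.cell_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    relief = (
        ndimage.maximum_filter(z, size=relief_window, mode="nearest")
        - ndimage.minimum_filter(z, size=relief_window, mode="nearest")
    )
    return (
        RasterGrid(slope, cell_size=dem.cell_size),
        RasterGrid(relief, cell_size=dem.cell_size),
    )


def _grade_by_breaks(values: np.ndarray, breaks) -> np.ndarray:
    """Level 1..len(breaks)+1 by ascending upper bounds (value <= break)."""
    return (np.digitize(values, np.asarray(breaks), right=True) + 1).astype(np.int16)


def _grade_quantile_desc(values: np.ndarray, n_levels: int = 5) -> np.ndarray:
    """Quantile levels with high values mapped to level 1."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_levels + 1)[1:-1]))
    if edges.size == 0:
        return np.ones(values.shape, dtype=np.int16)
    bins = np.digitize(values, edges, right=False)
    return (len(edges) + 1 - bins).astype(np.int16)


def grade_factors(
    quality: RasterGrid,
    landuse: LandUseRaster,
    ndvi: RasterGrid,
    slope: RasterGrid,
    relief: RasterGrid,
    dem: RasterGrid,
) -> dict[str, np.ndarray]:
    """Map the six factors onto resistance levels 1..5.

    Habitat quality is graded by equal intervals of Q (excellent habitat =
    level 1); land use by the fixed class table; NDVI by descending
    quantile bins (dense vegetation = level 1); elevation, slope and relief
    by their fixed breakpoints.
    """
    lu_levels = np.zeros(landuse.shape, dtype=np.int16)
    for name, code in landuse.legend.items():
        lu_levels[landuse.values == code] = LANDUSE_LEVELS[name]
    return {
        "habitat_quality": quality_grade(quality).values.astype(np.int16),
        "landuse": lu_levels,
        "ndvi": _grade_quantile_desc(ndvi.values),
        "elevation": _grade_by_breaks(dem.values, ELEVATION_BREAKS),
        "slope": _grade_by_breaks(slope.values, SLOPE_BREAKS),
        "relief": _grade_by_breaks(relief.values, RELIEF_BREAKS),
    }


def resistance_surface(
    levels: dict[str, np.ndarray],
    weights: dict[str, float] | None = None,
    normalize: bool = False,
    cell_size: float = 30.0,
) -> RasterGrid:
    """Weighted sum of the graded factor levels."""
    weights = dict(DEFAULT_WEIGHTS if weights is None else weights)
    missing = set(weights) - set(levels)
    if missing:
        raise ValueError(f"missing factor levels: {sorted(missing)}")
    total_w = sum(weights.values())
    r = np.zeros(next(iter(levels.values())).shape, dtype=float)
    for name, w in weights.items():
        w_eff = w / total_w if normalize else w
        r += w_eff * levels[name].astype(float)
    return RasterGrid(r, cell_size=cell_size)


_STEPS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def _grid_graph(resistance: np.ndarray, cell_km: float) -> sparse.csr_matrix:
    """Sparse 8-connected grid graph; edge weight = step length (km) times
    the mean resistance of the two cells."""
    rows, cols = resistance.shape
    idx = np.arange(rows * cols).reshape(rows, cols)
    data, ii, jj = [], [], []
    for dr, dc in ((0, 1), (1, 0), (1, 1), (1, -1)):
        r0 = slice(max(0, -dr), rows - max(0, dr))
        c0 = slice(max(0, -dc), cols - max(0, dc))
        r1 = slice(max(0, dr), rows + min(0, dr))
        c1 = slice(max(0, dc), cols + min(0, dc))
        a = idx[r0, c0].ravel()
        b = idx[r1, c1].ravel()
        step = cell_km * (np.sqrt(2.0) if dr and dc else 1.0)
        w = step * 0.5 * (resistance.ravel()[a] + resistance.ravel()[b])
        ii.append(a); jj.append(b); data.append(w)
    ii = np.concatenate(ii); jj = np.concatenate(jj); data = np.concatenate(data)
    n = rows * cols
    g = sparse.coo_matrix((data, (ii, jj)), shape=(n, n))
    return (g + g.T).tocsr()


def _select_pairs(sources: list[SourcePatch], mode: str) -> list[tuple[int, int]]:
    """Source index pairs to link: Delaunay neighbours of the centroids
    (falling back to all pairs for degenerate geometry) or all pairs."""
    m = len(sources)
    all_pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
    if mode == "all_pairs" or m <= 3:
        return all_pairs
    from scipy.spatial import Delaunay, QhullError

    pts = np.array([s.centroid for s in sources], dtype=float)
    try:
        tri = Delaunay(pts)
    except QhullError:
        return all_pairs
    pairs = set()
    for simplex in tri.simplices:
        for i in range(3):
            a, b = int(simplex[i]), int(simplex[(i + 1) % 3])
            pairs.add((min(a, b), max(a, b)))
    return sorted(pairs)


def least_cost_corridors(
    surface: RasterGrid,
    sources: list[SourcePatch],
    pair_mode: str = "delaunay",
) -> list[Corridor]:
    """Least-cost corridor per selected source pair.

    Unreachable pairs (infinite-resistance barriers) are reported with
    ``cost = inf`` and an empty path rather than fabricated.
    """
    if len(sources) < 2:
        raise ValueError("need at least two sources")
    rows, cols = surface.shape
    cell_km = surface.cell_size / 1000.0
    n_cells = rows * cols
    grid = _grid_graph(np.asarray(surface.values, dtype=float), cell_km)

    # Super node per source, zero-weight edges to its cells.  A true zero
    # would be dropped by the sparse container, so use a negligible epsilon.
    eps = 1e-12
    s_rows, s_cols = [], []
    for s_i, src in enumerate(sources):
        flat = src.cells[:, 0] * cols + src.cells[:, 1]
        s_rows.extend([s_i] * len(flat))
        s_cols.extend(flat.tolist())
    attach = sparse.coo_matrix(
        (np.full(len(s_rows), eps), (s_rows, s_cols)),
        shape=(len(sources), n_cells),
    )
    g = sparse.bmat([[grid, attach.T], [attach, None]], format="csr")

    pairs = _select_pairs(sources, pair_mode)
    by_start: dict[int, list[int]] = {}
    for i, j in pairs:
        by_start.setdefault(i, []).append(j)

    corridors = []
    for i, targets in sorted(by_start.items()):
        start = n_cells + i
        dist, pred = dijkstra(g, indices=start, return_predecessors=True)
        for j in targets:
            end = n_cells + j
            if not np.isfinite(dist[end]):
                corridors.append(Corridor(sources[i].id, sources[j].id,
                                          np.empty((0, 2), dtype=int),
                                          cost=float("inf")))
                continue
            node = pred[end]  # last grid cell before the target super node
            path = []
            while node != start and node >= 0:
                path.append((node // cols, node % cols))
                node = pred[node]
            path = np.array(path[::-1], dtype=int)
            length = 0.0
            for a, b in zip(path[:-1], path[1:]):
                step = np.sqrt(2.0) if (a[0] != b[0] and a[1] != b[1]) else 1.0
                length += step * cell_km
            corridors.append(Corridor(sources[i].id, sources[j].id, path,
                                      cost=float(dist[end]),
                                      length_km=float(length)))
    return corridors


def classify_corridors(
    corridors: list[Corridor],
    sources: list[SourcePatch],
    rule: str = "important_endpoints",
    cost_quantile: float = 0.25,
) -> list[Corridor]:
    """Assign corridor tiers.

    ``important_endpoints``: a corridor is important iff both endpoint
    sources are important (dPC > 3).  ``cost_quantile``: the lowest-cost
    fraction of corridors is important.  Geometry is never altered.
    """
    tiers = {s.id: s.tier for s in sources}
    if rule == "important_endpoints":
        for c in corridors:
            both = tiers.get(c.source_a) == "important" and \
                   tiers.get(c.source_b) == "important"
            c.tier = "important" if both else "general"
    elif rule == "cost_quantile":
        finite = [c.cost for c in corridors if np.isfinite(c.cost)]
        cut = np.quantile(finite, cost_quantile) if finite else np.inf
        for c in corridors:
            c.tier = "important" if c.cost <= cut else "general"
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return corridors
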