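"""Ecological source selection via the probability-of-connectivity index.

From the MSPA cores, the largest patches with high mean habitat quality
are taken as candidate sources (top 30 by default).  Each candidate is
scored with dPC, the percentage drop in the probability-of-connectivity
index PC when the patch is removed:

``PC = sum_i sum_j a_i a_j p*_ij / A_L^2``

where ``a_i`` are patch areas, ``A_L`` is the landscape area and ``p*_ij``
is the maximum product of stepwise dispersal probabilities over all paths
between i and j (``p*_ii = 1``).  Dispersal follows a negative-exponential
kernel ``p_ij = exp(-theta d_ij)`` on edge-to-edge Euclidean distances,
with ``theta`` fixed by the distance at which dispersal probability is 0.5
(2.5 km by default).  ``p*`` is computed exactly as a shortest path on
``-log p`` edge weights.

Patches with dPC > 1 are classed as (general) sources; dPC > 3 marks
important sources.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .metrics import PatchSet
from .raster import RasterGrid

__all__ = [
    "ConnectivityParams",
    "SourcePatch",
    "candidate_cores",
    "interpatch_distances",
    "pc_index",
    "dpc",
    "rank_sources",
    "write_conefor",
    "read_conefor",
]


@dataclass
class ConnectivityParams:
    """Dispersal model and landscape area for PC.

    ``theta = ln 2 / median_dispersal_m`` so that ``p = 0.5`` at the median
    dispersal distance.  Patch pairs farther apart than
    ``distance_cutoff_m`` get no direct edge (paths may still chain through
    stepping stones).
    """

    median_dispersal_m: float = 2500.0
    a_l_km2: float = 1.0
    distance_cutoff_m: float | None = None

    def __post_init__(self) -> None:
        if self.median_dispersal_m <= 0:
            raise ValueError("median dispersal distance must be positive")
        if self.a_l_km2 <= 0:
            raise ValueError("landscape area must be positive")

    @property
    def theta(self) -> float:
        return float(np.log(2.0) / self.median_dispersal_m)


@dataclass
class SourcePatch:
    """A candidate or selected ecological source."""

    id: int
    area_km2: float
    mean_quality: float
    cells: np.ndarray = field(repr=False)  # (n, 2) array of (row, col)
    centroid: tuple[float, float] = (0.0, 0.0)  # (row, col), cell units
    dpc: float | None = None
    tier: str = "excluded"


def candidate_cores(
    cores: PatchSet,
    quality: RasterGrid,
    n: int = 30,
    min_quality: float = 0.5,
) -> list[SourcePatch]:
    """Top-``n`` core patches by area among those with mean quality >=
    ``min_quality``.

    Area ties are broken by higher mean quality, then lower patch id.
    Returns all qualifying patches when fewer than ``n`` qualify; raises if
    none do.
    """
    rows = []
    for _, rec in cores.table.iterrows():
        pid = int(rec["patch_id"])
        mask = cores.labels == pid
        mean_q = float(quality.values[mask].mean())
        if mean_q < min_quality:
            continue
        cells = np.argwhere(mask)
        rows.append(
            SourcePatch(
                id=pid,
                area_km2=float(rec["area_km2"]),
                mean_quality=mean_q,
                cells=cells,
                centroid=tuple(cells.mean(axis=0)),
            )
        )
    if not rows:
        raise ValueError("no core patch meets the quality floor")
    rows.sort(key=lambda s: (-s.area_km2, -s.mean_quality, s.id))
    return rows[:n]


def interpatch_distances(patches: list[SourcePatch], cell_size: float) -> np.ndarray:
    """Pairwise edge-to-edge Euclidean distances (metres) between patch
    cell sets."""
    m = len(patches)
    dist = np.zeros((m, m), dtype=float)
    trees = [cKDTree(p.cells.astype(float)) for p in patches]
    for i in range(m):
        for j in range(i + 1, m):
            d, _ = trees[j].query(patches[i].cells.astype(float), k=1)
            dist[i, j] = dist[j, i] = float(d.min()) * cell_size
    return dist


def _max_product_probabilities(
    patches: list[SourcePatch], params: ConnectivityParams, cell_size: float
) -> np.ndarray:
    """Matrix of p*_ij: maximum path products of stepwise probabilities,
    via shortest paths on -log p edge weights."""
    from scipy.sparse.csgraph import dijkstra

    m = len(patches)
    dist = interpatch_distances(patches, cell_size)
    w = params.theta * dist  # -log p_ij for the direct edge
    if params.distance_cutoff_m is not None:
        w[dist > params.distance_cutoff_m] = np.inf
    np.fill_diagonal(w, np.inf)  # no self-edges; p*_ii handled below
    lengths = dijkstra(w, directed=False)
    p_star = np.exp(-lengths)
    np.fill_diagonal(p_star, 1.0)
    return p_star


def pc_index(
    patches: list[SourcePatch],
    params: ConnectivityParams,
    cell_size: float = 30.0,
    p_star: np.ndarray | None = None,
) -> float:
    """Probability of connectivity PC of the patch set."""
    if not patches:
        raise ValueError("PC needs at least one patch")
    if p_star is None:
        p_star = _max_product_probabilities(patches, params, cell_size)
    a = np.array([p.area_km2 for p in patches])
    return float(a @ p_star @ a / params.a_l_km2**2)


def dpc(
    patches: list[SourcePatch],
    params: ConnectivityParams,
    k: int,
    cell_size: float = 30.0,
) -> float:
    """dPC of patch ``k`` (index into ``patches``), in percent.

    ``dPC_k = 100 (PC - PC_without_k) / PC``.
    """
    pc_full = pc_index(patches, params, cell_size)
    if pc_full == 0:
        raise ValueError("PC of the full patch set is zero")
    rest = [p for i, p in enumerate(patches) if i != k]
    pc_rest = pc_index(rest, params, cell_size) if rest else 0.0
    return 100.0 * (pc_full - pc_rest) / pc_full


def rank_sources(
    patches: list[SourcePatch],
    params: ConnectivityParams,
    cell_size: float = 30.0,
    source_threshold: float = 1.0,
    important_threshold: float = 3.0,
) -> list[SourcePatch]:
    """Score every candidate with dPC and assign tiers.

    Tiers: ``important`` (dPC > important_threshold), ``general``
    (dPC > source_threshold), else ``excluded``.
    """
    for i, p in enumerate(patches):
        p.dpc = dpc(patches, params, i, cell_size)
        if p.dpc > important_threshold:
            p.tier = "important"
        elif p.dpc > source_threshold:
            p.tier = "general"
        else:
            p.tier = "excluded"
    return patches


def write_conefor(patches: list[SourcePatch], cell_size: float,
                  nodes_path, connections_path) -> None:
    """Write Conefor-style node (id area) and connection (id id distance)
    text files."""
    with open(nodes_path, "w") as fh:
        for p in patches:
            fh.write(f"{p.id} {p.area_km2:.6f}\n")
    dist = interpatch_distances(patches, cell_size)
    with open(connections_path, "w") as fh:
        for i in range(len(patches)):
            for j in range(i + 1, len(patches)):
                fh.write(f"{patches[i].id} {patches[j].id} {dist[i, j]:.3f}\n")


def read_conefor(nodes_path, connections_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read Conefor-style node and connection files into DataFrames."""
    nodes = pd.read_csv(nodes_path, sep=r"\s+", header=None,
                        names=["id", "area"])
    conns = pd.read_csv(connections_path, sep=r"\s+", header=None,
                        names=["id_a", "id_b", "distance"])
    return nodes, conns
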