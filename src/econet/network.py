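"""Ecological network topology, connectivity indices and attack robustness.

The corridor map is abstracted to a topological graph: nodes are the
source attachment points of corridors plus the points where corridors
cross (snapped within a tolerance); edges are the corridor segments
between nodes, with parallel edges collapsed and self-loops dropped.

Connectivity is summarised by the classic planar-network indices

- ``alpha = (L - V + 1) / (2V - 5)`` — circuit ratio (0..1),
- ``beta  = L / V`` — edges per node (0..3),
- ``gamma = L / (3 (V - 2))`` — edges relative to the planar maximum,

with V nodes and L edges; alpha and gamma need V >= 3.

Robustness is probed by node-removal (site-percolation) simulations: after
each removal the giant component size ``C_max`` gives the relative size
``S = C_max / N`` and the connectivity robustness ``R = C_max / (N - N_r)``
for ``N_r`` removed nodes.  Random attacks average many seeded random
removal orders; targeted attacks remove by descending degree or
betweenness with ties broken by node id.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .corridors import Corridor
from .sources import SourcePatch

__all__ = [
    "ConnectivityIndices",
    "build_graph",
    "connectivity_indices",
    "indices_from_counts",
    "random_attack",
    "targeted_attack",
    "collapse_summary",
    "write_graphml",
    "write_edgelist_csv",
]


@dataclass
class ConnectivityIndices:
    """Alpha, beta, gamma indices of a network with V nodes and L edges.

    ``alpha`` and ``gamma`` are ``None`` when V < 3 (undefined).
    """

    v: int
    l: int
    alpha: float | None
    beta: float
    gamma: float | None

    def rounded(self) -> "ConnectivityIndices":
        """Rounded for reporting: alpha/beta to 2 decimals, gamma to 3."""
        return ConnectivityIndices(
            v=self.v,
            l=self.l,
            alpha=None if self.alpha is None else round(self.alpha, 2),
            beta=round(self.beta, 2),
            gamma=None if self.gamma is None else round(self.gamma, 3),
        )


def indices_from_counts(v: int, l: int) -> ConnectivityIndices:
    """Indices straight from node and edge counts."""
    if v < 1:
        raise ValueError("need at least one node")
    alpha = (l - v + 1) / (2 * v - 5) if v >= 3 else None
    gamma = l / (3 * (v - 2)) if v >= 3 else None
    return ConnectivityIndices(v=v, l=l, alpha=alpha, beta=l / v, gamma=gamma)


def connectivity_indices(net: nx.Graph) -> ConnectivityIndices:
    """Indices of a built network graph."""
    return indices_from_counts(net.number_of_nodes(), net.number_of_edges())


def _snap_key(x: float, y: float, tol: float) -> tuple[int, int]:
    return (int(round(x / tol)), int(round(y / tol)))


def build_graph(
    corridors: list[Corridor],
    sources: list[SourcePatch] | None = None,
    snap_tolerance: float = 1.0,
) -> nx.Graph:
    """Topological graph of the corridor network.

    Corridor paths are in cell coordinates; crossings closer than
    ``snap_tolerance`` (cells) share one node.  Sources without any
    corridor become isolated nodes.  Unreachable corridors (empty paths)
    are skipped.
    """
    from shapely.geometry import LineString
    from shapely.ops import substring

    g = nx.Graph()
    if sources is not None:
        for s in sources:
            g.add_node(("src", s.id), kind="source",
                       x=float(s.centroid[1]), y=float(s.centroid[0]))

    lines = []
    for c in corridors:
        if len(c.path) < 2 or not np.isfinite(c.cost):
            continue
        coords = [(float(col), float(row)) for row, col in c.path]
        lines.append((c, LineString(coords)))

    # Split positions along each corridor where it crosses another.
    cuts: list[list[float]] = [[] for _ in lines]
    for i in range(len(lines)):
        for j in range(i + 1, len(lines)):
            inter = lines[i][1].intersection(lines[j][1])
            if inter.is_empty:
                continue
            pts = []
            if inter.geom_type == "Point":
                pts = [inter]
            elif inter.geom_type == "MultiPoint":
                pts = list(inter.geoms)
            else:  # overlapping segments: use their representative points
                pts = [inter.representative_point()]
            for p in pts:
                cuts[i].append(lines[i][1].project(p))
                cuts[j].append(lines[j][1].project(p))

    for (c, line), cut in zip(lines, cuts):
        breaks = sorted({d for d in cut if 1e-9 < d < line.length - 1e-9})
        stations = [0.0] + breaks + [line.length]
        node_keys = []
        for k, d in enumerate(stations):
            if k == 0:
                node_keys.append(("src", c.source_a))
            elif k == len(stations) - 1:
                node_keys.append(("src", c.source_b))
            else:
                x, y = line.interpolate(d).coords[0]
                node_keys.append(("x",) + _snap_key(x, y, snap_tolerance))
        for k in range(len(stations) - 1):
            a, b = node_keys[k], node_keys[k + 1]
            if a == b:
                continue
            seg = substring(line, stations[k], stations[k + 1])
            length = float(seg.length)
            if g.has_edge(a, b):
                g[a][b]["length"] = min(g[a][b]["length"], length)
            else:
                for key, d in ((a, stations[k]), (b, stations[k + 1])):
                    if key not in g:
                        x, y = line.interpolate(d).coords[0]
                        g.add_node(key, kind="crossing", x=float(x), y=float(y))
                g.add_edge(a, b, length=length, corridor=(c.source_a, c.source_b))
    return g


def _giant_size(g: nx.Graph) -> int:
    if g.number_of_nodes() == 0:
        return 0
    return max(len(c) for c in nx.connected_components(g))


def _attack_trajectory(net: nx.Graph, order: list) -> tuple[np.ndarray, np.ndarray]:
    """S and R after 0..N removals for one removal order."""
    n = net.number_of_nodes()
    g = net.copy()
    s = np.empty(n + 1)
    r = np.empty(n + 1)
    for t in range(n + 1):
        c_max = _giant_size(g)
        s[t] = c_max / n
        r[t] = c_max / (n - t) if t < n else np.nan
        if t < n:
            g.remove_node(order[t])
    return s, r


def random_attack(net: nx.Graph, n_trials: int = 100, seed: int = 0) -> pd.DataFrame:
    """Stochastic node-attack curves averaged over ``n_trials`` uniformly
    random removal orders.

    Returns a DataFrame with one row per removal step ``n_removed`` = 0..N
    and columns ``S_mean``, ``R_mean``, ``S_sd``, ``R_sd``.  ``R`` is
    undefined (NaN) once every node is removed.  Deterministic for a fixed
    seed; ``n_trials=1`` reproduces a single stochastic trajectory.
    """
    if net.number_of_nodes() < 1:
        raise ValueError("attack needs at least one node")
    rng = np.random.default_rng(seed)
    nodes = sorted(net.nodes, key=repr)
    s_all, r_all = [], []
    for _ in range(n_trials):
        order = [nodes[i] for i in rng.permutation(len(nodes))]
        s, r = _attack_trajectory(net, order)
        s_all.append(s)
        r_all.append(r)
    s_all = np.array(s_all)
    r_all = np.array(r_all)
    return pd.DataFrame(
        {
            "n_removed": np.arange(s_all.shape[1]),
            "S_mean": s_all.mean(axis=0),
            "R_mean": r_all.mean(axis=0),
            "S_sd": s_all.std(axis=0, ddof=0),
            "R_sd": r_all.std(axis=0, ddof=0),
        }
    )


def targeted_attack(net: nx.Graph, strategy: str = "degree") -> pd.DataFrame:
    """Deterministic attack removing nodes by descending centrality
    (initial ``degree`` or ``betweenness``), ties broken by node id."""
    if net.number_of_nodes() < 1:
        raise ValueError("attack needs at least one node")
    if strategy == "degree":
        score = dict(net.degree())
    elif strategy == "betweenness":
        score = nx.betweenness_centrality(net)
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    order = sorted(net.nodes, key=lambda u: (-score[u], repr(u)))
    s, r = _attack_trajectory(net, order)
    return pd.DataFrame(
        {
            "n_removed": np.arange(len(s)),
            "S_mean": s,
            "R_mean": r,
            "S_sd": 0.0,
            "R_sd": 0.0,
        }
    )


def collapse_summary(curve: pd.DataFrame, s_threshold: float = 0.1) -> int:
    """Smallest positive number of removed nodes at which mean S <=
    threshold; the full node count if the curve never reaches it."""
    below = curve[(curve["S_mean"] <= s_threshold) & (curve["n_removed"] > 0)]
    if below.empty:
        return int(curve["n_removed"].max())
    return int(below["n_removed"].iloc[0])


def _str_graph(net: nx.Graph) -> nx.Graph:
    g = nx.Graph()
    for u, data in net.nodes(data=True):
        g.add_node(repr(u), **{k: v for k, v in data.items()
                               if isinstance(v, (str, int, float, bool))})
    for u, v, data in net.edges(data=True):
        g.add_edge(repr(u), repr(v),
                   **{k: d for k, d in data.items()
                      if isinstance(d, (str, int, float, bool))})
    return g


def write_graphml(net: nx.Graph, path) -> None:
    """GraphML export (node keys stringified)."""
    nx.write_graphml(_str_graph(net), str(path))


def write_edgelist_csv(net: nx.Graph, path) -> None:
    """Edge-list CSV export with segment lengths."""
    rows = [
        {"node_a": repr(u), "node_b": repr(v),
         "length": data.get("length", float("nan"))}
        for u, v, data in net.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["node_a", "node_b", "length"]).to_csv(
        path, index=False)
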