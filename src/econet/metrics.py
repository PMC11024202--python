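"""Landscape pattern metrics on categorical rasters.

Implements the standard raster (FRAGSTATS-convention) definitions of the
ten indices used in the analysis, at class level (CA, NP, LPI, LSI,
COHESION, AI) and landscape level (LPI, FRAC_AM, CONTAG, COHESION, SHDI,
SHEI, LSI).

Conventions, stated once:

- patches are maximal connected components of one class, 8-connected by
  default;
- a patch perimeter counts the cell edges that face a different class,
  nodata, or the raster boundary;
- class and landscape LSI include the landscape boundary in total edge
  length;
- the aggregation index uses single-counted like adjacencies (rook) against
  the maximum achievable for the class area in a near-square arrangement;
- contagion uses double-counted rook adjacencies;
- Shannon diversity depends only on composition, so it can equally be
  computed from an area table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .raster import LandUseRaster

__all__ = [
    "PatchSet",
    "label_patches",
    "class_metrics",
    "landscape_metrics",
    "metric_timeseries",
    "shannon_indices",
]

_STRUCT8 = np.ones((3, 3), dtype=int)
_STRUCT4 = ndimage.generate_binary_structure(2, 1)


@dataclass
class PatchSet:
    """Patches of a categorical raster.

    ``table`` has one row per patch: ``patch_id``, ``class``,
    ``area_cells``, ``area_km2``, ``perimeter_edges``, ``perimeter_m``.
    ``labels`` assigns each cell its global patch id (0 outside patches).
    """

    table: pd.DataFrame
    labels: np.ndarray
    cell_size: float
    connectivity: int = 8


def _perimeter_per_patch(labels: np.ndarray, n_patches: int) -> np.ndarray:
    """Edge count per patch id; an edge faces a different label, label 0,
    or the raster boundary."""
    perim = np.zeros(n_patches + 1, dtype=np.int64)
    padded = np.pad(labels, 1, constant_values=0)
    for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        neighbor = padded[1 + dr : padded.shape[0] - 1 + dr,
                          1 + dc : padded.shape[1] - 1 + dc]
        differs = (labels != neighbor) & (labels > 0)
        np.add.at(perim, labels[differs], 1)
    return perim


def label_patches(raster: LandUseRaster, connectivity: int = 8) -> PatchSet:
    """Label per-class connected components and measure area and perimeter."""
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    struct = _STRUCT8 if connectivity == 8 else _STRUCT4
    mask = raster.mask()
    global_labels = np.zeros(raster.shape, dtype=np.int64)
    rows = []
    next_id = 1
    for name, code in raster.legend.items():
        class_mask = (raster.values == code) & mask
        if not class_mask.any():
            continue
        lab, nlab = ndimage.label(class_mask, structure=struct)
        ids = np.arange(1, nlab + 1)
        areas = ndimage.sum_labels(np.ones_like(lab), lab, ids).astype(np.int64)
        global_labels[class_mask] = lab[class_mask] + (next_id - 1)
        for k, a in zip(ids, areas):
            rows.append({"patch_id": next_id + k - 1, "class": name,
                         "area_cells": int(a)})
        next_id += nlab
    table = pd.DataFrame(rows, columns=["patch_id", "class", "area_cells"])
    perim = _perimeter_per_patch(global_labels, next_id - 1)
    table["perimeter_edges"] = perim[table["patch_id"].to_numpy()] if len(table) else []
    table["area_km2"] = table["area_cells"] * raster.cell_area_km2
    table["perimeter_m"] = table["perimeter_edges"] * raster.cell_size
    return PatchSet(table=table, labels=global_labels,
                    cell_size=raster.cell_size, connectivity=connectivity)


def _like_adjacencies(values: np.ndarray, mask: np.ndarray) -> dict[int, int]:
    """Single-counted rook adjacencies between same-class cells, per code."""
    out: dict[int, int] = {}
    for axis in (0, 1):
        a = np.take(values, range(values.shape[axis] - 1), axis=axis)
        b = np.take(values, range(1, values.shape[axis]), axis=axis)
        ma = np.take(mask, range(values.shape[axis] - 1), axis=axis)
        mb = np.take(mask, range(1, values.shape[axis]), axis=axis)
        same = (a == b) & ma & mb
        codes, counts = np.unique(a[same], return_counts=True)
        for c, n in zip(codes, counts):
            out[int(c)] = out.get(int(c), 0) + int(n)
    return out


def _adjacency_matrix(values: np.ndarray, mask: np.ndarray,
                      codes: list[int]) -> np.ndarray:
    """Double-counted rook adjacency counts g[i, k] between class codes."""
    idx = {c: i for i, c in enumerate(codes)}
    m = len(codes)
    g = np.zeros((m, m), dtype=np.int64)
    for axis in (0, 1):
        a = np.take(values, range(values.shape[axis] - 1), axis=axis)
        b = np.take(values, range(1, values.shape[axis]), axis=axis)
        ma = np.take(mask, range(values.shape[axis] - 1), axis=axis)
        mb = np.take(mask, range(1, values.shape[axis]), axis=axis)
        ok = ma & mb
        ia = np.vectorize(idx.get)(a[ok]) if ok.any() else np.array([], dtype=int)
        ib = np.vectorize(idx.get)(b[ok]) if ok.any() else np.array([], dtype=int)
        np.add.at(g, (ia, ib), 1)
        np.add.at(g, (ib, ia), 1)
    return g


def _max_like_adjacencies(area_cells: int) -> int:
    """Maximum single-counted like adjacencies for a class of given area,
    achieved by the near-square arrangement."""
    n = int(np.floor(np.sqrt(area_cells)))
    m = area_cells - n * n
    if m == 0:
        return 2 * n * (n - 1)
    if m <= n:
        return 2 * n * (n - 1) + 2 * m - 1
    return 2 * n * (n - 1) + 2 * m - 2


def _cohesion(perims: np.ndarray, areas: np.ndarray, total_cells: int) -> float:
    """Patch cohesion index from per-patch perimeters (edges) and areas
    (cells); total_cells is the landscape cell count Z."""
    if total_cells <= 1:
        return float("nan")
    num = perims.sum()
    den = (perims * np.sqrt(areas)).sum()
    return 100.0 * (1.0 - num / den) / (1.0 - 1.0 / np.sqrt(total_cells))


def shannon_indices(proportions) -> tuple[float, float]:
    """SHDI and SHEI from class proportions (any positive weights; they are
    renormalised).  SHEI uses m = number of classes with positive share and
    is defined as 0 when m = 1."""
    p = np.asarray(list(proportions), dtype=float)
    p = p[p > 0]
    if p.size == 0:
        raise ValueError("no classes with positive share")
    p = p / p.sum()
    shdi = float(-(p * np.log(p)).sum())
    shei = 0.0 if p.size == 1 else shdi / float(np.log(p.size))
    return shdi, shei


def class_metrics(patches: PatchSet, raster: LandUseRaster) -> pd.DataFrame:
    """Class-level CA, NP, LPI, LSI, COHESION, AI.

    Classes absent from the raster are omitted from the result rather than
    reported as zero.
    """
    mask = raster.mask()
    total_cells = int(np.count_nonzero(mask))
    total_km2 = total_cells * raster.cell_area_km2
    like = _like_adjacencies(raster.values, mask)
    rows = {}
    for name in raster.legend:
        sub = patches.table[patches.table["class"] == name]
        if sub.empty:
            continue
        areas = sub["area_cells"].to_numpy(dtype=float)
        perims = sub["perimeter_edges"].to_numpy(dtype=float)
        a_i = int(areas.sum())
        g_ii = like.get(raster.legend[name], 0)
        max_g = _max_like_adjacencies(a_i)
        rows[name] = {
            "CA": a_i * raster.cell_area_km2,
            "NP": len(sub),
            "LPI": 100.0 * areas.max() * raster.cell_area_km2 / total_km2,
            "LSI": 0.25 * perims.sum() / np.sqrt(a_i),
            "COHESION": _cohesion(perims, areas, total_cells),
            "AI": 100.0 * g_ii / max_g if max_g > 0 else 100.0,
        }
    df = pd.DataFrame(rows).T
    df.index.name = "class"
    return df


def _total_edge_edges(values: np.ndarray, mask: np.ndarray) -> int:
    """Total landscape edge length in cell edges, each internal edge counted
    once, including the boundary with nodata and the raster border."""
    total = 0
    padded_vals = np.pad(values, 1, constant_values=-1)
    padded_mask = np.pad(mask, 1, constant_values=False)
    for dr, dc in ((0, 1), (1, 0)):
        a = padded_vals[1:-1, 1:-1]
        b = padded_vals[1 + dr:padded_vals.shape[0] - 1 + dr,
                        1 + dc:padded_vals.shape[1] - 1 + dc]
        mb = padded_mask[1 + dr:padded_mask.shape[0] - 1 + dr,
                         1 + dc:padded_mask.shape[1] - 1 + dc]
        total += int(np.count_nonzero(mask & mb & (a != b)))
        # border / nodata edges, both orientations
        total += int(np.count_nonzero(mask & ~mb))
        total += int(np.count_nonzero(~mask & mb))
    # leading border row/column not covered by the positive shifts
    total += int(np.count_nonzero(mask[0, :])) + int(np.count_nonzero(mask[:, 0]))
    return total


def landscape_metrics(patches: PatchSet, raster: LandUseRaster) -> pd.Series:
    """Landscape-level LPI, FRAC_AM, CONTAG, COHESION, SHDI, SHEI, LSI."""
    mask = raster.mask()
    total_cells = int(np.count_nonzero(mask))
    if total_cells == 0:
        raise ValueError("raster contains no classified cells")
    total_km2 = total_cells * raster.cell_area_km2
    tab = patches.table
    areas = tab["area_cells"].to_numpy(dtype=float)
    perims = tab["perimeter_edges"].to_numpy(dtype=float)

    # FRAC_AM: area-weighted mean patch fractal dimension, p metres, a m².
    a_m2 = areas * raster.cell_size**2
    p_m = perims * raster.cell_size
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = 2.0 * np.log(0.25 * p_m) / np.log(a_m2)
    frac = np.where(np.log(a_m2) == 0, 1.0, frac)
    frac_am = float((frac * a_m2).sum() / a_m2.sum())

    # CONTAG over classes present, double-counted adjacencies.
    present = [c for c in raster.legend if (raster.values[mask] == raster.legend[c]).any()]
    codes = [raster.legend[c] for c in present]
    m = len(present)
    counts = np.array(
        [np.count_nonzero((raster.values == c) & mask) for c in codes], dtype=float
    )
    p_i = counts / counts.sum()
    if m == 1:
        contag = 100.0
    else:
        g = _adjacency_matrix(raster.values, mask, codes).astype(float)
        row_sums = g.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            q = np.where(row_sums > 0, g / row_sums, 0.0)
        pq = p_i[:, None] * q
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(pq > 0, pq * np.log(pq), 0.0)
        contag = 100.0 * (1.0 + terms.sum() / (2.0 * np.log(m)))

    shdi, shei = shannon_indices(p_i)
    return pd.Series(
        {
            "LPI": 100.0 * areas.max() * raster.cell_area_km2 / total_km2,
            "FRAC_AM": frac_am,
            "CONTAG": contag,
            "COHESION": _cohesion(perims, areas, total_cells),
            "SHDI": shdi,
            "SHEI": shei,
            "LSI": 0.25 * _total_edge_edges(raster.values, mask) / np.sqrt(total_cells),
        }
    )


def metric_timeseries(
    rasters: dict[str, LandUseRaster], connectivity: int = 8
) -> pd.DataFrame:
    """Long-format metric table (date, level, class, metric, value) over a
    date-labelled series of rasters."""
    rows = []
    for date, raster in rasters.items():
        patches = label_patches(raster, connectivity=connectivity)
        for cname, series in class_metrics(patches, raster).iterrows():
            for metric, value in series.items():
                rows.append({"date": date, "level": "class", "class": cname,
                             "metric": metric, "value": float(value)})
        for metric, value in landscape_metrics(patches, raster).items():
            rows.append({"date": date, "level": "landscape", "class": "",
                         "metric": metric, "value": float(value)})
    return pd.DataFrame(rows, columns=["date", "level", "class", "metric", "value"])
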