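"""Land-use change accounting.

Three classic change-detection quantities for categorical rasters:

- per-class areas and composition ratios (km² and % of classified area);
- the dynamic degree of land use ``K = (U_j - U_i) / U_i * (1/T) * 100``,
  the annualised relative area change of one class between two dates, in
  percent per year;
- the land-use transition matrix ``B``, the class-by-class cross-tabulation
  of cell-wise transitions converted to km², whose row sums reproduce the
  early-date class areas and column sums the late-date class areas.

Composition ratios use the sum of the six classified class areas as the
denominator, not any external administrative total; this is the convention
that makes areas and ratios mutually consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .raster import LandUseRaster

__all__ = [
    "class_areas",
    "dynamic_degree",
    "transition_matrix",
    "flow_export",
]


def class_areas(raster: LandUseRaster, date: str | None = None) -> pd.DataFrame:
    """Per-class area (km²) and ratio (% of total classified area).

    Returns a DataFrame indexed by class name with columns ``area_km2``
    and ``ratio_pct`` (and ``date`` when given).  Nodata cells are excluded.
    """
    counts = {}
    mask = raster.mask()
    if not mask.any():
        raise ValueError("raster contains no classified cells")
    for name, code in raster.legend.items():
        counts[name] = int(np.count_nonzero((raster.values == code) & mask))
    cell_area = raster.cell_area_km2
    areas = {name: n * cell_area for name, n in counts.items()}
    total = sum(areas.values())
    df = pd.DataFrame(
        {
            "area_km2": pd.Series(areas),
            "ratio_pct": pd.Series({k: 100.0 * v / total for k, v in areas.items()}),
        }
    )
    df.index.name = "class"
    if date is not None:
        df.insert(0, "date", date)
    return df


def dynamic_degree(u_early: float, u_late: float, years: float) -> float:
    """Dynamic degree of land use, in percent per year.

    ``K = (U_j - U_i) / U_i * (1 / T) * 100`` with ``U_i`` the early-date
    and ``U_j`` the late-date area of one class and ``T`` the elapsed years.
    The sign of K is the sign of the area change.

    Raises
    ------
    ValueError
        If ``u_early`` is not positive (the relative change is undefined)
        or ``years`` is not positive.
    """
    if u_early <= 0:
        raise ValueError("early-date area must be positive")
    if years <= 0:
        raise ValueError("time span must be positive")
    return (u_late - u_early) / u_early / years * 100.0


def transition_matrix(early: LandUseRaster, late: LandUseRaster) -> pd.DataFrame:
    """Class-by-class transition areas B (km²) between two dates.

    ``B.loc[i, j]`` is the area of class *i* at the early date that is class
    *j* at the late date.  Cells that are nodata at either date are excluded
    from both marginals.  Row sums equal the early-date class areas and
    column sums the late-date class areas over the jointly classified cells.
    """
    if not early.same_grid(late):
        raise ValueError("early and late rasters must share extent and cell size")
    if dict(early.legend) != dict(late.legend):
        raise ValueError("early and late rasters must share the legend")
    names = list(early.legend)
    codes = np.array([early.legend[n] for n in names])
    code_to_idx = {c: i for i, c in enumerate(codes)}
    m = len(names)

    mask = early.mask() & late.mask()
    e = early.values[mask]
    l = late.values[mask]
    idx_e = np.vectorize(code_to_idx.get)(e) if e.size else np.array([], dtype=int)
    idx_l = np.vectorize(code_to_idx.get)(l) if l.size else np.array([], dtype=int)
    counts = np.zeros((m, m), dtype=np.int64)
    np.add.at(counts, (idx_e, idx_l), 1)
    b = counts * early.cell_area_km2
    df = pd.DataFrame(b, index=names, columns=names)
    df.index.name = "from"
    df.columns.name = "to"
    return df


def flow_export(matrix: pd.DataFrame, include_diagonal: bool = True) -> pd.DataFrame:
    """Long-format (from, to, area_km2) flow table, zero flows omitted.

    Rows are sorted by decreasing area.  Re-aggregating the table (with
    ``include_diagonal=True``) reconstructs the matrix exactly up to the
    omitted zeros.
    """
    rows = []
    for i in matrix.index:
        for j in matrix.columns:
            v = float(matrix.loc[i, j])
            if v > 0 and (include_diagonal or i != j):
                rows.append({"from": i, "to": j, "area_km2": v})
    df = pd.DataFrame(rows, columns=["from", "to", "area_km2"])
    return df.sort_values("area_km2", ascending=False, ignore_index=True)
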