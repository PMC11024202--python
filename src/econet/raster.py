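"""Raster grid containers and I/O.

Every stage of the pipeline operates on small in-memory grids: a
:class:`RasterGrid` is a rectangular array of values with a cell size in
metres, an origin in map units, and a nodata sentinel.  Land use is a
:class:`LandUseRaster`, a categorical grid over the fixed six-class legend
used throughout (farmland, forest, grassland, water, construction, unused).

Grids are written as single-band TIFF files with the grid metadata (cell
size, origin, nodata, legend) serialised as JSON into the TIFF description
tag, via :mod:`tifffile`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "LEGEND",
    "CLASS_NAMES",
    "RasterGrid",
    "LandUseRaster",
    "read_raster",
    "write_raster",
]

#: Fixed land-use legend: name -> integer class code.
LEGEND: Mapping[str, int] = {
    "farmland": 1,
    "forest": 2,
    "grassland": 3,
    "water": 4,
    "construction": 5,
    "unused": 6,
}

#: Reverse legend: code -> name.
CLASS_NAMES: Mapping[int, str] = {v: k for k, v in LEGEND.items()}


@dataclass
class RasterGrid:
    """A rectangular grid of values on a square-cell lattice.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Cell values.  Class codes for categorical grids, floats otherwise.
    cell_size : float
        Cell edge length in metres.  Must be positive.
    nodata : int or float, optional
        Sentinel marking cells outside the analysis extent.
    origin : tuple of float
        Map coordinates (x, y) of the upper-left corner.
    """

    values: np.ndarray
    cell_size: float = 30.0
    nodata: float | int | None = None
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.values.size == 0:
            raise ValueError("raster extent must be non-empty")
        if not self.cell_size > 0:
            raise ValueError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def cell_area_km2(self) -> float:
        """Area of one cell in square kilometres."""
        return self.cell_size**2 / 1e6

    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries data."""
        if self.nodata is None:
            return np.ones(self.shape, dtype=bool)
        return self.values != self.nodata

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        """New grid with the same geometry but different values."""
        return replace(self, values=np.asarray(values))

    def same_grid(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.cell_size == other.cell_size


@dataclass
class LandUseRaster(RasterGrid):
    """Categorical land-use grid over the six-class legend."""

    legend: Mapping[str, int] = field(default_factory=lambda: dict(LEGEND))

    def __post_init__(self) -> None:
        super().__post_init__()
        self.values = self.values.astype(np.int64, copy=False)
        codes = set(np.unique(self.values).tolist())
        allowed = set(self.legend.values())
        if self.nodata is not None:
            allowed.add(int(self.nodata))
        unknown = codes - allowed
        if unknown:
            raise ValueError(f"cells carry codes outside the legend: {sorted(unknown)}")

    def class_mask(self, name: str) -> np.ndarray:
        """Boolean mask of cells belonging to the named class."""
        return self.values == self.legend[name]

    def class_counts(self) -> dict[str, int]:
        """Cell count per legend class (zero for absent classes)."""
        return {
            name: int(np.count_nonzero(self.values == code))
            for name, code in self.legend.items()
        }


def write_raster(path, grid: RasterGrid) -> None:
    """Write a grid as a single-band TIFF with JSON metadata."""
    import tifffile

    meta = {
        "cell_size": grid.cell_size,
        "origin": list(grid.origin),
        "nodata": grid.nodata,
        "categorical": isinstance(grid, LandUseRaster),
    }
    if isinstance(grid, LandUseRaster):
        meta["legend"] = dict(grid.legend)
    values = grid.values
    if values.dtype == np.int64:
        values = values.astype(np.int32)
    tifffile.imwrite(str(path), values, description=json.dumps(meta))


def read_raster(path) -> RasterGrid:
    """Read a grid written by :func:`write_raster`.

    Returns a :class:`LandUseRaster` when the file carries a legend.
    """
    import tifffile

    with tifffile.TiffFile(str(path)) as tif:
        page = tif.pages[0]
        values = page.asarray()
        meta = {}
        desc = page.tags.get("ImageDescription")
        if desc is not None:
            try:
                meta = json.loads(desc.value)
            except (TypeError, ValueError):
                meta = {}
    kwargs = dict(
        cell_size=float(meta.get("cell_size", 30.0)),
        nodata=meta.get("nodata"),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
    )
    if meta.get("categorical"):
        legend = {str(k): int(v) for k, v in meta.get("legend", LEGEND).items()}
        return LandUseRaster(values, legend=legend, **kwargs)
    return RasterGrid(values, **kwargs)
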