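"""Synthetic landscape generation.

Emulates the kind of inputs the analysis pipeline consumes: a clustered
multi-class land-use mosaic dominated by farmland, multi-date series with
prescribed class-to-class conversions (urban expansion eating farmland
around a seed), a smooth plains-plus-hills DEM, and an NDVI field whose
class means are ordered forest > grassland > farmland > water/construction.

Clustered categorical mosaics are produced by thresholding a Gaussian-
smoothed white-noise field at the quantiles of the requested class
proportions.  This is a standard neutral-landscape construction: it is
cheap, exactly controllable in composition, and yields large contiguous
patches whose typical size grows with the smoothing length.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .raster import LEGEND, LandUseRaster, RasterGrid

__all__ = [
    "TransitionRule",
    "ScenarioConfig",
    "generate_landuse",
    "evolve_landuse",
    "generate_dem",
    "generate_ndvi",
]


@dataclass
class TransitionRule:
    """One prescribed class-to-class conversion for :func:`evolve_landuse`.

    ``area_fraction`` is the fraction of the whole raster extent to convert;
    ``rule`` picks where the converted cells are taken from the source class:

    - ``near_urban_seed``: closest to the largest existing construction
      patch, so conversions grow contiguously out of the urban seed;
    - ``near_class_boundary``: closest to existing cells of the target
      class;
    - ``random``: uniformly at random over the source class.
    """

    from_class: str
    to_class: str
    area_fraction: float
    rule: str = "near_urban_seed"

    def __post_init__(self) -> None:
        if self.area_fraction < 0:
            raise ValueError("area_fraction must be non-negative")
        if self.rule not in ("near_urban_seed", "near_class_boundary", "random"):
            raise ValueError(f"unknown spatial rule {self.rule!r}")


@dataclass
class ScenarioConfig:
    """Parameters for one synthetic land-use scenario."""

    extent: tuple[int, int] = (200, 200)
    cell_size: float = 30.0
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "farmland": 0.65,
            "forest": 0.10,
            "grassland": 0.02,
            "water": 0.03,
            "construction": 0.19,
            "unused": 0.01,
        }
    )
    clustering: float = 8.0
    transitions: list[TransitionRule] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        rows, cols = self.extent
        if rows <= 0 or cols <= 0:
            raise ValueError("extent must be positive in both dimensions")
        unknown = set(self.class_proportions) - set(LEGEND)
        if unknown:
            raise ValueError(f"proportions name unknown classes: {sorted(unknown)}")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class proportions must sum to 1, got {total}")


def _smoothed_field(shape, clustering, rng) -> np.ndarray:
    """White noise smoothed by a Gaussian of the given length (cells)."""
    noise = rng.standard_normal(shape)
    if clustering > 0:
        noise = ndimage.gaussian_filter(noise, sigma=clustering, mode="reflect")
    return noise


def generate_landuse(config: ScenarioConfig) -> LandUseRaster:
    """Generate a clustered categorical land-use mosaic.

    The smoothed field is sliced at the empirical quantiles of the requested
    proportions, so realised composition matches the request up to quantile
    granularity (ties in the smoothed field are measure-zero).  Deterministic
    for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    fld = _smoothed_field(config.extent, config.clustering, rng)

    # Assign classes along the sorted field: contiguous quantile slabs.
    # Slab order is fixed so that spatial neighbourhoods are plausible:
    # construction cores sit inside farmland, which grades into forest,
    # grassland and water.  (Classes only border their slab neighbours.)
    order = np.argsort(fld, axis=None)
    n = fld.size
    values = np.empty(n, dtype=np.int64)
    start = 0
    slab_order = ["construction", "farmland", "forest", "grassland", "water",
                  "unused"]
    items = [(name, config.class_proportions[name]) for name in slab_order
             if config.class_proportions.get(name, 0) > 0]
    for i, (name, frac) in enumerate(items):
        stop = n if i == len(items) - 1 else start + int(round(frac * n))
        values[order[start:stop]] = LEGEND[name]
        start = stop
    return LandUseRaster(values.reshape(config.extent), cell_size=config.cell_size)


def _urban_seed_distance(landuse: LandUseRaster) -> np.ndarray:
    """Distance (cells) from the largest construction patch; falls back to
    the raster centre when no construction exists."""
    mask = landuse.class_mask("construction")
    if mask.any():
        labels, nlab = ndimage.label(mask, structure=np.ones((3, 3)))
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, nlab + 1))
        seed = labels == (1 + int(np.argmax(sizes)))
    else:
        seed = np.zeros(landuse.shape, dtype=bool)
        seed[landuse.shape[0] // 2, landuse.shape[1] // 2] = True
    return ndimage.distance_transform_edt(~seed)


def _grow_from_seed(landuse: LandUseRaster, from_code: int, n_convert: int,
                    rng) -> np.ndarray:
    """Pick ``n_convert`` source-class cells by region growing out of the
    urban seed, so conversions stay contiguous to existing construction.
    Falls back to nearest-by-distance cells when the contiguous frontier is
    exhausted."""
    values = landuse.values
    dist = _urban_seed_distance(landuse)
    candidate = values == from_code
    mass = landuse.class_mask("construction")
    if not mass.any():
        mass = dist == 0
    chosen_mask = np.zeros(values.shape, dtype=bool)
    remaining = n_convert
    while remaining > 0:
        frontier = candidate & ~chosen_mask & \
            ndimage.binary_dilation(mass | chosen_mask, structure=np.ones((3, 3)))
        idx = np.flatnonzero(frontier.ravel())
        if idx.size == 0:  # no contiguous growth possible any more
            idx = np.flatnonzero((candidate & ~chosen_mask).ravel())
            key = dist.ravel()[idx] + rng.random(idx.size) * 1e-6
            take = idx[np.argsort(key)[:remaining]]
            chosen_mask.ravel()[take] = True
            break
        key = dist.ravel()[idx] + rng.random(idx.size) * 1e-6
        take = idx[np.argsort(key)[: min(remaining, idx.size)]]
        chosen_mask.ravel()[take] = True
        remaining -= take.size
    return np.flatnonzero(chosen_mask.ravel())


def evolve_landuse(base: LandUseRaster, config: ScenarioConfig) -> LandUseRaster:
    """Apply the prescribed conversions to produce a later-date raster.

    Each :class:`TransitionRule` converts ``round(area_fraction * n_cells)``
    cells of the source class, chosen by the rule's spatial preference.
    Rules are applied in order on a working copy, so a cell converted by an
    earlier rule is no longer available to later ones.

    Raises
    ------
    ValueError
        If a rule requests more cells than the source class still has.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    values = base.values.copy()
    n = values.size
    for rule in config.transitions:
        from_code = LEGEND[rule.from_class]
        to_code = LEGEND[rule.to_class]
        n_convert = int(round(rule.area_fraction * n))
        if n_convert == 0:
            continue
        candidates = np.flatnonzero(values.ravel() == from_code)
        if n_convert > candidates.size:
            raise ValueError(
                f"transition {rule.from_class}->{rule.to_class} requests "
                f"{n_convert} cells but only {candidates.size} are available"
            )
        current = LandUseRaster(values, cell_size=base.cell_size, legend=base.legend)
        if rule.rule == "random":
            chosen = rng.choice(candidates, size=n_convert, replace=False)
        elif rule.rule == "near_urban_seed":
            chosen = _grow_from_seed(current, from_code, n_convert, rng)
        else:  # near_class_boundary
            target = values == to_code
            if target.any():
                dist = ndimage.distance_transform_edt(~target)
            else:
                dist = _urban_seed_distance(current)
            # Tiny random jitter breaks distance ties reproducibly.
            key = dist.ravel()[candidates] + rng.random(candidates.size) * 1e-6
            chosen = candidates[np.argsort(key)[:n_convert]]
        values.ravel()[chosen] = to_code
    return LandUseRaster(
        values, cell_size=base.cell_size, nodata=base.nodata,
        origin=base.origin, legend=base.legend,
    )


def generate_dem(
    extent: tuple[int, int],
    cell_size: float = 30.0,
    hill_fraction: float = 0.1,
    base_elevation: float = 30.0,
    hill_height: float = 170.0,
    smoothing: float = 12.0,
    seed: int = 0,
) -> RasterGrid:
    """Generate a smooth DEM of plains with a prescribed hill fraction.

    A smoothed random field is rescaled so that ``hill_fraction`` of cells
    sit above the plains level; hills rise up to ``hill_height`` metres
    above ``base_elevation``.  ``hill_fraction = 0`` yields a constant
    plain.
    """
    rows, cols = extent
    if rows <= 0 or cols <= 0:
        raise ValueError("extent must be positive in both dimensions")
    if hill_fraction <= 0:
        values = np.full(extent, base_elevation, dtype=float)
        return RasterGrid(values, cell_size=cell_size)
    rng = np.random.default_rng(seed)
    fld = _smoothed_field(extent, smoothing, rng)
    threshold = np.quantile(fld, 1.0 - hill_fraction)
    relief = np.clip(fld - threshold, 0.0, None)
    if relief.max() > 0:
        relief = relief / relief.max() * hill_height
    return RasterGrid(base_elevation + relief, cell_size=cell_size)


#: Default per-class NDVI means: forest > grassland > farmland > water/built.
DEFAULT_NDVI_MEANS = {
    "forest": 0.75,
    "grassland": 0.55,
    "farmland": 0.40,
    "unused": 0.15,
    "construction": 0.08,
    "water": 0.02,
}


def generate_ndvi(
    landuse: LandUseRaster,
    noise_sd: float = 0.05,
    class_means: dict[str, float] | None = None,
    seed: int = 0,
) -> RasterGrid:
    """NDVI field correlated with vegetation classes, clipped to [-1, 1]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    means = dict(DEFAULT_NDVI_MEANS)
    if class_means:
        means.update(class_means)
    rng = np.random.default_rng(seed)
    values = np.zeros(landuse.shape, dtype=float)
    for name, code in landuse.legend.items():
        values[landuse.values == code] = means.get(name, 0.0)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=landuse.shape)
    return RasterGrid(np.clip(values, -1.0, 1.0), cell_size=landuse.cell_size)
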