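"""Habitat-quality model (InVEST-style).

Habitat quality is habitat suitability H degraded by distance-decayed,
sensitivity-weighted threats through a half-saturation response:

- each threat r emanates from its source land-use class with a maximum
  impact distance ``d_max`` (km), a severity weight ``w_r`` and a linear or
  exponential distance decay ``i(d)``;
- the degradation score of a cell x of class j is

  ``D_x = sum_r (w_r / sum_w) * (1/N_r(x)) * sum_{y in threat r, d<=d_max}
  i(d_xy) * S_jr``

  where ``S_jr`` is the sensitivity of class j to threat r and ``N_r(x)``
  the number of threat-r cells within ``d_max`` of x (density
  normalisation, keeping D bounded in [0, 1] per threat);
- quality is ``Q_x = H_j * (1 - D_x^z / (D_x^z + k^z))`` with exponent
  ``z = 2.5`` and half-saturation ``k = 0.5``.

Decays: linear ``i = 1 - d/d_max``; exponential ``i = exp(-2.99 d/d_max)``
(about 5% remaining influence at ``d_max``); both cut to 0 beyond
``d_max``.  Distances are Euclidean between cell centres.  The influence
sums are evaluated by FFT convolution of the threat presence mask with the
decay kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .raster import LandUseRaster, RasterGrid

__all__ = [
    "Threat",
    "ThreatSpec",
    "SensitivityTable",
    "DEFAULT_THREATS",
    "DEFAULT_SENSITIVITY",
    "threat_rasters",
    "degradation",
    "quality",
    "quality_grade",
]


@dataclass
class Threat:
    """One threat factor: its source class, reach, severity and decay."""

    name: str
    source_class: str
    d_max_km: float
    weight: float
    decay: str = "linear"

    def __post_init__(self) -> None:
        if self.d_max_km <= 0:
            raise ValueError("d_max_km must be positive")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.decay not in ("linear", "exponential"):
            raise ValueError(f"unknown decay {self.decay!r}")


@dataclass
class ThreatSpec:
    """The set of threat factors."""

    threats: list[Threat]

    @property
    def total_weight(self) -> float:
        return sum(t.weight for t in self.threats)


#: Default threat parameterisation: farmland (4 km, w 0.5, linear),
#: construction (10 km, w 1, exponential), bare/unused land (2 km, w 3,
#: linear).
DEFAULT_THREATS = ThreatSpec(
    threats=[
        Threat("farmland", "farmland", 4.0, 0.5, "linear"),
        Threat("construction", "construction", 10.0, 1.0, "exponential"),
        Threat("bare_land", "unused", 2.0, 3.0, "linear"),
    ]
)


@dataclass
class SensitivityTable:
    """Habitat suitability H_j per class and sensitivity S_jr per threat.

    ``suitability`` maps class name -> H in [0, 1]; ``sensitivity`` maps
    class name -> {threat name -> S in [0, 1]}.
    """

    suitability: dict[str, float]
    sensitivity: dict[str, dict[str, float]]

    def __post_init__(self) -> None:
        for j, h in self.suitability.items():
            if not 0 <= h <= 1:
                raise ValueError(f"suitability of {j} outside [0, 1]")
        for j, row in self.sensitivity.items():
            for r, s in row.items():
                if not 0 <= s <= 1:
                    raise ValueError(f"sensitivity {j}/{r} outside [0, 1]")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SensitivityTable":
        """Build from a table with columns ``class``, ``suitability`` and
        one column per threat name."""
        df = df.set_index("class")
        threats = [c for c in df.columns if c != "suitability"]
        return cls(
            suitability=df["suitability"].to_dict(),
            sensitivity={j: {r: float(df.loc[j, r]) for r in threats}
                         for j in df.index},
        )


#: Default sensitivities (rows: land-use class; columns: threats).
DEFAULT_SENSITIVITY = SensitivityTable(
    suitability={
        "farmland": 0.2, "forest": 1.0, "grassland": 0.7, "water": 0.9,
        "construction": 0.0, "unused": 0.0,
    },
    sensitivity={
        "farmland": {"farmland": 0.3, "construction": 0.7, "bare_land": 0.5},
        "forest": {"farmland": 0.7, "construction": 0.9, "bare_land": 0.6},
        "grassland": {"farmland": 0.6, "construction": 0.6, "bare_land": 0.4},
        "water": {"farmland": 0.65, "construction": 0.85, "bare_land": 0.5},
        "construction": {"farmland": 0.0, "construction": 0.0, "bare_land": 0.0},
        "unused": {"farmland": 0.0, "construction": 0.0, "bare_land": 0.0},
    },
)


def threat_rasters(
    landuse: LandUseRaster, spec: ThreatSpec = DEFAULT_THREATS
) -> dict[str, np.ndarray]:
    """Binary presence grid per threat (1 on the threat's source class)."""
    out = {}
    for t in spec.threats:
        if t.source_class not in landuse.legend:
            raise ValueError(f"threat source class {t.source_class!r} not in legend")
        out[t.name] = landuse.class_mask(t.source_class).astype(np.uint8)
    return out


def _decay_kernel(threat: Threat, cell_size: float) -> np.ndarray:
    """Radially symmetric decay kernel i(d) sampled at cell centres."""
    d_max = threat.d_max_km * 1000.0
    radius = int(np.floor(d_max / cell_size))
    r = np.arange(-radius, radius + 1, dtype=float)
    d = np.hypot(r[:, None], r[None, :]) * cell_size
    if threat.decay == "linear":
        i = np.clip(1.0 - d / d_max, 0.0, None)
    else:
        i = np.exp(-2.99 * d / d_max)
    i[d > d_max] = 0.0
    return i


def degradation(
    landuse: LandUseRaster,
    threats: dict[str, np.ndarray] | None = None,
    spec: ThreatSpec = DEFAULT_THREATS,
    sens: SensitivityTable = DEFAULT_SENSITIVITY,
) -> RasterGrid:
    """Per-cell degradation score D (dimensionless, >= 0)."""
    if threats is None:
        threats = threat_rasters(landuse, spec)
    total_w = spec.total_weight
    d_total = np.zeros(landuse.shape, dtype=float)
    for t in spec.threats:
        mask = threats[t.name].astype(float)
        if not mask.any():
            continue
        kernel = _decay_kernel(t, landuse.cell_size)
        influence = fftconvolve(mask, kernel, mode="same")
        n_sources = fftconvolve(mask, (kernel > 0).astype(float), mode="same")
        with np.errstate(divide="ignore", invalid="ignore"):
            mean_influence = np.where(n_sources > 0.5, influence / np.maximum(n_sources, 1e-12), 0.0)
        mean_influence = np.clip(mean_influence, 0.0, None)
        s_map = np.zeros(landuse.shape, dtype=float)
        for j, code in landuse.legend.items():
            s_map[landuse.values == code] = sens.sensitivity.get(j, {}).get(t.name, 0.0)
        d_total += (t.weight / total_w) * mean_influence * s_map
    return RasterGrid(d_total, cell_size=landuse.cell_size)


def quality(
    d: RasterGrid,
    landuse: LandUseRaster,
    sens: SensitivityTable = DEFAULT_SENSITIVITY,
    z: float = 2.5,
    k: float = 0.5,
) -> RasterGrid:
    """Habitat quality Q = H * (1 - D^z / (D^z + k^z)), in [0, 1]."""
    if k <= 0:
        raise ValueError("half-saturation k must be positive")
    if (d.values < 0).any():
        raise ValueError("degradation must be non-negative")
    h_map = np.zeros(landuse.shape, dtype=float)
    for j, code in landuse.legend.items():
        h_map[landuse.values == code] = sens.suitability.get(j, 0.0)
    dz = np.power(d.values, z)
    q = h_map * (1.0 - dz / (dz + k**z))
    return RasterGrid(q, cell_size=landuse.cell_size)


def quality_grade(
    q: RasterGrid, n_classes: int = 5, method: str = "equal_interval"
) -> RasterGrid:
    """Grade quality into levels 1..n (1 = best) by equal intervals over
    [0, 1] or by quantiles.  A constant raster collapses to a single level
    (level 1) under quantile grading."""
    v = q.values
    if (v < 0).any() or (v > 1).any():
        raise ValueError("quality must lie in [0, 1]")
    if method == "equal_interval":
        edges = np.linspace(0.0, 1.0, n_classes + 1)[1:-1]
    elif method == "quantile":
        edges = np.unique(np.quantile(v, np.linspace(0, 1, n_classes + 1)[1:-1]))
        if edges.size == 0 or v.min() == v.max():
            return q.copy_with(np.ones_like(v, dtype=np.int16))
    else:
        raise ValueError(f"unknown grading method {method!r}")
    # np.digitize bins ascending; best quality = highest Q = level 1.
    bins = np.digitize(v, edges, right=False)
    n_levels = len(edges) + 1
    levels = n_levels - bins
    return q.copy_with(levels.astype(np.int16))
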