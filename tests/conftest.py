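import numpy as np
import pytest

from econet.raster import LEGEND, LandUseRaster
from econet.synthetic import ScenarioConfig, generate_landuse


def make_landuse(codes, cell_size=30.0):
    """LandUseRaster from a small integer array of legend codes."""
    return LandUseRaster(np.asarray(codes, dtype=np.int64), cell_size=cell_size)


@pytest.fixture(scope="session")
def default_proportions():
    return {
        "farmland": 0.65, "forest": 0.10, "grassland": 0.02,
        "water": 0.03, "construction": 0.19, "unused": 0.01,
    }


@pytest.fixture(scope="session")
def small_mosaic():
    """A clustered 60x60 six-class mosaic used across module tests."""
    return generate_landuse(ScenarioConfig(extent=(60, 60), seed=42))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_landuse(rng, shape, n_classes=6):
    """Unclustered random land-use raster (worst case for patch metrics)."""
    codes = list(LEGEND.values())[:n_classes]
    return LandUseRaster(rng.choice(codes, size=shape), cell_size=30.0)
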