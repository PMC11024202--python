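import numpy as np
import pytest

import oracles
from econet.corridors import (
    Corridor,
    classify_corridors,
    derive_terrain,
    grade_factors,
    least_cost_corridors,
    resistance_surface,
)
from econet.raster import LEGEND, RasterGrid
from econet.sources import SourcePatch


def cell_source(pid, row, col, tier="general"):
    return SourcePatch(id=pid, area_km2=0.0009, mean_quality=1.0,
                       cells=np.array([[row, col]]), centroid=(row, col),
                       tier=tier)


class TestDeriveTerrain:
    def test_flat_dem(self):
        slope, relief = derive_terrain(RasterGrid(np.zeros((10, 10))))
        assert (slope.values == 0).all()
        assert (relief.values == 0).all()

    def test_inclined_plane_slope(self):
        g = 0.2  # rise per metre along x
        x = np.arange(20) * 30.0
        dem = RasterGrid(np.tile(g * x, (20, 1)), cell_size=30.0)
        slope, _ = derive_terrain(dem)
        interior = slope.values[1:-1, 1:-1]
        assert np.allclose(interior, np.degrees(np.arctan(g)), atol=1e-9)

    def test_relief_matches_window_scan(self, rng):
        dem = RasterGrid(rng.random((15, 15)) * 100, cell_size=30.0)
        _, relief = derive_terrain(dem, relief_window=5)
        z = dem.values
        r, c = 7, 7
        window = z[r - 2:r + 3, c - 2:c + 3]
        assert relief.values[r, c] == pytest.approx(window.max() - window.min())

    def test_single_cell_rejected(self):
        with pytest.raises(ValueError):
            derive_terrain(RasterGrid(np.zeros((1, 1))))


class TestGradingAndSurface:
    def test_landuse_and_terrain_levels(self, small_mosaic):
        dem_vals = np.full(small_mosaic.shape, 45.0)
        dem = RasterGrid(dem_vals, cell_size=30.0)
        slope = RasterGrid(np.full(small_mosaic.shape, 12.0))
        relief = RasterGrid(np.zeros(small_mosaic.shape))
        ndvi = RasterGrid(np.random.default_rng(0).random(small_mosaic.shape))
        quality = RasterGrid(np.full(small_mosaic.shape, 0.9))
        levels = grade_factors(quality, small_mosaic, ndvi, slope, relief, dem)
        assert (levels["elevation"] == 2).all()     # 30-60 m
        assert (levels["slope"] == 3).all()         # 10-20 degrees
        forest = small_mosaic.class_mask("forest")
        constr = small_mosaic.class_mask("construction")
        assert (levels["landuse"][forest] == 1).all()
        assert (levels["landuse"][constr] == 5).all()
        assert (levels["habitat_quality"] == 1).all()  # excellent

    def test_surface_extremes_printed_weights(self):
        shape = (4, 4)
        ones = {k: np.ones(shape, dtype=np.int16) for k in
                ("habitat_quality", "landuse", "ndvi", "elevation", "slope",
                 "relief")}
        fives = {k: 5 * v for k, v in ones.items()}
        assert resistance_surface(ones).values.ravel()[0] == pytest.approx(0.98)
        assert resistance_surface(fives).values.ravel()[0] == pytest.approx(4.90)
        assert resistance_surface(
            fives, normalize=True).values.ravel()[0] == pytest.approx(5.0)

    def test_landuse_level_linearity(self):
        shape = (3, 3)
        levels = {k: np.ones(shape, dtype=np.int16) for k in
                  ("habitat_quality", "landuse", "ndvi", "elevation", "slope",
                   "relief")}
        base = resistance_surface(levels).values.copy()
        levels["landuse"][1, 1] += 2
        bumped = resistance_surface(levels).values
        assert bumped[1, 1] - base[1, 1] == pytest.approx(2 * 0.35)

    def test_missing_factor_rejected(self):
        with pytest.raises(ValueError):
            resistance_surface({"landuse": np.ones((2, 2))})


class TestLeastCostCorridors:
    def test_uniform_medium_straight_line(self):
        surface = RasterGrid(np.full((9, 9), 2.0), cell_size=1000.0)
        srcs = [cell_source(1, 4, 0), cell_source(2, 4, 8)]
        (c,) = least_cost_corridors(surface, srcs)
        assert c.length_km == pytest.approx(8.0)
        assert c.cost == pytest.approx(2.0 * 8.0)
        assert (c.path[:, 0] == 4).all()  # straight row

    def test_wall_with_gap_and_enumeration_oracle(self):
        res = np.full((5, 5), 1.0)
        res[:, 2] = 100.0
        res[4, 2] = 1.0  # the gap
        surface = RasterGrid(res, cell_size=1000.0)
        srcs = [cell_source(1, 0, 0), cell_source(2, 0, 4)]
        (c,) = least_cost_corridors(surface, srcs)
        assert (4, 2) in {tuple(p) for p in c.path}
        want = oracles.all_paths_min_cost(res.tolist(), (0, 0), (0, 4),
                                          cell_km=1.0)
        assert c.cost == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_grid_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        res = rng.uniform(0.5, 5.0, size=(4, 4))
        surface = RasterGrid(res, cell_size=1000.0)
        srcs = [cell_source(1, 0, 0), cell_source(2, 3, 3)]
        (c,) = least_cost_corridors(surface, srcs)
        want = oracles.all_paths_min_cost(res.tolist(), (0, 0), (3, 3),
                                          cell_km=1.0)
        assert c.cost == pytest.approx(want, rel=1e-9)

    def test_raising_resistance_never_lowers_cost(self, rng):
        res = rng.uniform(1.0, 3.0, size=(6, 6))
        srcs = [cell_source(1, 0, 0), cell_source(2, 5, 5)]
        (c0,) = least_cost_corridors(RasterGrid(res, cell_size=1000.0), srcs)
        res2 = res.copy()
        res2[2, 2] += 5.0
        (c1,) = least_cost_corridors(RasterGrid(res2, cell_size=1000.0), srcs)
        assert c1.cost >= c0.cost - 1e-12

    def test_corridor_at_least_euclidean_length(self, rng):
        res = rng.uniform(1.0, 4.0, size=(10, 10))
        srcs = [cell_source(1, 0, 0), cell_source(2, 7, 4)]
        (c,) = least_cost_corridors(RasterGrid(res, cell_size=1000.0), srcs)
        assert c.length_km >= np.hypot(7, 4) * 1.0 - 1e-9

    def test_triangle_inequality_on_costs(self, rng):
        res = rng.uniform(1.0, 4.0, size=(8, 8))
        srcs = [cell_source(1, 0, 0), cell_source(2, 0, 7),
                cell_source(3, 7, 3)]
        costs = {}
        for c in least_cost_corridors(RasterGrid(res, cell_size=1000.0),
                                      srcs, pair_mode="all_pairs"):
            costs[(c.source_a, c.source_b)] = c.cost
        assert costs[(1, 2)] <= costs[(1, 3)] + costs[(2, 3)] + 1e-9

    def test_forest_preferred_over_construction(self):
        """With all weight on land use, corridors between forest sources
        run through vegetated cells, not the built-up block."""
        from conftest import make_landuse
        from econet.corridors import LANDUSE_LEVELS

        codes = np.full((9, 9), LEGEND["grassland"])
        codes[2:7, 1:] = LEGEND["construction"]  # town band with a gap at col 0
        codes[0, 2] = codes[8, 2] = LEGEND["forest"]
        lu = make_landuse(codes)
        levels = {"landuse": np.zeros((9, 9), dtype=np.int16)}
        for name, code in lu.legend.items():
            levels["landuse"][lu.values == code] = LANDUSE_LEVELS[name]
        surface = resistance_surface(levels, weights={"landuse": 1.0},
                                     cell_size=30.0)
        srcs = [cell_source(1, 0, 2), cell_source(2, 8, 2)]
        (c,) = least_cost_corridors(surface, srcs)
        assert all(lu.values[r, c_] != LEGEND["construction"]
                   for r, c_ in map(tuple, c.path))

    def test_unreachable_pair_reported(self):
        res = np.full((5, 5), 1.0)
        res[:, 2] = np.inf
        srcs = [cell_source(1, 2, 0), cell_source(2, 2, 4)]
        (c,) = least_cost_corridors(RasterGrid(res, cell_size=1000.0), srcs)
        assert not np.isfinite(c.cost)
        assert len(c.path) == 0

    def test_needs_two_sources(self):
        with pytest.raises(ValueError):
            least_cost_corridors(RasterGrid(np.ones((3, 3))),
                                 [cell_source(1, 0, 0)])


class TestClassifyCorridors:
    def _corridors(self):
        path = np.array([[0, 0], [0, 1]])
        return [Corridor(1, 2, path, cost=1.0, length_km=0.03),
                Corridor(1, 3, path, cost=9.0, length_km=0.03)]

    def test_important_endpoints_rule(self):
        srcs = [cell_source(1, 0, 0, "important"),
                cell_source(2, 0, 5, "important"),
                cell_source(3, 5, 0, "general")]
        out = classify_corridors(self._corridors(), srcs)
        assert out[0].tier == "important"
        assert out[1].tier == "general"

    def test_cost_quantile_rule_preserves_geometry(self):
        srcs = [cell_source(1, 0, 0), cell_source(2, 0, 5),
                cell_source(3, 5, 0)]
        before = [c.path.copy() for c in self._corridors()]
        out = classify_corridors(self._corridors(), srcs, rule="cost_quantile",
                                 cost_quantile=0.5)
        assert out[0].tier == "important"
        assert out[1].tier == "general"
        for c, p in zip(out, before):
            assert (c.path == p).all()
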