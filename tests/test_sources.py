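import numpy as np
import pytest

import oracles
from econet.raster import RasterGrid
from econet.sources import (
    ConnectivityParams,
    SourcePatch,
    candidate_cores,
    dpc,
    interpatch_distances,
    pc_index,
    rank_sources,
    read_conefor,
    write_conefor,
)


def patch(pid, area, row, col=0.0, n_cells=1):
    """A compact square-ish patch around (row, col), for distance tests."""
    side = int(np.ceil(np.sqrt(n_cells)))
    cells = np.array([(int(row) + i, int(col) + j)
                      for i in range(side) for j in range(side)][:n_cells])
    return SourcePatch(id=pid, area_km2=area, mean_quality=1.0,
                       cells=cells, centroid=(row, col))


def collinear_patches(spacing_cells, areas):
    return [patch(i, a, row=0, col=i * spacing_cells)
            for i, a in enumerate(areas)]


class TestCandidateCores:
    def _cores(self, sizes, qualities, shape=(30, 30)):
        from econet.metrics import PatchSet
        import pandas as pd

        labels = np.zeros(shape, dtype=np.int64)
        qgrid = np.zeros(shape, dtype=float)
        rows, r0 = [], 0
        for k, (size, q) in enumerate(zip(sizes, qualities), start=1):
            labels[r0, :size] = k
            qgrid[r0, :size] = q
            rows.append({"patch_id": k, "class": "core", "area_cells": size,
                         "perimeter_edges": 2 * size + 2,
                         "area_km2": size * 0.0009,
                         "perimeter_m": (2 * size + 2) * 30})
            r0 += 2
        table = pd.DataFrame(rows)
        return (PatchSet(table=table, labels=labels, cell_size=30.0),
                RasterGrid(qgrid, cell_size=30.0))

    def test_ranked_by_area(self):
        cores, q = self._cores([5, 3, 1], [0.9, 0.9, 0.9])
        got = candidate_cores(cores, q, n=2)
        assert [s.id for s in got] == [1, 2]

    def test_fewer_than_n_returned(self):
        cores, q = self._cores([4, 2], [0.8, 0.8])
        assert len(candidate_cores(cores, q, n=30)) == 2

    def test_quality_floor_filters(self):
        cores, q = self._cores([5, 3], [0.2, 0.9])
        got = candidate_cores(cores, q, n=30, min_quality=0.5)
        assert [s.id for s in got] == [2]

    def test_area_tie_broken_by_quality_then_id(self):
        cores, q = self._cores([4, 4, 4], [0.6, 0.9, 0.9])
        got = candidate_cores(cores, q, n=3)
        assert [s.id for s in got] == [2, 3, 1]

    def test_no_qualifying_cores_raises(self):
        cores, q = self._cores([3], [0.1])
        with pytest.raises(ValueError):
            candidate_cores(cores, q, min_quality=0.5)


class TestPcIndex:
    def test_single_patch_closed_form(self):
        params = ConnectivityParams(a_l_km2=10.0)
        assert pc_index([patch(0, 4.0, 0)], params) == pytest.approx(
            16.0 / 100.0)

    def test_distant_patches_no_interaction(self):
        params = ConnectivityParams(median_dispersal_m=100.0, a_l_km2=10.0)
        patches = collinear_patches(spacing_cells=100000, areas=[2.0, 3.0])
        got = pc_index(patches, params, cell_size=30.0)
        assert got == pytest.approx((4.0 + 9.0) / 100.0, rel=1e-6)

    def test_stepping_stone_path_product(self):
        """p*_13 through the middle patch beats the long direct hop."""
        params = ConnectivityParams(median_dispersal_m=2500.0, a_l_km2=10.0)
        patches = collinear_patches(spacing_cells=2500 // 30, areas=[1.0, 1.0, 1.0])
        dist = interpatch_distances(patches, 30.0)
        theta = params.theta
        p_direct = np.exp(-theta * dist)
        np.fill_diagonal(p_direct, 1.0)
        want = oracles.pc_bruteforce([1.0, 1.0, 1.0], p_direct.tolist(), 10.0)
        assert pc_index(patches, params) == pytest.approx(want, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 5
        patches = [patch(i, float(rng.uniform(0.5, 3.0)),
                         row=int(rng.integers(0, 60)),
                         col=int(rng.integers(0, 60))) for i in range(n)]
        params = ConnectivityParams(median_dispersal_m=1000.0, a_l_km2=20.0)
        dist = interpatch_distances(patches, 30.0)
        p_direct = np.exp(-params.theta * dist)
        np.fill_diagonal(p_direct, 1.0)
        want = oracles.pc_bruteforce([p.area_km2 for p in patches],
                                     p_direct.tolist(), 20.0)
        assert pc_index(patches, params) == pytest.approx(want, rel=1e-9)

    def test_monotone_in_area(self):
        params = ConnectivityParams(a_l_km2=10.0)
        small = collinear_patches(10, [1.0, 1.0])
        large = collinear_patches(10, [1.5, 1.0])
        assert pc_index(large, params) > pc_index(small, params)


class TestDpc:
    def test_single_patch_is_everything(self):
        params = ConnectivityParams(a_l_km2=5.0)
        assert dpc([patch(0, 2.0, 0)], params, 0) == pytest.approx(100.0)

    def test_two_equal_isolated_patches_50(self):
        params = ConnectivityParams(median_dispersal_m=10.0, a_l_km2=10.0)
        patches = collinear_patches(100000, [1.0, 1.0])
        assert dpc(patches, params, 0) == pytest.approx(50.0, rel=1e-6)

    def test_stepping_stone_importance(self):
        """A negligible-area middle patch still matters when it carries the
        only path between two large patches (direct hop beyond the
        dispersal cutoff)."""
        params = ConnectivityParams(median_dispersal_m=500.0, a_l_km2=50.0,
                                    distance_cutoff_m=1500.0)
        areas = [10.0, 0.001, 10.0]
        patches = collinear_patches(1000 // 30 + 1, areas)  # hops ~1 km
        got = dpc(patches, params, 1)
        # oracle: recompute both PCs by enumeration, honouring the cutoff
        dist = interpatch_distances(patches, 30.0)
        p = np.exp(-params.theta * dist)
        p[dist > params.distance_cutoff_m] = 0.0
        np.fill_diagonal(p, 1.0)
        pc_all = oracles.pc_bruteforce(areas, p.tolist(), 50.0)
        p_rest = p[np.ix_([0, 2], [0, 2])]
        pc_rest = oracles.pc_bruteforce([10.0, 10.0], p_rest.tolist(), 50.0)
        want = 100.0 * (pc_all - pc_rest) / pc_all
        assert got == pytest.approx(want, rel=1e-9)
        assert got > 1.0  # far above its own area share

    def test_tiers_follow_thresholds(self):
        params = ConnectivityParams(median_dispersal_m=2500.0, a_l_km2=10.0)
        patches = collinear_patches(20, [3.0, 0.5, 0.002])
        ranked = rank_sources(patches, params)
        for p in ranked:
            assert 0.0 <= p.dpc <= 100.0
            if p.dpc > 3:
                assert p.tier == "important"
            elif p.dpc > 1:
                assert p.tier == "general"
            else:
                assert p.tier == "excluded"


class TestConeforIO:
    def test_round_trip(self, tmp_path):
        patches = collinear_patches(50, [2.0, 1.0, 0.5])
        nodes_p = tmp_path / "nodes.txt"
        conns_p = tmp_path / "connections.txt"
        write_conefor(patches, 30.0, nodes_p, conns_p)
        nodes, conns = read_conefor(nodes_p, conns_p)
        assert len(nodes) == 3 and len(conns) == 3
        assert nodes["area"].tolist() == pytest.approx([2.0, 1.0, 0.5])
        dist = interpatch_distances(patches, 30.0)
        assert conns["distance"].iloc[0] == pytest.approx(dist[0, 1], abs=1e-3)
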