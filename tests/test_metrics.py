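"""Class- and landscape-scale indices: analytic cases and oracle checks."""

import math

import numpy as np
import pytest
from scipy import stats

import oracles
from patchscape import (
    LandscapeGrid,
    LandscapeComposition,
    aggregation_index,
    class_area,
    class_table,
    cohesion,
    composition,
    count_like_adjacencies,
    delineate,
    format_class_table,
    format_landscape_table,
    geometric_fixture,
    landscape_table,
    largest_patch_index,
    pafrac,
    patch_density,
    pland,
    shannon_diversity,
    shannon_evenness,
)


def _grid(cells, cell_size=30.0):
    return LandscapeGrid(np.asarray(cells, dtype=np.int32), cell_size=cell_size)


class TestAreaComposition:
    def test_class_area_unit_conversion(self):
        # 10,000 cells of 30 m -> 900 ha
        pm = delineate(_grid(np.ones((100, 100))))
        assert class_area(pm, 1) == pytest.approx(900.0)

    def test_class_area_counts_cells(self, random_grid):
        grid = random_grid(seed=2)
        pm = delineate(grid)
        counts = np.unique(grid.cells, return_counts=True)
        for code, n in zip(*counts):
            assert class_area(pm, code) * 10_000 / grid.cell_size ** 2 == \
                pytest.approx(n)

    def test_pland_single_class_is_100(self):
        pm = delineate(_grid(np.ones((5, 5))))
        assert pland(pm, 1) == pytest.approx(100.0)

    def test_pland_sums_to_100(self, random_grid, legend):
        grid = random_grid(seed=7)
        pm = delineate(grid)
        total = sum(pland(pm, code) for code in np.unique(grid.cells))
        assert total == pytest.approx(100.0, abs=1e-9)


class TestDensityAndDominance:
    def test_one_patch_on_100_ha(self):
        # 10x10 cells of 100 m = 1,000,000 m^2 = 100 ha exactly
        pm = delineate(_grid(np.ones((10, 10)), cell_size=100.0))
        assert patch_density(pm) == pytest.approx(1.0)

    def test_lpi_whole_landscape(self):
        pm = delineate(_grid(np.ones((6, 6))))
        assert largest_patch_index(pm) == pytest.approx(100.0)

    def test_lpi_two_equal_halves(self):
        cells = np.ones((4, 4))
        cells[2:, :] = 2
        pm = delineate(_grid(cells))
        assert largest_patch_index(pm) == pytest.approx(50.0)

    def test_lpi_matches_brute_force(self, random_grid):
        grid = random_grid(seed=4)
        pm = delineate(grid)
        for code in np.unique(grid.cells):
            want = oracles.largest_patch_pct(grid.cells, grid.nodata_code,
                                             code, grid.cell_size, 8)
            assert largest_patch_index(pm, code) == pytest.approx(want)


class TestPafrac:
    def test_square_families_give_one(self):
        grid = geometric_fixture(
            (24, 24),
            [("forests", 1, 1, 2, 2), ("forests", 1, 6, 3, 3),
             ("forests", 6, 1, 5, 5), ("forests", 12, 12, 8, 8)],
            background="croplands",
        )
        pm = delineate(grid)
        assert pafrac(pm, grid.cells[1, 1], min_patches=4) == pytest.approx(1.0)

    def test_insufficient_patches_is_na(self, legend):
        grid = geometric_fixture((10, 10), [("water", 2, 2, 3, 3)],
                                 background="forests")
        pm = delineate(grid)
        assert math.isnan(pafrac(pm, legend.code_for_name("water"),
                                 min_patches=10))

    def test_matches_independent_regression(self, legend):
        rng = np.random.default_rng(12)
        rects, r = [], 0
        for _ in range(20):
            h, w = rng.integers(1, 4, size=2)
            rects.append(("grasslands", r, int(rng.integers(0, 30)), int(h), int(w)))
            r += 5
        grid = geometric_fixture((100, 40), rects, background="forests")
        pm = delineate(grid)
        code = legend.code_for_name("grasslands")
        patches = pm.patches_of_class(code)
        slope = stats.linregress(np.log([p.area for p in patches]),
                                 np.log([p.perimeter for p in patches])).slope
        assert pafrac(pm, code, min_patches=2) == pytest.approx(2 * slope)


class TestAggregation:
    def test_solid_block_is_100(self):
        adj = count_like_adjacencies(_grid(np.full((5, 5), 2)))
        assert aggregation_index(adj, 2) == pytest.approx(100.0)

    def test_checkerboard_class_is_zero(self):
        cells = np.indices((4, 4)).sum(axis=0) % 2 + 1
        adj = count_like_adjacencies(_grid(cells))
        assert aggregation_index(adj, 1) == pytest.approx(0.0)

    def test_matches_brute_force(self, random_grid):
        grid = random_grid(nrows=8, ncols=8, seed=6, n_classes=3)
        adj = count_like_adjacencies(grid)
        for code in np.unique(grid.cells):
            want = oracles.aggregation_index_pct(grid.cells, grid.nodata_code,
                                                 code)
            assert aggregation_index(adj, code) == pytest.approx(want)

    def test_landscape_ai_is_area_weighted_mean(self, random_grid):
        grid = random_grid(seed=8)
        adj = count_like_adjacencies(grid)
        z = grid.Z
        want = sum(
            adj.cell_counts[c] / z * aggregation_index(adj, c)
            for c in adj.cell_counts if adj.cell_counts[c] > 0
        )
        assert aggregation_index(adj) == pytest.approx(want)


class TestCohesion:
    def test_single_cell_patch_is_zero(self, legend):
        grid = geometric_fixture((5, 5), [("water", 2, 2, 1, 1)],
                                 background="forests")
        pm = delineate(grid)
        assert cohesion(pm, legend.code_for_name("water")) == pytest.approx(0.0)

    def test_below_100_on_finite_grids(self, random_grid):
        grid = random_grid(seed=10)
        pm = delineate(grid)
        for code in np.unique(grid.cells):
            assert cohesion(pm, code) < 100.0

    def test_matches_direct_formula(self, random_grid):
        grid = random_grid(seed=13)
        pm = delineate(grid)
        for code in np.unique(grid.cells):
            want = oracles.cohesion_pct(grid.cells, grid.nodata_code, code,
                                        grid.cell_size, 8)
            assert cohesion(pm, code) == pytest.approx(want)


class TestDiversity:
    def test_single_class_zero(self):
        comp = LandscapeComposition({1: 1.0}, m=1)
        assert shannon_diversity(comp) == 0.0
        assert shannon_evenness(0.0, 1) == 0.0

    def test_even_split_is_ln2(self):
        comp = LandscapeComposition({1: 0.5, 2: 0.5}, m=2)
        assert shannon_diversity(comp) == pytest.approx(math.log(2))

    def test_equal_proportions_evenness_is_one(self):
        for m in (2, 3, 6):
            comp = LandscapeComposition({i: 1 / m for i in range(m)}, m=m)
            shdi = shannon_diversity(comp)
            assert shannon_evenness(shdi, m) == pytest.approx(1.0)


class TestTables:
    def test_uniform_grid_row(self, legend):
        grid = _grid(np.full((6, 6), legend.code_for_name("forests")))
        tab = class_table(grid, legend)
        assert len(tab) == 1
        row = tab.iloc[0]
        assert row["Landscapes"] == "forests"
        assert row["PLAND"] == pytest.approx(100.0)
        assert row["NP"] == 1
        assert row["LPI"] == pytest.approx(100.0)
        assert row["AI"] == pytest.approx(100.0)

    def test_row_invariants_on_random_grids(self, random_grid, legend):
        for seed in range(20):
            grid = random_grid(nrows=15, ncols=15, seed=seed)
            tab = class_table(grid, legend)
            present = len(np.unique(grid.cells))
            assert len(tab) == present
            assert tab["PLAND"].sum() == pytest.approx(100.0, abs=1e-9)
            for _, row in tab.iterrows():
                assert row["CA"] > 0
                assert 0 < row["PLAND"] <= 100
                assert 0 < row["LPI"] <= row["PLAND"] + 1e-12
                assert 0 <= row["AI"] <= 100
                assert 0 <= row["COHESION"] < 100
                if not math.isnan(row["PAFRAC"]):
                    assert 1.0 - 0.2 <= row["PAFRAC"] <= 2.0 + 0.2

    def test_landscape_rows_in_input_order(self, legend, random_grid):
        grids = [random_grid(seed=s) for s in range(3)]
        for i, g in enumerate(grids):
            g.epoch_label = f"e{i}"
        tab = landscape_table(grids, legend)
        assert list(tab["Years"]) == ["e0", "e1", "e2"]
        assert (tab["NP"] > 0).all()

    def test_shei_identity_per_epoch(self, legend, random_grid):
        tab = landscape_table([random_grid(seed=1)], legend)
        m = len(np.unique(random_grid(seed=1).cells))
        assert tab["SHEI"].iloc[0] * math.log(m) == \
            pytest.approx(tab["SHDI"].iloc[0], abs=1e-9)

    def test_single_class_landscape_row(self, legend):
        grid = _grid(np.full((5, 5), 2))
        tab = landscape_table([grid], legend)
        assert tab["SHDI"].iloc[0] == 0.0
        assert tab["SHEI"].iloc[0] == 0.0

    def test_formatting_rounds_and_renders_na(self, legend):
        grid = geometric_fixture((10, 10), [("water", 2, 2, 3, 3)],
                                 background="forests")
        tab = format_class_table(class_table(grid, legend))
        water = tab[tab["Landscapes"] == "water"].iloc[0]
        assert water["PAFRAC"] == "N/A"
        assert water["CA"] == str(round(9 * 900 / 10_000))
        land = format_landscape_table(landscape_table([grid], legend))
        assert land["PD"].str.count(r"\.").iloc[0] == 1
        assert len(land["PD"].iloc[0].split(".")[1]) == 3
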