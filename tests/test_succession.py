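"""Transition matrices, ecological flow classification, Sankey export."""

import numpy as np
import pytest

import oracles
from patchscape import (
    LandscapeGrid,
    classify_flows,
    sankey_export,
    transition_matrix,
)
from patchscape.legend import ClassLegend, LegendEntry


def _pair(legend, seed=0, change=None, shape=(10, 10)):
    rng = np.random.default_rng(seed)
    cells1 = rng.choice(legend.codes, size=shape).astype(np.int32)
    cells2 = cells1.copy()
    if change is not None:
        (r, c), code = change
        cells2[r, c] = code
    g1 = LandscapeGrid(cells1, cell_size=30.0, epoch_label="t1")
    g2 = LandscapeGrid(cells2, cell_size=30.0, epoch_label="t2")
    return g1, g2


class TestTransitionMatrix:
    def test_identical_grids_are_diagonal(self, legend):
        g1, g2 = _pair(legend, seed=1)
        tm = transition_matrix(g1, g2, legend)
        off = tm.flows.to_numpy().copy()
        np.fill_diagonal(off, 0.0)
        assert off.sum() == 0.0

    def test_single_cell_change_is_009_ha(self, legend):
        cells = np.ones((2, 2), dtype=np.int32)
        g1 = LandscapeGrid(cells, cell_size=30.0, epoch_label="a")
        cells2 = cells.copy()
        cells2[0, 0] = 2
        g2 = LandscapeGrid(cells2, cell_size=30.0, epoch_label="b")
        tm = transition_matrix(g1, g2, legend)
        assert tm.flows.loc["croplands", "forests"] == pytest.approx(0.09)

    def test_matches_per_cell_tally(self, legend):
        rng = np.random.default_rng(5)
        g1 = LandscapeGrid(rng.choice(legend.codes, size=(9, 9)).astype(np.int32),
                           cell_size=30.0, epoch_label="t1")
        g2 = LandscapeGrid(rng.choice(legend.codes, size=(9, 9)).astype(np.int32),
                           cell_size=30.0, epoch_label="t2")
        tm = transition_matrix(g1, g2, legend)
        ref = oracles.cross_tabulate(g1.cells, g2.cells, legend.nodata_code,
                                     g1.cell_area / 10_000)
        for (c1, c2), ha in ref.items():
            n1 = legend.entry_for_code(c1).name
            n2 = legend.entry_for_code(c2).name
            assert tm.flows.loc[n1, n2] == pytest.approx(ha)
        assert tm.flows.to_numpy().sum() == pytest.approx(sum(ref.values()))

    def test_nodata_in_either_epoch_excluded(self, legend):
        g1, g2 = _pair(legend, seed=2)
        g1.cells[0, 0] = legend.nodata_code
        g2.cells[5, 5] = legend.nodata_code
        tm = transition_matrix(g1, g2, legend)
        joint_cells = 100 - 2
        assert tm.total_area == pytest.approx(joint_cells * 0.09)

    def test_area_conservation_per_class(self, legend):
        g1, g2 = _pair(legend, seed=3)
        g2.cells[g2.cells == legend.code_for_name("forests")] = \
            legend.code_for_name("croplands")
        tm = transition_matrix(g1, g2, legend)
        joint = g1.valid_mask & g2.valid_mask
        for name in legend.names:
            code = legend.code_for_name(name)
            t1_area = (g1.cells[joint] == code).sum() * 0.09
            assert tm.row_totals()[name] == pytest.approx(t1_area)


class TestClassification:
    @pytest.mark.parametrize("src,dst,category", [
        ("grasslands", "forests", "progressive"),
        ("forests", "grasslands", "regressive"),
        ("forests", "croplands", "anthropogenic_disturbance"),
        ("grasslands", "settlements", "anthropogenic_disturbance"),
        ("croplands", "water", "hydrological_conversion"),
        ("water", "forests", "progressive"),
        ("forests", "forests", "stable"),
    ])
    def test_flow_categories(self, legend, src, dst, category):
        cells1 = np.full((2, 2), legend.code_for_name(src), dtype=np.int32)
        cells2 = np.full((2, 2), legend.code_for_name(dst), dtype=np.int32)
        tm = transition_matrix(
            LandscapeGrid(cells1, 30.0, epoch_label="a"),
            LandscapeGrid(cells2, 30.0, epoch_label="b"), legend)
        flows = classify_flows(tm, legend)
        assert len(flows) == 1
        assert flows[0].category == category
        assert flows[0].area_ha == pytest.approx(0.36)

    def test_missing_rank_is_configuration_error(self):
        legend = ClassLegend(entries=(
            LegendEntry(1, "forests", succession_rank=None, role="natural"),
            LegendEntry(2, "grasslands", succession_rank=1, role="natural"),
        ))
        cells = np.ones((2, 2), dtype=np.int32)
        tm = transition_matrix(LandscapeGrid(cells, 30.0, epoch_label="a"),
                               LandscapeGrid(cells, 30.0, epoch_label="b"),
                               legend)
        with pytest.raises(ValueError, match="succession_rank"):
            classify_flows(tm, legend)


class TestSankey:
    def test_identical_grids_give_zero_links(self, legend):
        g1, g2 = _pair(legend, seed=4)
        tm = transition_matrix(g1, g2, legend)
        with pytest.warns(UserWarning, match="zero links"):
            doc = sankey_export([tm], legend)
        assert doc["links"] == []

    def test_one_changed_cell_one_link(self, legend):
        g1, g2 = _pair(legend, seed=6,
                       change=((0, 0), legend.code_for_name("water")))
        if g1.cells[0, 0] == legend.code_for_name("water"):
            g2.cells[0, 0] = legend.code_for_name("forests")
        tm = transition_matrix(g1, g2, legend)
        doc = sankey_export([tm], legend)
        assert len(doc["links"]) == 1
        assert doc["links"][0]["value_ha"] == pytest.approx(0.09)

    def test_chained_epochs_node_set(self, legend):
        grids = []
        rng = np.random.default_rng(7)
        for i in range(5):
            cells = rng.choice(legend.codes, size=(8, 8)).astype(np.int32)
            grids.append(LandscapeGrid(cells, 30.0, epoch_label=f"e{i}"))
        tms = [transition_matrix(a, b, legend)
               for a, b in zip(grids[:-1], grids[1:])]
        doc = sankey_export(tms, legend)
        assert len(doc["nodes"]) == len(legend) * 5
        # deterministic ordering: legend order within each epoch column
        assert [n["class"] for n in doc["nodes"][:len(legend)]] == \
            list(legend.names)
        # no diagonal links
        idx = {n["id"]: n for n in doc["nodes"]}
        for link in doc["links"]:
            assert idx[link["source"]]["class"] != idx[link["target"]]["class"]

    def test_non_chaining_matrices_rejected(self, legend):
        g1, g2 = _pair(legend, seed=8)
        tm = transition_matrix(g1, g2, legend)
        with pytest.raises(ValueError, match="chain"):
            sankey_export([tm, tm], legend)
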