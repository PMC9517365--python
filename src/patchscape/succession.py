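"""Inter-epoch transitions and ecological succession.

Aligned epoch pairs are cross-tabulated cell-by-cell into an area
transition (transfer) matrix in hectares. Off-diagonal flows are then
classified ecologically:

* rank increase among natural classes → **progressive** succession
  (toward the climax community, e.g. grassland → forest);
* rank decrease among natural classes → **regressive** succession
  (e.g. forest → grassland);
* any flow into a cropland or settlement class → **anthropogenic
  disturbance**;
* any flow into water → **hydrological conversion** (reservoir filling,
  channel change);
* the diagonal → **stable** (no succession).

Cells that are nodata in either epoch are excluded from the pair's matrix
(intersection mask). A chained, Sankey-ready node/link list can be
exported as JSON with the no-succession diagonal removed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence, Union

import numpy as np
import pandas as pd

from .grid import LandscapeGrid
from .legend import ClassLegend
from .raster_io import check_aligned

__all__ = [
    "TransitionMatrix",
    "SuccessionFlow",
    "transition_matrix",
    "classify_flows",
    "sankey_export",
    "FLOW_CATEGORIES",
]

FLOW_CATEGORIES = (
    "progressive",
    "regressive",
    "anthropogenic_disturbance",
    "hydrological_conversion",
    "stable",
)


@dataclass
class TransitionMatrix:
    """Square area-flow matrix between two epochs.

    ``flows.loc[i, j]`` is the area (ha) of class *i* at the first epoch
    that is class *j* at the second, over cells valid in both epochs.
    Row/column labels are class names in legend order.
    """

    flows: pd.DataFrame
    epoch_pair: tuple[str, str]

    @property
    def classes(self) -> list[str]:
        return list(self.flows.index)

    @property
    def total_area(self) -> float:
        """Jointly-valid area of the epoch pair, hectares."""
        return float(self.flows.to_numpy().sum())

    def row_totals(self) -> pd.Series:
        return self.flows.sum(axis=1)

    def col_totals(self) -> pd.Series:
        return self.flows.sum(axis=0)

    def to_csv(self, path: Union[str, Path]) -> None:
        self.flows.to_csv(path)


@dataclass(frozen=True)
class SuccessionFlow:
    """One classified off-diagonal (or stable diagonal) flow."""

    from_class: str
    to_class: str
    area_ha: float
    category: str


def transition_matrix(
    grid_t1: LandscapeGrid, grid_t2: LandscapeGrid, legend: ClassLegend
) -> TransitionMatrix:
    """Cross-tabulate two aligned epochs into an area matrix (ha)."""
    check_aligned([grid_t1, grid_t2])
    grid_t1.validate(legend)
    grid_t2.validate(legend)
    joint = grid_t1.valid_mask & grid_t2.valid_mask
    codes = np.array(legend.codes)
    k = len(codes)
    # map codes to 0..k-1 indices for a bincount cross-tab
    code_to_idx = {c: i for i, c in enumerate(codes.tolist())}
    idx1 = np.vectorize(code_to_idx.get, otypes=[np.int64])(grid_t1.cells[joint])
    idx2 = np.vectorize(code_to_idx.get, otypes=[np.int64])(grid_t2.cells[joint])
    counts = np.bincount(idx1 * k + idx2, minlength=k * k).reshape(k, k)
    ha_per_cell = grid_t1.cell_area / 10_000.0
    flows = pd.DataFrame(
        counts * ha_per_cell, index=list(legend.names), columns=list(legend.names)
    )
    return TransitionMatrix(
        flows=flows, epoch_pair=(grid_t1.epoch_label, grid_t2.epoch_label)
    )


def _flow_category(legend: ClassLegend, from_name: str, to_name: str) -> str:
    if from_name == to_name:
        return "stable"
    to_entry = legend.entry_for_name(to_name)
    from_entry = legend.entry_for_name(from_name)
    if to_entry.role == "anthropogenic":
        return "anthropogenic_disturbance"
    if to_entry.role == "water":
        return "hydrological_conversion"
    # natural destination: compare succession ranks where both are ranked
    if from_entry.succession_rank is None or to_entry.succession_rank is None:
        # e.g. water reverting to vegetation: movement toward a natural
        # class without a comparable rank counts as progressive recovery
        return "progressive"
    if to_entry.succession_rank > from_entry.succession_rank:
        return "progressive"
    if to_entry.succession_rank < from_entry.succession_rank:
        return "regressive"
    return "progressive"  # equal-rank lateral change toward natural cover


def classify_flows(tm: TransitionMatrix, legend: ClassLegend) -> list[SuccessionFlow]:
    """Label every nonzero flow with its ecological category.

    Requires succession ranks on natural classes; a natural class other
    than water without a rank participating in a natural→natural flow is a
    configuration error surfaced by :func:`_flow_category` rules above
    only when ranks are missing on both sides — validated here upfront.
    """
    for entry in legend:
        if entry.role == "natural" and entry.succession_rank is None:
            raise ValueError(
                f"natural class {entry.name!r} needs a succession_rank to "
                f"classify its flows"
            )
    out: list[SuccessionFlow] = []
    for from_name in tm.classes:
        for to_name in tm.classes:
            area = float(tm.flows.loc[from_name, to_name])
            if area <= 0:
                continue
            out.append(
                SuccessionFlow(
                    from_class=from_name,
                    to_class=to_name,
                    area_ha=area,
                    category=_flow_category(legend, from_name, to_name),
                )
            )
    return out


def sankey_export(
    tms: Sequence[TransitionMatrix],
    legend: ClassLegend,
    path: Union[str, Path, None] = None,
) -> dict:
    """Build (and optionally write) a Sankey-ready node/link document.

    Epochs chain left-to-right: nodes are (class, epoch) pairs in legend
    order within each epoch column; links carry the off-diagonal flow
    areas in hectares with their ecological category. Diagonal
    (no-succession) flows are removed, mirroring how succession Sankey
    diagrams are drawn.
    """
    if not tms:
        raise ValueError("at least one transition matrix is required")
    epochs: list[str] = [tms[0].epoch_pair[0]]
    for tm in tms:
        if tm.epoch_pair[0] != epochs[-1]:
            raise ValueError(
                f"transition matrices do not chain: expected pair starting "
                f"at {epochs[-1]!r}, got {tm.epoch_pair}"
            )
        epochs.append(tm.epoch_pair[1])

    names = list(legend.names)
    nodes = []
    node_index: dict[tuple[str, str], int] = {}
    for epoch in epochs:
        for name in names:
            node_index[(name, epoch)] = len(nodes)
            nodes.append({"id": len(nodes), "class": name, "epoch": epoch})

    links = []
    for k, tm in enumerate(tms):
        e1, e2 = epochs[k], epochs[k + 1]
        for flow in classify_flows(tm, legend):
            if flow.category == "stable":
                continue
            links.append({
                "source": node_index[(flow.from_class, e1)],
                "target": node_index[(flow.to_class, e2)],
                "value_ha": flow.area_ha,
                "category": flow.category,
            })
    if not links:
        warnings.warn("no off-diagonal flows: Sankey document has zero links")

    doc = {"nodes": nodes, "links": links}
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=2))
    return doc
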