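"""The categorical raster container.

A :class:`LandscapeGrid` is a single-band integer lattice with a nodata code
and a square cell size in metres. It is the unit every other module consumes:
patch delineation, metrics, transitions and the synthetic generator all
operate on validated grids.

Conventions: row-major storage with cell (0, 0) at the top-left (raster
convention). ``Z`` is the number of valid (non-nodata) cells and the total
landscape area ``A = Z * cell_size**2`` in square metres — nodata cells
contribute no area.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .legend import ClassLegend

__all__ = ["LandscapeGrid"]


@dataclass
class LandscapeGrid:
    """A categorical land-cover raster.

    Parameters
    ----------
    cells
        2-D integer array of class codes (and possibly the nodata code).
    cell_size
        Side length of a (square) cell in metres; must be positive.
    nodata_code
        Integer marking cells outside the mapped extent.
    epoch_label
        Free-text label for the epoch the map represents (e.g. ``"2018"``).
    """

    cells: np.ndarray
    cell_size: float
    nodata_code: int = -9999
    epoch_label: str = ""

    def __post_init__(self) -> None:
        cells = np.asarray(self.cells)
        if cells.ndim != 2:
            raise ValueError(f"cells must be 2-D, got shape {cells.shape}")
        if cells.shape[0] < 1 or cells.shape[1] < 1:
            raise ValueError("grid must have at least one row and one column")
        if not np.issubdtype(cells.dtype, np.integer):
            raise ValueError(f"cells must be integer-typed, got {cells.dtype}")
        if not self.cell_size > 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        self.cells = cells.astype(np.int32, copy=False)

    # -- basic geometry ---------------------------------------------------
    @property
    def nrows(self) -> int:
        return self.cells.shape[0]

    @property
    def ncols(self) -> int:
        return self.cells.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.cells.shape

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells inside the mapped extent."""
        return self.cells != self.nodata_code

    @property
    def Z(self) -> int:
        """Number of valid (non-nodata) cells."""
        return int(self.valid_mask.sum())

    @property
    def cell_area(self) -> float:
        """Area of one cell in square metres."""
        return float(self.cell_size) ** 2

    @property
    def A(self) -> float:
        """Total landscape area in square metres (valid cells only)."""
        return self.Z * self.cell_area

    @property
    def A_ha(self) -> float:
        """Total landscape area in hectares."""
        return self.A / 10_000.0

    # -- validation -------------------------------------------------------
    def validate(self, legend: ClassLegend) -> "LandscapeGrid":
        """Check every cell is either nodata or a legend code; Z >= 1.

        Returns self so the call chains; raises ``ValueError`` naming the
        first offending code and cell index otherwise.
        """
        if legend.nodata_code != self.nodata_code:
            raise ValueError(
                f"grid nodata code {self.nodata_code} differs from legend "
                f"nodata code {legend.nodata_code}"
            )
        allowed = np.array(legend.codes + (self.nodata_code,))
        bad = ~np.isin(self.cells, allowed)
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"unknown class code {int(self.cells[r, c])} at cell "
                f"({int(r)}, {int(c)}) not present in legend"
            )
        if self.Z < 1:
            raise ValueError("grid contains no valid cells")
        return self

    def class_cell_counts(self, legend: ClassLegend) -> dict[int, int]:
        """Cell count per legend code (codes absent from the grid map to 0)."""
        codes, counts = np.unique(self.cells[self.valid_mask], return_counts=True)
        lookup = dict(zip(codes.tolist(), counts.tolist()))
        return {code: lookup.get(code, 0) for code in legend.codes}

    def copy(self) -> "LandscapeGrid":
        return LandscapeGrid(
            cells=self.cells.copy(),
            cell_size=self.cell_size,
            nodata_code=self.nodata_code,
            epoch_label=self.epoch_label,
        )
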