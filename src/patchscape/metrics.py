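"""Class- and landscape-scale pattern indices.

Class scale (one row per land-cover class present):

* ``CA`` — total class area in hectares.
* ``PLAND`` — percentage of the landscape occupied by the class.
* ``NP`` — number of patches; ``PD`` — patches per 100 ha.
* ``LPI`` — largest patch area as a percentage of the landscape.
* ``PAFRAC`` — perimeter–area fractal dimension: twice the least-squares
  slope of ln(perimeter) on ln(area) across the class's patches; 1 for
  square-like patches, toward 2 for plane-filling convoluted ones.
* ``COHESION`` — patch cohesion, a percolation-motivated connectedness
  measure computed from perimeters and areas in cell units.
* ``AI`` — aggregation index: observed single-count like adjacencies as a
  percentage of the maximum achievable for the class's cell count.

Landscape scale: NP, PD, LPI and PAFRAC pooled over all patches, Shannon
diversity (SHDI) and evenness (SHEI) of the class proportions, and the
area-weighted mean AI.

All computations run at full precision; :func:`format_class_table` and
:func:`format_landscape_table` apply the report rounding conventions
(integer CA, one decimal at class level, three decimals at landscape
level) with undefined values rendered ``N/A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .grid import LandscapeGrid
from .legend import ClassLegend
from .patch_engine import (
    AdjacencyTable,
    PatchMap,
    count_like_adjacencies,
    delineate,
)

__all__ = [
    "LandscapeComposition",
    "class_area",
    "pland",
    "patch_density",
    "patch_density_from_area",
    "pland_from_areas",
    "largest_patch_index",
    "pafrac",
    "aggregation_index",
    "cohesion",
    "shannon_diversity",
    "shannon_evenness",
    "composition",
    "class_table",
    "landscape_table",
    "format_class_table",
    "format_landscape_table",
    "CLASS_TABLE_COLUMNS",
    "LANDSCAPE_TABLE_COLUMNS",
]

CLASS_TABLE_COLUMNS = [
    "Landscapes", "CA", "PLAND", "NP", "PD", "LPI", "PAFRAC", "COHESION", "AI",
]
LANDSCAPE_TABLE_COLUMNS = [
    "Years", "NP", "PD", "LPI", "PAFRAC", "SHDI", "SHEI", "AI",
]

#: Minimum number of patches for a meaningful perimeter–area regression.
DEFAULT_MIN_PATCHES = 10


@dataclass(frozen=True)
class LandscapeComposition:
    """Class proportions of the valid landscape area.

    ``proportions`` maps class code → fraction of valid area (sums to 1);
    ``m`` counts classes actually present (proportion > 0).
    """

    proportions: dict[int, float]
    m: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"proportions sum to {total}, expected 1")
        if self.m < 1:
            raise ValueError("at least one class must be present")


def composition(grid: LandscapeGrid, legend: ClassLegend) -> LandscapeComposition:
    """Proportions of valid area per present class, in legend order."""
    counts = grid.class_cell_counts(legend)
    z = grid.Z
    props = {code: n / z for code, n in counts.items() if n > 0}
    return LandscapeComposition(proportions=props, m=len(props))


# ---------------------------------------------------------------------------
# Class-scale indices
# ---------------------------------------------------------------------------

def class_area(patch_map: PatchMap, class_code: int) -> float:
    """CA: total area of the class's patches, hectares."""
    return sum(p.area for p in patch_map.patches_of_class(class_code)) / 10_000.0


def pland(patch_map: PatchMap, class_code: int) -> float:
    """PLAND: percentage of total landscape area occupied by the class."""
    a_total = patch_map.grid.A
    return 100.0 * sum(
        p.area for p in patch_map.patches_of_class(class_code)
    ) / a_total


def patch_density_from_area(n_patches: int, area_ha: float) -> float:
    """PD from a patch count and a landscape area in hectares: patches
    per 100 ha. Useful for recomputing densities from published tables."""
    return n_patches / area_ha * 100.0


def pland_from_areas(class_area_ha: float, total_area_ha: float) -> float:
    """PLAND from a class area and the total landscape area (same units)."""
    return 100.0 * class_area_ha / total_area_ha


def patch_density(patch_map: PatchMap, class_code: Optional[int] = None) -> float:
    """PD: patches per 100 hectares (class-level, or whole landscape)."""
    n = (len(patch_map.patches_of_class(class_code))
         if class_code is not None else patch_map.n_patches)
    return patch_density_from_area(n, patch_map.grid.A / 10_000)


def largest_patch_index(patch_map: PatchMap,
                        class_code: Optional[int] = None) -> float:
    """LPI: largest patch area as a percentage of total landscape area."""
    patches = (patch_map.patches_of_class(class_code)
               if class_code is not None else patch_map.patches)
    if not patches:
        raise ValueError("no patches to take the maximum over")
    return 100.0 * max(p.area for p in patches) / patch_map.grid.A


def pafrac(patch_map: PatchMap, class_code: Optional[int] = None,
           min_patches: int = DEFAULT_MIN_PATCHES) -> float:
    """Perimeter–area fractal dimension: 2 × slope of ln p on ln a.

    Returns ``nan`` (rendered ``N/A``) when fewer than ``min_patches``
    patches exist or the log-areas are (numerically) constant, in which
    case the regression slope is undefined.
    """
    patches = (patch_map.patches_of_class(class_code)
               if class_code is not None else patch_map.patches)
    if len(patches) < max(min_patches, 2):
        return float("nan")
    ln_a = np.log([p.area for p in patches])
    ln_p = np.log([p.perimeter for p in patches])
    if np.var(ln_a) < 1e-12:
        return float("nan")
    slope = np.cov(ln_a, ln_p, bias=True)[0, 1] / np.var(ln_a)
    return 2.0 * float(slope)


def aggregation_index(adjacency: AdjacencyTable,
                      class_code: Optional[int] = None) -> float:
    """AI: 100 × g_ii / max(g_ii) for a class; area-weighted mean over
    classes for the landscape.

    A class occupying a single cell has max(g_ii) = 0; its AI is 100 by
    convention (one cell is maximally aggregated).
    """
    if class_code is not None:
        if adjacency.cell_counts.get(class_code, 0) == 0:
            raise ValueError(f"class {class_code} occupies no cells")
        max_g = adjacency.max_g[class_code]
        if max_g == 0:
            return 100.0
        return 100.0 * adjacency.g[class_code] / max_g
    total_cells = sum(adjacency.cell_counts.values())
    ai = 0.0
    for code, cells in adjacency.cell_counts.items():
        if cells == 0:
            continue
        ai += cells / total_cells * aggregation_index(adjacency, code)
    return ai


def cohesion(patch_map: PatchMap, class_code: int,
             literal_denominator: bool = False) -> float:
    """COHESION: physical connectedness of a class, percent.

    With p*_ij the patch perimeter in cell-edge units and a*_ij the patch
    area in cells::

        COHESION = [1 - Σp* / Σ(p* √a*)] · [1 - 1/√Z]^(-1) · 100

    where Z is the number of valid cells in the landscape. 0 for a class
    consisting of one single-cell patch; strictly below 100 on any finite
    grid. ``literal_denominator`` switches to the non-standard variant
    Σ(p*·a*) with [1 - 1/Z]^(-1), kept for comparison only.
    """
    z = patch_map.grid.Z
    if z <= 1:
        return float("nan")
    patches = patch_map.patches_of_class(class_code)
    if not patches:
        raise ValueError(f"class {class_code} has no patches")
    cell_size = patch_map.grid.cell_size
    p_star = np.array([p.perimeter / cell_size for p in patches])
    a_star = np.array([float(p.cell_count) for p in patches])
    if literal_denominator:
        ratio = p_star.sum() / (p_star * a_star).sum()
        correction = 1.0 - 1.0 / z
    else:
        ratio = p_star.sum() / (p_star * np.sqrt(a_star)).sum()
        correction = 1.0 - 1.0 / math.sqrt(z)
    return (1.0 - ratio) / correction * 100.0


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def shannon_diversity(comp: LandscapeComposition) -> float:
    """SHDI = -Σ p_i ln p_i over classes with p_i > 0."""
    return float(-sum(p * math.log(p) for p in comp.proportions.values() if p > 0))


def shannon_evenness(shdi: float, m: int) -> float:
    """SHEI = SHDI / ln m for m ≥ 2 classes; 0 for a one-class landscape."""
    if m < 1:
        raise ValueError("m must be at least 1")
    if m == 1:
        return 0.0
    return shdi / math.log(m)


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

def class_table(
    grid: LandscapeGrid,
    legend: ClassLegend,
    connectivity: int = 8,
    min_patches: int = DEFAULT_MIN_PATCHES,
    literal_cohesion: bool = False,
) -> pd.DataFrame:
    """All eight class-scale indices, one row per present class.

    Rows follow legend order; classes absent from the grid are omitted.
    """
    grid.validate(legend)
    pm = delineate(grid, connectivity)
    adj = count_like_adjacencies(grid, legend)
    rows = []
    for entry in legend:
        if adj.cell_counts[entry.code] == 0:
            continue
        rows.append({
            "Landscapes": entry.name,
            "CA": class_area(pm, entry.code),
            "PLAND": pland(pm, entry.code),
            "NP": len(pm.patches_of_class(entry.code)),
            "PD": patch_density(pm, entry.code),
            "LPI": largest_patch_index(pm, entry.code),
            "PAFRAC": pafrac(pm, entry.code, min_patches),
            "COHESION": cohesion(pm, entry.code, literal_cohesion),
            "AI": aggregation_index(adj, entry.code),
        })
    return pd.DataFrame(rows, columns=CLASS_TABLE_COLUMNS)


def landscape_table(
    grids: Sequence[LandscapeGrid],
    legend: ClassLegend,
    connectivity: int = 8,
    min_patches: int = DEFAULT_MIN_PATCHES,
) -> pd.DataFrame:
    """Landscape-scale indices, one row per epoch in input order."""
    rows = []
    for grid in grids:
        grid.validate(legend)
        pm = delineate(grid, connectivity)
        adj = count_like_adjacencies(grid, legend)
        comp = composition(grid, legend)
        shdi = shannon_diversity(comp)
        rows.append({
            "Years": grid.epoch_label,
            "NP": pm.n_patches,
            "PD": patch_density(pm),
            "LPI": largest_patch_index(pm),
            "PAFRAC": pafrac(pm, None, min_patches),
            "SHDI": shdi,
            "SHEI": shannon_evenness(shdi, comp.m),
            "AI": aggregation_index(adj),
        })
    return pd.DataFrame(rows, columns=LANDSCAPE_TABLE_COLUMNS)


def _round_col(series: pd.Series, decimals: int) -> pd.Series:
    def fmt(x):
        if isinstance(x, float) and math.isnan(x):
            return "N/A"
        if decimals == 0:
            return str(int(round(x)))
        return f"{x:.{decimals}f}"
    return series.map(fmt)


def format_class_table(table: pd.DataFrame) -> pd.DataFrame:
    """Report rounding for the class table: CA and NP integer, PAFRAC two
    decimals, everything else one decimal; undefined values as ``N/A``."""
    out = table.copy()
    out["CA"] = _round_col(table["CA"], 0)
    out["NP"] = table["NP"].astype(int).astype(str)
    for col in ("PLAND", "PD", "LPI", "COHESION", "AI"):
        out[col] = _round_col(table[col], 1)
    out["PAFRAC"] = _round_col(table["PAFRAC"], 2)
    return out


def format_landscape_table(table: pd.DataFrame) -> pd.DataFrame:
    """Report rounding for the landscape table: NP integer, three decimals
    elsewhere; undefined values as ``N/A``."""
    out = table.copy()
    out["NP"] = table["NP"].astype(int).astype(str)
    for col in ("PD", "LPI", "PAFRAC", "SHDI", "SHEI", "AI"):
        out[col] = _round_col(table[col], 3)
    return out
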