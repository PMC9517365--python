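"""Independent brute-force oracles for patch geometry and indices.

Everything here is deliberately naive — BFS flood fill, per-edge
enumeration, direct formula evaluation — and shares no code with the
package, so agreement is evidence rather than tautology.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np


def flood_fill_labels(cells: np.ndarray, nodata: int, connectivity: int) -> np.ndarray:
    """BFS connected components per class; ids 1.. in scan order of the
    first-encountered cell of each component."""
    nrows, ncols = cells.shape
    if connectivity == 4:
        offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        offsets = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0)]
    labels = np.zeros((nrows, ncols), dtype=int)
    next_id = 1
    for r0 in range(nrows):
        for c0 in range(ncols):
            if cells[r0, c0] == nodata or labels[r0, c0] != 0:
                continue
            code = cells[r0, c0]
            queue = deque([(r0, c0)])
            labels[r0, c0] = next_id
            while queue:
                r, c = queue.popleft()
                for dr, dc in offsets:
                    rr, cc = r + dr, c + dc
                    if (0 <= rr < nrows and 0 <= cc < ncols
                            and labels[rr, cc] == 0 and cells[rr, cc] == code):
                        labels[rr, cc] = next_id
                        queue.append((rr, cc))
            next_id += 1
    return labels


def patch_table(cells: np.ndarray, nodata: int, cell_size: float,
                connectivity: int) -> list[dict]:
    """Per-patch class, cell count, area (m2) and perimeter (m) by
    exhaustive edge enumeration over 4-neighbour pairs and boundaries."""
    labels = flood_fill_labels(cells, nodata, connectivity)
    nrows, ncols = cells.shape
    n = labels.max()
    out = [
        {"patch_id": i + 1, "class": None, "cells": 0, "perimeter_edges": 0}
        for i in range(n)
    ]
    for r in range(nrows):
        for c in range(ncols):
            lab = labels[r, c]
            if lab == 0:
                continue
            rec = out[lab - 1]
            rec["class"] = int(cells[r, c])
            rec["cells"] += 1
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < nrows and 0 <= cc < ncols):
                    rec["perimeter_edges"] += 1  # lattice boundary
                elif cells[rr, cc] != cells[r, c]:
                    rec["perimeter_edges"] += 1  # other class or nodata
    for rec in out:
        rec["area"] = rec["cells"] * cell_size ** 2
        rec["perimeter"] = rec["perimeter_edges"] * cell_size
    return out


def like_adjacencies(cells: np.ndarray, nodata: int) -> dict[int, int]:
    """Single-count rook like-class pairs per class."""
    nrows, ncols = cells.shape
    g: dict[int, int] = {}
    for r in range(nrows):
        for c in range(ncols):
            v = cells[r, c]
            if v == nodata:
                continue
            g.setdefault(int(v), 0)
            for rr, cc in ((r, c + 1), (r + 1, c)):  # each pair once
                if 0 <= rr < nrows and 0 <= cc < ncols and cells[rr, cc] == v:
                    g[int(v)] += 1
    return g


def max_adjacency_by_construction(a: int) -> int:
    """Maximum like-adjacency count for ``a`` cells, found by building the
    densest packing (largest square plus a partial wrap of extras) and
    counting its pairs directly."""
    if a <= 0:
        return 0
    n = int(math.isqrt(a))
    m = a - n * n
    side = n + 2
    grid = np.zeros((side, side), dtype=bool)
    grid[:n, :n] = True
    extra_row = min(m, n)
    grid[n, :extra_row] = True
    grid[: m - extra_row, n] = True
    count = 0
    for r in range(side):
        for c in range(side):
            if not grid[r, c]:
                continue
            if c + 1 < side and grid[r, c + 1]:
                count += 1
            if r + 1 < side and grid[r + 1, c]:
                count += 1
    return count


def aggregation_index_pct(cells: np.ndarray, nodata: int, code: int) -> float:
    """AI in percent from brute pair counts and the constructed maximum."""
    g = like_adjacencies(cells, nodata).get(code, 0)
    a = int((cells == code).sum())
    max_g = max_adjacency_by_construction(a)
    if max_g == 0:
        return 100.0
    return 100.0 * g / max_g


def cohesion_pct(cells: np.ndarray, nodata: int, code: int, cell_size: float,
                 connectivity: int) -> float:
    """Patch cohesion by direct formula evaluation on brute patch geometry."""
    z = int((cells != nodata).sum())
    patches = [p for p in patch_table(cells, nodata, cell_size, connectivity)
               if p["class"] == code]
    num = sum(p["perimeter_edges"] for p in patches)
    den = sum(p["perimeter_edges"] * math.sqrt(p["cells"]) for p in patches)
    return (1.0 - num / den) / (1.0 - 1.0 / math.sqrt(z)) * 100.0


def largest_patch_pct(cells: np.ndarray, nodata: int, code: int,
                      cell_size: float, connectivity: int) -> float:
    patches = [p for p in patch_table(cells, nodata, cell_size, connectivity)
               if p["class"] == code]
    total = int((cells != nodata).sum()) * cell_size ** 2
    return 100.0 * max(p["area"] for p in patches) / total


def cross_tabulate(cells1: np.ndarray, cells2: np.ndarray, nodata: int,
                   cell_area_ha: float) -> dict[tuple[int, int], float]:
    """Per-cell double-loop transition tally in hectares."""
    out: dict[tuple[int, int], float] = {}
    nrows, ncols = cells1.shape
    for r in range(nrows):
        for c in range(ncols):
            v1, v2 = int(cells1[r, c]), int(cells2[r, c])
            if v1 == nodata or v2 == nodata:
                continue
            out[(v1, v2)] = out.get((v1, v2), 0.0) + cell_area_ha
    return out
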