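"""Seeded synthetic landscapes.

Real multi-decadal land-cover map series are rarely redistributable, so the
pipeline is exercised on neutral landscape models: categorical lattices
with controlled class proportions and controlled spatial aggregation,
generated by the modified-random-clusters procedure:

1. mark each cell independently with probability ``aggregation``;
2. label the marked cells into clusters (rook neighbourhood, whose
   site-percolation threshold the aggregation cap guards);
3. hand whole clusters to classes: first reserve one of the smallest
   clusters per class (smallest target gets the smallest cluster) so no
   class can be starved by a large-cluster overshoot, then repeatedly
   give the next cluster (in a seeded random order) to the class
   furthest below its target cell share;
4. fill each unmarked cell with the majority class among its
   cluster-assigned 8-neighbours (ties broken by legend order), falling
   back to a draw from the target distribution for cells with no
   assigned neighbour.

``aggregation`` is kept below the site-percolation threshold (~0.5927)
so marked clusters stay sub-spanning and the realized composition can
track the targets. Higher aggregation yields larger, more aggregated
patches — the fragmentation gradient the pattern indices respond to.

:func:`evolve_series` perturbs a base landscape with (from, to, fraction)
conversion rules sampled preferentially at patch boundaries, producing
aligned epoch series with known transition structure, and
:func:`geometric_fixture` places rectangles with analytically known patch
counts, areas and perimeters for exact-answer tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .grid import LandscapeGrid
from .legend import ClassLegend, six_class_legend

__all__ = [
    "SyntheticLandscapeConfig",
    "PERCOLATION_GUARD",
    "generate_random_cluster",
    "evolve_series",
    "geometric_fixture",
    "ganjiang_like_proportions",
]

#: Upper bound on the aggregation parameter: site-percolation threshold of
#: the square lattice, below which marked clusters remain sub-spanning.
PERCOLATION_GUARD = 0.59

_STRUCTURE_4 = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


def ganjiang_like_proportions() -> dict[str, float]:
    """Default composition: a strongly forest-dominated six-class basin
    (82% forest, ~11% cropland, ~5% grassland, minor water/settlements),
    the kind of ecological-red-line landscape the indices are meant for."""
    return {
        "croplands": 0.113,
        "forests": 0.820,
        "grasslands": 0.051,
        "water": 0.012,
        "settlements": 0.004,
    }


@dataclass
class SyntheticLandscapeConfig:
    """Parameters of the modified-random-clusters generator.

    ``target_proportions`` maps class name → target fraction of cells
    (must sum to 1); ``aggregation`` in [0, PERCOLATION_GUARD) controls
    clumping (0 = i.i.d. noise); ``seed`` drives all randomness.
    """

    nrows: int
    ncols: int
    target_proportions: dict[str, float]
    aggregation: float = 0.5
    cell_size: float = 30.0
    seed: int = 0
    legend: ClassLegend = field(default_factory=six_class_legend)
    epoch_label: str = ""

    def __post_init__(self) -> None:
        total = sum(self.target_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"target proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.target_proportions.values()):
            raise ValueError("target proportions must be non-negative")
        if not (0.0 <= self.aggregation < PERCOLATION_GUARD):
            raise ValueError(
                f"aggregation must lie in [0, {PERCOLATION_GUARD}) to keep "
                f"clusters sub-spanning, got {self.aggregation}"
            )
        for name in self.target_proportions:
            self.legend.entry_for_name(name)  # raises on unknown class
        if self.nrows < 1 or self.ncols < 1:
            raise ValueError("lattice must be at least 1×1")


def generate_random_cluster(config: SyntheticLandscapeConfig) -> LandscapeGrid:
    """Generate one landscape by the modified-random-clusters procedure.

    Fully reproducible given the seed. Raises when the targets are
    unreachable on the lattice (a positive-target class that cannot get a
    single cell).
    """
    rng = np.random.default_rng(config.seed)
    n_cells = config.nrows * config.ncols
    active = [
        (name, frac) for name, frac in config.target_proportions.items()
        if frac > 0
    ]
    # legend order for deterministic tie-breaks
    legend_rank = {e.name: i for i, e in enumerate(config.legend)}
    active.sort(key=lambda item: legend_rank[item[0]])
    for name, frac in active:
        if frac * n_cells < 1.0 and frac > 0:
            raise ValueError(
                f"class {name!r} targets {frac:.4%} of {n_cells} cells "
                f"(< 1 cell); use a larger grid"
            )
    codes = np.array([config.legend.code_for_name(n) for n, _ in active])
    fracs = np.array([f for _, f in active])

    cells = np.full((config.nrows, config.ncols), -1, dtype=np.int64)

    # 1–2: percolation marking and cluster labelling
    marked = rng.random((config.nrows, config.ncols)) < config.aggregation
    clusters, n_clusters = ndimage.label(marked, structure=_STRUCTURE_4)

    # 3: assign whole clusters, largest-remaining-deficit class first.
    # One of the smallest clusters is reserved per class beforehand
    # (smallest target ↔ smallest cluster) so a rare-class budget cannot
    # be swallowed whole by an early large cluster.
    if n_clusters > 0:
        sizes = np.bincount(clusters.ravel())[1:]  # cluster 1..n (0-based here)
        assigned_cells = np.zeros(len(active), dtype=np.int64)
        marked_total = int(marked.sum())
        cluster_class = np.zeros(n_clusters + 1, dtype=np.int64)
        perm = rng.permutation(n_clusters)
        ascending = perm[np.argsort(sizes[perm], kind="stable")]
        by_target = np.argsort(fracs, kind="stable")
        n_reserve = min(len(active), n_clusters)
        for cl0, k in zip(ascending[:n_reserve], by_target[:n_reserve]):
            cluster_class[cl0 + 1] = codes[k]
            assigned_cells[k] += sizes[cl0]
        for cl0 in rng.permutation(ascending[n_reserve:]):
            deficit = fracs * marked_total - assigned_cells
            k = int(np.argmax(deficit))  # ties resolve to legend order
            cluster_class[cl0 + 1] = codes[k]
            assigned_cells[k] += sizes[cl0]
        cells[marked] = cluster_class[clusters[marked]]

    # 4: majority-vote fill of unmarked cells from cluster-assigned
    # neighbours; argmax over legend-ordered classes breaks ties by
    # legend order
    nr, nc = config.nrows, config.ncols
    votes = np.zeros((len(codes), nr, nc), dtype=np.int16)
    for i, code in enumerate(codes):
        member = np.pad((marked & (cells == code)).astype(np.int16), 1)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                votes[i] += member[1 + dr:1 + dr + nr, 1 + dc:1 + dc + nc]
    best = np.argmax(votes, axis=0)
    has_neighbour = votes.sum(axis=0) > 0
    fill = ~marked & has_neighbour
    cells[fill] = codes[best[fill]]

    isolated = ~marked & ~has_neighbour
    cum = np.cumsum(fracs)
    draws = np.searchsorted(cum, rng.random(int(isolated.sum())),
                            side="right").clip(0, len(codes) - 1)
    cells[isolated] = codes[draws]

    grid = LandscapeGrid(
        cells=cells.astype(np.int32),
        cell_size=config.cell_size,
        nodata_code=config.legend.nodata_code,
        epoch_label=config.epoch_label,
    )
    realized = grid.class_cell_counts(config.legend)
    for name, frac in active:
        if realized[config.legend.code_for_name(name)] == 0:
            raise ValueError(
                f"class {name!r} (target {frac:.4%}) received no cells; "
                f"use a larger grid or lower aggregation"
            )
    return grid


def evolve_series(
    grid: LandscapeGrid,
    change_spec: Sequence[tuple[str, str, float]],
    seed: int,
    legend: Optional[ClassLegend] = None,
    epoch_label: str = "",
) -> LandscapeGrid:
    """Apply (from_class, to_class, fraction) conversion rules to a grid.

    For each rule in order, the stated fraction of the from-class's cells
    (rounded to the nearest cell) is converted to the to-class, sampling
    boundary cells — cells with a rook neighbour of another class — before
    interior ones, as real land-cover change nibbles at patch edges.
    Later rules see earlier edits. The result is aligned with the input.
    """
    legend = legend or six_class_legend()
    rng = np.random.default_rng(seed)
    cells = grid.cells.copy()
    valid = cells != grid.nodata_code
    for from_name, to_name, fraction in change_spec:
        if not (0.0 <= fraction <= 1.0):
            raise ValueError(f"fraction must be in [0, 1], got {fraction}")
        from_code = legend.code_for_name(from_name)
        to_code = legend.code_for_name(to_name)
        mask = (cells == from_code) & valid
        n_from = int(mask.sum())
        n_convert = int(round(fraction * n_from))
        if n_convert == 0:
            continue
        # boundary preference: cells with a rook neighbour of another class
        padded = np.pad(cells, 1, constant_values=grid.nodata_code)
        boundary = np.zeros_like(mask)
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            neigh = padded[1 + dr: 1 + dr + cells.shape[0],
                           1 + dc: 1 + dc + cells.shape[1]]
            boundary |= mask & (neigh != from_code)
        b_idx = np.flatnonzero((mask & boundary).ravel())
        i_idx = np.flatnonzero((mask & ~boundary).ravel())
        chosen = np.concatenate([
            rng.permutation(b_idx), rng.permutation(i_idx)
        ])[:n_convert]
        cells.ravel()[chosen] = to_code
    return LandscapeGrid(
        cells=cells,
        cell_size=grid.cell_size,
        nodata_code=grid.nodata_code,
        epoch_label=epoch_label or grid.epoch_label,
    )


def geometric_fixture(
    shape: tuple[int, int],
    rectangles: Sequence[tuple[str, int, int, int, int]],
    background: Optional[str] = None,
    cell_size: float = 30.0,
    legend: Optional[ClassLegend] = None,
) -> LandscapeGrid:
    """Deterministic grid of placed rectangles with known geometry.

    ``rectangles`` is a list of (class_name, row, col, height, width);
    rectangles must stay in bounds and not overlap. Cells not covered get
    the ``background`` class, or nodata when no background is given.
    """
    legend = legend or six_class_legend()
    cells = np.full(shape, legend.nodata_code, dtype=np.int32)
    covered = np.zeros(shape, dtype=bool)
    for name, r, c, h, w in rectangles:
        if r < 0 or c < 0 or r + h > shape[0] or c + w > shape[1]:
            raise ValueError(f"rectangle {name!r} at ({r},{c}) size {h}×{w} "
                             f"out of bounds for {shape}")
        region = covered[r:r + h, c:c + w]
        if region.any():
            raise ValueError(f"rectangle {name!r} overlaps a previous shape")
        cells[r:r + h, c:c + w] = legend.code_for_name(name)
        covered[r:r + h, c:c + w] = True
    if background is not None:
        cells[~covered] = legend.code_for_name(background)
    return LandscapeGrid(cells=cells, cell_size=cell_size,
                         nodata_code=legend.nodata_code)
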