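"""End-to-end pipeline stages behind the command-line front end.

Wires the stages together the way a land-cover change study runs them:
read aligned epoch maps → class table per epoch + one landscape table
(``run_metrics``) → transition matrix per consecutive epoch pair + a
chained Sankey document (``run_transitions``); ``run_simulate`` writes a
reproducible synthetic epoch series to exercise everything without real
imagery. Every run writes a manifest JSON recording the settings so
results can be reproduced.

On any failure the files written so far by the failing stage are removed,
so an output directory never holds a partial result set.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import yaml

from .grid import LandscapeGrid
from .legend import ClassLegend, read_legend, six_class_legend
from .metrics import (
    class_table,
    format_class_table,
    format_landscape_table,
    landscape_table,
    DEFAULT_MIN_PATCHES,
)
from .raster_io import check_aligned, read_raster, write_raster
from .succession import sankey_export, transition_matrix
from .synthetic import SyntheticLandscapeConfig, evolve_series, generate_random_cluster

__all__ = ["PipelineConfig", "run_metrics", "run_transitions", "run_simulate"]

logger = logging.getLogger("patchscape")


@dataclass
class PipelineConfig:
    """Settings shared by the pipeline stages.

    ``rasters`` lists epoch raster paths ordered oldest → newest;
    ``legend_path`` points at a YAML/JSON legend (the six-class default is
    used when omitted).
    """

    rasters: list[Path] = field(default_factory=list)
    legend_path: Optional[Path] = None
    out_dir: Path = Path("patchscape_out")
    connectivity: int = 8
    min_patches: int = DEFAULT_MIN_PATCHES
    formatted: bool = False
    literal_cohesion: bool = False
    seed: int = 0

    def load_legend(self) -> ClassLegend:
        if self.legend_path is None:
            return six_class_legend()
        return read_legend(self.legend_path)


class _OutputTracker:
    """Removes this run's outputs if the stage fails midway."""

    def __init__(self, out_dir: Path):
        self.out_dir = Path(out_dir)
        self.created: list[Path] = []

    def __enter__(self) -> "_OutputTracker":
        self.out_dir.mkdir(parents=True, exist_ok=True)
        return self

    def path(self, name: str) -> Path:
        p = self.out_dir / name
        self.created.append(p)
        return p

    def __exit__(self, exc_type, exc, tb) -> None:
        if exc_type is not None:
            for p in self.created:
                p.unlink(missing_ok=True)


def _write_manifest(tracker: _OutputTracker, stage: str, settings: dict) -> None:
    manifest = {"stage": stage, "settings": settings,
                "outputs": [p.name for p in tracker.created]}
    tracker.path(f"{stage}_manifest.json").write_text(json.dumps(manifest, indent=2))


def _load_epochs(config: PipelineConfig, legend: ClassLegend) -> list[LandscapeGrid]:
    grids = []
    for path in config.rasters:
        try:
            grids.append(read_raster(path, legend))
        except Exception as exc:
            raise type(exc)(f"epoch raster {path}: {exc}") from exc
    return grids


def run_metrics(config: PipelineConfig) -> list[Path]:
    """Per-epoch class tables plus one landscape table, as CSV."""
    if not config.rasters:
        raise ValueError("metrics stage needs at least one epoch raster")
    legend = config.load_legend()
    grids = _load_epochs(config, legend)
    with _OutputTracker(config.out_dir) as tracker:
        t0 = time.perf_counter()
        for grid in grids:
            tab = class_table(grid, legend, config.connectivity,
                              config.min_patches, config.literal_cohesion)
            absent = set(legend.names) - set(tab["Landscapes"])
            if absent:
                logger.info("epoch %s: classes absent, rows omitted: %s",
                            grid.epoch_label, sorted(absent))
            if config.formatted:
                tab = format_class_table(tab)
            out = tracker.path(f"class_metrics_{grid.epoch_label}.csv")
            tab.to_csv(out, index=False)
            logger.info("epoch %s: %d class rows -> %s",
                        grid.epoch_label, len(tab), out)
        land = landscape_table(grids, legend, config.connectivity,
                               config.min_patches)
        if config.formatted:
            land = format_landscape_table(land)
        out = tracker.path("landscape_metrics.csv")
        land.to_csv(out, index=False)
        logger.info("landscape table: %d epochs in %.2f s",
                    len(grids), time.perf_counter() - t0)
        _write_manifest(tracker, "metrics", {
            "rasters": [str(p) for p in config.rasters],
            "connectivity": config.connectivity,
            "min_patches": config.min_patches,
            "formatted": config.formatted,
            "literal_cohesion": config.literal_cohesion,
        })
        return list(tracker.created)


def run_transitions(config: PipelineConfig) -> list[Path]:
    """Transition matrix CSV per consecutive epoch pair + chained Sankey JSON."""
    if len(config.rasters) < 2:
        raise ValueError("transition stage needs at least two epoch rasters")
    legend = config.load_legend()
    grids = _load_epochs(config, legend)
    check_aligned(grids)
    with _OutputTracker(config.out_dir) as tracker:
        tms = []
        for g1, g2 in zip(grids[:-1], grids[1:]):
            tm = transition_matrix(g1, g2, legend)
            tms.append(tm)
            out = tracker.path(
                f"transition_{g1.epoch_label}_{g2.epoch_label}.csv")
            tm.to_csv(out)
            logger.info("transition %s -> %s: %.1f ha jointly valid",
                        g1.epoch_label, g2.epoch_label, tm.total_area)
        sankey_path = tracker.path("sankey.json")
        doc = sankey_export(tms, legend, sankey_path)
        logger.info("sankey: %d nodes, %d links",
                    len(doc["nodes"]), len(doc["links"]))
        _write_manifest(tracker, "transition", {
            "rasters": [str(p) for p in config.rasters],
        })
        return list(tracker.created)


def run_simulate(
    config_path: Union[str, Path],
    out_dir: Union[str, Path],
    seed: Optional[int] = None,
    fmt: str = "ascii",
) -> list[Path]:
    """Generate a reproducible synthetic epoch series from a YAML config.

    Config schema::

        nrows: 120
        ncols: 120
        cell_size: 30
        aggregation: 0.5
        seed: 42              # overridable by the seed argument
        target_proportions: {forests: 0.82, croplands: 0.113, ...}
        epochs:
          - label: "1986"
          - label: "1995"
            changes: [[forests, croplands, 0.02]]

    The first epoch is generated directly; each later epoch evolves the
    previous one by its ``changes`` rules.
    """
    doc = yaml.safe_load(Path(config_path).read_text())
    seed = int(doc.get("seed", 0)) if seed is None else int(seed)
    legend = (read_legend(doc["legend"]) if "legend" in doc
              else six_class_legend())
    epochs = doc.get("epochs") or [{"label": "epoch0"}]
    base_cfg = SyntheticLandscapeConfig(
        nrows=int(doc["nrows"]),
        ncols=int(doc["ncols"]),
        cell_size=float(doc.get("cell_size", 30.0)),
        target_proportions={k: float(v)
                            for k, v in doc["target_proportions"].items()},
        aggregation=float(doc.get("aggregation", 0.5)),
        seed=seed,
        legend=legend,
        epoch_label=str(epochs[0].get("label", "epoch0")),
    )
    suffix = ".tif" if fmt == "geotiff" else ".asc"
    with _OutputTracker(Path(out_dir)) as tracker:
        grid = generate_random_cluster(base_cfg)
        paths = [write_raster(grid, tracker.path(f"{grid.epoch_label}{suffix}"), fmt)]
        for i, epoch in enumerate(epochs[1:], start=1):
            changes = [tuple(rule) for rule in epoch.get("changes", [])]
            grid = evolve_series(grid, changes, seed=seed + i, legend=legend,
                                 epoch_label=str(epoch.get("label", f"epoch{i}")))
            paths.append(write_raster(
                grid, tracker.path(f"{grid.epoch_label}{suffix}"), fmt))
        logger.info("simulated %d epoch(s) at %dx%d, aggregation %.2f",
                    len(paths), base_cfg.nrows, base_cfg.ncols,
                    base_cfg.aggregation)
        _write_manifest(tracker, "simulate", {
            "config": str(config_path), "seed": seed, "format": fmt,
        })
        return list(tracker.created)
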