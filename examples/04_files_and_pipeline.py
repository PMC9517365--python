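"""File-based workflow: rasters on disk, legend config, pipeline stages.

Writes a synthetic epoch series as ESRI ASCII grids plus a YAML legend,
then runs the metrics and transition stages exactly as the command line
(`patchscape metrics ...` / `patchscape transition ...`) would.
"""

import tempfile
from pathlib import Path

from patchscape import (
    PipelineConfig,
    SyntheticLandscapeConfig,
    evolve_series,
    ganjiang_like_proportions,
    generate_random_cluster,
    run_metrics,
    run_transitions,
    six_class_legend,
    write_raster,
)
from patchscape.legend import write_legend

workdir = Path(tempfile.mkdtemp(prefix="patchscape_example_"))
legend = six_class_legend()
write_legend(legend, workdir / "legend.yaml")

base = generate_random_cluster(SyntheticLandscapeConfig(
    nrows=100, ncols=100, target_proportions=ganjiang_like_proportions(),
    aggregation=0.5, seed=2, epoch_label="2010"))
nxt = evolve_series(base, [("forests", "croplands", 0.04)], seed=3,
                    epoch_label="2018")
rasters = [write_raster(base, workdir / "2010.asc"),
           write_raster(nxt, workdir / "2018.asc")]

cfg = PipelineConfig(rasters=rasters, legend_path=workdir / "legend.yaml",
                     out_dir=workdir / "report", formatted=True)
outputs = run_metrics(cfg) + run_transitions(cfg)
print("Pipeline outputs:")
for path in outputs:
    print(" ", path.relative_to(workdir))
print("\nLandscape table:")
print((workdir / "report" / "landscape_metrics.csv").read_text())
# class_metrics_<epoch>.csv holds the eight class-scale indices per epoch;
# transition_2010_2018.csv the area flows in ha; sankey.json the chained
# node/link document with no-succession (diagonal) flows removed.
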