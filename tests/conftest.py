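import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from patchscape import (
    LandscapeGrid,
    SyntheticLandscapeConfig,
    ganjiang_like_proportions,
    generate_random_cluster,
    six_class_legend,
)


@pytest.fixture(scope="session")
def legend():
    return six_class_legend()


@pytest.fixture
def random_grid(legend):
    """Factory for seeded random six-class grids (i.i.d. cells)."""

    def make(nrows=12, ncols=12, seed=0, cell_size=30.0, n_classes=6):
        rng = np.random.default_rng(seed)
        codes = np.array(legend.codes[:n_classes])
        cells = rng.choice(codes, size=(nrows, ncols))
        return LandscapeGrid(cells=cells.astype(np.int32), cell_size=cell_size,
                             nodata_code=legend.nodata_code)

    return make


@pytest.fixture(scope="session")
def forest_dominated_grid(legend):
    """One clustered six-class landscape shared by read-only tests."""
    cfg = SyntheticLandscapeConfig(
        nrows=120, ncols=120,
        target_proportions=ganjiang_like_proportions(),
        aggregation=0.5, seed=11, epoch_label="base",
    )
    return generate_random_cluster(cfg)
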