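"""Published reference statistics shipped as inputs.

A multi-decadal Fragstats analysis of an ecological-red-line landscape in
a subtropical river basin (six land-cover classes, 30 m Landsat-derived
maps for 1986/1995/2005/2010/2018) provides printed class- and
landscape-scale index tables. The source rasters are not deposited, but
the printed columns are themselves inputs from which several quantities
can be recomputed — class percentages and densities from the area and
patch-count columns, evenness from diversity — and those recomputations
serve as arithmetic cross-checks of this package's index definitions.

Only the 2018 class table is arithmetically self-consistent with its
landscape row; the 1986 landscape densities imply a slightly different
total area, so cross-checks anchor on 2018.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "reference_class_table_2018",
    "reference_landscape_table",
]


def reference_class_table_2018() -> pd.DataFrame:
    """Class-scale statistics for the 2018 map: CA (ha), PLAND (%), NP,
    PD (per 100 ha), LPI (%), PAFRAC, COHESION (%), AI (%)."""
    rows = [
        # class,        CA (ha),  PLAND,  NP,   PD,   LPI,  PAFRAC, COHESION, AI
        ("croplands",   167_715,  11.3,  9420,  0.6,  0.1,  1.51,   87.8,  63.5),
        ("forests",   1_220_103,  82.0,  1853,  0.1,  7.9,  1.38,   99.5,  92.5),
        ("grasslands",   76_200,   5.1,  2325,  0.2,  0.2,  1.42,   90.3,  73.4),
        ("water",        18_052,   1.2,   423,  0.0,  0.2,  1.55,   94.4,  70.4),
        ("settlements",   6_445,   0.4,  1260,  0.1,  0.0,  1.40,   62.9,  47.5),
        ("others",           13,   0.0,     4,  0.0,  0.0,  None,   46.1,  50.0),
    ]
    return pd.DataFrame(
        rows,
        columns=["Landscapes", "CA", "PLAND", "NP", "PD", "LPI", "PAFRAC",
                 "COHESION", "AI"],
    )


def reference_landscape_table() -> pd.DataFrame:
    """Landscape-scale indices for the five epochs: NP, PD (per 100 ha),
    LPI (%), PAFRAC, SHDI, SHEI, AI (%)."""
    rows = [
        ("1986", 15_427, 1.042, 8.060, 1.452, 0.628, 0.350, 87.535),
        ("1995", 15_338, 1.031, 8.045, 1.452, 0.623, 0.348, 87.632),
        ("2005", 15_308, 1.029, 7.958, 1.452, 0.627, 0.350, 87.569),
        ("2010", 15_765, 1.060, 7.949, 1.459, 0.626, 0.349, 87.273),
        ("2018", 15_285, 1.027, 7.853, 1.442, 0.638, 0.356, 87.789),
    ]
    return pd.DataFrame(
        rows,
        columns=["Years", "NP", "PD", "LPI", "PAFRAC", "SHDI", "SHEI", "AI"],
    )
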