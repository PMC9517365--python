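"""Reading and writing categorical rasters.

Two on-disk formats are supported:

* **ESRI ASCII grid** (``.asc``) — the plain-text interchange format with
  ``NCOLS/NROWS/XLLCORNER/YLLCORNER/CELLSIZE/NODATA_VALUE`` headers.
* **GeoTIFF** — a single integer band; the cell size travels in the
  GeoTIFF ModelPixelScale tag and the nodata code in the GDAL nodata tag.
  Georeferencing beyond the cell size is carried through but unused by the
  metrics.

Both formats round-trip exactly on (cells, cell_size, nodata_code).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import numpy as np
import tifffile

from .grid import LandscapeGrid
from .legend import ClassLegend

__all__ = ["read_raster", "write_raster", "check_aligned", "AlignmentError"]

_MODEL_PIXEL_SCALE = 33550  # GeoTIFF: (sx, sy, sz) doubles
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113  # ASCII representation of the nodata value

_ASCII_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize")


class AlignmentError(ValueError):
    """Raised when multi-epoch grids are not co-registered."""


# ---------------------------------------------------------------------------
# ESRI ASCII grid
# ---------------------------------------------------------------------------

def _read_ascii(path: Path) -> tuple[np.ndarray, float, int]:
    header: dict[str, float] = {}
    data_lines: list[str] = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            key = parts[0].lower()
            if not data_lines and key in _ASCII_HEADER_KEYS + ("nodata_value",):
                header[key] = float(parts[1])
            else:
                data_lines.append(line)
    for req in ("ncols", "nrows", "cellsize"):
        if req not in header:
            raise ValueError(f"{path}: missing required ASCII grid header {req!r}")
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = int(header.get("nodata_value", -9999))
    values = np.loadtxt(data_lines, dtype=np.int64, ndmin=2)
    values = values.reshape(nrows, ncols)
    return values.astype(np.int32), float(header["cellsize"]), nodata


def _write_ascii(grid: LandscapeGrid, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"NCOLS {grid.ncols}\n")
        fh.write(f"NROWS {grid.nrows}\n")
        fh.write("XLLCORNER 0.0\n")
        fh.write("YLLCORNER 0.0\n")
        fh.write(f"CELLSIZE {grid.cell_size:g}\n")
        fh.write(f"NODATA_VALUE {grid.nodata_code}\n")
        np.savetxt(fh, grid.cells, fmt="%d")


# ---------------------------------------------------------------------------
# GeoTIFF (single integer band via tifffile)
# ---------------------------------------------------------------------------

def _read_geotiff(path: Path) -> tuple[np.ndarray, float, int]:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        if data.ndim == 3:  # single-band written as (1, r, c) or (r, c, 1)
            data = np.squeeze(data)
        if data.ndim != 2:
            raise ValueError(f"{path}: expected a single-band raster")
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError(
                f"{path}: band is {data.dtype}, expected an integer type"
            )
        scale_tag = page.tags.get(_MODEL_PIXEL_SCALE)
        cell_size = float(scale_tag.value[0]) if scale_tag is not None else 1.0
        nodata_tag = page.tags.get(_GDAL_NODATA)
        nodata = int(float(nodata_tag.value)) if nodata_tag is not None else -9999
    return data.astype(np.int32), cell_size, nodata


def _write_geotiff(grid: LandscapeGrid, path: Path) -> None:
    scale = (float(grid.cell_size), float(grid.cell_size), 0.0)
    tiepoint = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
    extratags = [
        (_MODEL_PIXEL_SCALE, "d", 3, scale, True),
        (_MODEL_TIEPOINT, "d", 6, tiepoint, True),
        (_GDAL_NODATA, "s", 0, str(grid.nodata_code), True),
    ]
    tifffile.imwrite(path, grid.cells, extratags=extratags)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _format_for_path(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("ascii", "geotiff"):
            raise ValueError(f"unknown raster format {fmt!r}")
        return fmt
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        return "geotiff"
    return "ascii"


def read_raster(
    path: Union[str, Path],
    legend: ClassLegend,
    epoch_label: str = "",
    fmt: str | None = None,
) -> LandscapeGrid:
    """Read a categorical raster and validate it against a legend.

    The format is inferred from the suffix (``.tif``/``.tiff`` → GeoTIFF,
    anything else → ESRI ASCII) unless ``fmt`` is given. Unknown class codes
    raise ``ValueError`` naming the code and the first offending cell.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if _format_for_path(path, fmt) == "geotiff":
        cells, cell_size, nodata = _read_geotiff(path)
    else:
        cells, cell_size, nodata = _read_ascii(path)
    grid = LandscapeGrid(
        cells=cells,
        cell_size=cell_size,
        nodata_code=nodata,
        epoch_label=epoch_label or path.stem,
    )
    return grid.validate(legend)


def write_raster(
    grid: LandscapeGrid, path: Union[str, Path], fmt: str | None = None
) -> Path:
    """Write a grid as an ESRI ASCII grid or GeoTIFF.

    ``read_raster`` on the result reproduces (cells, cell_size,
    nodata_code) exactly.
    """
    path = Path(path)
    if _format_for_path(path, fmt) == "geotiff":
        _write_geotiff(grid, path)
    else:
        _write_ascii(grid, path)
    return path


def check_aligned(grids: Sequence[LandscapeGrid]) -> None:
    """Verify that multi-epoch grids are co-registered.

    Transition analysis cross-tabulates cell-by-cell, so every epoch must
    share shape, cell size and nodata code. Raises :class:`AlignmentError`
    naming the first mismatching property.
    """
    if len(grids) < 2:
        raise ValueError("alignment check needs at least two grids")
    ref = grids[0]
    for g in grids[1:]:
        pair = f"{ref.epoch_label!r} vs {g.epoch_label!r}"
        if g.shape != ref.shape:
            raise AlignmentError(
                f"shape mismatch {ref.shape} vs {g.shape} ({pair})"
            )
        if g.cell_size != ref.cell_size:
            raise AlignmentError(
                f"cell-size mismatch {ref.cell_size} vs {g.cell_size} ({pair})"
            )
        if g.nodata_code != ref.nodata_code:
            raise AlignmentError(
                f"nodata-code mismatch {ref.nodata_code} vs {g.nodata_code} ({pair})"
            )
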