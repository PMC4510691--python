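"""File I/O: single-band TIFF rasters and CSV tables.

Rasters are written as single-band float64 TIFFs. The grid metadata
(origin, cell size and area, CRS tag, semantics) travels in the
ImageDescription tag as JSON, and the nodata sentinel is additionally
recorded in the GDAL_NODATA tag (42113) so GIS tools mask the rasters
correctly. Foreign single-band TIFFs without our metadata block are
readable too: the grid is reconstructed from the array shape and the
GDAL_NODATA tag when present.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .grid import Grid, Raster, RasterValidationError

__all__ = ["read_raster", "write_raster"]

_META_KEY = "cumimpact"
_GDAL_NODATA_TAG = 42113


def write_raster(raster: Raster, path: str | Path) -> None:
    """Write a raster to ``path`` as a single-band float64 TIFF.

    NaN cells are replaced by the grid's nodata sentinel on disk; the
    round trip through :func:`read_raster` restores them (and is bitwise
    exact for valid cells).
    """
    path = Path(path)
    if not path.parent.is_dir():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    g = raster.grid
    data = raster.values.copy()
    data[~raster.valid_mask] = g.nodata
    meta = {
        _META_KEY: {
            "n_rows": g.n_rows,
            "n_cols": g.n_cols,
            "cell_size": g.cell_size,
            "cell_area": g.cell_area,
            "origin_x": g.origin_x,
            "origin_y": g.origin_y,
            "crs_tag": g.crs_tag,
            "nodata": g.nodata,
            "semantics": raster.semantics,
        }
    }
    tifffile.imwrite(
        path,
        data,
        description=json.dumps(meta),
        extratags=[(_GDAL_NODATA_TAG, "s", 0, str(g.nodata), True)],
    )


def read_raster(path: str | Path, expected_tag: str | None = None) -> Raster:
    """Read a single-band TIFF as a :class:`Raster`.

    Parameters
    ----------
    path : path
        Single-band TIFF file.
    expected_tag : str, optional
        Semantics the caller requires. If the file carries a semantics tag
        it must match; otherwise the expected tag is adopted. Validation of
        the tag's invariants happens either way and errors name the first
        offending pixel.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"raster file not found: {path}")
    with tifffile.TiffFile(path) as tf:
        if len(tf.series) != 1:
            raise RasterValidationError(f"{path}: expected a single image series, found {len(tf.series)}")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise RasterValidationError(
                f"{path}: multi-band input ({page.samplesperpixel} samples/pixel); single-band required"
            )
        data = tf.asarray().astype(np.float64)
        if data.ndim != 2:
            raise RasterValidationError(f"{path}: multi-band/stacked input with shape {data.shape}")
        meta = None
        desc = page.description
        if desc:
            try:
                parsed = json.loads(desc)
                meta = parsed.get(_META_KEY)
            except (json.JSONDecodeError, AttributeError):
                meta = None
        nodata = None
        if _GDAL_NODATA_TAG in page.tags:
            try:
                nodata = float(page.tags[_GDAL_NODATA_TAG].value)
            except (TypeError, ValueError):
                nodata = None

    if meta is not None:
        grid = Grid(
            n_rows=int(meta["n_rows"]),
            n_cols=int(meta["n_cols"]),
            cell_size=float(meta["cell_size"]),
            cell_area=float(meta["cell_area"]),
            origin_x=float(meta["origin_x"]),
            origin_y=float(meta["origin_y"]),
            crs_tag=str(meta["crs_tag"]),
            nodata=float(meta["nodata"]),
        )
        semantics = str(meta["semantics"])
    else:
        grid = Grid(
            n_rows=data.shape[0],
            n_cols=data.shape[1],
            cell_size=1.0,
            nodata=nodata if nodata is not None else -9999.0,
        )
        semantics = expected_tag or "intensity"

    if expected_tag is not None and semantics != expected_tag:
        raise RasterValidationError(
            f"{path}: semantics mismatch: file says {semantics!r}, caller expects {expected_tag!r}"
        )

    data[data == grid.nodata] = np.nan
    return Raster(grid, data, semantics)
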