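"""Raster data model shared by every stage of the pipeline.

A :class:`Grid` describes an abstract equal-area grid: every cell has the
same area (``cell_area``), which is what makes per-cell fractions equal to
area fractions and unweighted zonal means equal to area-weighted means.
The equal-area contract is carried as metadata (``crs_tag`` plus a constant
``cell_area``); no reprojection is performed here.

Internally nodata is represented as NaN in a float64 array, regardless of
the raster's semantics; the sentinel recorded on the grid is only used at
the file boundary. NaN never participates in arithmetic and propagates
through every operation, which is exactly the nodata semantics downstream
modules rely on.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

__all__ = ["Grid", "Raster", "AlignmentError", "RasterValidationError", "assert_aligned", "SEMANTICS"]

#: Recognized semantics tags and what their cells may contain.
SEMANTICS = (
    "intensity",     # non-negative reals
    "normalized",    # reals in [0, 1]
    "presence",      # {0, 1}
    "impact",        # non-negative reals
    "change",        # any real
    "category",      # non-negative integers
    "region_label",  # non-negative integers
    "depth",         # any real (positive = below sea level)
)

DEFAULT_NODATA = -9999.0


class RasterValidationError(ValueError):
    """A raster's values violate the invariants of its semantics tag."""


class AlignmentError(ValueError):
    """Two rasters do not share the same grid."""


@dataclass(frozen=True)
class Grid:
    """Geometry shared by all layers of one analysis.

    Parameters
    ----------
    n_rows, n_cols : int
        Raster shape; row 0 is the top row, indices are 0-based.
    cell_size : float
        Cell edge length in map units.
    cell_area : float, optional
        Constant per-cell area. Defaults to ``cell_size ** 2``.
    origin_x, origin_y : float
        Map coordinates of the top-left corner of cell (0, 0).
    crs_tag : str
        Free-text label for the (equal-area) coordinate system.
    nodata : float
        Sentinel written to files; in memory nodata is always NaN.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    cell_area: float = 0.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    crs_tag: str = "synthetic-equal-area"
    nodata: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid shape must be at least 1x1, got {self.n_rows}x{self.n_cols}")
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be positive, got {self.cell_size}")
        if self.cell_area == 0.0:
            object.__setattr__(self, "cell_area", float(self.cell_size) ** 2)
        if self.cell_area <= 0:
            raise ValueError(f"cell_area must be positive, got {self.cell_area}")
        if not np.isfinite(self.nodata):
            raise ValueError("nodata sentinel must be finite (NaN is the in-memory representation)")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)


def _first_bad_index(mask: np.ndarray) -> tuple[int, int]:
    flat = int(np.flatnonzero(mask)[0])
    r, c = np.unravel_index(flat, mask.shape)
    return (int(r), int(c))


def _validate_values(values: np.ndarray, semantics: str) -> None:
    valid = np.isfinite(values)
    v = values[valid]
    if semantics == "intensity" or semantics == "impact":
        bad = valid & (values < 0)
        if bad.any():
            idx = _first_bad_index(bad)
            raise RasterValidationError(
                f"{semantics} raster has negative value {values[idx]} at pixel {idx}"
            )
    elif semantics == "normalized":
        bad = valid & ((values < 0) | (values > 1))
        if bad.any():
            idx = _first_bad_index(bad)
            raise RasterValidationError(
                f"normalized raster has out-of-[0,1] value {values[idx]} at pixel {idx}"
            )
    elif semantics == "presence":
        bad = valid & (values != 0) & (values != 1)
        if bad.any():
            idx = _first_bad_index(bad)
            raise RasterValidationError(
                f"presence raster has non-binary value {values[idx]} at pixel {idx}"
            )
    elif semantics in ("category", "region_label"):
        bad = valid & ((values < 0) | (values != np.floor(values)))
        if bad.any():
            idx = _first_bad_index(bad)
            raise RasterValidationError(
                f"{semantics} raster has non-(non-negative-integer) value {values[idx]} at pixel {idx}"
            )
    elif semantics in ("change", "depth"):
        pass
    else:
        raise RasterValidationError(f"unknown semantics tag {semantics!r}; expected one of {SEMANTICS}")


@dataclass
class Raster:
    """A single-band grid of values with semantics.

    ``values`` is always float64 with NaN marking nodata, even for
    categorical semantics — validation enforces integer-valued cells where
    required.
    """

    grid: Grid
    values: np.ndarray
    semantics: str = "intensity"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise RasterValidationError(f"raster values must be 2-D, got ndim={self.values.ndim}")
        if self.values.shape != self.grid.shape:
            raise AlignmentError(
                f"values shape {self.values.shape} does not match grid shape {self.grid.shape}"
            )
        _validate_values(self.values, self.semantics)

    # -- masks ---------------------------------------------------------

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean mask of cells holding data."""
        return np.isfinite(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    @property
    def n_nodata(self) -> int:
        return int((~self.valid_mask).sum())

    def valid_values(self) -> np.ndarray:
        return self.values[self.valid_mask]

    # -- construction helpers -----------------------------------------

    def with_values(self, values: np.ndarray, semantics: str | None = None) -> "Raster":
        """New raster on the same grid (re-validated)."""
        return Raster(self.grid, values, semantics or self.semantics)

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy(), self.semantics)

    @classmethod
    def full(cls, grid: Grid, fill: float, semantics: str = "intensity") -> "Raster":
        return cls(grid, np.full(grid.shape, fill, dtype=np.float64), semantics)

    def equals(self, other: "Raster") -> bool:
        """Cell-for-cell equality including the nodata pattern."""
        return (
            self.grid == other.grid
            and self.semantics == other.semantics
            and np.array_equal(self.values, other.values, equal_nan=True)
        )


def assert_aligned(rasters: Iterable[Raster]) -> None:
    """Verify all rasters share an identical grid.

    Raises :class:`AlignmentError` naming the first differing grid field.
    """
    rasters = list(rasters)
    if not rasters:
        raise ValueError("assert_aligned requires at least one raster")
    ref = rasters[0].grid
    for r in rasters[1:]:
        g = r.grid
        if g == ref:
            continue
        for name in ("n_rows", "n_cols", "cell_size", "cell_area", "origin_x", "origin_y", "crs_tag", "nodata"):
            if getattr(g, name) != getattr(ref, name):
                raise AlignmentError(
                    f"grids misaligned: field {name!r} differs ({getattr(ref, name)!r} vs {getattr(g, name)!r})"
                )
        raise AlignmentError("grids misaligned")  # pragma: no cover - all fields covered above
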