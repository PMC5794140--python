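"""Raster grid geometry and a minimal raster container.

All rasters in the pipeline share one grid: a north-up, square-pixel grid in
a projected coordinate system with meter units (distance weighting and
buffered accuracy are meaningless in degrees, so metric units are enforced
wherever distances are computed). Pixel cells are half-open intervals:
cell (row, col) covers [x0 + col*s, x0 + (col+1)*s) x (y_top - (row+1)*s,
y_top - row*s], so every point in the extent maps to exactly one pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
from shapely.geometry import box


class CRSError(ValueError):
    """Raised when a grid's coordinate system is missing or non-metric."""


@dataclass(frozen=True)
class GridGeometry:
    """North-up square-pixel grid.

    Parameters
    ----------
    origin_x, origin_y
        Coordinates of the grid's top-left corner (origin_y is the MAX y).
    pixel_size
        Pixel edge length in CRS units (> 0).
    shape
        (n_rows, n_cols).
    crs
        CRS identifier string (e.g. ``"EPSG:32630"``); informational.
    crs_units
        ``"m"`` for projected metric systems, ``"degree"`` for geographic.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    shape: tuple[int, int]
    crs: str = "EPSG:32630"
    crs_units: str = "m"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")
        nrows, ncols = self.shape
        if nrows <= 0 or ncols <= 0:
            raise ValueError(f"degenerate grid shape {self.shape}")
        if self.crs_units not in ("m", "degree"):
            raise CRSError(f"unknown crs_units {self.crs_units!r}")

    def require_metric(self) -> None:
        """Raise :class:`CRSError` unless the grid is in meter units."""
        if self.crs_units != "m":
            raise CRSError(
                f"grid CRS {self.crs!r} has units {self.crs_units!r}; "
                "a projected metric CRS is required for distance operations"
            )

    # -- extent ------------------------------------------------------------

    @property
    def n_rows(self) -> int:
        return self.shape[0]

    @property
    def n_cols(self) -> int:
        return self.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax)."""
        return (
            self.origin_x,
            self.origin_y - self.n_rows * self.pixel_size,
            self.origin_x + self.n_cols * self.pixel_size,
            self.origin_y,
        )

    @property
    def extent_polygon(self):
        return box(*self.extent)

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2

    def contains(self, x, y) -> np.ndarray:
        xmin, ymin, xmax, ymax = self.extent
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= xmin) & (x < xmax) & (y > ymin) & (y <= ymax)

    # -- coordinate transforms --------------------------------------------

    def xy_to_rowcol(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Map coordinates to (row, col) under the half-open cell convention.

        Coordinates outside the extent yield out-of-range indices; callers
        that care should check :meth:`contains` first.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.pixel_size).astype(np.int64)
        row = np.floor((self.origin_y - y) / self.pixel_size).astype(np.int64)
        # top edge belongs to row 0
        row = np.where(np.asarray(y) == self.origin_y, 0, row)
        return row, col

    def rowcol_to_center(self, row, col) -> tuple[np.ndarray, np.ndarray]:
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_x + (col + 0.5) * self.pixel_size
        y = self.origin_y - (row + 0.5) * self.pixel_size
        return x, y

    def cell_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one pixel cell."""
        x0 = self.origin_x + col * self.pixel_size
        y1 = self.origin_y - row * self.pixel_size
        return (x0, y1 - self.pixel_size, x0 + self.pixel_size, y1)

    def center_meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.mgrid[0 : self.n_rows, 0 : self.n_cols]
        return self.rowcol_to_center(rows, cols)

    def to_dict(self) -> dict:
        return {
            "origin_x": self.origin_x,
            "origin_y": self.origin_y,
            "pixel_size": self.pixel_size,
            "shape": list(self.shape),
            "crs": self.crs,
            "crs_units": self.crs_units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridGeometry":
        return cls(
            origin_x=d["origin_x"],
            origin_y=d["origin_y"],
            pixel_size=d["pixel_size"],
            shape=tuple(d["shape"]),
            crs=d.get("crs", "EPSG:32630"),
            crs_units=d.get("crs_units", "m"),
        )


@dataclass
class Raster:
    """A 2-D array bound to a :class:`GridGeometry` with an optional nodata value."""

    data: np.ndarray
    grid: GridGeometry
    nodata: float | int | None = None
    legend: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 2:
            raise ValueError(f"raster data must be 2-D, got ndim={self.data.ndim}")
        if self.data.shape != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) pixels."""
        if self.nodata is None:
            return np.ones(self.data.shape, dtype=bool)
        if np.issubdtype(self.data.dtype, np.floating) and np.isnan(self.nodata):
            return ~np.isnan(self.data)
        return self.data != self.nodata

    def sample(self, x, y) -> np.ndarray:
        """Nearest-pixel lookup at coordinates; raises if any point is outside."""
        inside = self.grid.contains(x, y)
        if not np.all(inside):
            raise ValueError("sample coordinates outside raster extent")
        row, col = self.grid.xy_to_rowcol(x, y)
        return self.data[row, col]

    def copy(self) -> "Raster":
        return Raster(self.data.copy(), self.grid, self.nodata, dict(self.legend))


def check_aligned(*rasters: Raster) -> GridGeometry:
    """Assert all rasters share one grid; return it."""
    if not rasters:
        raise ValueError("no rasters given")
    g0 = rasters[0].grid
    for r in rasters[1:]:
        if r.grid != g0:
            raise ValueError(f"raster grids differ: {r.grid} vs {g0}")
    return g0
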