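"""Planar raster grids: the common currency of every pipeline stage.

A :class:`RasterGrid` is a rectangular lattice of values on a planar
(meter-based) coordinate frame, with a cell size, a lower-left origin and a
nodata mask.  Row 0 of ``values`` is the TOP row of the map, matching the
on-disk convention of the ESRI ASCII grid format used for serialization.

No geographic CRS is modelled: the pipeline is projection-agnostic and all
coordinates are planar meters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["RasterGrid", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class RasterGrid:
    """Rectangular raster with cell size, origin and nodata mask.

    Parameters
    ----------
    values : ndarray of shape (nrows, ncols)
        Cell values; row 0 is the northernmost row.
    cell_size_m : float
        Edge length of the square cells, meters.
    origin_xy : (float, float)
        Planar coordinates of the lower-left corner of the grid.
    nodata_mask : ndarray of bool, optional
        True where the cell holds no data.  Defaults to all-valid.
    """

    values: np.ndarray
    cell_size_m: float
    origin_xy: tuple[float, float] = (0.0, 0.0)
    nodata_mask: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("raster values must be a 2-D array")
        if self.cell_size_m <= 0:
            raise ValueError("cell_size_m must be positive")
        if self.nodata_mask is None:
            self.nodata_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
            if self.nodata_mask.shape != self.values.shape:
                raise ValueError("nodata mask shape must equal values shape")

    # -- geometry -----------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """Planar (x, y) of a cell center; row 0 is the top row."""
        x0, y0 = self.origin_xy
        x = x0 + (col + 0.5) * self.cell_size_m
        y = y0 + (self.nrows - row - 0.5) * self.cell_size_m
        return x, y

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized cell-center coordinates, shape (nrows, ncols) each."""
        x0, y0 = self.origin_xy
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = x0 + (cols + 0.5) * self.cell_size_m
        y = y0 + (self.nrows - rows - 0.5) * self.cell_size_m
        return np.meshgrid(x, y)

    def index_of(self, x: float, y: float) -> tuple[int, int]:
        """(row, col) of the cell containing planar point (x, y)."""
        x0, y0 = self.origin_xy
        col = int(np.floor((x - x0) / self.cell_size_m))
        row = self.nrows - 1 - int(np.floor((y - y0) / self.cell_size_m))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise IndexError(f"point ({x}, {y}) outside raster extent")
        return row, col

    def like(self, values: np.ndarray, nodata_mask: np.ndarray | None = None) -> "RasterGrid":
        """New raster with identical grid spec and the given values."""
        mask = self.nodata_mask.copy() if nodata_mask is None else nodata_mask
        return RasterGrid(np.asarray(values), self.cell_size_m, self.origin_xy, mask)

    def same_grid(self, other: "RasterGrid") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.cell_size_m, other.cell_size_m)
            and np.allclose(self.origin_xy, other.origin_xy)
        )

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size_m / 1000.0) ** 2


def write_ascii_grid(grid: RasterGrid, path: str | Path) -> None:
    """Serialize a raster as an ESRI ASCII grid (plain text)."""
    path = Path(path)
    vals = np.where(grid.nodata_mask, _NODATA, grid.values.astype(float))
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.origin_xy[0]}\n"
        f"yllcorner {grid.origin_xy[1]}\n"
        f"cellsize {grid.cell_size_m}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with path.open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.8g")


def read_ascii_grid(path: str | Path) -> RasterGrid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        pos = fh.tell()
        for _ in range(6):
            line = fh.readline()
            key, val = line.split()
            header[key.lower()] = float(val)
            pos = fh.tell()
        fh.seek(pos)
        vals = np.loadtxt(fh, ndmin=2)
    nodata = header.get("nodata_value", _NODATA)
    mask = vals == nodata
    return RasterGrid(
        vals,
        cell_size_m=header["cellsize"],
        origin_xy=(header["xllcorner"], header["yllcorner"]),
        nodata_mask=mask,
    )
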