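"""Shared raster-grid geometry and plain-text raster I/O.

Grid convention: square cells of ``cell`` metres, origin at the lower-left
corner of the lower-left cell, cell-centre coordinates used everywhere.
Arrays are stored ``(ny, nx)`` with row 0 the southernmost row; the ESRI
ASCII grid interchange format stores the northernmost row first, and the
readers/writers below perform that flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Grid", "Raster", "write_ascii_grid", "read_ascii_grid"]

_NODATA = -9999.0


@dataclass(frozen=True)
class Grid:
    """Raster geometry: lower-left origin (m), cell size (m), shape."""

    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    def __post_init__(self) -> None:
        if self.cell <= 0:
            raise ValueError(f"cell size must be positive, got {self.cell}")
        if self.nx < 1 or self.ny < 1:
            raise ValueError("grid must have at least one cell per axis")

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) cell-centre coordinate arrays, each shaped (ny, nx)."""
        return np.meshgrid(self.x_centers(), self.y_centers())

    def extent(self) -> tuple[float, float, float, float]:
        return (
            self.x0,
            self.x0 + self.nx * self.cell,
            self.y0,
            self.y0 + self.ny * self.cell,
        )


@dataclass
class Raster:
    """A single-band raster on a :class:`Grid`; NaN marks missing cells."""

    grid: Grid
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    @property
    def mask(self) -> np.ndarray:
        """Boolean array, True where the cell is missing."""
        return np.isnan(self.values)

    def same_geometry(self, other: "Raster") -> bool:
        return self.grid == other.grid

    def copy(self) -> "Raster":
        return Raster(self.grid, self.values.copy())


def write_ascii_grid(raster: Raster, path: str | Path) -> None:
    """Write an ESRI ASCII grid (.asc); missing cells become NODATA."""
    g = raster.grid
    vals = np.where(raster.mask, _NODATA, raster.values)
    header = (
        f"ncols {g.nx}\n"
        f"nrows {g.ny}\n"
        f"xllcorner {g.x0!r}\n"
        f"yllcorner {g.y0!r}\n"
        f"cellsize {g.cell!r}\n"
        f"NODATA_value {_NODATA}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        # ESRI convention: first data row is the northernmost.
        np.savetxt(fh, vals[::-1], fmt="%.8g")


def read_ascii_grid(path: str | Path) -> Raster:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    with open(path) as fh:
        header: dict[str, float] = {}
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        vals = np.loadtxt(fh)
    vals = np.atleast_2d(vals)[::-1].copy()
    nodata = header.get("nodata_value", _NODATA)
    vals[vals == nodata] = np.nan
    grid = Grid(
        x0=header["xllcorner"],
        y0=header["yllcorner"],
        cell=header["cellsize"],
        nx=int(header["ncols"]),
        ny=int(header["nrows"]),
    )
    return Raster(grid, vals)
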