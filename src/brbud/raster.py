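"""Planar grids, ESRI ASCII raster I/O, and categorical habitat maps.

All rasters live on regular square-cell grids in projected metre coordinates.
Internally arrays are indexed ``values[iy, ix]`` with row 0 the *bottom* row
(y increasing with iy); ESRI ASCII files store rows top-down, so import and
export flip vertically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = ["GridSpec", "HabitatMap", "write_esri_ascii", "read_esri_ascii"]


@dataclass(frozen=True)
class GridSpec:
    """Regular square-cell grid: lower-left corner, cell size, shape."""

    x_min: float
    y_min: float
    cell: float
    n_cols: int
    n_rows: int

    def __post_init__(self) -> None:
        if not self.cell > 0:
            raise ValueError("cell size must be > 0")
        if self.n_cols < 1 or self.n_rows < 1:
            raise ValueError("grid must have at least one cell")

    @property
    def x_centers(self) -> np.ndarray:
        return self.x_min + (np.arange(self.n_cols) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y_min + (np.arange(self.n_rows) + 0.5) * self.cell

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell**2

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Column/row indices of the cells containing the given points."""
        ix = np.floor((np.asarray(x, dtype=float) - self.x_min) / self.cell).astype(int)
        iy = np.floor((np.asarray(y, dtype=float) - self.y_min) / self.cell).astype(int)
        return ix, iy

    def contains(self, x, y) -> np.ndarray:
        ix, iy = self.index_of(x, y)
        return (ix >= 0) & (ix < self.n_cols) & (iy >= 0) & (iy < self.n_rows)

    def same_geometry(self, other: "GridSpec", tol: float = 1e-9) -> bool:
        return (
            abs(self.x_min - other.x_min) <= tol
            and abs(self.y_min - other.y_min) <= tol
            and abs(self.cell - other.cell) <= tol
            and self.n_cols == other.n_cols
            and self.n_rows == other.n_rows
        )

    @classmethod
    def from_bounds(cls, x_lo: float, x_hi: float, y_lo: float, y_hi: float,
                    cell: float, margin: float = 0.0) -> "GridSpec":
        """Grid covering a bounding box expanded by ``margin`` on every side."""
        x_min = x_lo - margin
        y_min = y_lo - margin
        n_cols = max(1, int(np.ceil((x_hi + margin - x_min) / cell)))
        n_rows = max(1, int(np.ceil((y_hi + margin - y_min) / cell)))
        return cls(x_min, y_min, cell, n_cols, n_rows)


def write_esri_ascii(grid: GridSpec, values: np.ndarray, path,
                     nodata: float = -9999) -> None:
    """Write a grid as an ESRI ASCII raster (rows top-down)."""
    values = np.asarray(values)
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {float(grid.x_min)!r}\n")
        fh.write(f"yllcorner {float(grid.y_min)!r}\n")
        fh.write(f"cellsize {float(grid.cell)!r}\n")
        fh.write(f"NODATA_value {float(nodata):g}\n")
        np.savetxt(fh, values[::-1], fmt="%.10g")


def read_esri_ascii(path) -> tuple[GridSpec, np.ndarray, float]:
    """Read an ESRI ASCII raster; returns (grid, values, nodata)."""
    header: dict[str, float] = {}
    with open(path) as fh:
        pos = fh.tell()
        while True:
            line = fh.readline()
            parts = line.split()
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize",
                "nodata_value", "xllcenter", "yllcenter",
            }:
                header[parts[0].lower()] = float(parts[1])
                pos = fh.tell()
            else:
                break
        fh.seek(pos)
        values = np.loadtxt(fh, ndmin=2)
    n_cols, n_rows = int(header["ncols"]), int(header["nrows"])
    cell = header["cellsize"]
    if "xllcorner" in header:
        x_min, y_min = header["xllcorner"], header["yllcorner"]
    else:  # centre-registered variant
        x_min = header["xllcenter"] - cell / 2.0
        y_min = header["yllcenter"] - cell / 2.0
    if values.shape != (n_rows, n_cols):
        raise ValueError("raster body does not match declared nrows/ncols")
    grid = GridSpec(x_min, y_min, cell, n_cols, n_rows)
    return grid, values[::-1].copy(), header.get("nodata_value", -9999.0)


@dataclass
class HabitatMap:
    """Categorical habitat raster with an integer-code legend."""

    grid: GridSpec
    codes: np.ndarray  # int array, shape grid.shape, row 0 = bottom
    legend: dict[int, str] = field(default_factory=dict)
    nodata: int = -9999

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=int)
        if self.codes.shape != self.grid.shape:
            raise ValueError("codes shape does not match grid")
        present = set(np.unique(self.codes)) - {self.nodata}
        if not self.legend:
            self.legend = {int(c): str(int(c)) for c in sorted(present)}
        elif not present <= set(self.legend):
            missing = sorted(present - set(self.legend))
            raise ValueError(f"legend missing codes {missing}")

    def code_at(self, x, y):
        """Habitat code at point(s); nodata outside the raster."""
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 0
        shape = x.shape
        x = np.atleast_1d(x).ravel()
        y = np.atleast_1d(np.asarray(y, dtype=float)).ravel()
        ix, iy = self.grid.index_of(x, y)
        inside = self.grid.contains(x, y)
        out = np.full(x.shape, self.nodata, dtype=int)
        out[inside] = self.codes[iy[inside], ix[inside]]
        return int(out[0]) if scalar else out.reshape(shape)

    def resample_to(self, grid: GridSpec) -> "HabitatMap":
        """Nearest-neighbour resample onto another grid (cell centres)."""
        if self.grid.same_geometry(grid):
            return self
        xx, yy = np.meshgrid(grid.x_centers, grid.y_centers)
        codes = np.asarray(self.code_at(xx.ravel(), yy.ravel())).reshape(grid.shape)
        frac = float(np.mean(codes.ravel() == self.nodata))
        warnings.warn(
            f"habitat raster resampled to the UD grid; {frac:.1%} of target "
            "cells fall outside the source raster (set to NODATA)",
            stacklevel=2,
        )
        return HabitatMap(grid, codes, dict(self.legend), self.nodata)

    @classmethod
    def from_ascii(cls, path, legend: dict[int, str] | None = None) -> "HabitatMap":
        grid, values, nodata = read_esri_ascii(path)
        return cls(grid, values.astype(int), legend or {}, int(nodata))

    def to_ascii(self, path) -> None:
        write_esri_ascii(self.grid, self.codes, path, nodata=self.nodata)
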