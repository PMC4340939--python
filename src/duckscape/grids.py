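"""Raster grids on a local metric coordinate system.

All rasters in the package share one convention: a regular square-cell grid
in a local metric CRS with the origin at the south-west corner, row 0 at the
*north* edge, and cell centers at half-cell offsets.  Values are float64 in
memory; the file format is the plain-text ESRI ASCII grid, which round-trips
through any GIS.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

NODATA = -9999.0


@dataclass
class Grid:
    """A single-band raster on the package's shared grid convention.

    Parameters
    ----------
    data:
        2-D float array, row 0 = north edge.
    cell_size:
        Cell edge length in meters.
    x_origin, y_origin:
        Coordinates (m) of the south-west corner of the grid.
    nodata:
        Sentinel for missing cells.
    """

    data: np.ndarray
    cell_size: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    nodata: float = NODATA

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Grid data must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    @property
    def nrows(self) -> int:
        return self.data.shape[0]

    @property
    def ncols(self) -> int:
        return self.data.shape[1]

    @property
    def cell_area_km2(self) -> float:
        return (self.cell_size / 1000.0) ** 2

    def mask(self) -> np.ndarray:
        """Boolean array, True where data is valid."""
        return ~np.isclose(self.data, self.nodata) & ~np.isnan(self.data)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinate arrays (m) of every cell center, shape (nrows, ncols)."""
        cols = np.arange(self.ncols)
        rows = np.arange(self.nrows)
        x = self.x_origin + (cols + 0.5) * self.cell_size
        y = self.y_origin + (self.nrows - rows - 0.5) * self.cell_size
        return np.meshgrid(x, y)

    def row_of_y(self, y: float) -> int:
        """Row index whose center is nearest the given y coordinate."""
        r = self.nrows - 0.5 - (y - self.y_origin) / self.cell_size
        return int(np.clip(np.round(r), 0, self.nrows - 1))

    def like(self, data: np.ndarray) -> "Grid":
        """A new Grid sharing this grid's georeferencing."""
        return replace(self, data=np.asarray(data, dtype=float))


def grids_aligned(*grids: Grid) -> bool:
    g0 = grids[0]
    return all(
        g.data.shape == g0.data.shape
        and np.isclose(g.cell_size, g0.cell_size)
        and np.isclose(g.x_origin, g0.x_origin)
        and np.isclose(g.y_origin, g0.y_origin)
        for g in grids[1:]
    )


def write_ascii_grid(grid: Grid, path) -> None:
    """Write a Grid as an ESRI ASCII grid (.asc)."""
    header = (
        f"ncols {grid.ncols}\n"
        f"nrows {grid.nrows}\n"
        f"xllcorner {grid.x_origin!r}\n"
        f"yllcorner {grid.y_origin!r}\n"
        f"cellsize {grid.cell_size!r}\n"
        f"NODATA_value {grid.nodata!r}\n"
    )
    data = np.where(np.isnan(grid.data), grid.nodata, grid.data)
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, data, fmt="%.8g")


def read_ascii_grid(path) -> Grid:
    """Read an ESRI ASCII grid written by :func:`write_ascii_grid`."""
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, value = fh.readline().split()
            header[key.lower()] = float(value)
        data = np.loadtxt(fh)
    data = np.atleast_2d(data)
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"grid shape mismatch in {path}")
    return Grid(
        data=data,
        cell_size=header["cellsize"],
        x_origin=header["xllcorner"],
        y_origin=header["yllcorner"],
        nodata=header.get("nodata_value", NODATA),
    )
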