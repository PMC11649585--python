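"""Gridded raster layers on a projected coordinate system.

A :class:`RasterLayer` is a rows x cols array with an affine placement
(lower-left corner, square cell size) and a nodata sentinel. Rasters are
stored row-major with the top-left cell at ``values[0, 0]``; indices are
0-based internally. On-disk format is the ESRI ASCII grid (plain text),
which round-trips the affine metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["RasterLayer", "read_ascii_grid"]

_HEADER_KEYS = ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value")


@dataclass
class RasterLayer:
    """A single-band raster on a projected grid.

    Parameters
    ----------
    values : ndarray, shape (rows, cols)
        Cell values, row 0 at the top. ``nan`` entries are treated as nodata.
    xll, yll : float
        Projected coordinates of the lower-left corner of the grid.
    cell_size : float
        Cell edge length in projected units; must be positive.
    nodata : float
        Sentinel written to disk for missing cells.
    crs : str
        Free-form tag for the projected CRS; inputs to one analysis must share it.
    name : str
        Layer name (e.g. the environmental variable it carries).
    """

    values: np.ndarray
    xll: float = 0.0
    yll: float = 0.0
    cell_size: float = 1.0
    nodata: float = -9999.0
    crs: str = ""
    name: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2-D")
        if self.cell_size <= 0:
            raise ValueError("cell size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of valid (non-nodata) cells."""
        return np.isfinite(self.values)

    def copy_with(self, values: np.ndarray, name: str | None = None) -> "RasterLayer":
        return replace(self, values=np.asarray(values, dtype=float),
                       name=self.name if name is None else name,
                       meta=dict(self.meta))

    # --- georeferencing -------------------------------------------------
    def xy_from_rowcol(self, row, col):
        """Projected coordinates of cell centers."""
        row = np.asarray(row)
        col = np.asarray(col)
        nrows = self.values.shape[0]
        x = self.xll + (col + 0.5) * self.cell_size
        y = self.yll + (nrows - 1 - row + 0.5) * self.cell_size
        return x, y

    def rowcol_from_xy(self, x, y):
        """Containing-cell lookup (no interpolation).

        A point on an interior cell boundary belongs to the cell with the
        larger column / smaller row index (right/up convention); points on
        the outer max edge are clamped into the grid.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        nrows, ncols = self.values.shape
        col = np.floor((x - self.xll) / self.cell_size).astype(int)
        row_from_bottom = np.floor((y - self.yll) / self.cell_size).astype(int)
        # clamp points sitting exactly on the outer max edge
        col = np.where((col == ncols) & np.isclose(x, self.xll + ncols * self.cell_size),
                       ncols - 1, col)
        row_from_bottom = np.where(
            (row_from_bottom == nrows)
            & np.isclose(y, self.yll + nrows * self.cell_size),
            nrows - 1, row_from_bottom)
        if np.any((col < 0) | (col >= ncols) | (row_from_bottom < 0)
                  | (row_from_bottom >= nrows)):
            raise ValueError("coordinates fall outside the raster extent")
        row = nrows - 1 - row_from_bottom
        return row, col

    def extract(self, x, y) -> np.ndarray:
        """Values at point coordinates by containing-cell lookup."""
        row, col = self.rowcol_from_xy(x, y)
        return self.values[row, col]

    # --- I/O -------------------------------------------------------------
    def write_ascii(self, path) -> None:
        """Write the layer as an ESRI ASCII grid."""
        path = Path(path)
        nrows, ncols = self.values.shape
        out = np.where(np.isfinite(self.values), self.values, self.nodata)
        header = (f"ncols {ncols}\nnrows {nrows}\n"
                  f"xllcorner {self.xll!r}\nyllcorner {self.yll!r}\n"
                  f"cellsize {self.cell_size!r}\nNODATA_value {self.nodata!r}\n")
        with open(path, "w") as fh:
            fh.write(header)
            np.savetxt(fh, out, fmt="%.10g")


def read_ascii_grid(path, name: str = "") -> RasterLayer:
    """Read an ESRI ASCII grid into a :class:`RasterLayer`."""
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        values = np.loadtxt(fh)
    missing = [k for k in _HEADER_KEYS if k not in header]
    if missing:
        raise ValueError(f"{path}: malformed ASCII grid header, missing {missing}")
    values = np.atleast_2d(values)
    nodata = header["nodata_value"]
    values = np.where(values == nodata, np.nan, values)
    return RasterLayer(values, xll=header["xllcorner"], yll=header["yllcorner"],
                       cell_size=header["cellsize"], nodata=nodata,
                       name=name or path.stem)
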