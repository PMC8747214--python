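"""Georeferenced single-band raster grid with GeoTIFF I/O.

Registration convention: ``values[i, j]`` covers the cell whose centre is
``(origin_x + (j + 0.5) * cell_size, origin_y + (i + 0.5) * cell_size)``;
row 0 is the southern edge (y increases with row index). Coordinates are
projected metres. Nodata is NaN in memory and recorded via the GDAL_NODATA
tag on disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile

_NODATA = -9999.0

# GeoTIFF tag ids
_MODEL_PIXEL_SCALE = 33550
_MODEL_TIEPOINT = 33922
_GDAL_NODATA = 42113


@dataclass
class RasterGrid:
    origin_x: float
    origin_y: float
    cell_size: float
    values: np.ndarray
    crs: str = "local-metres"

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        nrow, ncol = self.values.shape
        xs = self.origin_x + (np.arange(ncol) + 0.5) * self.cell_size
        ys = self.origin_y + (np.arange(nrow) + 0.5) * self.cell_size
        return xs, ys

    def index_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col indices of the cells containing points (x, y)."""
        col = np.floor((np.asarray(x) - self.origin_x) / self.cell_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin_y) / self.cell_size).astype(int)
        return row, col

    def sample(self, x, y):
        """Nearest-cell value at map coordinates; NaN outside the grid."""
        row, col = self.index_of(x, y)
        row = np.atleast_1d(row)
        col = np.atleast_1d(col)
        nrow, ncol = self.values.shape
        inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
        out = np.full(row.shape, np.nan)
        out[inside] = self.values[row[inside], col[inside]]
        return out if out.size > 1 else float(out[0])

    def aligned_with(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.cell_size - other.cell_size) <= tol
        )

    # -- GeoTIFF I/O ------------------------------------------------------

    def save(self, path) -> None:
        data = self.values.astype(np.float32)
        data = np.where(np.isnan(data), np.float32(_NODATA), data)
        # GeoTIFF rasters store row 0 at the top (north); flip on write.
        extratags = [
            (_MODEL_PIXEL_SCALE, "d", 3, (self.cell_size, self.cell_size, 0.0)),
            (
                _MODEL_TIEPOINT,
                "d",
                6,
                (0.0, 0.0, 0.0, self.origin_x,
                 self.origin_y + self.values.shape[0] * self.cell_size, 0.0),
            ),
            (_GDAL_NODATA, "s", 0, str(_NODATA)),
        ]
        tifffile.imwrite(path, data[::-1], extratags=extratags)

    @classmethod
    def load(cls, path, crs: str = "local-metres") -> "RasterGrid":
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray().astype(float)
            scale = page.tags[_MODEL_PIXEL_SCALE].value
            tie = page.tags[_MODEL_TIEPOINT].value
            nodata = float(page.tags[_GDAL_NODATA].value)
        cell = float(scale[0])
        origin_x = float(tie[3])
        top_y = float(tie[4])
        data = data[::-1]
        data[data == nodata] = np.nan
        origin_y = top_y - data.shape[0] * cell
        return cls(origin_x, origin_y, cell, data, crs=crs)
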