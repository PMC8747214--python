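"""Digital terrain, surface, and canopy-height models from classified clouds.

The DTM interpolates ground-classified returns with a Delaunay TIN evaluated
at cell centres (exact for planar ground). The DSM takes the highest return
per cell, with TIN infill of empty cells from first returns so the canopy
surface has no holes inside the data hull. CHM = DSM - DTM clipped at zero.
The default resolution is 0.25 m.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

from .pointcloud import GROUND, NOISE, PointCloud
from .raster import RasterGrid

DEFAULT_CELL = 0.25


class DegenerateInputError(ValueError):
    """Raised when a cloud cannot support the requested surface."""


def _grid_for(cloud: PointCloud, cell_size: float,
              extent: tuple[float, float, float, float] | None):
    if extent is None:
        xmin, xmax = float(cloud.x.min()), float(cloud.x.max())
        ymin, ymax = float(cloud.y.min()), float(cloud.y.max())
    else:
        xmin, ymin, xmax, ymax = extent
    ncol = max(1, int(np.ceil((xmax - xmin) / cell_size)))
    nrow = max(1, int(np.ceil((ymax - ymin) / cell_size)))
    return xmin, ymin, nrow, ncol


def build_dtm(
    cloud: PointCloud,
    cell_size: float = DEFAULT_CELL,
    extent: tuple[float, float, float, float] | None = None,
) -> RasterGrid:
    """Delaunay-TIN terrain model from ground-classified points."""
    gmask = cloud.classification == GROUND
    if gmask.sum() < 3:
        raise DegenerateInputError("need at least 3 ground points")
    gx, gy, gz = cloud.x[gmask], cloud.y[gmask], cloud.z[gmask]
    xmin, ymin, nrow, ncol = _grid_for(cloud, cell_size, extent)
    xs = xmin + (np.arange(ncol) + 0.5) * cell_size
    ys = ymin + (np.arange(nrow) + 0.5) * cell_size
    gxx, gyy = np.meshgrid(xs, ys)
    try:
        interp = LinearNDInterpolator(np.column_stack([gx, gy]), gz)
    except QhullError as exc:
        raise DegenerateInputError("ground points are collinear") from exc
    values = interp(gxx, gyy)
    return RasterGrid(xmin, ymin, cell_size, values, crs=cloud.crs)


def build_dsm(
    cloud: PointCloud,
    cell_size: float = DEFAULT_CELL,
    extent: tuple[float, float, float, float] | None = None,
) -> RasterGrid:
    """Highest-return surface model with TIN infill of empty cells."""
    mask = cloud.classification != NOISE
    if mask.sum() == 0:
        raise DegenerateInputError("empty cloud")
    x, y, z = cloud.x[mask], cloud.y[mask], cloud.z[mask]
    xmin, ymin, nrow, ncol = _grid_for(cloud, cell_size, extent)
    row = np.floor((y - ymin) / cell_size).astype(int)
    col = np.floor((x - xmin) / cell_size).astype(int)
    inside = (row >= 0) & (row < nrow) & (col >= 0) & (col < ncol)
    values = np.full((nrow, ncol), -np.inf)
    np.maximum.at(values, (row[inside], col[inside]), z[inside])
    empty = ~np.isfinite(values)

    if empty.any():
        first = mask.copy()
        first[mask] = cloud.return_number[mask] == 1
        fx, fy, fz = cloud.x[first], cloud.y[first], cloud.z[first]
        xs = xmin + (np.arange(ncol) + 0.5) * cell_size
        ys = ymin + (np.arange(nrow) + 0.5) * cell_size
        gxx, gyy = np.meshgrid(xs, ys)
        try:
            interp = LinearNDInterpolator(np.column_stack([fx, fy]), fz)
            fill = interp(gxx, gyy)
            values[empty] = fill[empty]
        except QhullError:
            pass
    values[~np.isfinite(values)] = np.nan
    return RasterGrid(xmin, ymin, cell_size, values, crs=cloud.crs)


def build_chm(dsm: RasterGrid, dtm: RasterGrid) -> RasterGrid:
    """Canopy height model: DSM - DTM, clipped at 0, nodata propagated."""
    if not dsm.aligned_with(dtm):
        raise ValueError("DSM and DTM grids are not aligned")
    chm = dsm.values - dtm.values
    chm = np.where(np.isnan(chm), np.nan, np.clip(chm, 0, None))
    return RasterGrid(dsm.origin_x, dsm.origin_y, dsm.cell_size, chm, crs=dsm.crs)
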