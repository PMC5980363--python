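"""Topographic predictors derived from a DEM: slope, aspect, ruggedness,
and distance-to-class surfaces (escape terrain, riparian corridors).

Slope and aspect use Horn's 8-neighbor finite differences. The terrain
ruggedness index (TRI) is the mean absolute elevation difference between a
cell and its eight neighbors in a 3x3 window. On geographic grids, degree
cell sizes are converted to ground meters at each row's latitude.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from rangeshift.raster import RasterGrid, RasterStack, RasterError, metric_cell_size


@dataclass(frozen=True)
class TerrainConfig:
    """Knobs for terrain-derived predictors.

    escape_slope_deg: slope at or above which a cell counts as escape
        terrain for wild sheep (degrees; 30 is the conventional cutoff).
    aspect_encoding: "northness" decomposes circular aspect into
        cos/sin components suited to regression models; "degrees" keeps the
        raw compass bearing.
    """

    escape_slope_deg: float = 30.0
    aspect_encoding: str = "northness"

    def __post_init__(self) -> None:
        if not 0.0 < self.escape_slope_deg < 90.0:
            raise ValueError("escape slope threshold must be in (0, 90) degrees")
        if self.aspect_encoding not in ("northness", "degrees"):
            raise ValueError(f"unknown aspect encoding {self.aspect_encoding!r}")


def _cell_sizes_m(dem: RasterGrid, cell_size_m: float | None) -> tuple[np.ndarray, np.ndarray]:
    nrow = dem.shape[0]
    if cell_size_m is not None:
        return np.full(nrow, float(cell_size_m)), np.full(nrow, float(cell_size_m))
    dx_m, dy_m = metric_cell_size(dem)
    return dx_m, np.full(nrow, dy_m)


def slope_aspect(dem: RasterGrid, cell_size_m: float | None = None) -> tuple[RasterGrid, RasterGrid]:
    """Horn slope (percent rise) and aspect (degrees clockwise from north).

    Aspect points downslope; flat cells get nodata aspect. Edge cells and
    cells whose 3x3 window touches nodata are nodata in both outputs.
    ``cell_size_m`` overrides the latitude-derived ground cell size (useful
    for grids built in ground units).
    """
    if dem.shape[0] < 3 or dem.shape[1] < 3:
        raise RasterError("DEM smaller than the 3x3 derivative window")
    z = dem.values
    dx_m, dy_m = _cell_sizes_m(dem, cell_size_m)

    # Horn kernel on the 3x3 window:
    #   a b c
    #   d e f        gx = ((c+2f+i) - (a+2d+g)) / (8 dx)
    #   g h i        gy = ((a+2b+c) - (g+2h+i)) / (8 dy)   (north positive)
    a = z[:-2, :-2]; b = z[:-2, 1:-1]; c = z[:-2, 2:]
    d = z[1:-1, :-2];                  f = z[1:-1, 2:]
    g = z[2:, :-2];  h = z[2:, 1:-1];  i = z[2:, 2:]
    gx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * dx_m[1:-1, None])
    gy = ((a + 2 * b + c) - (g + 2 * h + i)) / (8.0 * dy_m[1:-1, None])

    slope = np.full(dem.shape, dem.nodata)
    aspect = np.full(dem.shape, dem.nodata)
    slope[1:-1, 1:-1] = 100.0 * np.hypot(gx, gy)
    az = np.degrees(np.arctan2(-gx, -gy)) % 360.0
    flat = (gx == 0) & (gy == 0)
    aspect[1:-1, 1:-1] = np.where(flat, dem.nodata, az)

    window_bad = ndimage.maximum_filter(dem.mask.astype(np.uint8), size=3) > 0
    slope[window_bad] = dem.nodata
    aspect[window_bad] = dem.nodata
    return (
        dem.with_values(slope, name="slope"),
        dem.with_values(aspect, name="aspect"),
    )


def tri(dem: RasterGrid) -> RasterGrid:
    """Terrain ruggedness index: mean |neighbor - center| over the 8
    neighbors of each interior cell; edges and nodata-touching cells nodata."""
    z = dem.values
    out = np.full(dem.shape, dem.nodata)
    if dem.shape[0] >= 3 and dem.shape[1] >= 3:
        center = z[1:-1, 1:-1]
        acc = np.zeros_like(center)
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == 0 and dj == 0:
                    continue
                acc += np.abs(z[1 + di : z.shape[0] - 1 + di, 1 + dj : z.shape[1] - 1 + dj] - center)
        out[1:-1, 1:-1] = acc / 8.0
    window_bad = ndimage.maximum_filter(dem.mask.astype(np.uint8), size=3) > 0
    out[window_bad] = dem.nodata
    return dem.with_values(out, name="tri")


def aspect_components(aspect: RasterGrid) -> tuple[RasterGrid, RasterGrid]:
    """Northness (cos) and eastness (sin) of the aspect bearing.

    Flat cells (nodata aspect) are encoded 0 in both components: no facing
    direction rather than a missing observation.
    """
    rad = np.radians(aspect.values)
    north = np.where(aspect.mask, 0.0, np.cos(rad))
    east = np.where(aspect.mask, 0.0, np.sin(rad))
    return (
        aspect.with_values(north, name="northness"),
        aspect.with_values(east, name="eastness"),
    )


def distance_to_class(mask: np.ndarray, grid: RasterGrid, cell_size_m: float | None = None) -> RasterGrid:
    """Euclidean distance in meters from each cell center to the nearest
    cell of the class; zero inside the class.

    On geographic grids the east-west cell size is taken at the grid's mean
    latitude (the north-south size is latitude-independent), so the
    transform is separable and exact under scipy's EDT.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != grid.shape:
        raise RasterError("mask shape does not match grid")
    if not mask.any():
        raise RasterError("empty class mask: distance surface undefined")
    if cell_size_m is None:
        dx_rows, dy_m = metric_cell_size(grid)
        dx_m = float(np.mean(dx_rows))
    else:
        dx_m = dy_m = float(cell_size_m)
    dist = ndimage.distance_transform_edt(~mask, sampling=(dy_m, dx_m))
    return grid.with_values(dist, name="distance")


def escape_terrain_distance(
    dem: RasterGrid, config: TerrainConfig = TerrainConfig(), cell_size_m: float | None = None
) -> RasterGrid:
    """Distance (m) to escape terrain: cells with slope >= the threshold."""
    slope_pct, _ = slope_aspect(dem, cell_size_m=cell_size_m)
    thresh_pct = 100.0 * np.tan(np.radians(config.escape_slope_deg))
    steep = slope_pct.valid & (slope_pct.values >= thresh_pct)
    if not steep.any():
        raise RasterError(
            f"no escape terrain: no cell reaches slope {config.escape_slope_deg:.0f} degrees"
        )
    out = distance_to_class(steep, dem, cell_size_m=cell_size_m)
    out.name = "dist_escape"
    return out


def terrain_stack(
    dem: RasterGrid,
    riparian_mask: np.ndarray | None = None,
    config: TerrainConfig = TerrainConfig(),
    cell_size_m: float | None = None,
) -> RasterStack:
    """All terrain predictors on the DEM grid.

    Layers: tri, slope, aspect (as northness/eastness when so configured),
    dist_escape, and dist_riparian when a riparian mask is given.
    """
    slope_g, aspect_g = slope_aspect(dem, cell_size_m=cell_size_m)
    layers = [tri(dem), slope_g]
    if config.aspect_encoding == "northness":
        layers.extend(aspect_components(aspect_g))
    else:
        layers.append(aspect_g)
    layers.append(escape_terrain_distance(dem, config, cell_size_m=cell_size_m))
    if riparian_mask is not None:
        rip = distance_to_class(riparian_mask, dem, cell_size_m=cell_size_m)
        rip.name = "dist_riparian"
        layers.append(rip)
    return RasterStack(layers)
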