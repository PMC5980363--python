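"""Georeferenced grid container and GeoTIFF I/O.

Grids are geographic (lon/lat), north-up, cell-center registered for value
lookups. Cell areas use the spherical cosine-of-latitude formula with an
Earth circumference of 40,030.2 km (111.195 km per degree).

GeoTIFF files are read and written through :mod:`tifffile` using the
standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, GeoKeyDirectory) and
the GDAL nodata tag, so outputs open in GDAL/QGIS and single-band GDAL
products are accepted as inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Literal, Mapping

import numpy as np
from scipy import ndimage

KM_PER_DEGREE = 111.195

# GeoTIFF / GDAL tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113

DEFAULT_NODATA = -9999.0


class RasterError(ValueError):
    """Raised for malformed rasters or incompatible grid operations."""


@dataclass(frozen=True)
class GridTransform:
    """North-up affine transform: origin at the north-west corner.

    ``west``/``north`` are the outer edges of the top-left cell; ``dx`` and
    ``dy`` are positive cell sizes in degrees.
    """

    west: float
    north: float
    dx: float
    dy: float

    def __post_init__(self) -> None:
        if self.dx <= 0 or self.dy <= 0:
            raise RasterError(f"cell size must be positive, got dx={self.dx}, dy={self.dy}")

    def cell_center(self, row: np.ndarray | int, col: np.ndarray | int) -> tuple[np.ndarray, np.ndarray]:
        lon = self.west + (np.asarray(col) + 0.5) * self.dx
        lat = self.north - (np.asarray(row) + 0.5) * self.dy
        return lon, lat

    def cell_index(self, lon: np.ndarray, lat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Cell containing each point; half-open [west, east) x (south, north]."""
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        col = np.floor((lon - self.west) / self.dx).astype(int)
        off = (self.north - lat) / self.dy
        row = np.floor(off).astype(int)
        # the northern outer edge belongs to row 0
        row = np.where(off == 0.0, 0, row)
        return row, col


@dataclass
class RasterGrid:
    """One rectangular layer of cell values with nodata handling."""

    values: np.ndarray
    transform: GridTransform
    crs: str = "EPSG:4326"
    nodata: float = DEFAULT_NODATA
    name: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise RasterError(f"expected a 2-D grid, got shape {self.values.shape}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def mask(self) -> np.ndarray:
        """Boolean mask of nodata cells (sentinel or NaN)."""
        return np.isnan(self.values) | (self.values == self.nodata)

    @property
    def valid(self) -> np.ndarray:
        return ~self.mask

    def masked(self) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.values, mask=self.mask)

    def with_values(self, values: np.ndarray, name: str | None = None) -> "RasterGrid":
        """New grid on the same georeferencing carrying ``values``."""
        return RasterGrid(
            values=np.asarray(values, dtype=np.float64),
            transform=self.transform,
            crs=self.crs,
            nodata=self.nodata,
            name=self.name if name is None else name,
        )

    def same_grid(self, other: "RasterGrid") -> bool:
        return self.shape == other.shape and self.transform == other.transform and self.crs == other.crs

    def lat_of_row(self, row: np.ndarray | int) -> np.ndarray:
        return self.transform.cell_center(row, 0)[1]

    def contains(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        t = self.transform
        nrow, ncol = self.shape
        lon = np.asarray(lon, dtype=float)
        lat = np.asarray(lat, dtype=float)
        east = t.west + ncol * t.dx
        south = t.north - nrow * t.dy
        return (lon >= t.west) & (lon < east) & (lat > south) & (lat <= t.north)

    def value_at(self, lon: np.ndarray, lat: np.ndarray) -> np.ndarray:
        """Cell-value lookup (no interpolation); points outside raise."""
        if not np.all(self.contains(lon, lat)):
            raise RasterError("point(s) outside grid extent")
        row, col = self.transform.cell_index(lon, lat)
        return self.values[row, col]


def pixel_area_km2(grid: RasterGrid, row: int | np.ndarray) -> np.ndarray:
    """Area of one cell in ``row``, in km².

    area = (cell_deg · 111.195 km)² · cos(latitude of the row center).
    """
    lat = np.asarray(grid.lat_of_row(row), dtype=float)
    if np.any(np.abs(lat) >= 90.0):
        raise RasterError("row-center latitude at or beyond a pole")
    t = grid.transform
    return (t.dx * KM_PER_DEGREE) * (t.dy * KM_PER_DEGREE) * np.cos(np.radians(lat))


def cell_area_grid_km2(grid: RasterGrid) -> np.ndarray:
    """Per-cell areas (km²) broadcast to the grid shape."""
    rows = np.arange(grid.shape[0])
    return np.broadcast_to(pixel_area_km2(grid, rows)[:, None], grid.shape).copy()


def metric_cell_size(grid: RasterGrid) -> tuple[np.ndarray, float]:
    """(per-row east-west cell size, north-south cell size) in meters."""
    lat = grid.lat_of_row(np.arange(grid.shape[0]))
    dx_m = grid.transform.dx * KM_PER_DEGREE * 1000.0 * np.cos(np.radians(lat))
    dy_m = grid.transform.dy * KM_PER_DEGREE * 1000.0
    return dx_m, dy_m


class RasterStack:
    """Ordered, name-addressable collection of co-registered layers."""

    def __init__(self, layers: Iterable[RasterGrid]):
        layers = list(layers)
        if not layers:
            raise RasterError("empty stack")
        names = [g.name for g in layers]
        if len(set(names)) != len(names):
            raise RasterError(f"duplicate layer names: {names}")
        ref = layers[0]
        for g in layers[1:]:
            if not g.same_grid(ref):
                raise RasterError(f"layer {g.name!r} does not share the stack grid")
        self._layers: dict[str, RasterGrid] = {g.name: g for g in layers}

    @property
    def names(self) -> list[str]:
        return list(self._layers)

    @property
    def grid(self) -> RasterGrid:
        return next(iter(self._layers.values()))

    def __getitem__(self, name: str) -> RasterGrid:
        try:
            return self._layers[name]
        except KeyError:
            raise KeyError(f"no layer {name!r}; have {self.names}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._layers

    def __iter__(self):
        return iter(self._layers.values())

    def __len__(self) -> int:
        return len(self._layers)

    def subset(self, names: Iterable[str]) -> "RasterStack":
        return RasterStack([self[n] for n in names])

    def add(self, *grids: RasterGrid) -> "RasterStack":
        return RasterStack(list(self._layers.values()) + list(grids))

    def replace(self, *grids: RasterGrid) -> "RasterStack":
        """New stack with layers of matching names swapped out."""
        new = dict(self._layers)
        for g in grids:
            if g.name not in new:
                raise KeyError(f"no layer {g.name!r} to replace")
            new[g.name] = g
        return RasterStack(new.values())

    def combined_mask(self, names: Iterable[str] | None = None) -> np.ndarray:
        names = self.names if names is None else list(names)
        mask = np.zeros(self.grid.shape, dtype=bool)
        for n in names:
            mask |= self[n].mask
        return mask


ResampleMethod = Literal["continuous", "categorical"]


def resample_to(layer: RasterGrid, template: RasterGrid, method: ResampleMethod = "continuous") -> RasterGrid:
    """Resample ``layer`` onto ``template``'s grid.

    Continuous layers are sampled bilinearly at the template cell centers,
    categorical layers by nearest neighbor. Any output cell whose
    interpolation footprint touches nodata (or falls outside the source)
    becomes nodata.
    """
    if method not in ("continuous", "categorical"):
        raise RasterError(f"unknown resample method {method!r}")
    if layer.same_grid(template):
        return layer
    ts, ls = template.transform, layer.transform
    rows = np.arange(template.shape[0])
    cols = np.arange(template.shape[1])
    lon, _ = ts.cell_center(0, cols)
    _, lat = ts.cell_center(rows, 0)
    # fractional index into the source layer, integer = cell center
    fx = (lon - (ls.west + ls.dx / 2)) / ls.dx
    fy = ((ls.north - ls.dy / 2) - lat) / ls.dy
    eps = 1e-9
    in_src = (
        (fx >= -0.5 - eps)[None, :]
        & (fx <= layer.shape[1] - 0.5 + eps)[None, :]
        & (fy >= -0.5 - eps)[:, None]
        & (fy <= layer.shape[0] - 0.5 + eps)[:, None]
    )
    if not in_src.any():
        raise RasterError(f"layer {layer.name!r} does not overlap template extent")
    fyy, fxx = np.meshgrid(fy, fx, indexing="ij")
    coords = np.vstack([fyy.ravel(), fxx.ravel()])
    order = 1 if method == "continuous" else 0
    src = np.where(layer.mask, 0.0, layer.values)
    out = ndimage.map_coordinates(src, coords, order=order, mode="nearest").reshape(template.shape)
    touched = ndimage.map_coordinates(layer.mask.astype(float), coords, order=order, mode="nearest")
    bad = (touched.reshape(template.shape) > 0) | ~in_src
    out[bad] = template.nodata
    return RasterGrid(out, ts, crs=template.crs, nodata=template.nodata, name=layer.name)


def align_stack(
    layers: Iterable[RasterGrid],
    template: RasterGrid,
    method_per_layer: Mapping[str, ResampleMethod] | None = None,
) -> RasterStack:
    """Co-register layers onto ``template``; continuous unless tagged otherwise."""
    method_per_layer = dict(method_per_layer or {})
    out = []
    for layer in layers:
        method = method_per_layer.get(layer.name, "continuous")
        out.append(resample_to(layer, template, method))
    return RasterStack(out)


def write_raster(path: str | Path, grid: RasterGrid) -> Path:
    """Write a single-band float64 GeoTIFF with georeferencing and nodata tags."""
    import tifffile

    path = Path(path)
    t = grid.transform
    scale = (float(t.dx), float(t.dy), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(t.west), float(t.north), 0.0)
    epsg = int(grid.crs.split(":")[1]) if grid.crs.upper().startswith("EPSG:") else 4326
    geokeys = (
        1, 1, 0, 3,
        1024, 0, 1, 2,      # model type: geographic
        1025, 0, 1, 1,      # raster type: pixel-is-area
        2048, 0, 1, epsg,   # geographic CRS
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, 12, 3, scale, True),
        (_TAG_MODEL_TIEPOINT, 12, 6, tiepoint, True),
        (_TAG_GEO_KEY_DIRECTORY, 3, len(geokeys), geokeys, True),
        (_TAG_GDAL_NODATA, 2, None, repr(float(grid.nodata)), True),
    ]
    tifffile.imwrite(path, grid.values.astype(np.float64), extratags=extratags)
    return path


def read_raster(path: str | Path, name: str | None = None) -> RasterGrid:
    """Read a single-band georeferenced GeoTIFF.

    The layer name defaults to the filename stem. Multi-band files and files
    without GeoTIFF georeferencing are rejected.
    """
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if len(tf.pages) > 1 or page.samplesperpixel != 1:
            raise RasterError(f"{path}: expected a single-band raster")
        values = page.asarray().astype(np.float64)
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise RasterError(f"{path}: missing GeoTIFF georeferencing tags")
        dx, dy, _ = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        west = tie[3] - tie[0] * dx
        north = tie[4] + tie[1] * dy
        nodata = DEFAULT_NODATA
        if _TAG_GDAL_NODATA in tags:
            nodata = float(tags[_TAG_GDAL_NODATA].value)
        epsg = 4326
        if _TAG_GEO_KEY_DIRECTORY in tags:
            keys = tags[_TAG_GEO_KEY_DIRECTORY].value
            for i in range(4, len(keys), 4):
                if keys[i] == 2048:
                    epsg = keys[i + 3]
    if values.ndim == 3:
        raise RasterError(f"{path}: expected a single-band raster")
    return RasterGrid(
        values,
        GridTransform(west=west, north=north, dx=dx, dy=dy),
        crs=f"EPSG:{epsg}",
        nodata=nodata,
        name=name or path.stem,
    )
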