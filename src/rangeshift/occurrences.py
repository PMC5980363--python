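"""Occurrence cleaning, train/test splitting, and background sampling.

Presence records are thinned to one per raster cell to blunt spatial
sampling bias, split 70/30 into training and testing sets, and paired with
background (pseudo-absence) points drawn uniformly inside a 95% minimum
convex polygon (MCP) of the presences.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import MultiPoint, Polygon

from rangeshift.raster import RasterGrid, RasterError

log = logging.getLogger(__name__)


@dataclass
class OccurrenceSet:
    """Presence points with optional train/test roles.

    ``points`` columns: lon, lat, and (after splitting) role in
    {"train", "test"}. ``provenance`` records whether the set is raw or
    thinned to one point per cell.
    """

    points: pd.DataFrame
    provenance: str = "raw"

    def __post_init__(self) -> None:
        missing = {"lon", "lat"} - set(self.points.columns)
        if missing:
            raise ValueError(f"occurrence table missing columns {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lonlat(self) -> np.ndarray:
        return self.points[["lon", "lat"]].to_numpy(dtype=float)

    def subset(self, role: str) -> "OccurrenceSet":
        sel = self.points[self.points["role"] == role].reset_index(drop=True)
        return OccurrenceSet(sel, provenance=self.provenance)

    @classmethod
    def from_csv(cls, path: str | Path) -> "OccurrenceSet":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        self.points.to_csv(path, index=False)


@dataclass
class BackgroundSet:
    """Background (pseudo-absence) points and the MCP that generated them."""

    points: pd.DataFrame
    polygon: Polygon
    retain: float

    def __len__(self) -> int:
        return len(self.points)

    @property
    def lonlat(self) -> np.ndarray:
        return self.points[["lon", "lat"]].to_numpy(dtype=float)


def thin_per_pixel(occ: OccurrenceSet, grid: RasterGrid) -> OccurrenceSet:
    """Keep one occurrence per occupied grid cell (the first in input order)."""
    if len(occ) == 0:
        raise ValueError("empty occurrence set")
    lon = occ.points["lon"].to_numpy(dtype=float)
    lat = occ.points["lat"].to_numpy(dtype=float)
    inside = grid.contains(lon, lat)
    if not inside.all():
        raise RasterError(f"{int((~inside).sum())} occurrence(s) outside the grid extent")
    row, col = grid.transform.cell_index(lon, lat)
    cell = row * grid.shape[1] + col
    _, first_idx = np.unique(cell, return_index=True)
    kept = occ.points.iloc[np.sort(first_idx)].reset_index(drop=True)
    log.info("thinned %d occurrences to %d (one per cell)", len(occ), len(kept))
    return OccurrenceSet(kept, provenance="thinned")


def split_train_test(occ: OccurrenceSet, fraction: float = 0.70, seed: int = 0) -> OccurrenceSet:
    """Random 70/30 train/test partition; train count = floor(fraction * n)."""
    n = len(occ)
    if n < 10:
        raise ValueError(f"need at least 10 points to split, got {n}")
    n_train = math.floor(fraction * n)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    role = np.empty(n, dtype=object)
    role[order[:n_train]] = "train"
    role[order[n_train:]] = "test"
    out = occ.points.copy()
    out["role"] = role
    return OccurrenceSet(out, provenance=occ.provenance)


def mcp_polygon(occ: OccurrenceSet, retain: float = 0.95) -> Polygon:
    """Convex hull of the presences after dropping the (1-retain) fraction
    farthest from the presence centroid; ceil(retain*n) points kept."""
    pts = occ.lonlat
    if len(pts) < 5:
        raise ValueError("need at least 5 presences for an MCP")
    centroid = pts.mean(axis=0)
    dist = np.hypot(pts[:, 0] - centroid[0], pts[:, 1] - centroid[1])
    n_keep = math.ceil(retain * len(pts))
    keep = np.argsort(dist, kind="stable")[:n_keep]
    hull = MultiPoint([tuple(p) for p in pts[keep]]).convex_hull
    if not isinstance(hull, Polygon) or hull.area == 0.0:
        raise ValueError("degenerate (collinear) presence hull")
    return hull


def mcp_background(
    occ: OccurrenceSet,
    grid: RasterGrid,
    n_background: int = 10_000,
    retain: float = 0.95,
    seed: int = 0,
    max_tries: int = 1000,
) -> BackgroundSet:
    """Uniform background points inside the retained-presence MCP.

    Rejection-samples the hull's bounding box, keeping draws that fall inside
    the hull and on a valid (non-nodata) cell of ``grid``.
    """
    hull = mcp_polygon(occ, retain=retain)
    minx, miny, maxx, maxy = hull.bounds
    rng = np.random.default_rng(seed)
    kept_lon: list[np.ndarray] = []
    kept_lat: list[np.ndarray] = []
    n_kept = 0
    for _ in range(max_tries):
        m = max(4 * (n_background - n_kept), 1024)
        lon = rng.uniform(minx, maxx, m)
        lat = rng.uniform(miny, maxy, m)
        in_hull = shapely.contains_xy(hull, lon, lat)
        ok = in_hull & grid.contains(lon, lat)
        if ok.any():
            row, col = grid.transform.cell_index(lon[ok], lat[ok])
            ok_idx = np.flatnonzero(ok)[grid.valid[row, col]]
            kept_lon.append(lon[ok_idx])
            kept_lat.append(lat[ok_idx])
            n_kept += len(ok_idx)
        if n_kept >= n_background:
            break
    else:
        raise RuntimeError("background sampling failed: hull covers no valid cells")
    lon = np.concatenate(kept_lon)[:n_background]
    lat = np.concatenate(kept_lat)[:n_background]
    points = pd.DataFrame({"lon": lon, "lat": lat})
    return BackgroundSet(points=points, polygon=hull, retain=retain)
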