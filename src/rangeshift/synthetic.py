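"""Synthetic mountainous landscape with a virtual species of known truth.

The generator emulates a high-mountain study system: a DEM spanning
3,300-7,300 m (higher toward the north), bioclim-style climate layers tied
to elevation through a -6.5 degC/km lapse rate plus spatially correlated
noise, land-cover fractions, a riparian network, and pseudo-GCM future
deltas (additive warming, multiplicative precipitation change, seeded
inter-GCM noise). The virtual species is temperature-limited with a cold
Gaussian optimum, prefers rugged terrain, and weakly tracks riparian
corridors; presence points are drawn with probability proportional to the
true suitability, which makes the truth recoverable by the downstream
models.

All randomness flows through explicit seeds; a configuration plus a seed
reproduces the landscape bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from rangeshift.occurrences import OccurrenceSet
from rangeshift.raster import GridTransform, RasterGrid, RasterStack, write_raster
from rangeshift.terrain import TerrainConfig, terrain_stack

#: layers treated as absolute temperatures (degC) under scenario deltas
TEMPERATURE_LAYERS = ("bio1", "bio9")
#: layers treated as precipitation amounts (mm) under scenario deltas
PRECIPITATION_LAYERS = ("bio18",)


@dataclass(frozen=True)
class LandscapeConfig:
    """Study-landscape envelope.

    The defaults describe a 300x300-cell window at 30 arc-sec (~2.5 deg on
    a side near 38 N) with elevations 3,300-7,300 m, matching the scale of
    a high-Pamir study area.
    """

    shape: tuple[int, int] = (300, 300)
    cell_deg: float = 1.0 / 120.0          # 30 arc-sec
    west: float = 72.5
    north: float = 39.5
    elevation_range_m: tuple[float, float] = (3300.0, 7300.0)
    correlation_length_cells: float = 15.0
    north_gradient: float = 3.0            # latitudinal trend, in smooth-field SDs
    roughness_amplitude: float = 0.7       # fine-scale relief, in smooth-field SDs
    roughness_length_cells: float = 1.0    # correlation length of the fine relief
    lapse_rate_c_per_km: float = 6.5
    temperature_sea_level_c: float = 20.0
    temperature_noise_c: float = 0.6
    riparian_quantile: float = 0.97
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.elevation_range_m
        if not lo < hi:
            raise ValueError("elevation range must be ordered (low, high)")
        if self.correlation_length_cells <= 0:
            raise ValueError("correlation length must be positive")

    @property
    def transform(self) -> GridTransform:
        return GridTransform(west=self.west, north=self.north, dx=self.cell_deg, dy=self.cell_deg)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], corr: float) -> np.ndarray:
    """Correlated random field: Gaussian-smoothed white noise, exactly
    zero-mean and unit-variance."""
    f = gaussian_filter(rng.standard_normal(shape), sigma=corr, mode="reflect")
    f -= f.mean()
    sd = f.std()
    return f / sd if sd > 0 else f


def generate_dem(config: LandscapeConfig) -> RasterGrid:
    """Smooth correlated random surface with a northward rise, rescaled so
    its minimum and maximum equal the configured elevation endpoints."""
    rng = np.random.default_rng(config.seed)
    broad = _smooth_field(rng, config.shape, config.correlation_length_cells)
    fine = _smooth_field(rng, config.shape, config.roughness_length_cells)
    nrow = config.shape[0]
    northness = (nrow - 1 - np.arange(nrow))[:, None] / max(nrow - 1, 1)  # 1 at north edge
    relief = broad + config.roughness_amplitude * fine + config.north_gradient * (northness - 0.5)
    lo, hi = config.elevation_range_m
    rmin, rmax = relief.min(), relief.max()
    elev = lo + (relief - rmin) * (hi - lo) / (rmax - rmin)
    return RasterGrid(elev, config.transform, nodata=-9999.0, name="dem")


def generate_climate(dem: RasterGrid, config: LandscapeConfig) -> RasterStack:
    """Bioclim-style climate suite on the DEM grid.

    Annual mean temperature (bio1) follows the configured lapse rate off the
    DEM plus correlated noise; the driest-quarter temperature (bio9) sits a
    winter offset below it. Precipitation of the warmest quarter (bio18) is
    a positive, spatially structured field with a mild orographic rise.
    Index-like layers (bio2 diurnal range, bio3 isothermality, bio4
    temperature seasonality, bio15 precipitation seasonality) are correlated
    noise around realistic arid-highland levels.
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    corr = config.correlation_length_cells
    shape = dem.shape
    elev = dem.values

    def noise(scale: float) -> np.ndarray:
        return scale * _smooth_field(rng, shape, corr)

    bio1 = (
        config.temperature_sea_level_c
        - config.lapse_rate_c_per_km * elev / 1000.0
        + noise(config.temperature_noise_c)
    )
    bio2 = 14.0 + noise(1.2)
    bio3 = 35.0 + noise(2.5)
    bio4 = 950.0 + noise(45.0)
    bio9 = bio1 - 10.0 + noise(0.8)
    bio15 = 80.0 + noise(8.0)
    bio18 = np.clip(55.0 + 25.0 * _smooth_field(rng, shape, corr) + 0.004 * (elev - elev.mean()), 1.0, None)

    layers = {
        "bio1": bio1, "bio2": bio2, "bio3": bio3, "bio4": bio4,
        "bio9": bio9, "bio15": bio15, "bio18": bio18,
    }
    return RasterStack(
        [dem.with_values(v, name=k) for k, v in layers.items()]
    )


def generate_landcover(dem: RasterGrid, config: LandscapeConfig) -> RasterStack:
    """Vegetation-cover and sparse-cover fractions: forage-bearing cover
    declines with elevation, sparse cover mirrors it."""
    rng = np.random.default_rng(config.seed + 2_000_003)
    corr = config.correlation_length_cells
    elev = dem.values
    veg = 1.0 / (1.0 + np.exp((elev - 4800.0) / 600.0)) + 0.08 * _smooth_field(rng, dem.shape, corr)
    veg = np.clip(veg, 0.0, 1.0)
    sparse = np.clip(1.0 - veg + 0.08 * _smooth_field(rng, dem.shape, corr), 0.0, 1.0)
    return RasterStack(
        [dem.with_values(veg, name="veg_cover"), dem.with_values(sparse, name="sparse_cover")]
    )


def generate_riparian_mask(dem: RasterGrid, config: LandscapeConfig) -> np.ndarray:
    """Riparian network as the upper tail of a smoothed random field —
    a sinuous corridor system covering (1 - quantile) of the landscape."""
    rng = np.random.default_rng(config.seed + 3_000_003)
    f = _smooth_field(rng, dem.shape, config.correlation_length_cells / 3.0)
    return f >= np.quantile(f, config.riparian_quantile)


@dataclass(frozen=True)
class VirtualSpecies:
    """Known truth: suitability in [0,1] as a product of responses.

    A Gaussian thermal niche on the annual mean temperature (the planted
    primary driver), a saturating preference for rugged terrain, and an
    exponential decay with riparian distance.
    """

    temp_layer: str = "bio1"
    temp_optimum_c: float = -9.0
    temp_width_c: float = 1.5
    ruggedness_layer: str = "tri"
    ruggedness_scale_m: float = 30.0
    riparian_layer: str = "dist_riparian"
    riparian_decay_m: float = 60_000.0

    @property
    def drivers(self) -> tuple[str, ...]:
        return (self.temp_layer, self.ruggedness_layer, self.riparian_layer)

    def suitability(self, stack: RasterStack) -> RasterGrid:
        missing = [d for d in self.drivers if d not in stack]
        if missing:
            raise KeyError(f"stack lacks driver layer(s) {missing}")
        t = stack[self.temp_layer].values
        r = stack[self.ruggedness_layer].values
        d = stack[self.riparian_layer].values
        s = (
            np.exp(-0.5 * ((t - self.temp_optimum_c) / self.temp_width_c) ** 2)
            * (1.0 - np.exp(-np.maximum(r, 0.0) / self.ruggedness_scale_m))
            * np.exp(-np.maximum(d, 0.0) / self.riparian_decay_m)
        )
        grid = stack.grid
        bad = stack.combined_mask(list(self.drivers))
        out = np.where(bad, grid.nodata, s)
        return grid.with_values(out, name="true_suitability")


def sample_occurrences(
    truth: VirtualSpecies, stack: RasterStack, n: int = 976, seed: int = 0
) -> OccurrenceSet:
    """Presence points drawn with probability proportional to the true
    suitability, uniformly jittered within their cells."""
    suit = truth.suitability(stack)
    weights = np.where(suit.valid, suit.values, 0.0).ravel()
    total = weights.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample presences")
    rng = np.random.default_rng(seed)
    cells = rng.choice(weights.size, size=n, replace=True, p=weights / total)
    row, col = np.unravel_index(cells, suit.shape)
    t = suit.transform
    lon = t.west + (col + rng.uniform(0, 1, n)) * t.dx
    lat = t.north - (row + rng.uniform(0, 1, n)) * t.dy
    return OccurrenceSet(pd.DataFrame({"lon": lon, "lat": lat}), provenance="raw")


@dataclass(frozen=True)
class ScenarioDelta:
    """One pseudo-GCM x RCP x horizon future.

    Additive temperature offsets (degC) per temperature layer,
    multiplicative precipitation factors per precipitation layer, and a
    seeded spatially correlated inter-GCM noise field added to temperature
    layers.
    """

    scenario: str                           # e.g. "rcp45_2050"
    gcm: str                                # e.g. "pgcm-a"
    temp_offsets: Mapping[str, float] = field(default_factory=dict)
    precip_factors: Mapping[str, float] = field(default_factory=dict)
    noise_scale_c: float = 0.0
    seed: int = 0

    @property
    def name(self) -> str:
        return f"{self.scenario}_{self.gcm}"


def apply_scenario(stack: RasterStack, delta: ScenarioDelta, config: LandscapeConfig | None = None) -> RasterStack:
    """Shift climate layers per the delta; non-climate layers untouched."""
    for name in list(delta.temp_offsets) + list(delta.precip_factors):
        if name not in stack:
            raise KeyError(f"delta names layer {name!r} absent from stack")
    corr = (config.correlation_length_cells if config else 15.0)
    rng = np.random.default_rng(delta.seed)
    noise = (
        delta.noise_scale_c * _smooth_field(rng, stack.grid.shape, corr)
        if delta.noise_scale_c > 0
        else 0.0
    )
    new_layers = []
    for g in stack:
        if g.name in delta.temp_offsets:
            vals = np.where(g.valid, g.values + delta.temp_offsets[g.name] + noise, g.values)
            new_layers.append(g.with_values(vals))
        elif g.name in delta.precip_factors:
            vals = np.where(g.valid, np.clip(g.values * delta.precip_factors[g.name], 0.0, None), g.values)
            new_layers.append(g.with_values(vals))
        else:
            new_layers.append(g)
    return RasterStack(new_layers)


#: mean warming (degC) by RCP and horizon, highland-amplified CMIP5-era levels
RCP_WARMING = {
    ("rcp45", 2050): 1.6,
    ("rcp45", 2070): 2.2,
    ("rcp85", 2050): 2.5,
    ("rcp85", 2070): 4.0,
}
#: warm-season precipitation drying factor by RCP and horizon
RCP_PRECIP_FACTOR = {
    ("rcp45", 2050): 0.96,
    ("rcp45", 2070): 0.94,
    ("rcp85", 2050): 0.92,
    ("rcp85", 2070): 0.88,
}
GCM_NAMES = ("pgcm-a", "pgcm-b", "pgcm-c", "pgcm-d")


def default_scenarios(
    seed: int = 0, noise_scale_c: float = 0.3
) -> dict[str, dict[str, ScenarioDelta]]:
    """The 4 pseudo-GCM x 2 RCP x 2 horizon scenario grid.

    Returns {scenario id: {gcm name: delta}}; all four GCMs of a scenario
    share the mean offsets and differ only by their seeded noise field.
    """
    out: dict[str, dict[str, ScenarioDelta]] = {}
    for (rcp, year), warm in RCP_WARMING.items():
        scen = f"{rcp}_{year}"
        out[scen] = {}
        for i, gcm in enumerate(GCM_NAMES):
            out[scen][gcm] = ScenarioDelta(
                scenario=scen,
                gcm=gcm,
                temp_offsets={name: warm for name in TEMPERATURE_LAYERS},
                precip_factors={name: RCP_PRECIP_FACTOR[(rcp, year)] for name in PRECIPITATION_LAYERS},
                noise_scale_c=noise_scale_c,
                seed=seed + 7_000_003 + 101 * i + 10_007 * len(out),
            )
    return out


@dataclass
class Landscape:
    """One generated study system: rasters, truth and raw occurrences."""

    config: LandscapeConfig
    dem: RasterGrid
    climate: RasterStack
    predictors: RasterStack       # climate + terrain + land cover
    riparian_mask: np.ndarray
    truth: VirtualSpecies
    occurrences: OccurrenceSet


def generate_landscape(
    config: LandscapeConfig = LandscapeConfig(),
    truth: VirtualSpecies = VirtualSpecies(),
    n_occurrences: int = 976,
    terrain_config: TerrainConfig = TerrainConfig(),
) -> Landscape:
    """Full study system from one config: DEM, climate, terrain and cover
    predictors, riparian network, and suitability-weighted presences."""
    dem = generate_dem(config)
    climate = generate_climate(dem, config)
    riparian = generate_riparian_mask(dem, config)
    terr = terrain_stack(dem, riparian_mask=riparian, config=terrain_config)
    cover = generate_landcover(dem, config)
    predictors = RasterStack(list(climate) + list(terr) + list(cover))
    occ = sample_occurrences(truth, predictors, n=n_occurrences, seed=config.seed + 4_000_003)
    return Landscape(
        config=config,
        dem=dem,
        climate=climate,
        predictors=predictors,
        riparian_mask=riparian,
        truth=truth,
        occurrences=occ,
    )


def write_fixture_set(landscape: Landscape, outdir: str | Path) -> Path:
    """Write the landscape as GeoTIFFs plus an occurrences CSV so the
    pipeline can be exercised from files alone."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_raster(outdir / "dem.tif", landscape.dem)
    for g in landscape.predictors:
        write_raster(outdir / f"{g.name}.tif", g)
    landscape.occurrences.to_csv(outdir / "occurrences.csv")
    return outdir
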