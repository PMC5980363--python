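"""Present-vs-future change classification and area accounting.

Each cell's (present, future) suitability bit pair maps to one of four
categories — stable (1,1), gain (0,1), loss (1,0), unsuitable (0,0) — and
per-category areas are summed with latitude-aware cell areas. Percentages
are expressed relative to the present suitable area (the study convention),
which is why gains can exceed 100%.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from rangeshift.ensemble import BinaryMap
from rangeshift.raster import RasterGrid, RasterError, cell_area_grid_km2

#: change-map cell coding
UNSUITABLE, STABLE, GAIN, LOSS, NODATA_CODE = 0, 1, 2, 3, 255

CATEGORIES = ("stable", "gain", "loss", "unsuitable")


@dataclass
class ChangeMap:
    grid: RasterGrid          # coded 0/1/2/3, nodata 255
    present_id: str
    scenario: str


@dataclass
class ChangeSummary:
    """Per-scenario stable/gain/loss accounting in km² and percent of the
    present suitable area."""

    scenario: str
    areas_km2: dict[str, float]
    present_total_km2: float

    @property
    def percentages(self) -> dict[str, float]:
        return {
            cat: 100.0 * self.areas_km2[cat] / self.present_total_km2 for cat in CATEGORIES
        }

    def rounded(self) -> dict[str, tuple[float, float]]:
        """(km², %) per category, half-up to one decimal for report tables."""
        return {
            cat: (round_half_up(self.areas_km2[cat], 1), round_half_up(self.percentages[cat], 1))
            for cat in CATEGORIES
        }


def round_half_up(x: float, decimals: int = 1) -> float:
    # pre-round far below the target precision so binary representation
    # noise (e.g. 46.149999...) cannot flip a half-up decision
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(round(float(x), decimals + 8))).quantize(q, rounding=ROUND_HALF_UP))


def percent_of_present(area_km2: float, present_km2: float, decimals: int = 1) -> float:
    """Report-style percentage of the present suitable area."""
    if present_km2 <= 0:
        raise ValueError("present suitable area must be positive")
    return round_half_up(100.0 * area_km2 / present_km2, decimals)


def classify_change(present: BinaryMap, future: BinaryMap) -> ChangeMap:
    """(present, future) bit pair -> category code per cell."""
    pg, fg = present.grid, future.grid
    if not pg.same_grid(fg):
        raise RasterError("present and future maps are not on the same grid")
    p = pg.values
    f = fg.values
    out = np.full(pg.shape, float(NODATA_CODE))
    ok = pg.valid & fg.valid
    code = np.select(
        [
            (p == 1) & (f == 1),
            (p == 0) & (f == 1),
            (p == 1) & (f == 0),
        ],
        [STABLE, GAIN, LOSS],
        default=UNSUITABLE,
    )
    out[ok] = code[ok]
    grid = pg.with_values(out, name=f"change_{future.scenario or 'future'}")
    grid.nodata = float(NODATA_CODE)
    return ChangeMap(grid=grid, present_id=present.source, scenario=future.scenario)


def summarize_areas(change: ChangeMap, present: BinaryMap) -> ChangeSummary:
    """Latitude-aware km² per category; percentages on the present suitable
    base. Fails explicitly when the present suitable area is zero."""
    g = change.grid
    areas = cell_area_grid_km2(g)
    ok = g.valid
    out = {}
    for cat, code in zip(CATEGORIES, (STABLE, GAIN, LOSS, UNSUITABLE)):
        out[cat] = float(areas[ok & (g.values == code)].sum())
    pg = present.grid
    present_total = float(areas[pg.valid & (pg.values == 1)].sum())
    if present_total <= 0:
        raise ValueError("present suitable area is zero; percentages undefined")
    return ChangeSummary(scenario=change.scenario, areas_km2=out, present_total_km2=present_total)


def average_scenarios(summaries: Sequence[ChangeSummary], scenario: str = "average") -> ChangeSummary:
    """Arithmetic mean of category areas across scenarios sharing a present
    map (e.g., the two RCPs at one horizon); percentages recompute from the
    averaged areas."""
    if not summaries:
        raise ValueError("no summaries to average")
    bases = {round(s.present_total_km2, 6) for s in summaries}
    if len(bases) > 1:
        raise ValueError("summaries do not share a present baseline")
    areas = {
        cat: float(np.mean([s.areas_km2[cat] for s in summaries])) for cat in CATEGORIES
    }
    return ChangeSummary(
        scenario=scenario,
        areas_km2=areas,
        present_total_km2=summaries[0].present_total_km2,
    )


def mean_printed_percentages(printed: Sequence[float], decimals: int = 1) -> float:
    """Report-parity companion to area averaging: the mean of the already
    rounded percentages as a table would print it."""
    return round_half_up(float(np.mean(list(printed))), decimals)


def elevation_band_summary(
    change: ChangeMap, dem: RasterGrid, band_width_m: float = 200.0
) -> pd.DataFrame:
    """Category areas (km²) per elevation band, plus mean elevation per
    category. Bands start at the lowest valid DEM value."""
    if band_width_m <= 0:
        raise ValueError("band width must be positive")
    g = change.grid
    if not dem.same_grid(g):
        raise RasterError("DEM is not on the change-map grid")
    areas = cell_area_grid_km2(g)
    ok = g.valid & dem.valid
    z = dem.values
    z0 = np.floor(z[ok].min() / band_width_m) * band_width_m
    band = np.floor((z - z0) / band_width_m).astype(int)
    rows = []
    for b in range(int(band[ok].max()) + 1):
        lo = z0 + b * band_width_m
        rec = {"band_low_m": lo, "band_high_m": lo + band_width_m}
        for cat, code in zip(CATEGORIES, (STABLE, GAIN, LOSS, UNSUITABLE)):
            sel = ok & (band == b) & (g.values == code)
            rec[f"{cat}_km2"] = float(areas[sel].sum())
        rows.append(rec)
    df = pd.DataFrame(rows)
    for cat, code in zip(CATEGORIES, (STABLE, GAIN, LOSS, UNSUITABLE)):
        sel = ok & (g.values == code)
        df.attrs[f"mean_elevation_{cat}"] = float(z[sel].mean()) if sel.any() else float("nan")
    return df
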