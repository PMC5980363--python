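"""Training-table assembly and collinearity pruning.

Presence and background points are turned into a point x predictor table by
cell-value lookup, and predictors with pairwise Pearson |r| above a
threshold are pruned greedily, keeping the higher-priority member of each
correlated pair. The priority ranking is an explicit, reproducible stand-in
for expert variable choice.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from rangeshift.occurrences import BackgroundSet, OccurrenceSet
from rangeshift.raster import RasterStack

log = logging.getLogger(__name__)

#: Default priority ranking: climate drivers retained by the study design,
#: then terrain and land-cover predictors. Earlier = kept when correlated.
DEFAULT_PRIORITY = [
    "bio1", "bio2", "bio3", "bio4", "bio9", "bio15", "bio18",
    "tri", "northness", "eastness", "aspect", "slope",
    "veg_cover", "sparse_cover", "dist_escape", "dist_riparian",
]


@dataclass(frozen=True)
class PruneConfig:
    threshold: float = 0.7          # strict: prune only |r| > threshold
    priority: tuple[str, ...] = tuple(DEFAULT_PRIORITY)

    def rank(self, name: str) -> int:
        try:
            return self.priority.index(name)
        except ValueError:
            return len(self.priority)


def extract_values(
    occ: OccurrenceSet,
    background: BackgroundSet,
    stack: RasterStack,
    background_split: float | None = 0.70,
    seed: int = 0,
) -> pd.DataFrame:
    """Point x predictor training table.

    One row per presence (response 1) and background point (response 0),
    with plain cell-value lookups (no interpolation) for every stack layer.
    Rows touching any nodata cell are dropped and counted in the log.
    Presences carry their train/test role; background rows get a seeded
    random train/test partition at ``background_split`` so held-out metrics
    see both classes (all "train" when ``background_split`` is None).
    """
    bg_roles = None
    if background_split is not None:
        rng = np.random.default_rng(seed)
        n_bg = len(background.points)
        order = rng.permutation(n_bg)
        bg_roles = np.empty(n_bg, dtype=object)
        n_train = int(np.floor(background_split * n_bg))
        bg_roles[order[:n_train]] = "train"
        bg_roles[order[n_train:]] = "test"
        bg_roles = pd.Series(bg_roles)
    frames = []
    for label, lonlat, roles in (
        (1, occ.lonlat, occ.points.get("role")),
        (0, background.lonlat, bg_roles),
    ):
        cols = {"lon": lonlat[:, 0], "lat": lonlat[:, 1]}
        for name in stack.names:
            cols[name] = stack[name].value_at(lonlat[:, 0], lonlat[:, 1])
        df = pd.DataFrame(cols)
        df["response"] = label
        df["role"] = roles.to_numpy() if roles is not None else "train"
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    bad = np.zeros(len(table), dtype=bool)
    for name in stack.names:
        nodata = stack[name].nodata
        bad |= table[name].isna().to_numpy() | (table[name].to_numpy() == nodata)
    if bad.all():
        raise ValueError("all rows fell on nodata cells")
    if bad.any():
        log.info("dropped %d of %d rows on nodata cells", int(bad.sum()), len(table))
    return table.loc[~bad].reset_index(drop=True)


def predictor_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in ("lon", "lat", "response", "role")]


def correlation_matrix(table: pd.DataFrame, names: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlations over all rows; constant columns get r = 0."""
    names = names or predictor_columns(table)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        corr = table[names].corr(method="pearson")
    const = [n for n in names if table[n].nunique() <= 1]
    if const:
        log.warning("constant predictor(s) %s: correlation treated as 0", const)
        corr.loc[const, :] = 0.0
        corr.loc[:, const] = 0.0
    np.fill_diagonal(corr.values, 1.0)
    return corr.fillna(0.0)


def correlation_prune(table: pd.DataFrame, config: PruneConfig = PruneConfig()) -> list[str]:
    """Greedy collinearity pruning.

    Pairs with |r| strictly above the threshold are visited in decreasing
    |r|; if both members are still retained, the lower-priority one is
    dropped. Returns the retained names in the table's column order.
    """
    names = predictor_columns(table)
    if len(names) < 2:
        raise ValueError("need at least two predictors to prune")
    if len(table) < 3:
        raise ValueError("need at least three rows to estimate correlations")
    corr = correlation_matrix(table, names)
    pairs = []
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            r = abs(float(corr.loc[a, b]))
            # strict inequality, with a guard so r == threshold up to
            # floating-point noise is never pruned
            if r > config.threshold + 1e-12:
                pairs.append((r, a, b))
    # decreasing |r|; alphabetical pair order breaks exact-|r| ties
    pairs.sort(key=lambda t: (-t[0], t[1], t[2]))
    retained = set(names)
    for r, a, b in pairs:
        if a in retained and b in retained:
            drop = a if config.rank(a) > config.rank(b) else b
            retained.discard(drop)
            keep = a if drop == b else b
            log.info("dropping %s (|r|=%.3f with %s)", drop, r, keep)
    return [n for n in names if n in retained]
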