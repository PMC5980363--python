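"""Binary-map ensembles and multi-GCM scenario consensus.

Each model's suitability surface is binarized at its frozen
sensitivity=specificity threshold; binary maps are summed into an integer
agreement surface; a cell is consensus-suitable when at least ``k`` models
agree (k=3 of 5 by default). For futures, model consensus is formed per
GCM, then cells suitable under at least ``k_gcms`` of the GCMs (2 of 4 by
default) make the combined future map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from rangeshift.models import FittedModel, predict_surface
from rangeshift.raster import RasterGrid, RasterStack, RasterError


@dataclass
class BinaryMap:
    """0/1/nodata grid from thresholding one suitability surface."""

    grid: RasterGrid
    source: str
    scenario: str
    threshold: float


@dataclass
class EnsembleMap:
    """Integer agreement counts in [0, max_count]."""

    grid: RasterGrid
    max_count: int
    sources: list[str] = field(default_factory=list)


def binarize(surface: RasterGrid, threshold: float, source: str = "", scenario: str = "") -> BinaryMap:
    """suitability >= threshold -> 1 else 0; nodata preserved."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {threshold}")
    vals = np.where(surface.valid, (surface.values >= threshold).astype(float), surface.nodata)
    return BinaryMap(
        grid=surface.with_values(vals, name=f"bin_{surface.name}"),
        source=source or surface.name,
        scenario=scenario,
        threshold=threshold,
    )


def agreement_sum(maps: Sequence[BinaryMap]) -> EnsembleMap:
    """Cell-wise sum of binary maps; nodata if any input is nodata."""
    if len(maps) < 2:
        raise ValueError("need at least two binary maps")
    ref = maps[0].grid
    total = np.zeros(ref.shape)
    bad = np.zeros(ref.shape, dtype=bool)
    for m in maps:
        if not m.grid.same_grid(ref):
            raise RasterError(f"binary map {m.source!r} is not on the shared grid")
        bad |= m.grid.mask
        total += np.where(m.grid.mask, 0.0, m.grid.values)
    total[bad] = ref.nodata
    return EnsembleMap(
        grid=ref.with_values(total, name="agreement"),
        max_count=len(maps),
        sources=[m.source for m in maps],
    )


def consensus(ensemble: EnsembleMap, k: int) -> BinaryMap:
    """Agreement count >= k -> 1 else 0."""
    if not 1 <= k <= ensemble.max_count:
        raise ValueError(f"k must be in [1, {ensemble.max_count}], got {k}")
    g = ensemble.grid
    vals = np.where(g.valid, (g.values >= k).astype(float), g.nodata)
    return BinaryMap(
        grid=g.with_values(vals, name=f"consensus_k{k}"),
        source=f"consensus>= {k}/{ensemble.max_count}",
        scenario="",
        threshold=float(k),
    )


def model_consensus(
    models: Sequence[FittedModel],
    thresholds: Mapping[str, float],
    stack: RasterStack,
    k_models: int = 3,
    scenario: str = "present",
) -> tuple[BinaryMap, EnsembleMap]:
    """Predict every family on ``stack``, binarize at its frozen threshold,
    and return the k-of-n model consensus plus the agreement surface."""
    binaries = []
    for model in models:
        surface = predict_surface(model, stack, scenario)
        binaries.append(
            binarize(surface, thresholds[model.family], source=model.family, scenario=scenario)
        )
    agg = agreement_sum(binaries)
    cons = consensus(agg, k_models)
    cons.scenario = scenario
    return cons, agg


@dataclass
class ScenarioSet:
    """One future scenario (RCP x horizon): per-GCM consensus maps and the
    combined >=k_gcms future map."""

    scenario: str
    per_gcm: dict[str, BinaryMap]
    gcm_agreement: EnsembleMap
    future_map: BinaryMap


def build_scenario(
    models: Sequence[FittedModel],
    thresholds: Mapping[str, float],
    gcm_stacks: Mapping[str, RasterStack],
    scenario: str,
    k_models: int = 3,
    k_gcms: int = 2,
) -> ScenarioSet:
    """Model consensus per GCM, then GCM consensus across the ensemble.

    ``gcm_stacks`` maps GCM name -> that GCM's future predictor stack; all
    stacks must share the present grid. Thresholds are the frozen
    present-day sensitivity=specificity values per family.
    """
    if not gcm_stacks:
        raise ValueError("no GCM stacks supplied")
    per_gcm = {}
    for gcm, stack in gcm_stacks.items():
        cons, _ = model_consensus(models, thresholds, stack, k_models, scenario=f"{scenario}_{gcm}")
        per_gcm[gcm] = cons
    agg = agreement_sum(list(per_gcm.values()))
    future = consensus(agg, k_gcms)
    future.scenario = scenario
    return ScenarioSet(scenario=scenario, per_gcm=per_gcm, gcm_agreement=agg, future_map=future)
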