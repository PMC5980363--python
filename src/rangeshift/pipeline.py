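"""End-to-end orchestration: occurrences -> models -> ensembles -> change.

A single :class:`PipelineConfig` drives thinning, the 70/30 split,
background sampling, predictor extraction and pruning, the five model fits
and their evaluation, the present-day model consensus, every future
scenario's GCM consensus, and the stable/gain/loss accounting. Every
artifact lands under the output directory together with a JSON manifest
recording inputs, seeds, thresholds and retained predictors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from rangeshift import __version__
from rangeshift.change import (
    CATEGORIES,
    ChangeSummary,
    average_scenarios,
    classify_change,
    elevation_band_summary,
    summarize_areas,
)
from rangeshift.ensemble import BinaryMap, build_scenario, model_consensus
from rangeshift.evaluation import EvaluationReport, evaluate_model
from rangeshift.models import FAMILIES, FittedModel, ModelSpec, fit_model, score_table, variable_importance
from rangeshift.occurrences import mcp_background, split_train_test, thin_per_pixel
from rangeshift.predictors import PruneConfig, correlation_matrix, correlation_prune, extract_values
from rangeshift.raster import RasterGrid, RasterStack, read_raster, write_raster
from rangeshift.synthetic import (
    Landscape,
    LandscapeConfig,
    VirtualSpecies,
    apply_scenario,
    default_scenarios,
    generate_landscape,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; seeds are explicit throughout."""

    outdir: Path = Path("rangeshift_run")
    seed: int = 0
    # inputs: synthetic landscape by default, or raster/occurrence files
    synthetic: bool = True
    landscape: LandscapeConfig | None = None
    truth: VirtualSpecies = field(default_factory=VirtualSpecies)
    n_occurrences: int = 976
    raster_dir: Path | None = None
    occurrence_csv: Path | None = None
    scenario_dirs: dict[str, dict[str, Path]] | None = None   # scenario -> gcm -> dir
    # processing
    split_fraction: float = 0.70
    n_background: int = 10_000
    mcp_retain: float = 0.95
    prune: PruneConfig = field(default_factory=PruneConfig)
    # modeling
    model_hyperparameters: dict[str, dict] = field(default_factory=dict)
    families: tuple[str, ...] = FAMILIES
    # ensembles
    k_models: int = 3
    k_gcms: int = 2
    gcm_noise_scale_c: float = 0.3
    # reporting
    elevation_band_m: float = 200.0
    write_rasters: bool = True
    importance_permutations: int = 3


@dataclass
class PipelineResult:
    config: PipelineConfig
    landscape: Landscape | None
    table: pd.DataFrame
    retained: list[str]
    models: dict[str, FittedModel]
    reports: dict[str, EvaluationReport]
    thresholds: dict[str, float]
    importance: dict[str, list[tuple[str, float]]]
    present_map: BinaryMap
    present_agreement: object
    scenarios: dict[str, object]
    summaries: dict[str, ChangeSummary]
    horizon_averages: dict[str, ChangeSummary]
    manifest: dict


def _load_file_inputs(config: PipelineConfig) -> tuple[RasterStack, pd.DataFrame, RasterGrid | None]:
    from rangeshift.occurrences import OccurrenceSet

    paths = sorted(Path(config.raster_dir).glob("*.tif"))
    if not paths:
        raise FileNotFoundError(f"no GeoTIFFs under {config.raster_dir}")
    layers = [read_raster(p) for p in paths]
    dem = next((g for g in layers if g.name == "dem"), None)
    stack = RasterStack([g for g in layers if g.name != "dem"])
    occ = OccurrenceSet.from_csv(config.occurrence_csv)
    return stack, occ, dem


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full analysis; any stage failure aborts with the stage
    named in the raised error."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "inputs"
    try:
        if config.synthetic:
            lc = config.landscape or LandscapeConfig(seed=config.seed)
            landscape = generate_landscape(lc, truth=config.truth, n_occurrences=config.n_occurrences)
            stack, occ, dem = landscape.predictors, landscape.occurrences, landscape.dem
        else:
            landscape = None
            stack, occ, dem = _load_file_inputs(config)

        stage = "occurrence processing"
        thinned = thin_per_pixel(occ, stack.grid)
        split = split_train_test(thinned, fraction=config.split_fraction, seed=config.seed + 11)
        background = mcp_background(
            split, stack.grid, n_background=config.n_background,
            retain=config.mcp_retain, seed=config.seed + 13,
        )

        stage = "predictor extraction and pruning"
        table = extract_values(
            split, background, stack,
            background_split=config.split_fraction, seed=config.seed + 17,
        )
        retained = correlation_prune(table, config.prune)
        corr = correlation_matrix(table)
        corr.to_csv(outdir / "predictor_correlations.csv")

        stage = "model fitting"
        models: dict[str, FittedModel] = {}
        reports: dict[str, EvaluationReport] = {}
        thresholds: dict[str, float] = {}
        importance: dict[str, list[tuple[str, float]]] = {}
        for i, family in enumerate(config.families):
            spec = ModelSpec(
                family=family,
                hyperparameters=config.model_hyperparameters.get(family, {}),
                seed=config.seed + 100 + i,
            )
            model = fit_model(spec, table, predictors=retained)
            tr_p, tr_b = score_table(model, table, "train")
            te_p, te_b = score_table(model, table, "test")
            report = evaluate_model(family, tr_p, tr_b, te_p, te_b)
            models[family] = model
            reports[family] = report
            thresholds[family] = report.threshold
            importance[family] = variable_importance(
                model, table, n_permutations=config.importance_permutations, seed=config.seed + 500 + i
            )
        perf = pd.DataFrame([r.to_dict() for r in reports.values()]).set_index("family")
        perf.to_csv(outdir / "model_performance.csv")
        pd.DataFrame(
            {fam: dict(imp) for fam, imp in importance.items()}
        ).to_csv(outdir / "variable_importance.csv")

        stage = "present consensus"
        model_list = list(models.values())
        present_map, present_agg = model_consensus(
            model_list, thresholds, stack, k_models=config.k_models, scenario="present"
        )
        if config.write_rasters:
            write_raster(outdir / "ensemble_count_present.tif", present_agg.grid)
            write_raster(outdir / "consensus_present.tif", present_map.grid)

        stage = "future scenarios"
        scenarios: dict[str, object] = {}
        summaries: dict[str, ChangeSummary] = {}
        band_tables = []
        if config.synthetic:
            deltas = default_scenarios(seed=config.seed, noise_scale_c=config.gcm_noise_scale_c)
            gcm_stacks_by_scenario = {
                scen: {gcm: apply_scenario(stack, d, landscape.config) for gcm, d in per_gcm.items()}
                for scen, per_gcm in deltas.items()
            }
        elif config.scenario_dirs:
            gcm_stacks_by_scenario = {}
            for scen, per_gcm in config.scenario_dirs.items():
                gcm_stacks_by_scenario[scen] = {}
                for gcm, d in per_gcm.items():
                    future_layers = {p.stem: read_raster(p) for p in sorted(Path(d).glob("*.tif"))}
                    gcm_stacks_by_scenario[scen][gcm] = stack.replace(*future_layers.values())
        else:
            gcm_stacks_by_scenario = {}

        for scen, gcm_stacks in gcm_stacks_by_scenario.items():
            ss = build_scenario(
                model_list, thresholds, gcm_stacks, scenario=scen,
                k_models=config.k_models, k_gcms=config.k_gcms,
            )
            scenarios[scen] = ss
            change = classify_change(present_map, ss.future_map)
            summaries[scen] = summarize_areas(change, present_map)
            if dem is not None:
                bands = elevation_band_summary(change, dem, band_width_m=config.elevation_band_m)
                bands.insert(0, "scenario", scen)
                band_tables.append(bands)
            if config.write_rasters:
                write_raster(outdir / f"ensemble_gcm_count_{scen}.tif", ss.gcm_agreement.grid)
                write_raster(outdir / f"consensus_{scen}.tif", ss.future_map.grid)
                write_raster(outdir / f"change_{scen}.tif", change.grid)

        stage = "change accounting"
        horizon_averages: dict[str, ChangeSummary] = {}
        horizons = sorted({s.split("_")[1] for s in summaries})
        for hz in horizons:
            group = [summaries[s] for s in summaries if s.endswith(f"_{hz}")]
            if group:
                horizon_averages[hz] = average_scenarios(group, scenario=f"average_{hz}")
        rows = []
        for name, summ in {**summaries, **horizon_averages}.items():
            rec = {"scenario": name, "present_km2": round(summ.present_total_km2, 1)}
            for cat in CATEGORIES:
                km2, pct = summ.rounded()[cat]
                rec[f"{cat}_km2"] = km2
                rec[f"{cat}_pct"] = pct
            rows.append(rec)
        change_df = pd.DataFrame(rows)
        change_df.to_csv(outdir / "change_summary.csv", index=False)
        if band_tables:
            pd.concat(band_tables, ignore_index=True).to_csv(outdir / "elevation_bands.csv", index=False)
        background.points.to_csv(outdir / "background_points.csv", index=False)
        (outdir / "mcp.wkt").write_text(background.polygon.wkt + "\n")
        split.to_csv(outdir / "occurrences_thinned.csv")

        stage = "manifest"
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "synthetic": config.synthetic,
            "n_occurrences_raw": len(occ),
            "n_occurrences_thinned": len(thinned),
            "n_background": len(background),
            "retained_predictors": retained,
            "thresholds": {k: round(v, 6) for k, v in thresholds.items()},
            "k_models": config.k_models,
            "k_gcms": config.k_gcms,
            "scenarios": sorted(scenarios),
            "families": list(config.families),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineResult(
        config=config,
        landscape=landscape,
        table=table,
        retained=retained,
        models=models,
        reports=reports,
        thresholds=thresholds,
        importance=importance,
        present_map=present_map,
        present_agreement=present_agg,
        scenarios=scenarios,
        summaries=summaries,
        horizon_averages=horizon_averages,
        manifest=manifest,
    )
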