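"""Config-driven orchestration of the full modelling workflow.

Stages, in order: simulate (optional) -> occurrence thinning -> host
pre-models and richness layer -> collinearity filter -> offset grid + AIC
selection -> predictor combinations x model kinds x replicates -> metric
panels and paired Wilcoxon comparison -> permutation/jackknife importance
-> path analysis -> niche overlap -> current and scenario threat
assessment. Every stage writes its artifacts under the run directory and
the manifest records config, seeds, and package version, so a rerun from
the manifest reproduces all tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core_geo import (
    thin_occurrences,
    write_esri_ascii,
    write_geojson,
    write_occurrences,
)
from .evaluation import (
    altitude_profile,
    build_cell_table,
    compare_combinations,
    path_analysis,
)
from .niche import niche_analysis
from .predictors import host_richness, offset_grid, offset_report, select_offset, spearman_filter
from .sdm import (
    FeatureExpansion,
    fit_maxent,
    run_replicates,
    sample_background,
    variable_contribution,
)
from .synthetic_data import default_scenario, make_future
from .threat import scenario_trend, threshold_sweep

log = logging.getLogger("hostsdm")

COMBINATION_LABELS = ("C", "C+E", "C+H", "C+E+H")


@dataclass
class RunConfig:
    seed: int
    outdir: str = "runs/run"
    n_replicates: int = 20
    n_background: int = 2000
    model_kinds: tuple[str, ...] = ("maxent",)
    combinations: tuple[str, ...] = COMBINATION_LABELS
    feature_classes: tuple[str, ...] = ("linear", "quadratic")
    lambda_mult: float = 1.0
    n_trees: int = 200
    richness_threshold: float = 0.66
    suitability_thresholds: tuple[float, ...] = (0.33, 0.66, 0.90)
    niche_grid_resolution: int = 100
    niche_reps: int = 100
    host_dependence_weight: float = 6.0
    n_focal_presences: int = 200
    include_hosts: bool = True
    write_rasters: bool = True
    #: scenario label -> period label -> (delta T in K, precip fraction)
    future_ladder: dict = field(
        default_factory=lambda: {
            "SSP126": {"2030": (0.6, -0.01), "2050": (0.9, -0.02), "2070": (1.1, -0.02), "2090": (1.2, -0.03)},
            "SSP245": {"2030": (0.7, -0.02), "2050": (1.2, -0.03), "2070": (1.7, -0.04), "2090": (2.1, -0.05)},
            "SSP370": {"2030": (0.8, -0.02), "2050": (1.6, -0.05), "2070": (2.5, -0.07), "2090": (3.4, -0.09)},
            "SSP585": {"2030": (0.9, -0.03), "2050": (2.0, -0.06), "2070": (3.2, -0.09), "2090": (4.4, -0.12)},
        }
    )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = json.load(fh)
        cfg = cls(seed=raw.pop("seed"))
        for k, v in raw.items():
            if not hasattr(cfg, k):
                raise KeyError(f"unknown config key {k!r}")
            setattr(cfg, k, tuple(v) if isinstance(getattr(cfg, k), tuple) else v)
        return cfg


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.time()
            log.info("stage %s: start", name)
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s: done in %.1fs", name, time.time() - t0)
            return out

        return wrapped

    return deco


def run_pipeline(cfg: RunConfig) -> Path:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    cfg_json = json.dumps(asdict(cfg), sort_keys=True, default=str)
    manifest = {
        "config": json.loads(cfg_json),
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": cfg.seed,
        "hostsdm_version": __version__,
    }

    scenario = _simulate(cfg, outdir)
    layers = scenario.layers
    spec = next(iter(layers.values())).spec

    presences = thin_occurrences(scenario.focal_presences, spec)

    climate_names = [n for n in layers if n != "elevation"]
    richness = scenario.host_richness

    retained = _filter_layers(cfg, presences, layers, climate_names, outdir)
    base_names = retained + ["elevation"]

    offsets, best_offset = _offsets(cfg, scenario, spec, presences, outdir)

    comparison, backgrounds, combo_layers = _compare(
        cfg, presences, layers, base_names, richness, best_offset, spec, outdir
    )

    best_label = "C+E+H" if cfg.include_hosts else "C+E"
    if best_label not in combo_layers:
        best_label = list(combo_layers)[-1]
    importance = _importance(
        cfg, presences, backgrounds[best_label], combo_layers[best_label], outdir
    )

    full_model = fit_maxent(
        presences,
        backgrounds[best_label],
        combo_layers[best_label],
        features=FeatureExpansion(classes=cfg.feature_classes),
        lambda_mult=cfg.lambda_mult,
        seed=cfg.seed,
    )
    suitability = full_model.predict(combo_layers[best_label])
    if cfg.write_rasters:
        write_esri_ascii(suitability, outdir / "suitability_current.asc")

    if cfg.include_hosts:
        _path_analysis_stage(layers, richness, suitability, outdir)
        _niche_stage(cfg, scenario, layers, climate_names, outdir)
    else:
        log.info("hosts disabled: skipping richness combinations, path analysis, niche overlap")

    _threat_stage(cfg, scenario, full_model, combo_layers[best_label], suitability, outdir)

    prof = altitude_profile(suitability, layers["elevation"], presence_threshold=0.66)
    prof.to_csv(outdir / "altitude_profile.csv", index=False)

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


@_stage("simulate")
def _simulate(cfg: RunConfig, outdir: Path):
    scenario = default_scenario(
        seed=cfg.seed,
        host_dependence_weight=cfg.host_dependence_weight,
        n_focal_presences=cfg.n_focal_presences,
        richness_threshold=cfg.richness_threshold,
    )
    write_occurrences(scenario.focal_presences, outdir / "focal_occurrences.csv")
    write_occurrences(scenario.host_presences, outdir / "host_occurrences.csv")
    write_geojson(scenario.expert_range, outdir / "expert_range.geojson")
    if cfg.write_rasters:
        write_esri_ascii(scenario.host_richness, outdir / "host_richness.asc")
        write_esri_ascii(scenario.focal.true_suitability, outdir / "truth_focal.asc")
    truth_manifest = {
        "seed": cfg.seed,
        "focal": {
            "host_dependence_weight": scenario.focal.host_dependence_weight,
            "intercept": scenario.focal.intercept,
            "terms": [asdict(t) for t in scenario.focal.response_terms],
        },
        "hosts": [
            {"species_id": t.species_id, "terms": [asdict(x) for x in t.response_terms]}
            for t in scenario.host_truths
        ],
    }
    with open(outdir / "truth_manifest.json", "w") as fh:
        json.dump(truth_manifest, fh, indent=2)
    return scenario


@_stage("collinearity_filter")
def _filter_layers(cfg, presences, layers, climate_names, outdir):
    # contribution values from a quick single-fit permutation importance
    bg = sample_background(
        next(iter(layers.values())).spec, n=cfg.n_background, seed=cfg.seed + 1,
        exclude=presences,
    )
    pre = run_replicates(
        presences, bg, {n: layers[n] for n in climate_names}, n=1,
        model_kind="maxent", seed=cfg.seed, compute_boyce=False,
        feature_classes=("linear", "quadratic"),
    )
    contrib = variable_contribution(
        pre, presences, bg, {n: layers[n] for n in climate_names},
        n_permutations=3, seed=cfg.seed, jackknife=False,
    )["contribution_pct"]
    retained = spearman_filter(
        {n: layers[n] for n in climate_names}, contrib, threshold=0.8
    )
    pd.DataFrame(
        {
            "layer": climate_names,
            "contribution_pct": [contrib[n] for n in climate_names],
            "retained": [n in retained for n in climate_names],
        }
    ).to_csv(outdir / "collinearity_filter.csv", index=False)
    return retained


@_stage("offsets")
def _offsets(cfg, scenario, spec, presences, outdir):
    offsets = offset_grid(scenario.expert_range, spec)
    best = select_offset(offsets, presences)
    offset_report(offsets, best).to_csv(outdir / "offset_selection.csv", index=False)
    if cfg.write_rasters:
        write_esri_ascii(best.raster, outdir / "offset_best.asc")
    return offsets, best


@_stage("compare_combinations")
def _compare(cfg, presences, layers, base_names, richness, best_offset, spec, outdir):
    combo_layers = {}
    backgrounds = {}
    base = {n: layers[n] for n in base_names}
    with_h = dict(base)
    with_h["host_richness"] = richness
    uniform_bg = sample_background(spec, n=cfg.n_background, seed=cfg.seed + 2, exclude=presences)
    biased_bg = sample_background(
        spec, n=cfg.n_background, weight=best_offset.raster, seed=cfg.seed + 3,
        exclude=presences,
    )
    for label in cfg.combinations:
        if "H" in label and not cfg.include_hosts:
            log.info("skipping combination %s (hosts disabled)", label)
            continue
        combo_layers[label] = with_h if "H" in label else base
        backgrounds[label] = biased_bg if "E" in label else uniform_bg
    comparison = compare_combinations(
        presences,
        combo_layers,
        backgrounds,
        model_kinds=cfg.model_kinds,
        n_replicates=cfg.n_replicates,
        seed=cfg.seed,
        feature_classes=cfg.feature_classes,
        lambda_mult=cfg.lambda_mult,
        n_trees=cfg.n_trees,
    )
    comparison.pvalues.to_csv(outdir / "comparison_wilcoxon.csv", index=False)
    long = []
    for (label, kind), frame in comparison.panels.items():
        f = frame.drop(columns=["flags"]).copy()
        f.insert(0, "replicate", np.arange(len(f)))
        f.insert(0, "model_kind", kind)
        f.insert(0, "combination", label)
        long.append(f)
    pd.concat(long, ignore_index=True).to_csv(outdir / "replicate_metrics.csv", index=False)
    return comparison, backgrounds, combo_layers


@_stage("importance")
def _importance(cfg, presences, background, layer_stack, outdir):
    reps = run_replicates(
        presences, background, layer_stack,
        n=min(cfg.n_replicates, 10), model_kind="maxent", seed=cfg.seed,
        compute_boyce=False, feature_classes=cfg.feature_classes,
        lambda_mult=cfg.lambda_mult,
    )
    imp = variable_contribution(
        reps, presences, background, layer_stack, n_permutations=5, seed=cfg.seed
    )
    pd.DataFrame(
        [
            {
                "layer": n,
                "contribution_pct": imp["contribution_pct"][n],
                "jackknife_alone_auc": imp["jackknife"][n]["alone_auc"],
                "jackknife_without_auc": imp["jackknife"][n]["without_auc"],
            }
            for n in imp["contribution_pct"]
        ]
    ).to_csv(outdir / "variable_importance.csv", index=False)
    return imp


@_stage("path_analysis")
def _path_analysis_stage(layers, richness, suitability, outdir):
    table = build_cell_table(layers, richness, suitability)
    result = path_analysis(table)
    with open(outdir / "path_analysis.json", "w") as fh:
        json.dump(result, fh, indent=2)
    rows = []
    for var, eff in result["effects"].items():
        rows.append({"variable": var, **eff})
    pd.DataFrame(rows).to_csv(outdir / "path_effects.csv", index=False)
    return result


@_stage("niche")
def _niche_stage(cfg, scenario, layers, climate_names, outdir):
    res = niche_analysis(
        {n: layers[n] for n in climate_names},
        scenario.focal_presences,
        scenario.host_presences,
        grid_resolution=cfg.niche_grid_resolution,
        reps=cfg.niche_reps,
        seed=cfg.seed,
    )
    with open(outdir / "niche_report.json", "w") as fh:
        json.dump(
            {k: res[k] for k in ("D", "p_D", "I", "p_I", "stability", "expansion", "unfilling")},
            fh,
            indent=2,
        )
    np.savetxt(outdir / "niche_density_focal.txt", res["z_focal"])
    np.savetxt(outdir / "niche_density_host.txt", res["z_host"])
    return res


@_stage("threat")
def _threat_stage(cfg, scenario, model, model_layers, suitability, outdir):
    sweep = threshold_sweep(suitability, cfg.suitability_thresholds)
    pd.DataFrame(
        [
            {
                "threshold": r.threshold,
                "eoo_km2": r.eoo_km2,
                "aoo_km2": r.aoo_km2,
                "category": r.category,
                "criterion": r.criterion,
            }
            for r in sweep
        ]
    ).to_csv(outdir / "threat_current.csv", index=False)

    future = {}
    for scen, periods in cfg.future_ladder.items():
        future[scen] = {}
        for period, (dt, dp) in periods.items():
            shifted = make_future(scenario.layers, delta_temperature=dt, delta_precip_fraction=dp)
            shifted["host_richness"] = scenario.host_richness
            future[scen][period] = model.predict(
                {n: shifted[n] for n in model_layers}
            )
    trend = scenario_trend(suitability, future, threshold=cfg.suitability_thresholds[0])
    trend.to_csv(outdir / "threat_future.csv", index=False)
    return trend
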