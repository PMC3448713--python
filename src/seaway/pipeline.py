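"""End-to-end orchestration: synthetic domain -> occurrences -> covariates ->
seasonal maxent fits -> evaluation -> distribution products.

This module also owns the on-disk layout used by the CLI stages, so each
stage can be run separately against a directory of plain-text layers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import evaluation, mapping, maxent_engine, occurrence, synthetic_domain as synth
from .covariates import (
    CovariateStack,
    SEASONAL_NAMES,
    SampleMatrix,
    build_samples,
    cost_distance,
    krige_field,
    reclassify_cost,
)
from .raster import Raster, read_ascii_grid
from .seasons import SEASONS

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "build_stack", "run_pipeline", "write_stack", "read_stack"]


@dataclass
class PipelineConfig:
    domain: synth.SyntheticDomainConfig = field(default_factory=synth.SyntheticDomainConfig)
    species: synth.VirtualSpecies = field(
        default_factory=lambda: synth.VirtualSpecies(
            response_coefficients={
                "temp": (7.2, -0.4),  # mild quadratic optimum at 9 degC
                "spawn_attr": (-0.05, 0.0),  # drawn toward the attractors
                "winter_attr": (-0.05, 0.0),
            },
            intercept=-31.0,
        )
    )
    years: tuple[int, int] = (2004, 2006)
    n_hydrophones: int = 40
    n_background: int = 2000
    n_tags: int = 60
    kfolds: int = 10
    reg_multiplier: float = 3.0
    krige_stride: int = 0  # 0 = use fields directly; >0 = krige from coarse points
    temp_noise_sd: float = 0.4
    hinge_knots: int = 5
    feature_classes: frozenset = maxent_engine.DEFAULT_CLASSES
    with_jackknife: bool = False
    tol: float = 1e-5
    max_iter: int = 10000


def _krige_emulate(layer: Raster, stride: int) -> Raster:
    """Re-grid a field through ordinary kriging from a coarse point grid,
    emulating interpolation of coarse ocean-model output onto the 1 km grid."""
    rr = np.arange(0, layer.n_rows, stride)
    cc = np.arange(0, layer.n_cols, stride)
    pts = []
    for r in rr:
        for c in cc:
            x, y = layer.cell_center(int(r), int(c))
            pts.append((x, y, layer.values[r, c]))
    return krige_field(pts, layer)


def build_stack(
    bathymetry: Raster,
    latitude: Raster,
    config: PipelineConfig,
    seed: int,
) -> CovariateStack:
    """Cost-distance attraction layers plus (optionally kriged) seasonal fields."""
    cost = reclassify_cost(bathymetry)
    spawn = cost_distance(cost, config.domain.spawning_attractor)
    winter = cost_distance(cost, config.domain.overwintering_attractor)
    seasonal = {}
    for year in range(config.years[0], config.years[1] + 1):
        for season in SEASONS:
            layers = synth.make_seasonal_fields(
                bathymetry, latitude, season, seed=seed, year=year,
                temp_noise_sd=config.temp_noise_sd,
            )
            if config.krige_stride > 0:
                layers = {k: _krige_emulate(v, config.krige_stride) for k, v in layers.items()}
            seasonal[(season, year)] = layers
    stack = CovariateStack(bathymetry, spawn, winter, seasonal)
    stack.average_over_years()
    return stack


@dataclass
class PipelineResult:
    bathymetry: Raster
    latitude: Raster
    stack: CovariateStack
    records: list
    samples: dict[str, SampleMatrix]
    reports: dict[str, evaluation.EvaluationReport]
    models: dict[str, maxent_engine.MaxEntModel]
    surfaces: dict[str, Raster]
    mean_surface: Raster
    threshold_maps: dict[str, Raster]
    profiles: dict[str, mapping.LatitudinalProfile]


def run_pipeline(config: PipelineConfig, seed: int) -> PipelineResult:
    """Full run: synthesis, telemetry, aggregation, fits, evaluation, maps."""
    bathy, lat = synth.make_domain(config.domain)
    stack = build_stack(bathy, lat, config, seed)

    hydro = synth.default_hydrophones(bathy, n=config.n_hydrophones, seed=seed)
    months = [
        (y, m)
        for y in range(config.years[0], config.years[1] + 1)
        for m in range(1, 13)
    ]
    events = synth.simulate_telemetry(
        config.species, stack, hydro, months, seed=seed, n_tags=config.n_tags
    )
    logger.info("simulated %d detection events at %d sites", len(events), len(hydro))

    days = occurrence.detection_days(events)
    sites = synth.sites_table(hydro, lat)
    records = occurrence.aggregate_seasonal(days, sites)
    logger.info("aggregated %d seasonal presence records", len(records))

    samples, reports, models = {}, {}, {}
    surfaces, thresholds = {}, {}
    for season in SEASONS:
        sm = build_samples(
            records, stack, season,
            n_background=config.n_background, seed=seed, window_years=config.years,
        )
        samples[season] = sm
        rep, model = evaluation.evaluate_season(
            sm, K=min(config.kfolds, sm.n_presence), seed=seed, r=config.reg_multiplier,
            classes=config.feature_classes, hinge_knots=config.hinge_knots,
            with_jackknife=config.with_jackknife, tol=config.tol, max_iter=config.max_iter,
        )
        reports[season] = rep
        models[season] = model

    season_surfaces, mean_surface = mapping.seasonal_surface(models, stack)
    profiles = {}
    for season in SEASONS:
        surfaces[season] = season_surfaces[season]
        thresholds[season] = mapping.threshold_map(
            season_surfaces[season], reports[season].logistic_threshold
        )
        profiles[season] = mapping.latitudinal_profile(
            season_surfaces[season], lat, season=season
        )

    return PipelineResult(
        bathymetry=bathy, latitude=lat, stack=stack, records=records,
        samples=samples, reports=reports, models=models,
        surfaces=surfaces, mean_surface=mean_surface,
        threshold_maps=thresholds, profiles=profiles,
    )


# ---------------------------------------------------------------------------
# directory layout for CLI stage handoff
# ---------------------------------------------------------------------------


def write_stack(stack: CovariateStack, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    stack.depth.write_ascii_grid(out / "depth.asc")
    stack.spawn_attr.write_ascii_grid(out / "spawn_attr.asc")
    stack.winter_attr.write_ascii_grid(out / "winter_attr.asc")
    for (season, year), layers in stack.seasonal.items():
        tag = f"{season}_{year if year is not None else 'avg'}"
        for name, layer in layers.items():
            layer.write_ascii_grid(out / f"{name}_{tag}.asc")


def read_stack(indir: str | Path) -> CovariateStack:
    ind = Path(indir)
    depth = read_ascii_grid(ind / "depth.asc")
    spawn = read_ascii_grid(ind / "spawn_attr.asc")
    winter = read_ascii_grid(ind / "winter_attr.asc")
    seasonal: dict[tuple[str, int | None], dict[str, Raster]] = {}
    for path in sorted(ind.glob("*.asc")):
        parts = path.stem.rsplit("_", 2)
        if len(parts) != 3 or parts[1] not in (s for s in SEASONS):
            continue
        name = parts[0]
        if name not in SEASONAL_NAMES:
            continue
        year = None if parts[2] == "avg" else int(parts[2])
        seasonal.setdefault((parts[1], year), {})[name] = read_ascii_grid(path)
    return CovariateStack(depth, spawn, winter, seasonal)


def load_config(path: str | Path) -> PipelineConfig:
    """Pipeline configuration from a YAML file (all keys optional)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    domain = synth.SyntheticDomainConfig(**{
        **{k: tuple(v) if isinstance(v, list) else v for k, v in raw.get("domain", {}).items()}
    })
    sp = raw.get("species")
    if sp:
        species = synth.VirtualSpecies(
            response_coefficients={k: tuple(v) for k, v in sp["response_coefficients"].items()},
            intercept=float(sp.get("intercept", 0.0)),
            season_weights=sp.get("season_weights", {}),
            detection_rate=float(sp.get("detection_rate", 2.0)),
        )
    else:
        species = PipelineConfig().species
    kwargs = {
        k: v
        for k, v in raw.items()
        if k in {"n_hydrophones", "n_background", "n_tags", "kfolds",
                 "reg_multiplier", "krige_stride", "hinge_knots", "with_jackknife"}
    }
    if "years" in raw:
        kwargs["years"] = tuple(raw["years"])
    return PipelineConfig(domain=domain, species=species, **kwargs)
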