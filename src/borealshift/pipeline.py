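"""End-to-end pipeline: simulate -> composite -> cover models -> albedo &
forcing -> change report.

Each stage is an importable function; :func:`run_pipeline` chains them,
writes artifacts (cover maps, forcing rasters, reports, a config
snapshot, fire perimeters and a manifest with per-stage hashes) into an
output directory, and returns the in-memory results.  A rerun with the
same config and seed reproduces the change report bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.ndimage import distance_transform_edt

from . import albedo as alb
from . import change as chg
from . import compositing as cmp
from . import cover_mapping as cvm
from . import inventory as inv
from . import synthetic as syn
from . import vectors
from .config import PipelineConfig
from .rasters import GridSpec, write_raster

log = logging.getLogger(__name__)

SEASONS = syn.SEASONS


@dataclass
class CoverResult:
    """Fitted models and per-epoch maps for one response."""

    response: str
    spec3: object
    spec1: object
    model3: object
    model1: object
    features3: list[str]
    features1: list[str]
    validation: dict
    maps: dict  # epoch -> CoverMap


@dataclass
class PipelineResult:
    config: PipelineConfig
    truth: syn.LandscapeTruth
    stacks: dict
    dec: CoverResult
    canopy: CoverResult
    albedo_models: dict  # season -> {model, importances, cv_r2}
    albedo_maps: dict  # (season, epoch) -> SeasonalAlbedo
    kernels: dict  # season -> KernelField
    forcings: dict  # season -> ForcingMap
    mask: chg.AnalysisMask
    fire_year_raster: np.ndarray
    fire_class_raster: np.ndarray
    report: pd.DataFrame
    regional_report: pd.DataFrame | None
    recovery: dict
    outdir: Path | None = None
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------- stages


def simulate(config: PipelineConfig) -> syn.LandscapeTruth:
    config.validate()
    return syn.generate_truth(config.generation, seed=config.seed)


def build_stack(truth: syn.LandscapeTruth, config: PipelineConfig, epoch: int) -> cmp.FeatureStack:
    """Render seasonal reflectance for an epoch and assemble the feature stack."""
    comps = {}
    for season in SEASONS:
        refl = syn.render_reflectance(
            truth,
            epoch,
            season,
            n_dates=config.n_dates,
            cloud_fraction=config.cloud_fraction,
            noise_sd=config.reflectance_noise_sd,
            seed=config.seed,
        )
        comps[season] = cmp.median_composite(refl, epoch=epoch)
    terrain = cmp.terrain_layers(truth.dem, truth.pixel_size)
    return cmp.assemble_stack(comps["spring"], comps["summer"], comps["fall"], terrain)


def _attach_features(
    records: pd.DataFrame, stack: cmp.FeatureStack, require_complete: bool = True
) -> pd.DataFrame:
    """Join stack layer values at record pixel locations; drop off-mask records."""
    rows = records["row"].to_numpy(int)
    cols = records["col"].to_numpy(int)
    ok = stack.complete_mask[rows, cols] if require_complete else stack.summer_mask[rows, cols]
    if (~ok).any():
        log.info("dropping %d records outside the complete composite mask", int((~ok).sum()))
    records = records.loc[ok].reset_index(drop=True)
    rows, cols = records["row"].to_numpy(int), records["col"].to_numpy(int)
    feats = stack.layers[:, rows, cols].T
    out = records.copy()
    for j, name in enumerate(stack.names):
        out[name] = feats[:, j]
    return out


def select_features(
    stack: cmp.FeatureStack, config: PipelineConfig
) -> tuple[list[str], list[str]]:
    """Correlation-pruned feature lists for the three- and one-season modes."""
    rng = np.random.default_rng(config.seed)
    idx = np.argwhere(stack.complete_mask)
    if len(idx) < 2:
        raise ValueError("too few complete pixels to sample for pruning")
    pick = rng.choice(len(idx), size=min(config.prune_sample_size, len(idx)), replace=False)
    rows, cols = idx[pick, 0], idx[pick, 1]
    sample = stack.layers[:, rows, cols].T
    retained3 = cmp.prune_correlated(stack.names, sample, config.correlation_threshold)
    one_idx = [stack.names.index(n) for n in cvm.ONE_SEASON_LAYERS]
    retained1 = cmp.prune_correlated(
        cvm.ONE_SEASON_LAYERS, sample[:, one_idx], config.correlation_threshold
    )
    return retained3, retained1


def _train_response(
    records: pd.DataFrame,
    response: str,
    features3: list[str],
    features1: list[str],
    stacks: dict,
    config: PipelineConfig,
    map_response: str,
) -> CoverResult:
    labelled = inv.split_train_validation(records, config.train_fraction, seed=config.seed)
    train = labelled[labelled["split"] == "train"]
    val = labelled[labelled["split"] == "validation"]
    val_thin = inv.thin_for_validation(
        val, config.thin_distance, pixel_size=config.generation.pixel_size, seed=config.seed
    )
    spec3 = cvm.grid_search(
        train, features3, response, "three_season",
        grid=config.cover_grid, folds=config.cv_folds, repeats=config.cv_repeats,
        seed=config.seed,
    )
    model3 = cvm.fit(train, spec3)
    spec1 = cvm.grid_search(
        train, features1, response, "one_season",
        grid=config.cover_grid, folds=config.cv_folds, repeats=config.cv_repeats,
        seed=config.seed,
    )
    model1 = cvm.fit(train, spec1)
    validation = cvm.validate(model3, val_thin, spec3.features, response)
    maps = {
        epoch: cvm.predict_map(
            model3, model1, stacks[epoch], spec3.features, spec1.features, map_response
        )
        for epoch in config.epochs
    }
    return CoverResult(
        response=map_response,
        spec3=spec3,
        spec1=spec1,
        model3=model3,
        model1=model1,
        features3=spec3.features,
        features1=spec1.features,
        validation=validation,
        maps=maps,
    )


def train_deciduous(
    truth: syn.LandscapeTruth,
    stacks: dict,
    features3: list[str],
    features1: list[str],
    config: PipelineConfig,
) -> CoverResult:
    """Inventory plots -> balanced response -> models -> per-epoch maps."""
    epoch_a = config.epochs[0]
    plots = syn.sample_plots(
        truth, epoch_a, config.n_plots, ba_noise=config.ba_noise, seed=config.seed
    )
    plots = inv.attach_response(plots)
    plots = _attach_features(plots, stacks[epoch_a])
    balanced = inv.binned_undersample(
        plots, bin_width=config.bin_width, target=config.undersample_target,
        seed=config.seed,
    )
    return _train_response(
        balanced, "dec_fraction", features3, features1, stacks, config,
        map_response="deciduous_fraction",
    )


def train_canopy(
    truth: syn.LandscapeTruth,
    stacks: dict,
    features3: list[str],
    features1: list[str],
    config: PipelineConfig,
) -> tuple[CoverResult, np.ndarray]:
    """Stratified reference-cover sample -> models -> per-epoch maps."""
    ref_epoch = config.reference_epoch
    if ref_epoch not in stacks:
        stacks[ref_epoch] = build_stack(truth, config, ref_epoch)
    _, cover_ref = syn.evaluate_composition(truth, ref_epoch)
    rng = np.random.default_rng([config.seed, 11])
    reference = np.clip(
        cover_ref + rng.normal(0.0, config.canopy_reference_noise_sd, cover_ref.shape),
        0.0,
        1.0,
    )
    samples = cvm.train_canopy_reference(
        reference,
        n_per_stratum=config.canopy_n_per_stratum,
        seed=config.seed,
        valid_mask=stacks[ref_epoch].complete_mask,
    )
    samples = _attach_features(samples, stacks[ref_epoch])
    result = _train_response(
        samples, "tree_canopy_cover", features3, features1, stacks, config,
        map_response="tree_canopy_cover",
    )
    return result, reference


def _fill_invalid(values: np.ndarray, valid: np.ndarray) -> np.ndarray:
    """Fill invalid cells with their nearest valid value (for interpolation)."""
    if valid.all():
        return values
    if not valid.any():
        raise ValueError("no valid cells to fill from")
    _, (ri, ci) = distance_transform_edt(~valid, return_indices=True)
    return values[ri, ci]


def build_seasonal_albedo(
    truth: syn.LandscapeTruth, config: PipelineConfig, epoch: int, season: str
) -> alb.SeasonalAlbedo:
    """Composite synthetic daily coarse albedo and downscale to the grid."""
    days, valids = [], []
    for i in range(config.n_albedo_days):
        ca = syn.render_albedo(
            truth, epoch, season,
            coarse_factor=config.albedo_coarse_factor,
            noise_sd=config.albedo_noise_sd,
            seed=config.seed * 1000 + i,
        )
        days.append(ca.values)
        valids.append(ca.valid)
    coarse = alb.seasonal_albedo_composite(
        np.stack(days), np.stack(valids), season, epoch
    )
    filled = _fill_invalid(
        np.where(coarse.valid_mask, coarse.albedo, 0.0), coarse.valid_mask
    )
    f = config.albedo_coarse_factor
    fine = alb.downscale(filled, f, clip_range=(0.0, 1.0))
    fine_valid = np.kron(coarse.valid_mask, np.ones((f, f), dtype=bool))
    return alb.SeasonalAlbedo(
        season=season,
        epoch=epoch,
        albedo=np.where(fine_valid, fine, np.nan),
        valid_mask=fine_valid,
    )


def albedo_and_forcing(
    truth: syn.LandscapeTruth,
    dec_maps: dict,
    cover_maps: dict,
    config: PipelineConfig,
) -> tuple[dict, dict, dict, dict]:
    """Per season: fit the albedo model at the first epoch, predict both
    epochs, and convert the change to forcing via the downscaled kernel."""
    epoch_a, epoch_b = config.epochs[0], config.epochs[-1]
    models, maps, kernels, forcings = {}, {}, {}, {}
    for season in SEASONS:
        observed = build_seasonal_albedo(truth, config, epoch_a, season)
        records = alb.sample_albedo_training(
            observed, dec_maps[epoch_a], cover_maps[epoch_a],
            bin_width=config.bin_width, n_per_bin=config.albedo_n_per_bin,
            seed=config.seed,
        )
        model, importances, cv_r2 = alb.fit_albedo_model(
            records, hyperparams=config.albedo_hyperparams, seed=config.seed
        )
        models[season] = {"model": model, "importances": importances, "cv_r2": cv_r2}
        pred_a = alb.predict_albedo(model, dec_maps[epoch_a], cover_maps[epoch_a], season)
        pred_b = alb.predict_albedo(model, dec_maps[epoch_b], cover_maps[epoch_b], season)
        maps[(season, epoch_a)] = pred_a
        maps[(season, epoch_b)] = pred_b
        kern_coarse = syn.render_kernel(truth, season, config.albedo_coarse_factor)
        kernels[season] = alb.KernelField(
            season=season, kernel=alb.downscale(kern_coarse, config.albedo_coarse_factor)
        )
        forcings[season] = alb.radiative_forcing(pred_a, pred_b, kernels[season])
    return models, maps, kernels, forcings


def default_regions(shape: tuple[int, int]) -> list[tuple[str, "shapely.Geometry"]]:
    """Two-half west/east partition of the grid in pixel coordinates."""
    rows, cols = shape
    west = shapely.box(0, 0, cols / 2.0, rows)
    east = shapely.box(cols / 2.0, 0, cols, rows)
    return [("west", west), ("east", east)]


def change_report(
    truth: syn.LandscapeTruth,
    dec: CoverResult,
    canopy: CoverResult,
    albedo_maps: dict,
    forcings: dict,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame | None, chg.AnalysisMask, np.ndarray, np.ndarray]:
    epoch_a, epoch_b = config.epochs[0], config.epochs[-1]
    shape = truth.grid_shape
    year_r, class_r = chg.rasterize_fires(truth.fires, shape)
    burned_between = (year_r > epoch_a) & (year_r <= epoch_b)

    cov_a = np.nan_to_num(canopy.maps[epoch_a].estimate, nan=0.0)
    cov_b = np.nan_to_num(canopy.maps[epoch_b].estimate, nan=0.0)
    amask = chg.analysis_mask(cov_a, cov_b, burned_between, config.tree_cover_threshold)
    mask = amask.mask & dec.maps[epoch_a].valid_mask & dec.maps[epoch_b].valid_mask

    deltas = {
        "dec": dec.maps[epoch_b].estimate - dec.maps[epoch_a].estimate,
        "cover": canopy.maps[epoch_b].estimate - canopy.maps[epoch_a].estimate,
    }
    sig = {
        "dec": chg.significance(
            deltas["dec"],
            dec.maps[epoch_a].uncertainty,
            np.nan_to_num(dec.maps[epoch_b].uncertainty, nan=0.0),
            config.z_critical,
        ),
        "cover": chg.significance(
            deltas["cover"],
            np.nan_to_num(canopy.maps[epoch_a].uncertainty, nan=0.0),
            np.nan_to_num(canopy.maps[epoch_b].uncertainty, nan=0.0),
            config.z_critical,
        ),
    }
    dalbedo = {
        s: albedo_maps[(s, epoch_b)].albedo - albedo_maps[(s, epoch_a)].albedo
        for s in SEASONS
    }
    strata = chg.fire_strata(class_r)
    report = chg.stratified_summary(
        deltas, sig, dalbedo, forcings, strata, mask, truth.pixel_size
    )
    regional = None
    if config.split_regions:
        regional = chg.regional_summary(
            default_regions(shape), deltas, sig, dalbedo, forcings, mask, truth.pixel_size
        )
    return report, regional, amask, year_r, class_r


def recovery_stats(
    truth: syn.LandscapeTruth, result: CoverResult, config: PipelineConfig
) -> dict:
    """Map accuracy against synthetic truth on the tree-dominated domain.

    Evaluated on pixels with true canopy cover at or above the
    tree-dominated threshold: below it the background signal dominates the
    spectral mixture and composition is not identifiable, which is why the
    analysis itself is masked to tree-dominated pixels.
    """
    out = {}
    for epoch, cover_map in result.maps.items():
        dec_t, cov_t = syn.evaluate_composition(truth, epoch)
        target = dec_t if result.response == "deciduous_fraction" else cov_t
        ok = cover_map.valid_mask & np.isfinite(cover_map.estimate)
        ok &= cov_t >= config.tree_cover_threshold
        err = cover_map.estimate[ok] - target[ok]
        ss_tot = float(np.sum((target[ok] - target[ok].mean()) ** 2))
        out[epoch] = {
            "rmse": float(np.sqrt(np.mean(err**2))),
            "r2": 1.0 - float(np.sum(err**2)) / ss_tot if ss_tot > 0 else float("nan"),
            "n": int(ok.sum()),
            "three_season_share": cover_map.three_season_share(),
        }
    return out


# ------------------------------------------------------------- orchestration


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: PipelineConfig | None = None,
    outdir: str | Path | None = None,
    resume: bool = False,
) -> PipelineResult:
    """Execute the full pipeline; optionally write artifacts to ``outdir``.

    With ``resume=True``, stages whose artifact files already exist in
    ``outdir`` are not re-written (the computation itself is re-derived
    deterministically from config and seed).
    """
    config = config if config is not None else PipelineConfig()
    config.validate()
    outpath = Path(outdir) if outdir is not None else None
    if outpath is not None:
        outpath.mkdir(parents=True, exist_ok=True)

    log.info("stage simulate")
    truth = simulate(config)
    grid = GridSpec(shape=truth.grid_shape, pixel_size=truth.pixel_size)

    log.info("stage composite")
    stacks = {epoch: build_stack(truth, config, epoch) for epoch in config.epochs}
    features3, features1 = select_features(stacks[config.epochs[0]], config)

    log.info("stage train/predict deciduous fraction")
    dec = train_deciduous(truth, stacks, features3, features1, config)
    log.info("stage train/predict tree canopy cover")
    canopy, reference = train_canopy(truth, stacks, features3, features1, config)

    log.info("stage albedo & forcing")
    albedo_models, albedo_maps, kernels, forcings = albedo_and_forcing(
        truth, dec.maps, canopy.maps, config
    )

    log.info("stage change report")
    report, regional, amask, year_r, class_r = change_report(
        truth, dec, canopy, albedo_maps, forcings, config
    )

    recovery = {
        "deciduous_fraction": recovery_stats(truth, dec, config),
        "tree_canopy_cover": recovery_stats(truth, canopy, config),
    }

    result = PipelineResult(
        config=config,
        truth=truth,
        stacks=stacks,
        dec=dec,
        canopy=canopy,
        albedo_models=albedo_models,
        albedo_maps=albedo_maps,
        kernels=kernels,
        forcings=forcings,
        mask=amask,
        fire_year_raster=year_r,
        fire_class_raster=class_r,
        report=report,
        regional_report=regional,
        recovery=recovery,
        outdir=outpath,
    )
    if outpath is not None:
        _write_artifacts(result, grid, resume=resume)
    return result


def _write_artifacts(result: PipelineResult, grid: GridSpec, resume: bool) -> None:
    out = result.outdir
    cfg = result.config

    def fresh(path: Path) -> bool:
        return not (resume and path.exists())

    if fresh(out / "config.yaml"):
        cfg.to_yaml(out / "config.yaml")
    if fresh(out / "fires.geojson"):
        vectors.write_fires(out / "fires.geojson", result.truth.fires)
    for res in (result.dec, result.canopy):
        for epoch, cover_map in res.maps.items():
            path = out / f"{res.response}_{epoch}.tif"
            if fresh(path):
                write_raster(
                    path,
                    np.stack(
                        [
                            cover_map.estimate,
                            cover_map.uncertainty,
                            cover_map.source_mode.astype(np.float32),
                        ]
                    ),
                    grid,
                )
    for season, fmap in result.forcings.items():
        path = out / f"forcing_{season}.tif"
        if fresh(path):
            write_raster(path, fmap.forcing, grid)
    if fresh(out / "report.csv"):
        result.report.to_csv(out / "report.csv", index=False, float_format="%.10g")
    if result.regional_report is not None and fresh(out / "regional_report.csv"):
        result.regional_report.to_csv(
            out / "regional_report.csv", index=False, float_format="%.10g"
        )
    if fresh(out / "stats.json"):
        stats = {
            "recovery": {k: {str(e): v for e, v in d.items()} for k, d in result.recovery.items()},
            "dec_cv": result.dec.spec3.cv_stats,
            "dec_validation": result.dec.validation,
            "canopy_cv": result.canopy.spec3.cv_stats,
            "canopy_validation": result.canopy.validation,
            "albedo_models": {
                s: {"importances": m["importances"], "cv_r2": m["cv_r2"]}
                for s, m in result.albedo_models.items()
            },
        }
        (out / "stats.json").write_text(json.dumps(stats, indent=2))
    manifest = {
        "seed": cfg.seed,
        "epochs": list(cfg.epochs),
        "artifacts": {
            p.name: _sha256(p)
            for p in sorted(out.iterdir())
            if p.suffix in {".csv", ".json", ".yaml", ".geojson"}
            and p.name != "manifest.json"
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
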