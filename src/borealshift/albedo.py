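"""Seasonal albedo modelling and kernel-based radiative forcing.

Daily blue-sky albedo rasters (already screened for solar zenith angle by
their validity masks) are composited to per-pixel seasonal medians,
downscaled from the coarse albedo grid to the analysis grid by bicubic
convolution, and used to train a two-predictor ensemble model
albedo = f(deciduous fraction, tree canopy cover) per season from
stratified samples within 0.1 albedo intervals.  Epoch-to-epoch change in
modelled albedo times the (negative) all-sky radiative kernel gives the
shortwave radiative forcing:

    RF = (alpha_end - alpha_start) * K      [W m^-2]

so an albedo increase yields a negative forcing (biophysical cooling).
The non-winter aggregate is the unweighted mean of the spring, summer and
fall maps on their common mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ensemble as ens
from .cover_mapping import CoverMap

log = logging.getLogger(__name__)

ALBEDO_PREDICTORS = ("deciduous_fraction", "tree_canopy_cover")

DEFAULT_ALBEDO_GRID = {
    "n_trees": [100],
    "max_features": [1.0],
    "min_samples_split": [2, 5],
    "min_samples_leaf": [1, 3],
}


@dataclass
class SeasonalAlbedo:
    """Seasonal albedo raster at analysis resolution with a validity mask."""

    season: str
    epoch: int
    albedo: np.ndarray
    valid_mask: np.ndarray


@dataclass
class KernelField:
    """Radiative kernel at analysis resolution, W m^-2 per unit albedo.

    Negative by convention: raising albedo reduces absorbed shortwave.
    """

    season: str
    kernel: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.kernel)):
            raise ValueError("kernel must be finite everywhere")


@dataclass
class ForcingMap:
    """Per-pixel shortwave forcing between two epochs for one season."""

    season: str
    period: tuple[int, int]
    forcing: np.ndarray  # NaN where masked
    valid_mask: np.ndarray


def seasonal_albedo_composite(
    days: np.ndarray,
    valid: np.ndarray,
    season: str,
    epoch: int = 0,
) -> SeasonalAlbedo:
    """Per-pixel median over valid days; invalid where no day is valid."""
    days = np.asarray(days, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    if days.ndim != 3 or days.shape != valid.shape:
        raise ValueError(
            f"days {days.shape} and validity {valid.shape} must be (n_days, rows, cols)"
        )
    stack = np.where(valid, days, np.nan)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels are masked below
        med = np.nanmedian(stack, axis=0)
    mask = valid.any(axis=0)
    med = np.where(mask, med, np.nan)
    return SeasonalAlbedo(season=season, epoch=epoch, albedo=med, valid_mask=mask)


def _keys_weights(frac: np.ndarray, a: float = -0.5) -> np.ndarray:
    """Keys bicubic convolution weights for the 4 taps at offsets -1..2."""
    # kernel: (a+2)|x|^3-(a+3)|x|^2+1 for |x|<=1; a|x|^3-5a|x|^2+8a|x|-4a for 1<|x|<2
    x = np.stack([frac + 1.0, frac, 1.0 - frac, 2.0 - frac])
    ax = np.abs(x)
    w_near = (a + 2.0) * ax**3 - (a + 3.0) * ax**2 + 1.0
    w_far = a * ax**3 - 5.0 * a * ax**2 + 8.0 * a * ax - 4.0 * a
    return np.where(ax <= 1.0, w_near, np.where(ax < 2.0, w_far, 0.0))


def _axis_matrix(n_coarse: int, factor: int) -> np.ndarray:
    """(n_fine, n_coarse) bicubic interpolation matrix along one axis.

    Fine sample i maps to coarse coordinate (i + 0.5)/factor - 0.5 (cell
    centres aligned); edge taps are clamped (replicated boundary).
    """
    n_fine = n_coarse * factor
    u = (np.arange(n_fine) + 0.5) / factor - 0.5
    base = np.floor(u).astype(int)
    frac = u - base
    w = _keys_weights(frac)  # (4, n_fine)
    mat = np.zeros((n_fine, n_coarse))
    for tap in range(4):
        idx = np.clip(base + tap - 1, 0, n_coarse - 1)
        np.add.at(mat, (np.arange(n_fine), idx), w[tap])
    return mat


def downscale(
    coarse: np.ndarray, factor: int, clip_range: tuple[float, float] | None = None
) -> np.ndarray:
    """Bicubic-convolution interpolation from a coarse to a fine grid.

    ``factor`` is the integer resolution ratio (e.g. 16 for 500 m -> ~30 m).
    ``clip_range`` clips the output to a physical range (used for albedo;
    kernels are not clipped).
    """
    coarse = np.asarray(coarse, dtype=float)
    if int(factor) != factor or factor < 1:
        raise ValueError(f"scale factor must be a positive integer, got {factor}")
    if factor == 1:
        out = coarse.copy()
    else:
        wr = _axis_matrix(coarse.shape[0], int(factor))
        wc = _axis_matrix(coarse.shape[1], int(factor))
        out = wr @ coarse @ wc.T
    if clip_range is not None:
        out = np.clip(out, *clip_range)
    return out


def sample_albedo_training(
    albedo: SeasonalAlbedo,
    dec_map: CoverMap,
    cover_map: CoverMap,
    bin_width: float = 0.1,
    n_per_bin: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Stratified training sample within each 0.1 albedo interval.

    Records carry (deciduous_fraction, tree_canopy_cover, albedo); at most
    ``n_per_bin`` per bin, seeded.
    """
    ok = albedo.valid_mask & dec_map.valid_mask & cover_map.valid_mask
    ok &= np.isfinite(albedo.albedo)
    if not ok.any():
        raise ValueError("no valid pixels shared by albedo and cover maps")
    n_bins = int(round(1.0 / bin_width))
    vals = albedo.albedo
    strata = np.clip((vals * n_bins).astype(int), 0, n_bins - 1)
    rng = np.random.default_rng(seed)
    rows, cols = [], []
    for b in range(n_bins):
        members = np.argwhere(ok & (strata == b))
        if len(members) == 0:
            continue
        pick = rng.choice(len(members), size=min(n_per_bin, len(members)), replace=False)
        rows.append(members[pick, 0])
        cols.append(members[pick, 1])
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    return pd.DataFrame(
        {
            "deciduous_fraction": dec_map.estimate[r, c],
            "tree_canopy_cover": cover_map.estimate[r, c],
            "albedo": vals[r, c],
            "row": r,
            "col": c,
        }
    )


def fit_albedo_model(
    records: pd.DataFrame,
    hyperparams: dict | None = None,
    seed: int = 0,
    folds: int = 5,
) -> tuple[ens.BaggedTreeEnsemble, dict, float]:
    """Fit the two-predictor seasonal albedo ensemble.

    Returns (model, per-predictor importance shares, cross-validated r^2).
    Importances are impurity-reduction shares averaged over trees.
    """
    if len(records) < 50:
        raise ValueError(f"need >= 50 albedo training records, got {len(records)}")
    X = records[list(ALBEDO_PREDICTORS)].to_numpy(dtype=float)
    y = records["albedo"].to_numpy(dtype=float)
    if np.any(X.std(axis=0) == 0):
        const = [p for p, s in zip(ALBEDO_PREDICTORS, X.std(axis=0)) if s == 0]
        raise ValueError(f"degenerate (constant) predictors: {const}")
    if hyperparams is None:
        hyperparams = {
            "n_trees": 100,
            "max_features": 1.0,
            "min_samples_split": 5,
            "min_samples_leaf": 2,
        }
    stats = ens.cross_validate(X, y, hyperparams, folds=folds, repeats=1, seed=seed)
    model = ens.BaggedTreeEnsemble(random_state=seed, **hyperparams).fit(X, y)
    imp = model.feature_importances_
    importances = dict(zip(ALBEDO_PREDICTORS, (imp / imp.sum()).tolist()))
    return model, importances, stats["mean_r2"]


def predict_albedo(
    model: ens.BaggedTreeEnsemble,
    dec_map: CoverMap,
    cover_map: CoverMap,
    season: str,
    mask: np.ndarray | None = None,
) -> SeasonalAlbedo:
    """Predict seasonal albedo from composition maps on the analysis mask."""
    ok = dec_map.valid_mask & cover_map.valid_mask
    if mask is not None:
        ok &= mask
    shape = ok.shape
    out = np.full(shape, np.nan)
    if ok.any():
        X = np.column_stack([dec_map.estimate[ok], cover_map.estimate[ok]])
        out[ok] = model.predict(X)
    return SeasonalAlbedo(season=season, epoch=dec_map.epoch, albedo=out, valid_mask=ok)


def radiative_forcing(
    albedo_start: SeasonalAlbedo,
    albedo_end: SeasonalAlbedo,
    kernel: KernelField,
) -> ForcingMap:
    """Forcing = (albedo_end - albedo_start) * kernel, per pixel."""
    if albedo_start.season != albedo_end.season or albedo_start.season != kernel.season:
        raise ValueError(
            f"season mismatch: {albedo_start.season}/{albedo_end.season}/{kernel.season}"
        )
    if albedo_start.albedo.shape != albedo_end.albedo.shape or (
        kernel.kernel.shape != albedo_start.albedo.shape
    ):
        raise ValueError("forcing inputs are not co-registered")
    mask = albedo_start.valid_mask & albedo_end.valid_mask
    forcing = np.where(mask, (albedo_end.albedo - albedo_start.albedo) * kernel.kernel, np.nan)
    return ForcingMap(
        season=kernel.season,
        period=(albedo_start.epoch, albedo_end.epoch),
        forcing=forcing,
        valid_mask=mask,
    )


def nonwinter_mean(forcings: dict[str, ForcingMap]) -> ForcingMap:
    """Unweighted mean of the three seasonal forcing maps on the common mask."""
    maps = [forcings[s] for s in ("spring", "summer", "fall")]
    mask = maps[0].valid_mask & maps[1].valid_mask & maps[2].valid_mask
    mean = np.where(mask, np.mean([m.forcing for m in maps], axis=0), np.nan)
    return ForcingMap(
        season="nonwinter", period=maps[0].period, forcing=mean, valid_mask=mask
    )
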