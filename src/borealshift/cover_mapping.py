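"""Fractional cover mapping with leaf-spread uncertainty.

Trains, selects and applies ensemble-regression models for two fractional
responses — deciduous fraction (from inventory plots) and tree canopy
cover (from a stratified sample of a reference cover raster) — and
produces per-pixel estimate and uncertainty rasters.

Two model modes are fitted per response: a three-season model using all
spectral/index layers of spring, summer and fall plus terrain, and a
one-season fallback using only summer and terrain layers.  The
three-season model scores pixels where all three seasonal composites are
valid; the one-season model fills pixels with a valid summer composite
only; the remainder is nodata.  The fraction of the domain scored by the
three-season model is logged (the real-data analogue ran 83.6-91.2%
three-season).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import ensemble as ens
from .compositing import BANDS, INDICES, TERRAIN, FeatureStack

log = logging.getLogger(__name__)

SOURCE_NODATA, SOURCE_THREE_SEASON, SOURCE_ONE_SEASON = 0, 1, 2

ONE_SEASON_LAYERS = tuple(f"summer_{n}" for n in BANDS + INDICES) + TERRAIN


@dataclass
class CoverMap:
    """Per-pixel fractional estimate with paired leaf-spread uncertainty."""

    response: str
    epoch: int
    estimate: np.ndarray  # NaN at nodata
    uncertainty: np.ndarray  # NaN at nodata
    source_mode: np.ndarray  # uint8, SOURCE_* codes

    @property
    def valid_mask(self) -> np.ndarray:
        return self.source_mode != SOURCE_NODATA

    def three_season_share(self) -> float:
        """Share of scored pixels predicted by the three-season model."""
        scored = self.valid_mask.sum()
        if scored == 0:
            return float("nan")
        return float((self.source_mode == SOURCE_THREE_SEASON).sum() / scored)


def one_season_features(features: list[str]) -> list[str]:
    """Restrict a retained-feature list to summer + terrain layers."""
    return [f for f in features if f in ONE_SEASON_LAYERS]


def grid_search(
    records: pd.DataFrame,
    features: list[str],
    response: str,
    mode: str = "three_season",
    grid: dict | None = None,
    folds: int = 5,
    repeats: int = 3,
    seed: int = 0,
) -> ens.ModelSpec:
    """Select hyperparameters by repeated cross-validated grid search."""
    if mode == "one_season":
        features = one_season_features(features)
    elif mode != "three_season":
        raise ValueError(f"unknown mode {mode!r}")
    X = records[features].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    hp, stats = ens.grid_search(X, y, grid=grid, folds=folds, repeats=repeats, seed=seed)
    return ens.ModelSpec(
        response=response,
        mode=mode,
        features=list(features),
        hyperparams=hp,
        cv_stats=stats,
        seed=seed,
    )


def fit(records: pd.DataFrame, spec: ens.ModelSpec) -> ens.BaggedTreeEnsemble:
    """Fit the bagged ensemble described by ``spec`` on training records."""
    missing = [f for f in spec.features if f not in records.columns]
    if missing:
        raise ValueError(f"features missing from records: {missing}")
    X = records[spec.features].to_numpy(dtype=float)
    y = records[spec.response].to_numpy(dtype=float)
    model = ens.BaggedTreeEnsemble(random_state=spec.seed, **spec.hyperparams)
    return model.fit(X, y)


def leaf_uncertainty(model: ens.BaggedTreeEnsemble, X: np.ndarray) -> np.ndarray:
    """Pooled leaf-spread sd for feature rows X (see ensemble module)."""
    return model.leaf_uncertainty(np.atleast_2d(X))


def predict_map(
    three_model: ens.BaggedTreeEnsemble,
    one_model: ens.BaggedTreeEnsemble,
    stack: FeatureStack,
    three_features: list[str],
    one_features: list[str],
    response: str,
) -> CoverMap:
    """Score a feature stack: three-season where complete, summer-only fallback.

    Both fitted models must be supplied; pixels valid in neither mask are
    nodata.
    """
    bad = [f for f in one_features if f not in ONE_SEASON_LAYERS]
    if bad:
        raise ValueError(f"one-season model may not use non-summer layers: {bad}")
    shape = stack.complete_mask.shape
    estimate = np.full(shape, np.nan)
    uncertainty = np.full(shape, np.nan)
    source = np.zeros(shape, dtype=np.uint8)

    three_mask = stack.complete_mask
    one_mask = stack.summer_mask & ~three_mask
    if not three_mask.any() and not one_mask.any():
        log.warning("no pixels valid in any season: empty cover map")
    if three_mask.any():
        X = stack.matrix(three_features, three_mask)
        est, sd = three_model.predict_with_uncertainty(X)
        estimate[three_mask] = np.clip(est, 0.0, 1.0)
        uncertainty[three_mask] = sd
        source[three_mask] = SOURCE_THREE_SEASON
    if one_mask.any():
        X = stack.matrix(one_features, one_mask)
        est, sd = one_model.predict_with_uncertainty(X)
        estimate[one_mask] = np.clip(est, 0.0, 1.0)
        uncertainty[one_mask] = sd
        source[one_mask] = SOURCE_ONE_SEASON
    cover = CoverMap(
        response=response,
        epoch=stack.epoch,
        estimate=estimate,
        uncertainty=uncertainty,
        source_mode=source,
    )
    if cover.valid_mask.any():
        log.info(
            "%s epoch %d: %.1f%% of scored pixels used the three-season model",
            response,
            stack.epoch,
            100.0 * cover.three_season_share(),
        )
    return cover


def validate(
    model: ens.BaggedTreeEnsemble,
    records: pd.DataFrame,
    features: list[str],
    response: str,
) -> dict:
    """Adjusted r^2 and RMSE on (thinned) held-out records.

    Adjusts for the retained-feature count; if n <= features + 1 the
    adjustment is undefined and plain r^2 is reported with a flag.
    """
    X = records[features].to_numpy(dtype=float)
    y = records[response].to_numpy(dtype=float)
    pred = model.predict(X)
    n, p = len(y), len(features)
    r2 = ens._r2(y, pred)
    out = {"rmse": ens._rmse(y, pred), "n": n, "adjusted": False}
    if n > p + 1 and np.isfinite(r2):
        out["r2"] = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
        out["adjusted"] = True
    else:
        out["r2"] = r2
        log.warning("n=%d too small to adjust r^2 for %d features; plain r^2 reported", n, p)
    return out


def train_canopy_reference(
    reference: np.ndarray,
    n_per_stratum: int,
    n_strata: int = 10,
    seed: int = 0,
    valid_mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Stratified random sample of a reference tree-cover raster.

    Strata are ``n_strata`` equal-width cover bins; empty strata are
    logged and skipped.  Returns (row, col, tree_canopy_cover) records.
    """
    reference = np.asarray(reference, dtype=float)
    ok = np.isfinite(reference)
    if valid_mask is not None:
        ok &= valid_mask
    strata = np.minimum((reference * n_strata).astype(int), n_strata - 1)
    rng = np.random.default_rng(seed)
    rows, cols = [], []
    for s in range(n_strata):
        members = np.argwhere(ok & (strata == s))
        if len(members) == 0:
            log.info("canopy stratum %d/%d is empty; skipped", s, n_strata)
            continue
        pick = rng.choice(len(members), size=min(n_per_stratum, len(members)), replace=False)
        rows.append(members[pick, 0])
        cols.append(members[pick, 1])
    if not rows:
        raise ValueError("reference raster has no valid pixels to sample")
    r = np.concatenate(rows)
    c = np.concatenate(cols)
    return pd.DataFrame(
        {"row": r, "col": c, "tree_canopy_cover": reference[r, c]}
    )
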