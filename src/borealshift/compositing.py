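"""Seasonal compositing and the 36-feature predictor stack.

Per epoch, three seasonal composites (spring: March-May, summer:
June-August, fall: September-November membership decided upstream) are
built by per-pixel selection of the date whose NDVI is the order-statistic
median among that pixel's clear observations; the selected date's band
values are carried through together, which keeps each pixel's spectrum
physically consistent.  Even counts take the lower median date.

From each composite, five vegetation indices are derived:

    NDVI = (NIR - Red) / (NIR + Red)
    NDWI = (NIR - SWIR1) / (NIR + SWIR1)        (moisture variant)
    SAVI = 1.5 * (NIR - Red) / (NIR + Red + 0.5)
    VARI = (Green - Red) / (Green + Red - Blue)
    EVI  = 2.5 * (NIR - Red) / (NIR + 6*Red - 7.5*Blue + 1)

Together with Horn slope, elevation and aspect, the predictor stack holds
3 seasons x (6 bands + 5 indices) + 3 terrain layers = 36 named layers in
a frozen registry order, so fitted models are portable across runs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .synthetic import BANDS, SEASONS

log = logging.getLogger(__name__)

INDICES = ("ndvi", "ndwi", "savi", "vari", "evi")
TERRAIN = ("slope", "elevation", "aspect")

#: Frozen layer order: per season its 6 bands then 5 indices, then terrain.
LAYER_NAMES: tuple[str, ...] = tuple(
    f"{season}_{name}" for season in SEASONS for name in BANDS + INDICES
) + TERRAIN

assert len(LAYER_NAMES) == 36


@dataclass
class SeasonalComposite:
    """Median-value composite of one season for one nominal epoch."""

    season: str
    epoch: int
    bands: np.ndarray  # (6, rows, cols), NaN where invalid
    valid_mask: np.ndarray  # (rows, cols) bool

    def band(self, name: str) -> np.ndarray:
        if name not in BANDS:
            raise KeyError(f"missing band {name!r}; composite bands are {BANDS}")
        return self.bands[BANDS.index(name)]


@dataclass
class FeatureStack:
    """Ordered 36-layer predictor raster for one epoch."""

    epoch: int
    layers: np.ndarray  # (36, rows, cols)
    names: tuple[str, ...]
    complete_mask: np.ndarray  # all three seasons valid
    summer_mask: np.ndarray  # summer valid

    def __post_init__(self) -> None:
        if len(self.names) != 36 or self.layers.shape[0] != 36:
            raise ValueError(f"feature stack must hold 36 layers, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        if np.any(self.complete_mask & ~self.summer_mask):
            raise ValueError("complete_mask must be a subset of summer_mask")

    def layer(self, name: str) -> np.ndarray:
        try:
            return self.layers[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no layer named {name!r}") from None

    def matrix(self, names: list[str] | tuple[str, ...], mask: np.ndarray) -> np.ndarray:
        """Feature matrix (n_pixels, n_features) over the masked pixels,
        rows in C scan order of the mask."""
        idx = [self.names.index(n) for n in names]
        return self.layers[idx][:, mask].T


def export_registry(path) -> None:
    """Write the frozen layer-order registry as a JSON sidecar."""
    with open(path, "w") as fh:
        json.dump({"layer_names": list(LAYER_NAMES)}, fh, indent=2)


def _ndvi(bands: np.ndarray) -> np.ndarray:
    nir = bands[..., BANDS.index("nir"), :, :]
    red = bands[..., BANDS.index("red"), :, :]
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, np.nan)
    return out


def median_composite(dates, season: str | None = None, epoch: int | None = None) -> SeasonalComposite:
    """Compose multi-date band stacks by per-pixel median-NDVI date selection.

    ``dates`` is a ReflectanceStack-like object with ``bands``
    (n_dates, 6, rows, cols) and ``valid`` (n_dates, rows, cols); pixels
    with zero valid dates are masked out.
    """
    bands = np.asarray(dates.bands, dtype=float)
    valid = np.asarray(dates.valid, dtype=bool)
    if bands.ndim != 4 or bands.shape[1] != len(BANDS):
        raise ValueError(f"expected bands shaped (n_dates, 6, rows, cols), got {bands.shape}")
    if valid.shape != (bands.shape[0],) + bands.shape[2:]:
        raise ValueError(
            f"validity shape {valid.shape} does not match bands {bands.shape}"
        )
    season = season if season is not None else dates.season
    epoch = epoch if epoch is not None else getattr(dates, "year", 0)
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}")

    ndvi = _ndvi(bands)
    usable = valid & np.isfinite(ndvi)
    key = np.where(usable, ndvi, np.inf)
    order = np.argsort(key, axis=0, kind="stable")
    k = usable.sum(axis=0)
    med_rank = np.clip((k - 1) // 2, 0, None)
    sel = np.take_along_axis(order, med_rank[None], axis=0)[0]  # (rows, cols)
    sel_b = np.broadcast_to(sel[None, None], (1,) + bands.shape[1:])
    out = np.take_along_axis(bands, sel_b, axis=0)[0]
    mask = k > 0
    out = np.where(mask[None], out, np.nan)
    return SeasonalComposite(season=season, epoch=int(epoch), bands=out, valid_mask=mask)


def compute_indices(composite: SeasonalComposite) -> dict[str, np.ndarray]:
    """Five vegetation index layers; zero-denominator pixels become NaN."""
    if composite.bands.shape[0] != len(BANDS):
        raise ValueError(
            f"composite must carry all 6 bands {BANDS}, got {composite.bands.shape[0]}"
        )
    blue = composite.band("blue")
    green = composite.band("green")
    red = composite.band("red")
    nir = composite.band("nir")
    swir1 = composite.band("swir1")

    def safe(num, den):
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(den != 0, num / den, np.nan)

    return {
        "ndvi": safe(nir - red, nir + red),
        "ndwi": safe(nir - swir1, nir + swir1),
        "savi": 1.5 * safe(nir - red, nir + red + 0.5),
        "vari": safe(green - red, green + red - blue),
        "evi": 2.5 * safe(nir - red, nir + 6.0 * red - 7.5 * blue + 1.0),
    }


def terrain_layers(
    dem: np.ndarray, pixel_size: float = 30.0
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Slope, elevation and aspect from a DEM via Horn's 3x3 method.

    Slope and aspect in degrees; aspect is compass degrees clockwise from
    north of the downslope direction, with flat cells set to 0 by
    convention.  Edge cells use edge-replicated padding.
    """
    dem = np.asarray(dem, dtype=float)
    if not np.all(np.isfinite(dem)):
        raise ValueError("dem must be finite")
    if dem.ndim != 2 or dem.shape[0] < 3 or dem.shape[1] < 3:
        raise ValueError(f"dem must be at least 3x3, got {dem.shape}")
    z = np.pad(dem, 1, mode="edge")
    a, b, c = z[:-2, :-2], z[:-2, 1:-1], z[:-2, 2:]
    d, f = z[1:-1, :-2], z[1:-1, 2:]
    g, h, i = z[2:, :-2], z[2:, 1:-1], z[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + g)) / (8.0 * pixel_size)
    dzdy = ((g + 2 * h + i) - (a + 2 * b + c)) / (8.0 * pixel_size)
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(dzdy, -dzdx))
    aspect = np.mod(90.0 - aspect, 360.0)
    aspect[slope == 0] = 0.0
    return slope, dem.copy(), aspect


def assemble_stack(
    spring: SeasonalComposite,
    summer: SeasonalComposite,
    fall: SeasonalComposite,
    terrain: tuple[np.ndarray, np.ndarray, np.ndarray],
) -> FeatureStack:
    """Assemble the 36-layer stack in registry order for one epoch."""
    comps = {"spring": spring, "summer": summer, "fall": fall}
    shape = spring.bands.shape[1:]
    for name, comp in comps.items():
        if comp.season != name:
            raise ValueError(f"composite in {name} slot has season {comp.season!r}")
        if comp.bands.shape[1:] != shape:
            raise ValueError(
                f"shape mismatch: {name} composite {comp.bands.shape[1:]} vs {shape}"
            )
    slope, elevation, aspect = terrain
    if slope.shape != shape:
        raise ValueError(f"terrain shape {slope.shape} does not match {shape}")

    layers = np.empty((36,) + shape)
    pos = 0
    for season in SEASONS:
        comp = comps[season]
        indices = compute_indices(comp)
        for band in BANDS:
            layers[pos] = comp.band(band)
            pos += 1
        for idx in INDICES:
            layers[pos] = indices[idx]
            pos += 1
    for arr in (slope, elevation, aspect):
        layers[pos] = arr
        pos += 1

    complete = spring.valid_mask & summer.valid_mask & fall.valid_mask
    # degenerate index denominators make a spectral layer NaN: drop from masks
    spectral_ok = np.isfinite(layers[:33]).all(axis=0)
    complete &= spectral_ok
    summer_idx = [LAYER_NAMES.index(f"summer_{n}") for n in BANDS + INDICES]
    summer_ok = np.isfinite(layers[summer_idx]).all(axis=0)
    summer_mask = summer.valid_mask & summer_ok
    complete &= summer_mask
    epochs = {spring.epoch, summer.epoch, fall.epoch}
    if len(epochs) != 1:
        raise ValueError(f"composites span multiple epochs: {sorted(epochs)}")
    return FeatureStack(
        epoch=spring.epoch,
        layers=layers,
        names=LAYER_NAMES,
        complete_mask=complete,
        summer_mask=summer_mask,
    )


def prune_correlated(
    names: tuple[str, ...] | list[str],
    samples: np.ndarray,
    threshold: float = 0.95,
) -> list[str]:
    """Greedy correlation pruning over a pixel sample.

    Scans layers in the fixed registry order and drops a layer iff its
    absolute Pearson correlation with any already-retained layer exceeds
    ``threshold``.  Zero-variance layers are retained and flagged in the
    log (their correlation is undefined).  Deterministic for a fixed
    sample; invariant to sample row order.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[0] < 2:
        raise ValueError(f"need a (n>=2, n_layers) sample matrix, got {samples.shape}")
    if samples.shape[1] != len(names):
        raise ValueError(
            f"sample has {samples.shape[1]} columns but {len(names)} names given"
        )
    sd = samples.std(axis=0)
    retained: list[int] = []
    for j in range(samples.shape[1]):
        if sd[j] == 0:
            log.warning("layer %s has zero variance in the pruning sample; retained", names[j])
            retained.append(j)
            continue
        drop = False
        for k in retained:
            if sd[k] == 0:
                continue
            r = np.corrcoef(samples[:, j], samples[:, k])[0, 1]
            if abs(r) > threshold:
                drop = True
                break
        if not drop:
            retained.append(j)
    return [names[j] for j in retained]
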