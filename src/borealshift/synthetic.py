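"""Seeded synthetic boreal landscapes.

Generates ground truth (deciduous fraction, tree canopy cover, fire
history, terrain), and renders from it the observational inputs the
downstream analysis expects: multi-date seasonal surface reflectance with
cloud masks, forest-inventory plot tables, coarse seasonal albedo with a
validity screen, and negative-valued albedo radiative kernels.

The forward models encode the structure the analysis assumes:

* Post-fire succession follows relay floristics.  Canopy cover recovers as
  a saturating exponential ``c0 * (1 - exp(-t / tau_c))``; deciduous
  fraction pulses up early and relaxes toward an evergreen-dominated late
  state, ``d_late + (d_peak - d_late) * (t / tau_d) * exp(1 - t / tau_d)``,
  which peaks at exactly ``d_peak`` when ``t == tau_d``.
* Reflectance is a linear mixture of deciduous, evergreen and background
  endmembers weighted by composition, with the deciduous/evergreen
  near-infrared contrast largest in summer (leaf-on) and smallest in
  spring (leaf-off).
* Albedo increases with deciduous fraction in every season and decreases
  with canopy cover outside summer (canopy masking of snow), via
  ``alpha = b0 + b_d*d + b_c*c + b_dc*d*c`` per season.
* Kernels are smooth negative fields (raising albedo reduces absorbed
  shortwave radiation at the top of the atmosphere).

Every generator is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter
from shapely.geometry import Polygon
from shapely.geometry.base import BaseGeometry

from .geom import covered_mask

SEASONS = ("spring", "summer", "fall")
BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")
ENDMEMBER_NAMES = ("deciduous", "evergreen", "background")

# Reflectance endmembers, shape (endmember, season, band) with the orders
# above.  Chosen so the summer NIR of the deciduous endmember exceeds the
# evergreen one (0.45 vs 0.25) and the contrast shrinks in leaf-off spring
# (0.22 vs 0.18); the spring background is bright (residual snow / litter).
DEFAULT_ENDMEMBERS = np.array(
    [
        [  # deciduous
            [0.06, 0.08, 0.09, 0.22, 0.20, 0.14],  # spring (leaf-off)
            [0.04, 0.08, 0.05, 0.45, 0.22, 0.12],  # summer (leaf-on)
            [0.05, 0.09, 0.10, 0.30, 0.22, 0.14],  # fall (senescing)
        ],
        [  # evergreen
            [0.04, 0.06, 0.06, 0.18, 0.14, 0.08],
            [0.03, 0.05, 0.04, 0.25, 0.13, 0.07],
            [0.04, 0.06, 0.05, 0.20, 0.12, 0.07],
        ],
        [  # background
            [0.30, 0.32, 0.34, 0.38, 0.30, 0.25],
            [0.10, 0.14, 0.16, 0.25, 0.30, 0.28],
            [0.12, 0.15, 0.17, 0.24, 0.28, 0.26],
        ],
    ]
)

# Seasonal albedo response to composition: alpha = b0 + b_d*d + b_c*c + b_dc*d*c.
# b_d > 0 every season; b_c < 0 with the largest magnitude in spring, when
# the canopy masks snow most; |b_dc| < |b_c| keeps d(alpha)/dc < 0 for all d
# in spring and fall.
DEFAULT_ALBEDO_COEFFS = {
    "spring": {"b0": 0.62, "b_d": 0.10, "b_c": -0.38, "b_dc": 0.05},
    "summer": {"b0": 0.16, "b_d": 0.06, "b_c": -0.04, "b_dc": 0.0},
    "fall": {"b0": 0.40, "b_d": 0.08, "b_c": -0.20, "b_dc": 0.03},
}

# Synthetic all-sky kernel magnitudes, W m^-2 per unit albedo increase.
DEFAULT_KERNEL_MEANS = {"spring": -120.0, "summer": -150.0, "fall": -70.0}

FIRE_YEAR_MIN, FIRE_YEAR_MAX = 1950, 2018

# RNG stream tags so each renderer draws from an independent substream.
_TAG = {"truth": 1, "reflectance": 2, "plots": 3, "albedo": 4, "kernel": 5}
_SEASON_TAG = {s: i for i, s in enumerate(SEASONS)}


class ConfigurationError(ValueError):
    """A generation parameter is out of its valid range."""


def _rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), *map(int, tags)])


@dataclass(frozen=True)
class FireEvent:
    """A dated fire perimeter in grid coordinates."""

    polygon: BaseGeometry
    year: int


@dataclass
class GenerationConfig:
    """Parameters of the synthetic landscape.

    Succession defaults (tau_c=25 y, tau_d=15 y, d_peak=0.75, d_late=0.10)
    give a deciduous pulse peaking 15 years post-fire and canopy closure on
    a ~25-year e-folding scale, consistent with boreal relay floristics.
    """

    grid_shape: tuple[int, int] = (256, 256)
    pixel_size: float = 30.0
    blur_sigma: float = 8.0
    dec_base_mean: float = 0.35
    dec_base_sd: float = 0.15
    cover_base_mean: float = 0.60
    cover_base_sd: float = 0.15
    n_fires: int = 24
    fire_year_range: tuple[int, int] = (FIRE_YEAR_MIN, FIRE_YEAR_MAX)
    fire_radius_range: tuple[float, float] = (10.0, 45.0)
    tau_c: float = 25.0
    tau_d: float = 15.0
    d_peak: float = 0.75
    d_late: float = 0.10
    dem_mean: float = 300.0
    dem_relief: float = 120.0
    albedo_invalid_fraction: float = 0.05
    kernel_rel_sd: float = 0.08
    endmembers: np.ndarray = field(
        default_factory=lambda: DEFAULT_ENDMEMBERS.copy()
    )
    albedo_coeffs: dict = field(
        default_factory=lambda: {s: dict(c) for s, c in DEFAULT_ALBEDO_COEFFS.items()}
    )
    kernel_means: dict = field(default_factory=lambda: dict(DEFAULT_KERNEL_MEANS))

    def validate(self) -> None:
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 1:
            raise ConfigurationError(f"grid_shape must be positive: {self.grid_shape}")
        if not (0.0 <= self.d_late <= self.d_peak <= 1.0):
            raise ConfigurationError(
                f"require 0 <= d_late <= d_peak <= 1, got d_late={self.d_late}, "
                f"d_peak={self.d_peak}"
            )
        if self.tau_c <= 0 or self.tau_d <= 0:
            raise ConfigurationError("tau_c and tau_d must be positive")
        if self.n_fires < 0:
            raise ConfigurationError(f"n_fires must be >= 0: {self.n_fires}")
        lo, hi = self.fire_year_range
        if not (FIRE_YEAR_MIN <= lo <= hi <= FIRE_YEAR_MAX):
            raise ConfigurationError(
                f"fire_year_range must lie within [{FIRE_YEAR_MIN}, {FIRE_YEAR_MAX}]: "
                f"{self.fire_year_range}"
            )
        if not (0.0 <= self.albedo_invalid_fraction < 1.0):
            raise ConfigurationError(
                f"albedo_invalid_fraction must be in [0, 1): "
                f"{self.albedo_invalid_fraction}"
            )
        em = np.asarray(self.endmembers)
        if em.shape != (3, 3, 6):
            raise ConfigurationError(f"endmembers must have shape (3, 3, 6): {em.shape}")
        if em.min() < 0 or em.max() > 1:
            raise ConfigurationError("endmembers must lie within [0, 1]")


@dataclass
class LandscapeTruth:
    """Seeded synthetic ground truth for one landscape."""

    grid_shape: tuple[int, int]
    pixel_size: float
    dec_base: np.ndarray
    cover_base: np.ndarray
    fires: list[FireEvent]
    succession_params: dict
    endmembers: np.ndarray
    albedo_coeffs: dict
    dem: np.ndarray
    seed: int
    config: GenerationConfig


@dataclass
class ReflectanceStack:
    """Multi-date reflectance for one season, with per-date validity."""

    season: str
    year: int
    bands: np.ndarray  # (n_dates, 6, rows, cols)
    valid: np.ndarray  # (n_dates, rows, cols)
    band_names: tuple[str, ...] = BANDS


@dataclass
class CoarseAlbedo:
    """Block-averaged albedo raster with a validity screen."""

    season: str
    year: int
    values: np.ndarray
    valid: np.ndarray
    coarse_factor: int


def _smooth_field(rng: np.random.Generator, shape, sigma: float) -> np.ndarray:
    """Unit-variance spatially autocorrelated Gaussian field."""
    z = rng.standard_normal(shape)
    if sigma > 0:
        z = gaussian_filter(z, sigma, mode="reflect")
    sd = z.std()
    return z / sd if sd > 0 else z


def _random_fire_polygon(
    rng: np.random.Generator, shape, radius_range
) -> BaseGeometry:
    rows, cols = shape
    cx = rng.uniform(0, cols)
    cy = rng.uniform(0, rows)
    radius = rng.uniform(*radius_range)
    n_vert = 12
    angles = np.sort(rng.uniform(0, 2 * np.pi, n_vert))
    radii = radius * rng.uniform(0.6, 1.0, n_vert)
    xs = cx + radii * np.cos(angles)
    ys = cy + radii * np.sin(angles)
    return Polygon(np.column_stack([xs, ys])).buffer(0)


def generate_truth(config: GenerationConfig | None = None, seed: int = 0) -> LandscapeTruth:
    """Generate a seeded LandscapeTruth; identical (config, seed) gives
    byte-identical fields."""
    config = config if config is not None else GenerationConfig()
    config.validate()
    rng = _rng(seed, _TAG["truth"])
    shape = tuple(config.grid_shape)

    dec_base = np.clip(
        config.dec_base_mean
        + config.dec_base_sd * _smooth_field(rng, shape, config.blur_sigma),
        0.0,
        1.0,
    )
    cover_base = np.clip(
        config.cover_base_mean
        + config.cover_base_sd * _smooth_field(rng, shape, config.blur_sigma),
        0.0,
        1.0,
    )
    dem = config.dem_mean + config.dem_relief * _smooth_field(
        rng, shape, config.blur_sigma
    )

    fires: list[FireEvent] = []
    grid_box = shapely.box(0, 0, shape[1], shape[0])
    lo, hi = config.fire_year_range
    for _ in range(config.n_fires):
        poly = _random_fire_polygon(rng, shape, config.fire_radius_range)
        year = int(rng.integers(lo, hi + 1))
        if not poly.intersects(grid_box):
            continue  # fully off-grid draw; drop rather than retry to keep streams simple
        fires.append(FireEvent(polygon=poly, year=year))

    return LandscapeTruth(
        grid_shape=shape,
        pixel_size=config.pixel_size,
        dec_base=dec_base,
        cover_base=cover_base,
        fires=fires,
        succession_params={
            "tau_c": config.tau_c,
            "tau_d": config.tau_d,
            "d_peak": config.d_peak,
            "d_late": config.d_late,
        },
        endmembers=np.asarray(config.endmembers, dtype=float),
        albedo_coeffs={s: dict(c) for s, c in config.albedo_coeffs.items()},
        dem=dem,
        seed=int(seed),
        config=config,
    )


def most_recent_fire_year(
    fires: list[FireEvent], shape: tuple[int, int], upto_year: int | None = None
) -> np.ndarray:
    """Per-pixel year of the most recent fire (<= upto_year); -1 where unburned.

    Pixel membership is centre-in-polygon (``covers``); overlapping fires
    keep the most recent year.
    """
    years = np.full(shape, -1, dtype=int)
    relevant = [f for f in fires if upto_year is None or f.year <= upto_year]
    for fire in sorted(relevant, key=lambda f: f.year):
        if not (FIRE_YEAR_MIN <= fire.year <= FIRE_YEAR_MAX):
            raise ValueError(f"fire year out of range [1950, 2018]: {fire.year}")
        years[covered_mask(fire.polygon, shape)] = fire.year
    return years


def succession_curves(params: dict, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Relative deciduous and cover succession values at stand age t >= 0.

    Returns (dec, cover_scale): dec is the absolute deciduous fraction and
    cover_scale multiplies the pixel's mature cover c0.
    """
    t = np.asarray(t, dtype=float)
    tau_c, tau_d = params["tau_c"], params["tau_d"]
    d_peak, d_late = params["d_peak"], params["d_late"]
    dec = d_late + (d_peak - d_late) * (t / tau_d) * np.exp(1.0 - t / tau_d)
    cover_scale = 1.0 - np.exp(-t / tau_c)
    return dec, cover_scale


def evaluate_composition(
    truth: LandscapeTruth, year: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deciduous fraction and canopy cover fields at ``year``.

    Pixels whose most recent fire was t years earlier follow the succession
    curves; unburned pixels (including years before any fire) return the
    long-term base fields.
    """
    fire_year = most_recent_fire_year(truth.fires, truth.grid_shape, upto_year=year)
    burned = fire_year >= 0
    t = np.where(burned, year - fire_year, 0).astype(float)
    dec_succ, cover_scale = succession_curves(truth.succession_params, t)
    dec = np.where(burned, dec_succ, truth.dec_base)
    cover = np.where(burned, truth.cover_base * cover_scale, truth.cover_base)
    return np.clip(dec, 0.0, 1.0), np.clip(cover, 0.0, 1.0)


def mixture_reflectance(
    endmembers: np.ndarray, season: str, dec: np.ndarray, cover: np.ndarray
) -> np.ndarray:
    """Noiseless linear-mixture reflectance, shape (6, rows, cols)."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    s = SEASONS.index(season)
    e_dec = endmembers[0, s][:, None, None]
    e_eve = endmembers[1, s][:, None, None]
    e_bg = endmembers[2, s][:, None, None]
    d = dec[None]
    c = cover[None]
    return c * (d * e_dec + (1.0 - d) * e_eve) + (1.0 - c) * e_bg


def render_reflectance(
    truth: LandscapeTruth,
    year: int,
    season: str,
    n_dates: int = 4,
    cloud_fraction: float = 0.1,
    noise_sd: float = 0.02,
    seed: int = 0,
) -> ReflectanceStack:
    """Render a multi-date reflectance stack with seeded cloud masks."""
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    if n_dates < 1:
        raise ValueError(f"n_dates must be >= 1: {n_dates}")
    dec, cover = evaluate_composition(truth, year)
    base = mixture_reflectance(truth.endmembers, season, dec, cover)
    rng = _rng(truth.seed, _TAG["reflectance"], _SEASON_TAG[season], year, seed)
    rows, cols = truth.grid_shape
    bands = np.empty((n_dates, 6, rows, cols))
    valid = np.empty((n_dates, rows, cols), dtype=bool)
    for i in range(n_dates):
        r = base.copy()
        if noise_sd > 0:
            r = r + rng.normal(0.0, noise_sd, size=r.shape)
        bands[i] = np.clip(r, 0.0, 1.0)
        valid[i] = rng.random((rows, cols)) >= cloud_fraction
    return ReflectanceStack(season=season, year=year, bands=bands, valid=valid)


def sample_plots(
    truth: LandscapeTruth,
    year: int,
    n_plots: int,
    ba_noise: float = 0.08,
    seed: int = 0,
    max_total_ba: float = 40.0,
) -> "pandas.DataFrame":
    """Draw forest-inventory plots consistent with pixel composition.

    Total basal area scales with canopy cover (``max_total_ba`` m2/ha at
    full cover); the deciduous share is a noisy draw centred on the pixel
    deciduous fraction.  Plots fall only on pixels with cover > 0.
    """
    import pandas as pd

    if n_plots < 1:
        raise ValueError(f"n_plots must be >= 1: {n_plots}")
    dec, cover = evaluate_composition(truth, year)
    eligible = np.argwhere(cover > 0)
    if len(eligible) == 0:
        raise ValueError("no eligible pixels: canopy cover is zero everywhere")
    rng = _rng(truth.seed, _TAG["plots"], year, seed)
    pick = rng.choice(len(eligible), size=n_plots, replace=n_plots > len(eligible))
    rows, cols = eligible[pick, 0], eligible[pick, 1]
    d = dec[rows, cols]
    c = cover[rows, cols]
    share = d if ba_noise == 0 else np.clip(d + rng.normal(0.0, ba_noise, n_plots), 0, 1)
    total = max_total_ba * c
    return pd.DataFrame(
        {
            "plot_id": np.arange(n_plots),
            "row": rows,
            "col": cols,
            "deciduous_ba": share * total,
            "evergreen_ba": (1.0 - share) * total,
        }
    )


def composition_albedo(coeffs: dict, dec: np.ndarray, cover: np.ndarray) -> np.ndarray:
    """Closed-form seasonal albedo from composition (before noise/clipping)."""
    return (
        coeffs["b0"]
        + coeffs["b_d"] * dec
        + coeffs["b_c"] * cover
        + coeffs["b_dc"] * dec * cover
    )


def render_albedo(
    truth: LandscapeTruth,
    year: int,
    season: str,
    coarse_factor: int = 16,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> CoarseAlbedo:
    """Render a block-averaged albedo raster with a seeded validity screen.

    The invalid subset stands in for solar-zenith screening of the daily
    albedo product.
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    rows, cols = truth.grid_shape
    if coarse_factor < 1 or rows % coarse_factor or cols % coarse_factor:
        raise ValueError(
            f"coarse_factor {coarse_factor} must be >= 1 and divide grid "
            f"dimensions {truth.grid_shape}"
        )
    dec, cover = evaluate_composition(truth, year)
    fine = composition_albedo(truth.albedo_coeffs[season], dec, cover)
    rng = _rng(truth.seed, _TAG["albedo"], _SEASON_TAG[season], year, seed)
    if noise_sd > 0:
        fine = fine + rng.normal(0.0, noise_sd, size=fine.shape)
    fine = np.clip(fine, 0.0, 1.0)
    f = coarse_factor
    coarse = fine.reshape(rows // f, f, cols // f, f).mean(axis=(1, 3))
    valid = rng.random(coarse.shape) >= truth.config.albedo_invalid_fraction
    return CoarseAlbedo(
        season=season, year=year, values=coarse, valid=valid, coarse_factor=f
    )


def render_kernel(
    truth: LandscapeTruth, season: str, coarse_factor: int = 16
) -> np.ndarray:
    """Smooth negative kernel raster, W m^-2 per unit albedo increase.

    Magnitudes are synthetic stand-ins with plausible seasonal ordering
    (largest in summer when insolation is highest).
    """
    if season not in SEASONS:
        raise ValueError(f"unknown season {season!r}; expected one of {SEASONS}")
    rows, cols = truth.grid_shape
    if coarse_factor < 1 or rows % coarse_factor or cols % coarse_factor:
        raise ValueError(
            f"coarse_factor {coarse_factor} must be >= 1 and divide grid "
            f"dimensions {truth.grid_shape}"
        )
    shape = (rows // coarse_factor, cols // coarse_factor)
    mean = truth.config.kernel_means[season]
    rel_sd = truth.config.kernel_rel_sd
    if rel_sd == 0:
        return np.full(shape, float(mean))
    rng = _rng(truth.seed, _TAG["kernel"], _SEASON_TAG[season])
    z = _smooth_field(rng, shape, max(truth.config.blur_sigma / coarse_factor, 0.5))
    field = mean * (1.0 + rel_sd * z)
    return np.minimum(field, -1e-9)
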