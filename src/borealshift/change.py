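"""Epoch-to-epoch change classification, masking and stratified reporting.

Change in a fractional layer is classed as unchanged iff it rounds to
0.00 at two decimals (half-away-from-zero, i.e. |delta| < 0.005), else by
its sign.  Per-pixel significance uses a z-test on the propagated
leaf-spread uncertainties of the two epochs,
|delta| > z * sqrt(sd_start^2 + sd_end^2), a documented stand-in for the
source analysis' supplementary procedure (default z = 1.96).

The analysis mask keeps tree-dominated pixels: canopy cover >= 0.25 in
either epoch, plus the pre-fire inclusion rule (cover > 0.25 in the
earlier epoch and burned between the epochs — kept explicit for
provenance even though such pixels already satisfy the threshold rule).

Fire-age classes partition 1950-2018 into old (1950-1978), intermediate
(1979-1998) and recent (1999-2018).  Reports mirror the structure of the
source tables: per stratum, areas (Mha) of increase/decrease/unchanged
and of significant change, mean +/- sd of composition and albedo change,
and mean +/- sd forcing split into warming (positive) and cooling
(negative) pixels per season.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geom import covered_mask
from .synthetic import FIRE_YEAR_MAX, FIRE_YEAR_MIN, FireEvent

log = logging.getLogger(__name__)

INCREASE, UNCHANGED, DECREASE = 1, 0, -1

FIRE_AGE_CLASSES = {
    "old": (1950, 1978),
    "intermediate": (1979, 1998),
    "recent": (1999, 2018),
}
_CLASS_CODE = {"old": 1, "intermediate": 2, "recent": 3}
NO_FIRE = -1

TREE_COVER_THRESHOLD = 0.25
SEASONS3 = ("spring", "summer", "fall")


@dataclass
class AnalysisMask:
    """Tree-dominated analysis mask with per-pixel rule provenance."""

    mask: np.ndarray
    provenance: np.ndarray  # 0 out, 1 cover_ge_threshold, 2 prefire_inclusion


def analysis_mask(
    cover_start: np.ndarray,
    cover_end: np.ndarray,
    burned_between: np.ndarray | None = None,
    threshold: float = TREE_COVER_THRESHOLD,
) -> AnalysisMask:
    """Tree-dominated mask: cover >= threshold in either epoch, or cover >
    threshold pre-fire for pixels that burned between the epochs."""
    ge = (cover_start >= threshold) | (cover_end >= threshold)
    if burned_between is None:
        burned_between = np.zeros_like(ge)
    prefire = (cover_start > threshold) & burned_between & ~ge
    mask = ge | prefire
    prov = np.zeros(mask.shape, dtype=np.uint8)
    prov[ge] = 1
    prov[prefire] = 2
    return AnalysisMask(mask=mask, provenance=prov)


def classify_change(delta: np.ndarray) -> np.ndarray:
    """{increase, unchanged, decrease} codes from a change raster.

    Unchanged iff the change rounds to 0.00 at two decimal digits with
    half-away-from-zero rounding.
    """
    delta = np.asarray(delta, dtype=float)
    out = np.zeros(delta.shape, dtype=np.int8)
    out[delta >= 0.005] = INCREASE
    out[delta <= -0.005] = DECREASE
    return out


def significance(
    delta: np.ndarray,
    sd_start: np.ndarray,
    sd_end: np.ndarray,
    z: float = 1.96,
) -> np.ndarray:
    """Per-pixel z-test on propagated epoch uncertainties."""
    sd_start = np.asarray(sd_start, dtype=float)
    sd_end = np.asarray(sd_end, dtype=float)
    if np.any(sd_start < 0) or np.any(sd_end < 0):
        raise ValueError("uncertainty layers must be >= 0")
    comb = np.sqrt(sd_start**2 + sd_end**2)
    with np.errstate(invalid="ignore"):
        sig = np.abs(delta) > z * comb
    zero_sd = comb == 0
    sig = np.where(zero_sd, delta != 0, sig)
    return sig & np.isfinite(delta)


def rasterize_fires(
    fires: list[FireEvent], shape: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Most-recent-fire-year raster and fire-age-class raster.

    Pixel membership is centre-in-polygon; overlapping fires keep the most
    recent year.  Unburned pixels carry NO_FIRE (-1) / class code 0.
    """
    years = np.full(shape, NO_FIRE, dtype=int)
    for i, fire in enumerate(sorted(fires, key=lambda f: f.year)):
        if not (FIRE_YEAR_MIN <= fire.year <= FIRE_YEAR_MAX):
            raise ValueError(
                f"fire feature {i}: year {fire.year} outside [1950, 2018]"
            )
        try:
            inside = covered_mask(fire.polygon, shape)
        except ValueError as exc:
            raise ValueError(f"fire feature {i}: {exc}") from exc
        years[inside] = fire.year
    classes = np.zeros(shape, dtype=np.uint8)
    for name, (lo, hi) in FIRE_AGE_CLASSES.items():
        classes[(years >= lo) & (years <= hi)] = _CLASS_CODE[name]
    return years, classes


def fire_age_class(year: int) -> str:
    """Fire-age class name for a fire year; classes partition [1950, 2018]."""
    for name, (lo, hi) in FIRE_AGE_CLASSES.items():
        if lo <= year <= hi:
            return name
    raise ValueError(f"year {year} outside [1950, 2018]")


def area_accounting(
    class_raster: np.ndarray, mask: np.ndarray, pixel_size: float
) -> dict[str, float]:
    """Areas (Mha) of increase/decrease/unchanged within the mask.

    area per pixel = pixel_size^2 / 1e4 ha; Mha = ha / 1e6.
    A 30 m pixel is 0.09 ha.
    """
    per_pixel_mha = (pixel_size**2 / 1e4) / 1e6
    return {
        "increase": float((mask & (class_raster == INCREASE)).sum() * per_pixel_mha),
        "decrease": float((mask & (class_raster == DECREASE)).sum() * per_pixel_mha),
        "unchanged": float((mask & (class_raster == UNCHANGED)).sum() * per_pixel_mha),
        "total": float(mask.sum() * per_pixel_mha),
    }


def _mean_sd(values: np.ndarray) -> tuple[float, float, int]:
    n = values.size
    if n == 0:
        return float("nan"), float("nan"), 0
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if n > 1 else 0.0
    return mean, sd, n


def stratified_summary(
    deltas: dict[str, np.ndarray],
    sig: dict[str, np.ndarray],
    dalbedo: dict[str, np.ndarray],
    forcings: dict[str, "ForcingMap"],
    strata: dict[str, np.ndarray],
    mask: np.ndarray,
    pixel_size: float,
) -> pd.DataFrame:
    """Per-stratum change report rows.

    ``deltas`` maps a variable name (e.g. 'dec', 'cover') to its change
    raster, ``sig`` to its significance raster; ``dalbedo`` and
    ``forcings`` are per-season.  Every row satisfies exact area
    conservation (increase + decrease + unchanged = masked stratum area)
    and significant area <= change area; both are asserted.
    """
    per_pixel_mha = (pixel_size**2 / 1e4) / 1e6
    rows = []
    for stratum_name, stratum in strata.items():
        m = mask & stratum
        row: dict = {"stratum": stratum_name, "n_pixels": int(m.sum())}
        row["area_Mha"] = float(m.sum() * per_pixel_mha)
        for var, delta in deltas.items():
            classes = classify_change(np.where(m, delta, 0.0))
            areas = area_accounting(classes, m, pixel_size)
            s = sig[var] & m
            n_inc = int((m & (classes == INCREASE)).sum())
            n_dec = int((m & (classes == DECREASE)).sum())
            n_unc = int((m & (classes == UNCHANGED)).sum())
            n_sig_inc = int((s & (classes == INCREASE)).sum())
            n_sig_dec = int((s & (classes == DECREASE)).sum())
            # exact conservation, asserted in pixel counts (Mha values are
            # each count * pixel area with one shared factor)
            assert n_inc + n_dec + n_unc == int(m.sum())
            assert n_sig_inc <= n_inc and n_sig_dec <= n_dec
            row[f"{var}_increase_Mha"] = areas["increase"]
            row[f"{var}_decrease_Mha"] = areas["decrease"]
            row[f"{var}_unchanged_Mha"] = areas["unchanged"]
            row[f"{var}_sig_increase_Mha"] = n_sig_inc * per_pixel_mha
            row[f"{var}_sig_decrease_Mha"] = n_sig_dec * per_pixel_mha
            row[f"{var}_n_increase"] = n_inc
            row[f"{var}_n_decrease"] = n_dec
            row[f"{var}_n_unchanged"] = n_unc
            vals = delta[m & np.isfinite(delta)]
            mean, sd, _ = _mean_sd(vals)
            row[f"d{var}_mean"] = mean
            row[f"d{var}_sd"] = sd
        for season, da in dalbedo.items():
            vals = da[m & np.isfinite(da)]
            mean, sd, _ = _mean_sd(vals)
            row[f"dalbedo_{season}_mean"] = mean
            row[f"dalbedo_{season}_sd"] = sd
        for season, fmap in forcings.items():
            f = fmap.forcing
            ok = m & fmap.valid_mask & np.isfinite(f)
            vals = f[ok]
            mean, sd, n = _mean_sd(vals)
            row[f"forcing_{season}_mean"] = mean
            row[f"forcing_{season}_sd"] = sd
            row[f"forcing_{season}_n"] = n
            warm, wsd, wn = _mean_sd(vals[vals > 0])
            cool, csd, cn = _mean_sd(vals[vals < 0])
            row[f"forcing_{season}_warming_mean"] = warm
            row[f"forcing_{season}_warming_sd"] = wsd
            row[f"forcing_{season}_warming_n"] = wn
            row[f"forcing_{season}_cooling_mean"] = cool
            row[f"forcing_{season}_cooling_sd"] = csd
            row[f"forcing_{season}_cooling_n"] = cn
        rows.append(row)
    return pd.DataFrame(rows)


def fire_strata(
    class_raster: np.ndarray, include_domain: bool = True
) -> dict[str, np.ndarray]:
    """Standard report strata: domain, each fire-age class, all perimeters."""
    strata: dict[str, np.ndarray] = {}
    if include_domain:
        strata["domain"] = np.ones(class_raster.shape, dtype=bool)
    for name, code in _CLASS_CODE.items():
        strata[f"fires_{name}"] = class_raster == code
    strata["fires_all"] = class_raster != 0
    return strata


def rasterize_regions(
    regions: list[tuple[str, "BaseGeometry"]], shape: tuple[int, int]
) -> dict[str, np.ndarray]:
    """Region masks from a polygon partition; overlap is an error.

    Pixels outside every region form an 'unassigned' stratum when present.
    """
    masks: dict[str, np.ndarray] = {}
    seen = np.zeros(shape, dtype=bool)
    for name, poly in regions:
        m = covered_mask(poly, shape)
        overlap = m & seen
        if overlap.any():
            raise ValueError(
                f"region {name!r} overlaps a previous region on "
                f"{int(overlap.sum())} pixels; regions must be a partition"
            )
        seen |= m
        masks[name] = m
    if not seen.all():
        masks["unassigned"] = ~seen
    return masks


def regional_summary(
    regions: list[tuple[str, "BaseGeometry"]],
    deltas: dict[str, np.ndarray],
    sig: dict[str, np.ndarray],
    dalbedo: dict[str, np.ndarray],
    forcings: dict[str, "ForcingMap"],
    mask: np.ndarray,
    pixel_size: float,
) -> pd.DataFrame:
    """Per-region rows with the same statistics as the domain summary."""
    strata = rasterize_regions(regions, mask.shape)
    return stratified_summary(deltas, sig, dalbedo, forcings, strata, mask, pixel_size)
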