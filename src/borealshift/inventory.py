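"""Forest-inventory plot handling.

Converts per-plot basal areas into the deciduous-fraction response
variable (deciduous basal area over total basal area), balances the
response distribution by binned under-sampling, splits into 70/30
train/validation sets, and thins validation plots on a distance grid to
reduce spatial autocorrelation.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

PLOT_COLUMNS = ("plot_id", "row", "col", "deciduous_ba", "evergreen_ba")


def deciduous_fraction(deciduous_ba, evergreen_ba):
    """Deciduous share of total basal area, in [0, 1]."""
    deciduous_ba = np.asarray(deciduous_ba, dtype=float)
    evergreen_ba = np.asarray(evergreen_ba, dtype=float)
    total = deciduous_ba + evergreen_ba
    if np.any(deciduous_ba < 0) or np.any(evergreen_ba < 0):
        raise ValueError("basal areas must be >= 0")
    if np.any(total <= 0):
        raise ValueError("plot with zero total basal area: deciduous fraction undefined")
    return deciduous_ba / total


def attach_response(records: pd.DataFrame) -> pd.DataFrame:
    """Add a ``dec_fraction`` column; drop zero-basal-area plots with a logged count."""
    total = records["deciduous_ba"] + records["evergreen_ba"]
    bad = total <= 0
    if bad.any():
        log.info("excluding %d plots with zero total basal area", int(bad.sum()))
        records = records.loc[~bad]
    out = records.copy()
    out["dec_fraction"] = deciduous_fraction(
        out["deciduous_ba"].to_numpy(), out["evergreen_ba"].to_numpy()
    )
    return out


def _bin_index(values: np.ndarray, bin_width: float) -> np.ndarray:
    n_bins = int(round(1.0 / bin_width))
    if abs(n_bins * bin_width - 1.0) > 1e-9:
        raise ValueError(f"bin_width {bin_width} must divide 1 evenly")
    return np.minimum((values / bin_width).astype(int), n_bins - 1)


def binned_undersample(
    records: pd.DataFrame,
    bin_width: float = 0.1,
    target: int | None = None,
    seed: int = 0,
    response: str = "dec_fraction",
) -> pd.DataFrame:
    """Balance the response distribution by binned under-sampling.

    Within each response bin, retain ``min(bin count, target)`` records by
    seeded sampling without replacement; the default target is the
    smallest non-empty bin count, giving an exactly uniform histogram.
    """
    if len(records) == 0:
        raise ValueError("cannot balance an empty plot set")
    bins = _bin_index(records[response].to_numpy(), bin_width)
    counts = pd.Series(bins).value_counts()
    if target is None:
        target = int(counts.min())
    rng = np.random.default_rng(seed)
    kept = []
    for b in sorted(counts.index):
        members = np.flatnonzero(bins == b)
        if len(members) > target:
            members = rng.choice(members, size=target, replace=False)
        kept.append(np.sort(members))
    keep = np.concatenate(kept)
    return records.iloc[keep].reset_index(drop=True)


def split_train_validation(
    records: pd.DataFrame, train_fraction: float = 0.70, seed: int = 0
) -> pd.DataFrame:
    """Seeded shuffle-split; adds an exhaustive, disjoint ``split`` label.

    The training size is ``floor(train_fraction * n)``.
    """
    n = len(records)
    if n < 10:
        raise ValueError(f"need at least 10 records to split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    split = np.empty(n, dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train:]] = "validation"
    out = records.copy()
    out["split"] = split
    return out


def thin_for_validation(
    records: pd.DataFrame,
    min_distance: float = 1000.0,
    pixel_size: float = 30.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Thin plots on a square grid of cell side ``min_distance`` metres.

    Keeps one seeded-random record per occupied cell, reducing spatial
    autocorrelation among validation plots.
    """
    if min_distance <= 0:
        raise ValueError(f"min_distance must be > 0: {min_distance}")
    if len(records) == 0:
        return records.copy()
    cell_r = np.floor(records["row"].to_numpy() * pixel_size / min_distance).astype(int)
    cell_c = np.floor(records["col"].to_numpy() * pixel_size / min_distance).astype(int)
    rng = np.random.default_rng(seed)
    keep = []
    frame = pd.DataFrame({"cell_r": cell_r, "cell_c": cell_c})
    for _, members in frame.groupby(["cell_r", "cell_c"], sort=True):
        idx = members.index.to_numpy()
        keep.append(idx[rng.integers(len(idx))])
    return records.iloc[np.sort(keep)].reset_index(drop=True)
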