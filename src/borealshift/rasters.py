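"""Raster I/O on a single reference grid.

Rasters are stored as float32 TIFF files with NaN as the nodata value,
plus a small JSON sidecar (``<file>.grid.json``) carrying the grid
contract: shape, pixel size in metres, and origin.  Every read validates
the raster against the run's reference grid; the analysis operates on a
single equal-area grid, so no CRS machinery is involved.  Write-then-read
restores float32 values bit-exactly, including the nodata mask.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import tifffile


@dataclass(frozen=True)
class GridSpec:
    """The run's reference grid contract."""

    shape: tuple[int, int]
    pixel_size: float
    origin: tuple[float, float] = (0.0, 0.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["shape"] = list(self.shape)
        d["origin"] = list(self.origin)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            shape=tuple(d["shape"]),
            pixel_size=float(d["pixel_size"]),
            origin=tuple(d.get("origin", (0.0, 0.0))),
        )


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".grid.json")


def write_raster(path, data: np.ndarray, grid: GridSpec) -> None:
    """Write a float32 raster (2D, or 3D multi-band) with its grid sidecar.

    Masked/nodata cells are represented as NaN.
    """
    path = Path(path)
    data = np.asarray(data, dtype=np.float32)
    shape = data.shape[-2:]
    if tuple(shape) != tuple(grid.shape):
        raise ValueError(f"data shape {shape} does not match grid {grid.shape}")
    kwargs = {"photometric": "minisblack"}
    if data.ndim == 3:
        kwargs["planarconfig"] = "separate"
    tifffile.imwrite(path, data, **kwargs)
    with open(_sidecar(path), "w") as fh:
        json.dump(grid.to_dict(), fh)


def read_raster(path, grid: GridSpec | None = None) -> tuple[np.ndarray, GridSpec]:
    """Read a raster and its grid metadata, validating against ``grid``."""
    path = Path(path)
    data = tifffile.imread(path)
    side = _sidecar(path)
    if side.exists():
        with open(side) as fh:
            meta = GridSpec.from_dict(json.load(fh))
    else:
        meta = GridSpec(shape=data.shape[-2:], pixel_size=float("nan"))
    if grid is not None:
        if tuple(meta.shape) != tuple(grid.shape) or tuple(data.shape[-2:]) != tuple(
            grid.shape
        ):
            raise ValueError(
                f"{path.name}: raster grid {tuple(data.shape[-2:])} does not match "
                f"reference grid {tuple(grid.shape)}"
            )
    return data, meta


def nodata_mask(data: np.ndarray) -> np.ndarray:
    """Boolean mask of nodata (NaN) cells."""
    return ~np.isfinite(data)
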