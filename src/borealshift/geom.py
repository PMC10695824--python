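"""Planar geometry on the analysis grid.

The analysis grid is treated as an equal-area plane measured in pixel
units: the pixel at (row, col) has its centre at x = col + 0.5,
y = row + 0.5.  Fire-perimeter and region polygons are expressed in these
coordinates.  Membership uses the ``covers`` predicate, so a pixel whose
centre lies exactly on a polygon boundary counts as inside.
"""

from __future__ import annotations

import numpy as np
import shapely
from shapely.geometry.base import BaseGeometry


def pixel_centres(shape: tuple[int, int]) -> tuple[np.ndarray, np.ndarray]:
    """Return (x, y) coordinate arrays of pixel centres for a grid shape."""
    rows, cols = shape
    y, x = np.mgrid[0:rows, 0:cols].astype(float)
    return x + 0.5, y + 0.5


def covered_mask(polygon: BaseGeometry, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centre is covered by ``polygon``."""
    if polygon.is_empty or not polygon.is_valid:
        raise ValueError(f"invalid or empty polygon: {polygon.wkt[:80]}")
    x, y = pixel_centres(shape)
    pts = shapely.points(x.ravel(), y.ravel())
    shapely.prepare(polygon)
    return shapely.covers(polygon, pts).reshape(shape)
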