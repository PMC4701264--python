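"""Planar geo-coordinate contract shared by all raster containers.

All coordinates are planar metres (a projected system such as UTM is assumed
but never interpreted). Pixels are square, north-up, no rotation. Pixel
indexing is 0-based (row, col) with row 0 at the north edge; the *centre* of
pixel (row, col) maps to world

    x = origin_easting  + (col + 0.5) * gsd
    y = origin_northing - (row + 0.5) * gsd

so ``origin_easting``/``origin_northing`` are the *outer corner* of the
top-left pixel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class GeoTransform:
    """Affine north-up transform with square pixels.

    Parameters
    ----------
    origin_easting, origin_northing : float
        World coordinates (metres) of the top-left corner of pixel (0, 0).
    gsd : float
        Ground sample distance, metres per pixel. Must be positive.
    """

    origin_easting: float
    origin_northing: float
    gsd: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.gsd) or self.gsd <= 0:
            raise ValueError(f"gsd must be finite and > 0, got {self.gsd}")
        if not (np.isfinite(self.origin_easting) and np.isfinite(self.origin_northing)):
            raise ValueError("origin coordinates must be finite")

    def world_of(self, row, col):
        """World coordinates (x, y) of pixel-centre(s)."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_easting + (col + 0.5) * self.gsd
        y = self.origin_northing - (row + 0.5) * self.gsd
        return x, y

    def pixel_of(self, x, y):
        """Nearest pixel (row, col) for world point(s).

        Ties on a pixel boundary round half-down (toward the smaller index),
        so the mapping is a deterministic left/top-inclusive rule.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        fc = (x - self.origin_easting) / self.gsd  # continuous col from left edge
        fr = (self.origin_northing - y) / self.gsd  # continuous row from top edge
        # nearest centre with round-half-down: centre of index i sits at i+0.5
        col = np.ceil(fc - 1.0).astype(int)
        row = np.ceil(fr - 1.0).astype(int)
        return row, col

    def extent(self, shape: tuple[int, int]) -> tuple[float, float, float, float]:
        """Outer-edge extent (min_x, min_y, max_x, max_y) of an H x W raster."""
        h, w = shape
        return (
            self.origin_easting,
            self.origin_northing - h * self.gsd,
            self.origin_easting + w * self.gsd,
            self.origin_northing,
        )
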