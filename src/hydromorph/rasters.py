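"""In-memory raster containers: RGB orthoimagery, CIELAB imagery, label maps."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geo import GeoTransform


def _default_mask(shape: tuple[int, int]) -> np.ndarray:
    return np.ones(shape, dtype=bool)


@dataclass
class RGBImage:
    """Georeferenced 8-bit RGB orthoimage with a validity mask.

    ``valid_mask`` marks pixels inside the channel-boundary / data area;
    classification and area accounting ignore pixels outside it.
    """

    pixels: np.ndarray  # H x W x 3 uint8
    transform: GeoTransform
    valid_mask: np.ndarray = None  # H x W bool

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got shape {self.pixels.shape}")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixels.dtype != np.uint8:
            self.pixels = np.clip(self.pixels, 0, 255).astype(np.uint8)
        if self.valid_mask is None:
            self.valid_mask = _default_mask(self.pixels.shape[:2])
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.pixels.shape[:2]:
            raise ValueError("valid_mask shape must match pixel grid")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]


@dataclass
class LabImage:
    """Per-pixel CIELAB values (D65, 2 degree observer) with georeferencing.

    L in [0, 100]; a is the green-red axis, b the blue-yellow axis. Clustering
    and (by default) classification operate on (a, b) only, which makes them
    insensitive to uniform illumination changes.
    """

    L: np.ndarray
    a: np.ndarray
    b: np.ndarray
    transform: GeoTransform
    valid_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.L = np.asarray(self.L, dtype=float)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (self.L.shape == self.a.shape == self.b.shape):
            raise ValueError("L, a, b must share one H x W shape")
        if self.valid_mask is None:
            self.valid_mask = _default_mask(self.L.shape)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.L.shape:
            raise ValueError("valid_mask shape must match L/a/b")
        lo, hi = self.L.min(initial=0.0), self.L.max(initial=0.0)
        if lo < -1e-6 or hi > 100 + 1e-6:
            raise ValueError(f"L out of [0, 100]: range ({lo}, {hi})")

    @property
    def shape(self) -> tuple[int, int]:
        return self.L.shape

    def ab_stack(self) -> np.ndarray:
        """(a, b) as an H x W x 2 array."""
        return np.stack([self.a, self.b], axis=-1)


@dataclass
class ClassifiedMap:
    """Per-pixel class codes (0 = unclassified) after merge and masking."""

    labels: np.ndarray  # H x W integer class codes
    transform: GeoTransform
    valid_mask: np.ndarray = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if self.valid_mask is None:
            self.valid_mask = _default_mask(self.labels.shape)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.valid_mask.shape != self.labels.shape:
            raise ValueError("valid_mask shape must match labels")
        if np.any(self.labels[~self.valid_mask] != 0):
            raise ValueError("labels must be 0 outside valid_mask")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape
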