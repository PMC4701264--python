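"""Tiled classification of a full reach orthoimage and per-class area accounting.

The orthoimage is processed in tiles (the full-reach workflow uses 20) to
bound memory; tiles are placed back by pixel offset with no resampling, so
the mosaic is exactly identical to a single-tile classification. Per-class
binary activations are merged to one label per pixel: the class of maximal
activation among those passing their threshold, 0 (unclassified) if none
pass, with ties broken by class-code order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ann_classifier import BinaryClassifier, image_features
from .classes import UNCLASSIFIED, FeatureClass
from .colour_cluster import rgb_to_lab
from .rasters import ClassifiedMap, LabImage, RGBImage


@dataclass(frozen=True)
class TileLayout:
    """Disjoint rectangular windows exactly covering an image."""

    n_tiles: int
    rows: int
    cols: int
    windows: tuple  # of (row0, col0, height, width)

    def __post_init__(self) -> None:
        if self.rows * self.cols != self.n_tiles:
            raise ValueError("rows * cols must equal n_tiles")


def plan_tiles(image_shape: tuple[int, int], n_tiles: int = 20) -> TileLayout:
    """Plan a near-square tile grid whose windows exactly cover the image.

    The factorisation of ``n_tiles`` with the most balanced aspect is used,
    oriented so the longer tile-grid axis follows the longer image axis;
    the last row/column absorbs any remainder pixels.
    """
    h, w = image_shape
    if n_tiles < 1:
        raise ValueError("n_tiles must be >= 1")
    if n_tiles > h * w:
        raise ValueError(f"cannot split {h}x{w} image into {n_tiles} non-empty tiles")
    # most balanced factor pair of n_tiles
    best = (1, n_tiles)
    for r in range(1, int(np.sqrt(n_tiles)) + 1):
        if n_tiles % r == 0:
            best = (r, n_tiles // r)
    small, large = best
    rows, cols = (large, small) if h >= w else (small, large)
    if rows > h or cols > w:
        # fall back to whatever orientation fits
        rows, cols = (small, large) if small <= h and large <= w else (large, small)
    if rows > h or cols > w:
        raise ValueError(f"{n_tiles} tiles do not fit a {h}x{w} image")
    hs = [h // rows] * rows
    hs[-1] += h - sum(hs)
    ws = [w // cols] * cols
    ws[-1] += w - sum(ws)
    windows = []
    r0 = 0
    for th in hs:
        c0 = 0
        for tw in ws:
            windows.append((r0, c0, th, tw))
            c0 += tw
        r0 += th
    return TileLayout(n_tiles=n_tiles, rows=rows, cols=cols, windows=tuple(windows))


def classify_reach(image: RGBImage, classifiers: list[BinaryClassifier],
                   layout: TileLayout | None = None) -> ClassifiedMap:
    """Classify a full orthoimage tile by tile into a single labelled map.

    Every classifier must share one feature space. Pixels outside the image's
    valid mask stay 0; so do pixels where no classifier reaches its threshold.
    """
    if not classifiers:
        raise ValueError("need at least one classifier")
    spaces = {c.feature_space for c in classifiers}
    if len(spaces) > 1:
        raise ValueError(f"classifiers mix feature spaces: {sorted(spaces)}")
    space = spaces.pop()
    clfs = sorted(classifiers, key=lambda c: int(c.target_class))
    codes = np.array([int(c.target_class) for c in clfs])

    h, w = image.shape
    if layout is None:
        layout = plan_tiles((h, w), 1)
    labels = np.zeros((h, w), dtype=np.int32)
    for (r0, c0, th, tw) in layout.windows:
        if r0 + th > h or c0 + tw > w:
            raise ValueError(f"tile window {(r0, c0, th, tw)} exceeds image {image.shape}")
        sub_rgb = image.pixels[r0:r0 + th, c0:c0 + tw]
        sub_valid = image.valid_mask[r0:r0 + th, c0:c0 + tw]
        if not sub_valid.any():
            continue
        sub = RGBImage(pixels=sub_rgb, transform=image.transform, valid_mask=sub_valid)
        lab = rgb_to_lab(sub)
        feats = image_features(lab, space, rgb=sub_rgb)
        flat = feats[sub_valid]
        # rank on logits: identical ordering to activations (sigmoid is
        # strictly monotone) but immune to float saturation at 1.0
        acts = np.stack([c.decision(flat) for c in clfs])        # n_clf x N
        passing = acts >= np.array([c.decision_cut for c in clfs])[:, None]
        acts_masked = np.where(passing, acts, -np.inf)
        winner = np.argmax(acts_masked, axis=0)                  # first max wins ties
        any_pass = passing.any(axis=0)
        tile_labels = np.where(any_pass, codes[winner], UNCLASSIFIED)
        out = np.zeros((th, tw), dtype=np.int32)
        out[sub_valid] = tile_labels
        labels[r0:r0 + th, c0:c0 + tw] = out
    return ClassifiedMap(labels=labels, transform=image.transform,
                         valid_mask=image.valid_mask.copy())


@dataclass
class AreaReport:
    """Per-class areas in square metres over the valid (in-boundary) pixels."""

    per_class: dict
    unclassified: float
    total: float
    gsd: float

    def as_dict(self) -> dict:
        d = {cls.name.lower(): area for cls, area in self.per_class.items()}
        d["unclassified"] = self.unclassified
        d["total"] = self.total
        return d


def area_report(cmap: ClassifiedMap) -> AreaReport:
    """Pixel-count areas: area(class) = count * gsd^2, in square metres."""
    px_area = cmap.transform.gsd ** 2
    labels = cmap.labels[cmap.valid_mask]
    per_class = {}
    for cls in FeatureClass:
        per_class[cls] = float(np.count_nonzero(labels == int(cls)) * px_area)
    unclassified = float(np.count_nonzero(labels == UNCLASSIFIED) * px_area)
    total = float(labels.size * px_area)
    return AreaReport(per_class=per_class, unclassified=unclassified,
                      total=total, gsd=cmap.transform.gsd)
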