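"""Synthetic river-reach orthoimagery with pixel-level truth.

Renders a meandering single-thread channel at a configurable ground sample
distance (default 2.5 cm): a deep-water core flanked by shallow margins,
riffle bands where the whole wetted width carries a high-frequency foam/ripple
texture, gravel side bars on inner bends (some vegetated), vegetated banks
with erosion strips on outer bends, grass beyond, tree-canopy blobs with cast
shadows, and patches of submerged and emergent vegetation. Every pixel gets a
truth label; ground-truth grid points, a channel-boundary mask and control
points with known offsets accompany the image, so the whole classification
pipeline is testable without any field data.

Class colours were chosen to be separable on the CIELAB (a, b) plane with the
two documented exceptions that make the hard cases reproducible: erosion sits
near shadow, and riffle shares the shallow-water base colour, becoming
distinguishable only through its foam texture (mixing towards a pale warm
off-white). Pixel noise is iid Gaussian per channel, clipped to [0, 255].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .classes import FeatureClass as FC
from .classes import UNCLASSIFIED
from .colour_cluster import TrainingRegion
from .geo import GeoTransform
from .imagery_io import ControlPointPair, GroundTruthPoint
from .rasters import ClassifiedMap, RGBImage
from .reach_pipeline import TileLayout


@dataclass
class ClassAppearance:
    """Mean colour and optional texture of one feature class."""

    mean_rgb: tuple[float, float, float]
    texture: str | None = None  # None | "ripple" | "speckle"


def default_appearance() -> dict:
    return {
        FC.SIDE_BAR:       ClassAppearance((192, 172, 138)),
        FC.EROSION:        ClassAppearance((122, 76, 48)),
        FC.RIFFLE:         ClassAppearance((88, 128, 134), texture="ripple"),
        FC.DEEP_WATER:     ClassAppearance((28, 58, 82)),
        FC.SHALLOW_WATER:  ClassAppearance((88, 128, 134)),
        FC.TREE:           ClassAppearance((26, 82, 26), texture="speckle"),
        FC.VEGETATED_BAR:  ClassAppearance((140, 152, 62)),
        FC.VEGETATED_BANK: ClassAppearance((70, 118, 98)),
        FC.SUBMERGED_VEG:  ClassAppearance((104, 118, 58)),
        FC.EMERGENT_VEG:   ClassAppearance((96, 170, 88)),
        FC.GRASS:          ClassAppearance((152, 178, 96)),
        FC.SHADOW:         ClassAppearance((36, 38, 46)),
    }


def default_fractions() -> dict:
    return {
        FC.DEEP_WATER: 0.16,
        FC.SHALLOW_WATER: 0.12,
        FC.RIFFLE: 0.09,
        FC.SUBMERGED_VEG: 0.018,
        FC.EMERGENT_VEG: 0.008,
        FC.SIDE_BAR: 0.035,
        FC.VEGETATED_BAR: 0.02,
        FC.VEGETATED_BANK: 0.09,
        FC.EROSION: 0.012,
        FC.TREE: 0.05,
        FC.SHADOW: 0.02,
        # grass fills the remainder
    }


@dataclass
class SceneSpec:
    """Parameters of a synthetic reach scene.

    Defaults emulate a 2.5 cm GSD orthoimage of a low-flow upland reach:
    ~40% wetted area dominated by deep water and riffle, narrow erosion
    strips, scattered canopy with cast shadows, grass beyond the banks.
    """

    width: int = 1000
    height: int = 800
    gsd: float = 0.025
    seed: int = 0
    sinuosity: float = 0.8
    class_fractions: dict = field(default_factory=default_fractions)
    appearance: dict = field(default_factory=default_appearance)
    noise_sd: float = 3.0
    ripple_strength: float = 1.0
    foam_rgb: tuple[float, float, float] = (245, 250, 210)
    tree_radius_px: int = 16
    origin: tuple[float, float] = (300000.0, 5700000.0)
    boundary_margin_px: int = 30
    truth_grid_spacing: float = 2.0
    n_control_points: int = 30

    def __post_init__(self) -> None:
        fr = self.class_fractions
        if any(v < 0 for v in fr.values()):
            raise ValueError("class fractions must be >= 0")
        if sum(fr.values()) > 1.0 + 1e-9:
            raise ValueError(f"class fractions sum to {sum(fr.values()):.3f} > 1")
        for app in self.appearance.values():
            if any(not (0 <= v <= 255) for v in app.mean_rgb):
                raise ValueError("mean colours must be within [0, 255]")


@dataclass
class SyntheticScene:
    image: RGBImage
    truth: ClassifiedMap          # masked to the boundary (labels 0 outside)
    truth_all: np.ndarray         # unmasked wall-to-wall truth labels
    boundary: np.ndarray
    truth_points: list
    control_points: list
    spec: SceneSpec


def _disk(h: int, w: int, r0: float, c0: float, radius: float) -> np.ndarray:
    rr = np.arange(h)[:, None] - r0
    cc = np.arange(w)[None, :] - c0
    return rr * rr + cc * cc <= radius * radius


def _segments_total(total_len: float, centres: list[float],
                    width_limit: float) -> list[tuple[float, float]]:
    """Split a total length into equal segments centred on the given positions."""
    if total_len <= 0 or not centres:
        return []
    per = total_len / len(centres)
    segs = []
    for c in centres:
        x0 = max(0.0, c - per / 2)
        x1 = min(width_limit, c + per / 2)
        segs.append((x0, x1))
    return segs


def generate_scene(spec: SceneSpec) -> SyntheticScene:
    """Render a scene: truth labels, noisy RGB image, boundary, points.

    Fully deterministic given ``spec`` (including its seed): the same spec
    yields bit-identical scenes.
    """
    h, w = spec.height, spec.width
    rng = np.random.default_rng(spec.seed)
    fr = dict(spec.class_fractions)
    transform = GeoTransform(origin_easting=spec.origin[0],
                             origin_northing=spec.origin[1], gsd=spec.gsd)

    # single-class degenerate spec: a uniform scene
    nonzero = {c: v for c, v in fr.items() if v > 0}
    if len(nonzero) == 1 and abs(sum(nonzero.values()) - 1.0) < 1e-9:
        cls = next(iter(nonzero))
        truth = np.full((h, w), int(cls), dtype=np.int32)
        boundary = np.ones((h, w), dtype=bool)
        img = _render(truth, boundary, spec, rng)
        return _finish(spec, transform, img, truth, boundary, rng)

    truth = np.full((h, w), int(FC.GRASS), dtype=np.int32)
    rows = np.arange(h)[:, None].astype(float)
    cols = np.arange(w)[None, :].astype(float)

    # --- channel geometry -------------------------------------------------
    n_periods = 2.0
    amp = spec.sinuosity * h / 8.0
    phase = rng.uniform(0, 2 * np.pi)
    centre = h / 2.0 + amp * np.sin(2 * np.pi * n_periods * cols / w + phase)  # 1 x W
    dy = rows - centre                                                          # H x W

    water_frac = (fr.get(FC.DEEP_WATER, 0) + fr.get(FC.SHALLOW_WATER, 0)
                  + fr.get(FC.RIFFLE, 0) + fr.get(FC.SUBMERGED_VEG, 0)
                  + fr.get(FC.EMERGENT_VEG, 0))
    w_wet = water_frac * h / 2.0
    riffle_len = fr.get(FC.RIFFLE, 0) * w / max(water_frac, 1e-12)
    bw = 0.07 * h                                  # bar strip thickness
    t_bank = (fr.get(FC.VEGETATED_BANK, 0) + fr.get(FC.EROSION, 0)) * h / 2.0

    # bend apexes of the sine centreline
    apex_x, apex_sign = [], []
    k = 0
    while True:
        xk = ((np.pi / 2 + k * np.pi - phase) / (2 * np.pi * n_periods)) * w
        k += 1
        if xk > w:
            break
        if xk < 0:
            continue
        apex_x.append(xk)
        apex_sign.append(1.0 if np.sin(2 * np.pi * n_periods * xk / w + phase) > 0 else -1.0)

    # riffle bands between apexes (channel crossings), away from bars
    cross_x = [x for x in np.linspace(w * 0.08, w * 0.92, 4)]
    riffle_bands = _segments_total(riffle_len, cross_x[:3], w)
    in_riffle = np.zeros((1, w), dtype=bool)
    for x0, x1 in riffle_bands:
        in_riffle |= (cols >= x0) & (cols < x1)
    riffle_cols = in_riffle[0]

    w_deep = (fr.get(FC.DEEP_WATER, 0) * h * w
              / max(2.0 * (w - riffle_cols.sum()), 1e-12))

    # --- bank strips (before bars so bars overwrite their inner part) -----
    abs_dy = np.abs(dy)
    bank = (abs_dy >= w_wet) & (abs_dy < w_wet + t_bank)
    truth[bank] = int(FC.VEGETATED_BANK)

    # erosion strips on outer bends
    er_len = fr.get(FC.EROSION, 0) * h * w / max(t_bank, 1e-12)
    er_apex = apex_x[:2] if len(apex_x) >= 2 else apex_x
    for (x0, x1), ax in zip(_segments_total(er_len, er_apex, w), er_apex):
        s = apex_sign[apex_x.index(ax)]
        seg = (cols >= x0) & (cols < x1) & (s * dy >= w_wet) & (s * dy < w_wet + t_bank)
        truth[seg] = int(FC.EROSION)

    # --- side bars on inner bends -----------------------------------------
    bars_frac = fr.get(FC.SIDE_BAR, 0) + fr.get(FC.VEGETATED_BAR, 0)
    bar_len = bars_frac * h * w / max(bw, 1e-12)
    bar_apex = apex_x[-3:] if len(apex_x) >= 3 else apex_x
    bare_share = (fr.get(FC.SIDE_BAR, 0) / bars_frac) if bars_frac > 0 else 0.0
    bar_cols_by_side = {1.0: np.zeros(w, bool), -1.0: np.zeros(w, bool)}
    for (x0, x1), ax in zip(_segments_total(bar_len, bar_apex, w), bar_apex):
        s = -apex_sign[apex_x.index(ax)]           # inner side of the bend
        strip = (s * dy >= w_wet) & (s * dy < w_wet + bw)
        xsplit = x0 + bare_share * (x1 - x0)
        bare = (cols >= x0) & (cols < xsplit) & strip
        veg = (cols >= xsplit) & (cols < x1) & strip
        truth[bare] = int(FC.SIDE_BAR)
        truth[veg] = int(FC.VEGETATED_BAR)
        cmask = (np.arange(w) >= x0) & (np.arange(w) < x1)
        bar_cols_by_side[s] |= cmask
    # push the bank strip outwards where a bar sits inside it
    for s in (1.0, -1.0):
        cmask = bar_cols_by_side[s][None, :]
        outer_bank = cmask & (s * dy >= w_wet + bw) & (s * dy < w_wet + bw + t_bank)
        inner_bank_veg = outer_bank & (truth == int(FC.GRASS))
        truth[inner_bank_veg] = int(FC.VEGETATED_BANK)

    # --- water -------------------------------------------------------------
    wet = abs_dy < w_wet
    truth[wet] = int(FC.SHALLOW_WATER)
    truth[wet & (abs_dy < w_deep) & ~in_riffle] = int(FC.DEEP_WATER)
    truth[wet & in_riffle] = int(FC.RIFFLE)

    # submerged vegetation patches in the shallow margins
    _place_patches(truth, rng, FC.SUBMERGED_VEG, fr.get(FC.SUBMERGED_VEG, 0),
                   radius=12, centre=centre[0], lo=w_deep + 14, hi=w_wet - 14,
                   allowed_cols=~riffle_cols, overwrite=(FC.SHALLOW_WATER,))
    # emergent vegetation at the water margin
    _place_patches(truth, rng, FC.EMERGENT_VEG, fr.get(FC.EMERGENT_VEG, 0),
                   radius=8, centre=centre[0], lo=w_wet - 19, hi=w_wet - 9,
                   allowed_cols=~riffle_cols, overwrite=(FC.SHALLOW_WATER,))

    # --- trees and shadows --------------------------------------------------
    r_t = spec.tree_radius_px
    tree_area = fr.get(FC.TREE, 0) * h * w
    n_trees = int(round(tree_area / (np.pi * r_t ** 2)))
    n_sh = max(n_trees, 1)
    r_sh = float(np.sqrt(fr.get(FC.SHADOW, 0) * h * w / (n_sh * np.pi)))
    tree_centres = []
    attempts = 0
    while len(tree_centres) < n_trees and attempts < 40 * max(n_trees, 1):
        attempts += 1
        cx = rng.uniform(0, w)
        band = w_wet + bw + t_bank + 40
        dy_c = rng.uniform(-band, band)
        if abs(dy_c) < 0.9 * w_wet:
            continue  # keep canopy off the channel core
        cy = float(np.interp(cx, np.arange(w), centre[0])) + dy_c
        if not (r_t <= cy < h - r_t):
            continue
        if any((cx - px) ** 2 + (cy - py) ** 2 < (1.9 * r_t) ** 2
               for px, py in tree_centres):
            continue
        tree_centres.append((cx, cy))
    tree_mask = np.zeros((h, w), dtype=bool)
    shadow_mask = np.zeros((h, w), dtype=bool)
    for cx, cy in tree_centres:
        tree_mask |= _disk(h, w, cy, cx, r_t)
        shadow_mask |= _disk(h, w, cy + 1.5 * r_t, cx - 1.5 * r_t, r_sh)
    shadow_mask &= ~tree_mask
    truth[shadow_mask] = int(FC.SHADOW)
    truth[tree_mask] = int(FC.TREE)

    boundary = abs_dy <= (w_wet + bw + t_bank + spec.boundary_margin_px)

    img = _render(truth, boundary, spec, rng)
    return _finish(spec, transform, img, truth, boundary, rng)


def _place_patches(truth, rng, cls, frac, *, radius, centre, lo, hi,
                   allowed_cols, overwrite) -> None:
    if frac <= 0 or hi <= lo:
        return
    h, w = truth.shape
    target = frac * h * w
    n = max(1, int(round(target / (np.pi * radius ** 2))))
    ok_cols = np.nonzero(allowed_cols)[0]
    ok_cols = ok_cols[(ok_cols >= radius) & (ok_cols < w - radius)]
    if len(ok_cols) == 0:
        return
    codes = tuple(int(c) for c in overwrite)
    for _ in range(n):
        cx = float(rng.choice(ok_cols))
        side = 1.0 if rng.random() < 0.5 else -1.0
        dy_c = side * rng.uniform(lo, hi)
        cy = centre[int(cx)] + dy_c
        patch = _disk(h, w, cy, cx, radius)
        sel = patch & np.isin(truth, codes)
        truth[sel] = int(cls)


def _render(truth: np.ndarray, boundary: np.ndarray, spec: SceneSpec,
            rng: np.random.Generator) -> np.ndarray:
    """Paint class colours, apply textures and Gaussian noise."""
    h, w = truth.shape
    img = np.zeros((h, w, 3), dtype=float)
    lut = np.zeros((max(int(c) for c in FC) + 1, 3))
    for cls, app in spec.appearance.items():
        lut[int(cls)] = app.mean_rgb
    img = lut[truth]

    rows = np.arange(h)[:, None]
    cols = np.arange(w)[None, :]
    for cls, app in spec.appearance.items():
        sel = truth == int(cls)
        if not sel.any() or app.texture is None:
            continue
        if app.texture == "ripple" and spec.ripple_strength > 0:
            phase_r = rng.uniform(0, 2 * np.pi)
            s = 0.5 + 0.5 * np.sin(2 * np.pi * cols / 7.0
                                   + 1.7 * np.sin(2 * np.pi * rows / 11.0) + phase_r)
            u = np.clip(0.6 * s + 0.4 * rng.random((h, w)), 0, 1)
            wgt = spec.ripple_strength * (0.40 + 0.35 * u)
            foam = np.asarray(spec.foam_rgb, dtype=float)
            img[sel] = img[sel] * (1 - wgt[sel][:, None]) + foam * wgt[sel][:, None]
        elif app.texture == "speckle":
            fac = 0.75 + 0.5 * rng.random((h, w))
            img[sel] *= fac[sel][:, None]
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def _finish(spec, transform, img, truth, boundary, rng) -> SyntheticScene:
    h, w = truth.shape
    masked = truth.copy()
    masked[~boundary] = UNCLASSIFIED
    truth_map = ClassifiedMap(labels=masked, transform=transform, valid_mask=boundary)
    image = RGBImage(pixels=img, transform=transform, valid_mask=boundary)

    # truth points on the configured grid over the boundary extent
    bnd_rows, bnd_cols = np.nonzero(boundary)
    from .validation import overlay_grid
    if len(bnd_rows):
        xs, ys = transform.world_of(bnd_rows, bnd_cols)
        extent = (xs.min(), ys.min(), xs.max(), ys.max())
        pts = overlay_grid(extent, spacing=spec.truth_grid_spacing,
                           boundary=(boundary, transform))
    else:
        pts = np.empty((0, 2))
    r, c = transform.pixel_of(pts[:, 0], pts[:, 1]) if len(pts) else ([], [])
    truth_points = [
        GroundTruthPoint(easting=float(x), northing=float(y),
                         truth_class=FC(int(truth[ri, ci])))
        for (x, y), ri, ci in zip(pts, r, c)
    ]

    # control points: reference == image-derived until perturbed
    extent = transform.extent((h, w))
    cps = []
    mx = min(1.0, 0.05 * (extent[2] - extent[0]))
    my = min(1.0, 0.05 * (extent[3] - extent[1]))
    for i in range(spec.n_control_points):
        x = rng.uniform(extent[0] + mx, extent[2] - mx)
        y = rng.uniform(extent[1] + my, extent[3] - my)
        role = "GCP" if i % 3 else "XP"
        cps.append(ControlPointPair(id=f"CP{i:03d}", role=role,
                                    x_ref=x, y_ref=y, x_img=x, y_img=y))
    return SyntheticScene(image=image, truth=truth_map, truth_all=truth.copy(),
                          boundary=boundary, truth_points=truth_points,
                          control_points=cps, spec=spec)


def realised_fractions(scene: SyntheticScene) -> dict:
    """Truth-pixel fraction of each class over the whole (unmasked) image."""
    labels = scene.truth_all
    total = labels.size
    return {cls: float(np.count_nonzero(labels == int(cls)) / total) for cls in FC}


def perturb_control_points(scene: SyntheticScene, sigma: float,
                           seed: int) -> list[ControlPointPair]:
    """Add iid Gaussian offsets (sd ``sigma`` per axis) to image-derived coords."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for p in scene.control_points:
        dx, dy = rng.normal(0.0, sigma, size=2) if sigma > 0 else (0.0, 0.0)
        out.append(replace(p, x_img=p.x_ref + dx, y_img=p.y_ref + dy))
    return out


def inject_tile_misalignment(cmap: ClassifiedMap, layout: TileLayout,
                             shift: int, fraction_tiles: float,
                             seed: int) -> tuple[ClassifiedMap, np.ndarray]:
    """Shift a random subset of tiles by up to ``shift`` pixels.

    Emulates mosaicking misregistration from an external GIS workflow: the
    affected tiles' labels are displaced (gaps filled with 0), and a GE mask
    flags a seam band of width ``shift`` around each displaced tile so grid
    samples there can be accounted as georeferencing errors.

    Returns the displaced map and the GE mask. ``shift=0`` or
    ``fraction_tiles=0`` is the identity (empty GE mask).
    """
    if shift < 0:
        raise ValueError("shift must be >= 0")
    labels = cmap.labels.copy()
    ge_mask = np.zeros(cmap.shape, dtype=bool)
    n_sel = int(round(fraction_tiles * layout.n_tiles))
    if shift == 0 or n_sel == 0:
        return ClassifiedMap(labels=labels, transform=cmap.transform,
                             valid_mask=cmap.valid_mask.copy()), ge_mask
    rng = np.random.default_rng(seed)
    chosen = rng.choice(layout.n_tiles, size=min(n_sel, layout.n_tiles),
                        replace=False)
    for idx in chosen:
        r0, c0, th, tw = layout.windows[idx]
        dr, dc = 0, 0
        while dr == 0 and dc == 0:
            dr = int(rng.integers(-shift, shift + 1))
            dc = int(rng.integers(-shift, shift + 1))
        tile = labels[r0:r0 + th, c0:c0 + tw]
        moved = np.zeros_like(tile)
        src_r = slice(max(0, -dr), th - max(0, dr))
        dst_r = slice(max(0, dr), th - max(0, -dr))
        src_c = slice(max(0, -dc), tw - max(0, dc))
        dst_c = slice(max(0, dc), tw - max(0, -dc))
        moved[dst_r, dst_c] = tile[src_r, src_c]
        labels[r0:r0 + th, c0:c0 + tw] = moved
        band = np.zeros((th, tw), dtype=bool)
        band[:shift, :] = True
        band[-shift:, :] = True
        band[:, :shift] = True
        band[:, -shift:] = True
        ge_mask[r0:r0 + th, c0:c0 + tw] |= band
    labels[~cmap.valid_mask] = UNCLASSIFIED
    return ClassifiedMap(labels=labels, transform=cmap.transform,
                         valid_mask=cmap.valid_mask.copy()), ge_mask


def training_regions_from_truth(scene: SyntheticScene, classes=None, *,
                                window: int = 41, min_cover: float = 0.5
                                ) -> list[TrainingRegion]:
    """Pick one training window per class from the truth map.

    For each class the window (trying sizes ``window``, then smaller) with the
    highest truth coverage is selected; the truth pixels inside it form the
    reference sketch. Mirrors an operator choosing areas where the feature of
    interest fills at least half the selection.
    """
    from scipy.ndimage import uniform_filter

    truth = scene.truth.labels
    h, w = truth.shape
    if classes is None:
        classes = [c for c in FC if np.any(truth == int(c))]
    regions = []
    for cls in classes:
        found = None
        for size in (window, max(3, window // 2 | 1), 15, 9):
            if size > min(h, w):
                continue
            frac = uniform_filter((truth == int(cls)).astype(float), size=size,
                                  mode="constant")
            # restrict window centres so the window stays in bounds
            half = size // 2
            interior = np.zeros_like(frac, dtype=bool)
            interior[half:h - (size - half) + 1, half:w - (size - half) + 1] = True
            frac[~interior] = -1.0
            r, c = np.unravel_index(np.argmax(frac), frac.shape)
            if frac[r, c] >= min_cover:
                r0, c0 = r - half, c - half
                ref = truth[r0:r0 + size, c0:c0 + size] == int(cls)
                found = TrainingRegion(target_class=cls, window=(r0, c0, size, size),
                                       reference_mask=ref)
                break
        if found is None:
            raise ValueError(f"no window with >= {min_cover:.0%} coverage found "
                             f"for class {cls.name}")
        regions.append(found)
    return regions
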