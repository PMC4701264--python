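"""CIELAB transform and k-means assisted construction of training masks.

The classification workflow operates in the CIELAB colour space and clusters
pixels on the chromatic (a, b) plane only, deliberately ignoring lightness L
so results are insensitive to uniform illumination changes. Training masks
for each feature class are built by clustering a small operator-selected
window and picking the union of clusters that best matches an operator
reference sketch, increasing k from 2 up to a maximum of 10 until the match
is good enough.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .classes import FeatureClass
from .rasters import LabImage, RGBImage

# sRGB (IEC 61966-2-1) linear-RGB -> XYZ matrix, D65 2-degree observer.
_SRGB_TO_XYZ = np.array([
    [0.4124564, 0.3575761, 0.1804375],
    [0.2126729, 0.7151522, 0.0721750],
    [0.0193339, 0.1191920, 0.9503041],
])
# White point derived from the matrix itself (image of RGB=(1,1,1)) so that
# greys map to a = b = 0 exactly, not merely to within rounding of published
# D65 constants.
_WHITE = _SRGB_TO_XYZ @ np.ones(3)

_DELTA = 6.0 / 29.0


class DegenerateInputError(ValueError):
    """Raised when clustering is requested with fewer distinct points than k."""


def srgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Convert sRGB values in [0, 255] (any leading shape, last axis 3) to CIELAB."""
    c = np.asarray(rgb, dtype=float) / 255.0
    lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
    xyz = lin @ _SRGB_TO_XYZ.T
    t = xyz / _WHITE
    f = np.where(t > _DELTA ** 3, np.cbrt(t), t / (3 * _DELTA ** 2) + 4.0 / 29.0)
    L = 116.0 * f[..., 1] - 16.0
    a = 500.0 * (f[..., 0] - f[..., 1])
    b = 200.0 * (f[..., 1] - f[..., 2])
    return np.stack([L, a, b], axis=-1)


def rgb_to_lab(image: RGBImage) -> LabImage:
    """Transform an RGB orthoimage to CIELAB, preserving georeferencing and mask."""
    lab = srgb_to_lab(image.pixels)
    # guard against tiny negative L from floating point at pure black
    L = np.clip(lab[..., 0], 0.0, 100.0)
    return LabImage(L=L, a=lab[..., 1], b=lab[..., 2],
                    transform=image.transform, valid_mask=image.valid_mask.copy())


# ---------------------------------------------------------------------------
# k-means on the (a, b) plane


@dataclass
class ClusterModel:
    """Fitted k-means model on (a, b) chroma values."""

    k: int
    centroids: np.ndarray  # k x 2
    seed: int
    inertia: float
    n_iter: int = 0
    inertia_history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.centroids = np.asarray(self.centroids, dtype=float)
        if not (1 <= self.k <= 10):
            raise ValueError(f"k must be in [1, 10], got {self.k}")
        if not np.all(np.isfinite(self.centroids)):
            raise ValueError("centroids must be finite")
        if self.inertia < 0:
            raise ValueError("inertia must be >= 0")


def _farthest_point_seeds(points: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Greedy farthest-point initial centroids; first pick from the RNG, ties by index."""
    n = len(points)
    first = int(rng.integers(n))
    chosen = [first]
    d2 = np.sum((points - points[first]) ** 2, axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))  # argmax takes the lowest index on ties
        chosen.append(nxt)
        d2 = np.minimum(d2, np.sum((points - points[nxt]) ** 2, axis=1))
    return points[chosen].copy()


def _initial_centroids(points: np.ndarray, k: int, seed: int,
                       restart: int) -> np.ndarray:
    """Deterministic restart-diversified seeding.

    Restart 0 is greedy farthest-point from an RNG-chosen start; later
    restarts cycle the starting point through the data and finally fall back
    to random k-subsets, so small instances explore every farthest-point
    seeding before resorting to chance.
    """
    rng = np.random.default_rng(seed)
    n = len(points)
    if restart == 0:
        return _farthest_point_seeds(points, k, rng)
    if restart - 1 < n:
        first = (restart - 1) % n
        chosen = [first]
        d2 = np.sum((points - points[first]) ** 2, axis=1)
        for _ in range(1, k):
            nxt = int(np.argmax(d2))
            chosen.append(nxt)
            d2 = np.minimum(d2, np.sum((points - points[nxt]) ** 2, axis=1))
        return points[chosen].copy()
    idx = rng.choice(n, size=k, replace=False)
    return points[idx].copy()


def _lloyd_from(points: np.ndarray, centroids: np.ndarray, max_iter: int = 300
                ) -> tuple[np.ndarray, np.ndarray, float, int, list]:
    """Lloyd iterations from explicit starting centroids."""
    k = len(centroids)
    centroids = centroids.copy()
    assign = np.full(len(points), -1)
    history: list[float] = []
    for it in range(max_iter):
        d2 = np.sum((points[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
        new_assign = np.argmin(d2, axis=1)
        # empty-cluster repair: re-seed at the point farthest from its centroid
        for c in range(k):
            if not np.any(new_assign == c):
                far = int(np.argmax(d2[np.arange(len(points)), new_assign]))
                centroids[c] = points[far]
                new_assign[far] = c
        inertia = float(np.sum((points - centroids[new_assign]) ** 2))
        history.append(inertia)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for c in range(k):
            centroids[c] = points[assign == c].mean(axis=0)
    # final inertia at the converged means
    inertia = float(np.sum((points - centroids[assign]) ** 2))
    history.append(inertia)
    return centroids, assign, inertia, it + 1, history


def lloyd_kmeans(points: np.ndarray, k: int, seed: int, *, n_init: int = 10,
                 max_iter: int = 300) -> tuple[ClusterModel, np.ndarray]:
    """Deterministic k-means (Lloyd) on an N x 2 point set.

    Runs ``n_init`` restarts with diversified deterministic seedings and keeps
    the lowest-inertia solution. On small instances (all k-subsets of the
    distinct points enumerable within a fixed budget) every k-subset is also
    tried as a start, which in practice reaches the global optimum a single
    greedy-seeded run can miss.

    Raises
    ------
    DegenerateInputError
        If there are fewer distinct points than k.
    """
    from math import comb

    points = np.asarray(points, dtype=float)
    if points.ndim != 2:
        raise ValueError("points must be N x d")
    if not (1 <= k <= 10):
        raise ValueError(f"k must be in [1, 10], got {k}")
    distinct = np.unique(points, axis=0)
    if len(distinct) < k:
        raise DegenerateInputError(
            f"need at least k={k} distinct points, got {len(distinct)}")

    starts = [_initial_centroids(points, k, seed + i, restart=i)
              for i in range(max(1, n_init))]
    if comb(len(distinct), k) <= 256:
        starts.extend(distinct[list(sub)].copy()
                      for sub in itertools.combinations(range(len(distinct)), k))
    best = None
    for cents in starts:
        cen, assign, inertia, n_iter, hist = _lloyd_from(points, cents, max_iter)
        if best is None or inertia < best[2] - 1e-12:
            best = (cen, assign, inertia, n_iter, hist)
    cen, assign, inertia, n_iter, hist = best
    model = ClusterModel(k=k, centroids=cen, seed=seed, inertia=inertia,
                         n_iter=n_iter, inertia_history=hist)
    return model, assign


def kmeans_ab(image: LabImage, k: int, seed: int, *, n_init: int = 4
              ) -> tuple[ClusterModel, np.ndarray]:
    """Cluster the valid pixels of a Lab image on (a, b) only.

    Returns the fitted model and an H x W assignment map with -1 at
    masked-out pixels. The L channel is never consulted, so the result is
    invariant to any constant lightness shift.
    """
    valid = image.valid_mask
    pts = np.column_stack([image.a[valid], image.b[valid]])
    if pts.shape[0] == 0:
        raise DegenerateInputError("no valid pixels to cluster")
    model, assign = lloyd_kmeans(pts, k, seed, n_init=n_init)
    out = np.full(image.shape, -1, dtype=int)
    out[valid] = assign
    return model, out


# ---------------------------------------------------------------------------
# training regions


@dataclass
class TrainingRegion:
    """Operator-selected window plus a reference sketch of the target feature.

    The reference mask must cover at least half the window: training windows
    are picked so the feature of interest dominates the selected area.
    """

    target_class: FeatureClass
    window: tuple[int, int, int, int]  # row0, col0, height, width
    reference_mask: np.ndarray

    def __post_init__(self) -> None:
        r0, c0, h, w = self.window
        if h < 1 or w < 1 or r0 < 0 or c0 < 0:
            raise ValueError(f"invalid window {self.window}")
        self.reference_mask = np.asarray(self.reference_mask, dtype=bool)
        if self.reference_mask.shape != (h, w):
            raise ValueError("reference_mask shape must equal the window shape")
        cover = self.reference_mask.mean()
        if cover < 0.5:
            raise ValueError(
                f"reference mask covers {cover:.0%} of the window; >= 50% required")

    def check_bounds(self, shape: tuple[int, int]) -> None:
        r0, c0, h, w = self.window
        if r0 + h > shape[0] or c0 + w > shape[1]:
            raise ValueError(f"window {self.window} exceeds image shape {shape}")


@dataclass
class TrainingMaskResult:
    """Output of the iterative-k training-mask search."""

    mask: np.ndarray          # boolean over the window
    model: ClusterModel
    chosen_k: int
    jaccard: float
    meets_threshold: bool
    selected_clusters: tuple[int, ...]


def _best_subset(counts: np.ndarray, overlaps: np.ndarray, n_ref: int
                 ) -> tuple[tuple[int, ...], float]:
    """Exhaustively pick the cluster subset with maximal Jaccard vs the reference.

    counts[c] is the cluster size, overlaps[c] the count of cluster pixels
    inside the reference mask. With k <= 10 there are at most 1023 subsets.
    """
    k = len(counts)
    best_subset: tuple[int, ...] = ()
    best_j = -1.0
    for r in range(1, k + 1):
        for subset in itertools.combinations(range(k), r):
            inter = overlaps[list(subset)].sum()
            union = n_ref + counts[list(subset)].sum() - inter
            j = inter / union if union > 0 else 0.0
            if j > best_j + 1e-12:
                best_j = j
                best_subset = subset
    return best_subset, float(best_j)


def build_training_mask(image: LabImage, region: TrainingRegion, *,
                        k_max: int = 10, accept_threshold: float = 0.8,
                        seed: int = 0) -> TrainingMaskResult:
    """Build a binary training mask for one feature class by iterative k-means.

    For k = 2..k_max the window is clustered on (a, b); the union of clusters
    maximising the Jaccard overlap with the operator reference sketch is
    selected (exhaustive subset search). The loop stops at the first k whose
    best Jaccard reaches ``accept_threshold``; otherwise the best k found is
    returned with ``meets_threshold=False``.
    """
    if not (2 <= k_max <= 10):
        raise ValueError(f"k_max must be in [2, 10], got {k_max}")
    region.check_bounds(image.shape)
    r0, c0, h, w = region.window
    valid = image.valid_mask[r0:r0 + h, c0:c0 + w]
    a = image.a[r0:r0 + h, c0:c0 + w]
    b = image.b[r0:r0 + h, c0:c0 + w]
    ref = region.reference_mask & valid
    pts = np.column_stack([a[valid], b[valid]])
    ref_flat = ref[valid]
    n_ref = int(ref_flat.sum())

    best: TrainingMaskResult | None = None
    for k in range(2, k_max + 1):
        try:
            model, assign = lloyd_kmeans(pts, k, seed)
        except DegenerateInputError:
            break
        counts = np.bincount(assign, minlength=k)
        overlaps = np.bincount(assign[ref_flat], minlength=k)
        subset, j = _best_subset(counts, overlaps, n_ref)
        sel_flat = np.isin(assign, subset)
        mask = np.zeros((h, w), dtype=bool)
        mask[valid] = sel_flat
        result = TrainingMaskResult(mask=mask, model=model, chosen_k=k,
                                    jaccard=j, meets_threshold=j >= accept_threshold,
                                    selected_clusters=subset)
        if best is None or j > best.jaccard + 1e-12:
            best = result
        if j >= accept_threshold:
            return result
    assert best is not None
    return best


def load_regions(path: str | Path, image_shape: tuple[int, int]) -> list[TrainingRegion]:
    """Load training regions from a YAML/JSON list.

    Each entry: ``{class: <name>, window: [row0, col0, height, width],
    reference_mask: <raster path, optional>}``. Without a mask path the whole
    window is the reference.
    """
    import yaml

    entries = yaml.safe_load(Path(path).read_text())
    if not isinstance(entries, list):
        raise ValueError(f"{path}: expected a list of region entries")
    regions = []
    base = Path(path).parent
    for e in entries:
        from .classes import parse_class
        window = tuple(int(v) for v in e["window"])
        mpath = e.get("reference_mask")
        if mpath:
            from .imagery_io import read_boundary_mask
            mask = read_boundary_mask(base / mpath)
        else:
            mask = np.ones(window[2:], dtype=bool)
        region = TrainingRegion(target_class=parse_class(e["class"]),
                                window=window, reference_mask=mask)
        region.check_bounds(image_shape)
        regions.append(region)
    return regions
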