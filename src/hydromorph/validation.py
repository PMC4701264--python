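"""Grid-based accuracy assessment and control-point coregistration error.

A regular grid (2 m spacing for a full-scale reach) is overlaid on the
classified map; the truth class at each grid point is compared with the
map category via a confusion matrix, from which overall accuracy

    AC = (TN + TP) / (TN + TP + FN + FP)

and per-class true/false positive/negative ratios

    TPR = TP / (FN + TP)    TNR = TN / (TN + FP)
    FNR = FN / (FN + TP)    FPR = FP / (TN + FP)

are derived by one-vs-rest tallies. Map-side categories merge the non-tree
vegetation classes into VG. For the tree class, tree-row points predicted VG
count as true positives as well as TE (canopy correctly recognised as
vegetation, just not attributed to the tree layer); the convention is
switchable via ``tree_vg_as_tp``.

Coregistration error is the combined planimetric RMSE over control points:
RMSE = sqrt( sum_j [(x_hat_j - x_j)^2 + (y_hat_j - y_j)^2] / N ).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import CATEGORY_OF, PRED_CATEGORIES, TRUTH_ORDER, UNCLASSIFIED, FeatureClass
from .imagery_io import ControlPointPair, GroundTruthPoint
from .rasters import ClassifiedMap


class OutOfExtentError(ValueError):
    """Raised when grid points fall outside the classified map."""

    def __init__(self, indices):
        self.indices = list(indices)
        super().__init__(f"{len(self.indices)} point(s) outside the map extent "
                         f"(first few: {self.indices[:5]})")


# ---------------------------------------------------------------------------
# grid overlay and sampling


def overlay_grid(boundary_extent: tuple[float, float, float, float],
                 spacing: float = 2.0, boundary=None) -> np.ndarray:
    """Axis-aligned lattice of validation points over a world extent.

    The lattice is anchored at the extent's minimum corner and includes both
    edges when they land on the lattice. ``boundary`` may be a
    ``(mask, transform)`` pair or a :class:`ClassifiedMap`; points whose
    nearest pixel is outside the mask (or the raster) are dropped.

    Returns an N x 2 array of (x, y); empty when the extent is degenerate.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    min_x, min_y, max_x, max_y = boundary_extent
    if max_x < min_x or max_y < min_y:
        raise ValueError("degenerate extent")
    eps = spacing * 1e-9
    xs = np.arange(min_x, max_x + eps, spacing)
    ys = np.arange(min_y, max_y + eps, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    if boundary is not None:
        if isinstance(boundary, ClassifiedMap):
            mask, transform = boundary.valid_mask, boundary.transform
        else:
            mask, transform = boundary
        rows, cols = transform.pixel_of(pts[:, 0], pts[:, 1])
        h, w = mask.shape
        e = transform.extent((h, w))
        on_edge = ((pts[:, 0] >= e[0]) & (pts[:, 0] <= e[2])
                   & (pts[:, 1] >= e[1]) & (pts[:, 1] <= e[3]))
        rows = np.where(on_edge, np.clip(rows, 0, h - 1), rows)
        cols = np.where(on_edge, np.clip(cols, 0, w - 1), cols)
        inb = (rows >= 0) & (rows < h) & (cols >= 0) & (cols < w)
        keep = np.zeros(len(pts), dtype=bool)
        keep[inb] = mask[rows[inb], cols[inb]]
        pts = pts[keep]
    return pts


def category_of_label(code: int) -> str:
    """Merged map category for a raster class code ('NC' for unclassified)."""
    if code == UNCLASSIFIED:
        return "NC"
    return CATEGORY_OF[FeatureClass(code)]


def sample_predictions(cmap: ClassifiedMap, points: np.ndarray,
                       ge_mask: np.ndarray | None = None) -> list[str]:
    """Nearest-pixel map category at each grid point.

    Non-tree vegetation labels collapse to the merged VG category. Points on a
    pixel boundary resolve by the round-half-down rule of
    :meth:`GeoTransform.pixel_of`; points whose nearest pixel is outside the
    raster raise :class:`OutOfExtentError` (listing the offending indices)
    rather than being dropped. ``ge_mask`` (from tile fault injection) turns
    affected samples into the GE category.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    rows, cols = cmap.transform.pixel_of(points[:, 0], points[:, 1])
    h, w = cmap.shape
    min_x, min_y, max_x, max_y = cmap.transform.extent((h, w))
    on_edge = ((points[:, 0] >= min_x) & (points[:, 0] <= max_x)
               & (points[:, 1] >= min_y) & (points[:, 1] <= max_y))
    rows = np.where(on_edge, np.clip(rows, 0, h - 1), rows)
    cols = np.where(on_edge, np.clip(cols, 0, w - 1), cols)
    bad = (rows < 0) | (rows >= h) | (cols < 0) | (cols >= w)
    if bad.any():
        raise OutOfExtentError(np.nonzero(bad)[0])
    out = []
    for r, c in zip(rows, cols):
        if ge_mask is not None and ge_mask[r, c]:
            out.append("GE")
        else:
            out.append(category_of_label(int(cmap.labels[r, c])))
    return out


# ---------------------------------------------------------------------------
# confusion matrix and metrics


@dataclass
class ConfusionMatrix:
    """Truth-by-prediction counts over validation grid points."""

    truth_classes: tuple
    pred_categories: tuple
    counts: np.ndarray  # truth x pred integers

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.truth_classes), len(self.pred_categories)):
            raise ValueError("counts shape must be truth x pred")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def col_index(self, category: str) -> int:
        return self.pred_categories.index(category)


def confusion(truth, pred: list[str]) -> ConfusionMatrix:
    """Tally a confusion matrix from aligned truth/prediction lists.

    ``truth`` holds :class:`FeatureClass` values or
    :class:`~hydromorph.imagery_io.GroundTruthPoint`. Prediction categories
    are the merged map categories; GE appears only when fault injection
    flagged points, NC only when unclassified pixels were sampled.
    """
    if len(truth) != len(pred):
        raise ValueError(f"length mismatch: {len(truth)} truth vs {len(pred)} predictions")
    tclasses = [t.truth_class if isinstance(t, GroundTruthPoint) else FeatureClass(t)
                for t in truth]
    cats = list(PRED_CATEGORIES)
    if "NC" in pred:
        cats.append("NC")
    unknown = sorted(set(pred) - set(cats))
    if unknown:
        raise ValueError(f"unknown prediction categories: {unknown}")
    counts = np.zeros((len(TRUTH_ORDER), len(cats)), dtype=np.int64)
    t_index = {c: i for i, c in enumerate(TRUTH_ORDER)}
    c_index = {c: j for j, c in enumerate(cats)}
    for t, p in zip(tclasses, pred):
        counts[t_index[t], c_index[p]] += 1
    return ConfusionMatrix(truth_classes=TRUTH_ORDER, pred_categories=tuple(cats),
                           counts=counts)


@dataclass
class ClassMetrics:
    tp: int
    fn: int
    fp: int
    tn: int
    tpr: float | None
    tnr: float | None
    fnr: float | None
    fpr: float | None


@dataclass
class MetricReport:
    """Overall accuracy plus per-class one-vs-rest ratios.

    ``ac`` is the overall accuracy: the fraction of grid points classified
    correctly (``agreement`` is an alias). ``ac_pooled`` additionally reports
    the accuracy formula evaluated on the pooled one-vs-rest TP/TN/FP/FN
    sums; with merged map categories the pooled value double-counts
    within-category confusions, so ``ac`` is the headline number. Undefined
    ratios (class absent from truth or prediction) are None, never silently
    0 or 1.
    """

    ac: float
    agreement: float
    ac_pooled: float
    n_points: int
    per_class: dict = field(default_factory=dict)

    def tpr(self, cls: FeatureClass) -> float | None:
        return self.per_class[cls].tpr


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def metrics(cm: ConfusionMatrix, *, tree_vg_as_tp: bool = True) -> MetricReport:
    """Per-class TPR/TNR/FNR/FPR and overall AC from a confusion matrix.

    TP for class i is the count in its own merged category column; for the
    tree class, tree-row points in the VG column also count as TP when
    ``tree_vg_as_tp`` (the default convention for canopy recognised as
    vegetation). FN = row total - TP; FP = own-column total - own-column TP;
    TN is the remainder.
    """
    if cm.grand_total == 0:
        raise ValueError("empty confusion matrix")
    row_tot = cm.row_totals()
    col_tot = cm.col_totals()
    n = cm.grand_total
    per_class = {}
    sum_tp = sum_fn = sum_fp = sum_tn = 0
    diag = 0
    for i, cls in enumerate(cm.truth_classes):
        own = CATEGORY_OF[cls]
        j = cm.col_index(own)
        tp_own = int(cm.counts[i, j])
        tp = tp_own
        if tree_vg_as_tp and cls == FeatureClass.TREE and "VG" in cm.pred_categories:
            tp += int(cm.counts[i, cm.col_index("VG")])
        diag += tp
        fn = int(row_tot[i]) - tp
        fp = int(col_tot[j]) - tp_own
        tn = n - tp - fn - fp
        per_class[cls] = ClassMetrics(
            tp=tp, fn=fn, fp=fp, tn=tn,
            tpr=_ratio(tp, fn + tp), tnr=_ratio(tn, tn + fp),
            fnr=_ratio(fn, fn + tp), fpr=_ratio(fp, tn + fp),
        )
        sum_tp += tp; sum_fn += fn; sum_fp += fp; sum_tn += tn
    pooled = (sum_tn + sum_tp) / (sum_tn + sum_tp + sum_fn + sum_fp)
    return MetricReport(ac=diag / n, agreement=diag / n, ac_pooled=float(pooled),
                        n_points=n, per_class=per_class)


# ---------------------------------------------------------------------------
# coregistration


@dataclass(frozen=True)
class CoregistrationReport:
    rmse: float
    mae_x: float
    mae_y: float
    n: int
    role: str | None


def coregistration_rmse(pairs: list[ControlPointPair],
                        role_filter: str | None = None) -> CoregistrationReport:
    """Combined planimetric RMSE (and per-axis MAE) over control-point pairs.

    ``role_filter`` restricts to "GCP" or "XP"; filtering everything away is
    an error rather than a silent zero.
    """
    if role_filter is not None:
        pairs = [p for p in pairs if p.role == role_filter]
    if not pairs:
        raise ValueError(f"no control points left after filtering (role={role_filter})")
    dx = np.array([p.x_img - p.x_ref for p in pairs])
    dy = np.array([p.y_img - p.y_ref for p in pairs])
    rmse = float(np.sqrt(np.mean(dx ** 2 + dy ** 2)))
    return CoregistrationReport(rmse=rmse, mae_x=float(np.abs(dx).mean()),
                                mae_y=float(np.abs(dy).mean()),
                                n=len(pairs), role=role_filter)
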