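"""Assemble per-class training sets from cluster-built masks and train the
one-vs-rest classifier set for a reach."""

from __future__ import annotations

import numpy as np

from .ann_classifier import BinaryClassifier, TrainingSet, image_features, train_binary_mlp
from .classes import FeatureClass
from .colour_cluster import TrainingRegion, build_training_mask, rgb_to_lab
from .rasters import RGBImage


def assemble_training_set(features_by_class: dict, target_class: FeatureClass,
                          *, max_positives: int = 3000,
                          negatives_per_positive: float = 2.0,
                          seed: int = 0) -> TrainingSet:
    """Build a balanced binary training set for one target class.

    Positives come from the target class's pixel features; negatives are
    drawn evenly across the other classes, ``negatives_per_positive`` per
    positive in total. Balancing keeps the MSE-trained sigmoid output
    comparable to the 0.5 decision threshold.
    """
    rng = np.random.default_rng(seed)
    if target_class not in features_by_class:
        raise ValueError(f"no features for target class {target_class.name}")
    pos = np.asarray(features_by_class[target_class], dtype=float)
    if len(pos) > max_positives:
        pos = pos[rng.choice(len(pos), max_positives, replace=False)]
    others = [c for c in features_by_class if c != target_class]
    if not others:
        raise ValueError("need at least one non-target class for negatives")
    n_neg_total = max(1, int(round(len(pos) * negatives_per_positive)))
    # floor per-class negatives so small positive sets still see every
    # competing colour cluster well enough to pin the decision boundary
    per_class = max(1, n_neg_total // len(others), min(300, max_positives))
    negs = []
    for c in others:
        f = np.asarray(features_by_class[c], dtype=float)
        take = min(per_class, len(f))
        negs.append(f[rng.choice(len(f), take, replace=False)])
    neg = np.vstack(negs)
    feats = np.vstack([pos, neg])
    labels = np.concatenate([np.ones(len(pos), bool), np.zeros(len(neg), bool)])
    return TrainingSet(features=feats, labels=labels)


def train_classifiers(image: RGBImage, regions: list[TrainingRegion], *,
                      feature_space: str = "ab", hidden_size: int = 8,
                      max_iter: int = 200, k_max: int = 10,
                      accept_threshold: float = 0.8,
                      max_positives: int = 3000, seed: int = 0
                      ) -> tuple[list[BinaryClassifier], dict]:
    """Full training workflow: cluster each region, collect masked pixel
    features per class, and train one binary MLP per class.

    Returns the classifier list (class-code order) and a diagnostics dict with
    each region's chosen k and Jaccard overlap.
    """
    lab = rgb_to_lab(image)
    feats_full = image_features(lab, feature_space, rgb=image.pixels)
    features_by_class: dict[FeatureClass, list] = {}
    diagnostics: dict = {"regions": []}
    for i, region in enumerate(regions):
        result = build_training_mask(lab, region, k_max=k_max,
                                     accept_threshold=accept_threshold,
                                     seed=seed + 17 * i)
        r0, c0, h, w = region.window
        window_feats = feats_full[r0:r0 + h, c0:c0 + w][result.mask]
        features_by_class.setdefault(region.target_class, []).append(window_feats)
        diagnostics["regions"].append({
            "class": region.target_class.name,
            "window": list(region.window),
            "chosen_k": result.chosen_k,
            "jaccard": result.jaccard,
            "meets_threshold": result.meets_threshold,
            "n_pixels": int(result.mask.sum()),
        })
    merged = {c: np.vstack(v) for c, v in features_by_class.items()}
    classifiers = []
    for j, cls in enumerate(sorted(merged, key=int)):
        ts = assemble_training_set(merged, cls, max_positives=max_positives,
                                   seed=seed + 101 * j)
        clf = train_binary_mlp(ts, target_class=cls, feature_space=feature_space,
                               hidden_size=hidden_size, max_iter=max_iter,
                               seed=seed + 1009 * j)
        classifiers.append(clf)
    diagnostics["iterations"] = {c.target_class.name: c.iterations_used
                                 for c in classifiers}
    return classifiers, diagnostics
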