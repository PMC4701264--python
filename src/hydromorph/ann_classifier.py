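"""One-vs-rest binary multilayer perceptrons for per-class pixel classification.

Each feature class gets its own three-layer network (input, hidden, output)
with sigmoid activations and a single output node that is trained to 1 on
pixels of the target feature and 0 on everything else. Training minimises the
mean squared estimation error with a quasi-Newton (BFGS) optimiser driven by
analytic backpropagated gradients. Inputs default to the chromatic (a, b)
pair to match the clustering space; (L, a, b) and raw RGB are selectable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize

from .classes import FeatureClass
from .rasters import LabImage

FEATURE_SPACES = ("ab", "lab", "rgb")


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


@dataclass
class TrainingSet:
    """Feature matrix plus binary labels (1 = target feature, 0 = other)."""

    features: np.ndarray  # N x input_dim
    labels: np.ndarray    # N booleans

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels).astype(bool)
        if self.features.ndim != 2 or len(self.features) != len(self.labels):
            raise ValueError("features must be N x d aligned with N labels")
        if len(self.labels) < 2:
            raise ValueError("need at least 2 training samples")
        if not np.all(np.isfinite(self.features)):
            raise ValueError("features must be finite")


@dataclass
class BinaryClassifier:
    """A trained one-vs-rest MLP for a single feature class.

    ``input_mean``/``input_scale`` standardise features before the forward
    pass (stored from the training set); ``threshold`` converts the sigmoid
    activation into a binary mask.
    """

    target_class: FeatureClass
    feature_space: str
    input_dim: int
    hidden_size: int
    weights_in: np.ndarray   # input_dim x hidden
    bias_hidden: np.ndarray  # hidden
    weights_out: np.ndarray  # hidden
    bias_out: float
    input_mean: np.ndarray
    input_scale: np.ndarray
    threshold: float = 0.5
    iterations_used: int = 0
    converged: bool = True
    seed: int = 0
    loss_history: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if self.feature_space not in FEATURE_SPACES:
            raise ValueError(f"feature_space must be one of {FEATURE_SPACES}")
        if not (0.0 < self.threshold < 1.0):
            raise ValueError("threshold must be in (0, 1)")
        if self.hidden_size < 1:
            raise ValueError("hidden_size must be >= 1")
        for arr in (self.weights_in, self.bias_hidden, self.weights_out,
                    self.input_mean, self.input_scale):
            if not np.all(np.isfinite(arr)):
                raise ValueError("classifier parameters must be finite")

    def decision(self, features: np.ndarray) -> np.ndarray:
        """Output-node pre-activation (logit). Monotone in the activation but
        free of sigmoid saturation, so comparisons between classifiers remain
        meaningful where activations would round to exactly 1.0."""
        x = (np.asarray(features, dtype=float) - self.input_mean) / self.input_scale
        if x.shape[-1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} input features, got {x.shape[-1]}")
        hidden = _sigmoid(x @ self.weights_in + self.bias_hidden)
        return hidden @ self.weights_out + self.bias_out

    def activation(self, features: np.ndarray) -> np.ndarray:
        """Forward pass: sigmoid(w_out . sigmoid(W_in x + b_h) + b_out)."""
        return _sigmoid(self.decision(features))

    @property
    def decision_cut(self) -> float:
        """Logit value equivalent to ``threshold`` on the activation scale."""
        return float(np.log(self.threshold / (1.0 - self.threshold)))


def _unpack(theta: np.ndarray, d: int, h: int):
    i = 0
    w1 = theta[i:i + d * h].reshape(d, h); i += d * h
    b1 = theta[i:i + h]; i += h
    w2 = theta[i:i + h]; i += h
    b2 = theta[i]
    return w1, b1, w2, b2


def _mse_loss_grad(theta: np.ndarray, x: np.ndarray, y: np.ndarray,
                   d: int, h: int, sw: np.ndarray | None = None
                   ) -> tuple[float, np.ndarray]:
    n = len(x)
    if sw is None:
        sw = np.full(n, 1.0 / n)
    w1, b1, w2, b2 = _unpack(theta, d, h)
    a1 = _sigmoid(x @ w1 + b1)            # N x h
    out = _sigmoid(a1 @ w2 + b2)          # N
    err = out - y
    loss = float(np.sum(sw * err ** 2))
    dz2 = 2.0 * sw * err * out * (1.0 - out)       # N
    gw2 = a1.T @ dz2
    gb2 = dz2.sum()
    da1 = np.outer(dz2, w2)
    dz1 = da1 * a1 * (1.0 - a1)
    gw1 = x.T @ dz1
    gb1 = dz1.sum(axis=0)
    grad = np.concatenate([gw1.ravel(), gb1, gw2, [gb2]])
    return loss, grad


def train_binary_mlp(data: TrainingSet, *, target_class: FeatureClass | None = None,
                     feature_space: str = "ab", hidden_size: int = 8,
                     max_iter: int = 200, tol: float = 1e-6, threshold: float = 0.5,
                     n_restarts: int = 6, seed: int = 0) -> BinaryClassifier:
    """Train a binary MLP on a labelled feature set.

    Weights are initialised uniformly in (-0.5, 0.5) and fitted by BFGS on the
    mean squared error between the sigmoid output and the 0/1 labels. MSE with
    saturating sigmoids has poor local minima, so ``n_restarts`` runs with
    derived seeds (seed, seed+1, ...) are made and the lowest-loss fit kept;
    the whole procedure is deterministic given ``seed``. Non-convergence
    within ``max_iter`` iterations is reported via the ``converged`` flag on
    the returned classifier, never as an exception.
    """
    x_raw = data.features
    y = data.labels.astype(float)
    d = x_raw.shape[1]
    mean = x_raw.mean(axis=0)
    scale = x_raw.std(axis=0)
    scale = np.where(scale < 1e-8, 1.0, scale)
    x = (x_raw - mean) / scale

    # class-balanced sample weights: each label class contributes half the loss
    n_pos = float(y.sum())
    n_neg = float(len(y) - n_pos)
    if n_pos > 0 and n_neg > 0:
        sw = np.where(y > 0.5, 0.5 / n_pos, 0.5 / n_neg)
    else:
        sw = np.full(len(y), 1.0 / len(y))

    n_params = d * hidden_size + hidden_size + hidden_size + 1
    best = None
    for i in range(max(1, n_restarts)):
        rng = np.random.default_rng(seed + i)
        theta0 = rng.uniform(-0.5, 0.5, size=n_params)
        history: list[float] = [_mse_loss_grad(theta0, x, y, d, hidden_size, sw)[0]]

        def callback(theta):
            history.append(_mse_loss_grad(theta, x, y, d, hidden_size, sw)[0])

        res = minimize(_mse_loss_grad, theta0, args=(x, y, d, hidden_size, sw),
                       method="BFGS", jac=True, callback=callback,
                       options={"maxiter": max_iter, "gtol": tol})
        if best is None or res.fun < best[0].fun - 1e-15:
            best = (res, history)
    res, history = best
    w1, b1, w2, b2 = _unpack(res.x, d, hidden_size)
    return BinaryClassifier(
        target_class=target_class if target_class is not None else FeatureClass.SIDE_BAR,
        feature_space=feature_space, input_dim=d, hidden_size=hidden_size,
        weights_in=w1, bias_hidden=b1, weights_out=w2, bias_out=float(b2),
        input_mean=mean, input_scale=scale, threshold=threshold,
        iterations_used=int(res.nit), converged=bool(res.success or res.nit < max_iter),
        seed=seed, loss_history=history,
    )


def image_features(image: LabImage, feature_space: str,
                   rgb: np.ndarray | None = None) -> np.ndarray:
    """Per-pixel feature stack (H x W x d) for the requested feature space.

    ``rgb`` (H x W x 3, 0-255) must be supplied for the "rgb" space since a
    Lab image does not carry the original pixel values.
    """
    if feature_space == "ab":
        return np.stack([image.a, image.b], axis=-1)
    if feature_space == "lab":
        return np.stack([image.L, image.a, image.b], axis=-1)
    if feature_space == "rgb":
        if rgb is None:
            raise ValueError("feature_space 'rgb' needs the original RGB array")
        return np.asarray(rgb, dtype=float)
    raise ValueError(f"unknown feature space {feature_space!r}")


def predict_mask(clf: BinaryClassifier, image: LabImage,
                 rgb: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Apply a classifier pixelwise; returns (mask, activation).

    Masked-out pixels get activation 0 and mask False. The mask is
    ``activation >= threshold`` elsewhere.
    """
    feats = image_features(image, clf.feature_space, rgb)
    if feats.shape[-1] != clf.input_dim:
        raise ValueError(f"classifier expects input_dim={clf.input_dim}, "
                         f"features have {feats.shape[-1]}")
    valid = image.valid_mask
    act = np.zeros(image.shape, dtype=float)
    act[valid] = clf.activation(feats[valid])
    mask = (act >= clf.threshold) & valid
    return mask, act


# ---------------------------------------------------------------------------
# serialisation


def save_bundle(classifiers: list[BinaryClassifier], path: str | Path) -> None:
    """Serialise classifiers to one portable JSON bundle."""
    payload = []
    for c in classifiers:
        payload.append({
            "target_class": c.target_class.name,
            "feature_space": c.feature_space,
            "input_dim": c.input_dim,
            "hidden_size": c.hidden_size,
            "weights_in": c.weights_in.tolist(),
            "bias_hidden": c.bias_hidden.tolist(),
            "weights_out": c.weights_out.tolist(),
            "bias_out": c.bias_out,
            "input_mean": c.input_mean.tolist(),
            "input_scale": c.input_scale.tolist(),
            "threshold": c.threshold,
            "iterations_used": c.iterations_used,
            "converged": c.converged,
            "seed": c.seed,
        })
    Path(path).write_text(json.dumps({"format": "hydromorph-bundle-1",
                                      "classifiers": payload}, indent=1))


def load_bundle(path: str | Path) -> list[BinaryClassifier]:
    doc = json.loads(Path(path).read_text())
    if doc.get("format") != "hydromorph-bundle-1":
        raise ValueError(f"{path} is not a hydromorph classifier bundle")
    out = []
    for e in doc["classifiers"]:
        out.append(BinaryClassifier(
            target_class=FeatureClass[e["target_class"]],
            feature_space=e["feature_space"], input_dim=e["input_dim"],
            hidden_size=e["hidden_size"],
            weights_in=np.asarray(e["weights_in"], dtype=float),
            bias_hidden=np.asarray(e["bias_hidden"], dtype=float),
            weights_out=np.asarray(e["weights_out"], dtype=float),
            bias_out=float(e["bias_out"]),
            input_mean=np.asarray(e["input_mean"], dtype=float),
            input_scale=np.asarray(e["input_scale"], dtype=float),
            threshold=float(e["threshold"]),
            iterations_used=int(e["iterations_used"]),
            converged=bool(e["converged"]), seed=int(e["seed"]),
        ))
    return out
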