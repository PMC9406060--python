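"""Ridge-regression encoding baseline on multi-layer image features.

The control model extracts features from a fixed (untrained here)
multi-layer convolutional network — five pooling stages and two fully
connected stages, seven layers in total — fits a ridge regression from
each layer's features to the voxel responses over a grid of penalties, and
selects the layer/penalty with the best training-set mean accuracy. The
extractor is pluggable: any object with an ``extract(images) -> {name:
(n, D)}`` method works, e.g. one wrapping a pretrained classification
network (weights must be supplied by the user; none are bundled).
``RandomFeatureExtractor`` provides a fixed-seed random-weight extractor
of the same seven-layer shape for self-contained runs and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import Ridge

from .datasets import VoxelResponses
from .evaluation import AccuracyVector, pearson_accuracy
from .nn import conv_forward, conv_output_size

__all__ = ["LayerFeatureSet", "RandomFeatureExtractor", "RidgeResult", "ridge_encode"]

DEFAULT_LAMBDAS = tuple(np.logspace(-2, 4, 7))


@dataclass
class LayerFeatureSet:
    """Ordered map layer-name -> (n, D) feature matrix per split."""

    names: list[str]
    train: dict[str, np.ndarray]
    val: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        n_train = {self.train[n].shape[0] for n in self.names}
        n_val = {self.val[n].shape[0] for n in self.names}
        if len(n_train) != 1 or len(n_val) != 1:
            raise ValueError("all layers must share the sample count")


class RandomFeatureExtractor:
    """Seven-layer random-weight feature extractor (5 pool + 2 fc).

    Weights are drawn once from a fixed seed; extraction is deterministic
    thereafter. Synthetic stand-in for a pretrained feature extractor.
    """

    def __init__(self, side: int, seed: int = 0, base_channels: int = 16, fc_dim: int = 256) -> None:
        rng = np.random.default_rng(seed)
        self.side = side
        self._convs = []
        c_in = 1
        s = side
        for stage in range(5):
            c_out = base_channels * min(2**stage, 8)
            k = 3
            fan = c_in * k * k
            w = rng.normal(0, np.sqrt(2.0 / fan), (c_out, c_in, k, k))
            self._convs.append(w)
            c_in = c_out
            s = conv_output_size(s, k, 1, 1) // 2  # conv then 2x2 pool
            if s < 1:
                raise ValueError(f"side {side} too small for five pooling stages")
        flat = c_in * s * s
        self._fc = [
            rng.normal(0, np.sqrt(1.0 / flat), (flat, fc_dim)),
            rng.normal(0, np.sqrt(1.0 / fc_dim), (fc_dim, fc_dim)),
        ]

    @staticmethod
    def _pool2(x: np.ndarray) -> np.ndarray:
        n, c, h, w = x.shape
        h2, w2 = h - h % 2, w - w % 2
        x = x[:, :, :h2, :w2].reshape(n, c, h2 // 2, 2, w2 // 2, 2)
        return x.mean(axis=(3, 5))

    def extract(self, images: np.ndarray) -> dict[str, np.ndarray]:
        x = np.asarray(images, dtype=np.float64)
        if x.ndim == 3:
            x = x[:, None]
        feats: dict[str, np.ndarray] = {}
        for i, w in enumerate(self._convs, start=1):
            x, _ = conv_forward(x, w, None, stride=1, pad=1)
            x = np.maximum(x, 0.0)
            x = self._pool2(x)
            feats[f"pool{i}"] = x.reshape(x.shape[0], -1)
        flat = x.reshape(x.shape[0], -1)
        fc6 = np.maximum(flat @ self._fc[0], 0.0)
        fc7 = np.maximum(fc6 @ self._fc[1], 0.0)
        feats["fc6"] = fc6
        feats["fc7"] = fc7
        return feats

    def layer_features(self, train_images: np.ndarray, val_images: np.ndarray) -> LayerFeatureSet:
        tr = self.extract(train_images)
        va = self.extract(val_images)
        return LayerFeatureSet(names=list(tr), train=tr, val=va)


@dataclass
class RidgeResult:
    selected_layer: str
    selected_lambda: float
    train_scores: dict[str, dict[float, float]]  # layer -> lambda -> mean train rho
    val_predictions: np.ndarray
    val_accuracy: AccuracyVector
    coefs: np.ndarray = field(repr=False, default=None)
    intercept: np.ndarray = field(repr=False, default=None)


def ridge_encode(
    features: LayerFeatureSet,
    responses: VoxelResponses,
    lambdas=DEFAULT_LAMBDAS,
    *,
    threshold: float = 0.27,
) -> RidgeResult:
    """Fit ridge maps per layer and penalty; select by training mean accuracy.

    Returns the selected model's validation predictions and accuracy.
    Requesting a non-positive penalty on a rank-deficient design raises,
    advising a positive penalty.
    """
    lambdas = list(lambdas)
    if not lambdas:
        raise ValueError("lambda grid must be nonempty")
    y = responses.train
    best = None
    scores: dict[str, dict[float, float]] = {}
    for name in features.names:
        x = features.train[name]
        if x.shape[0] != y.shape[0]:
            raise ValueError(f"layer {name}: sample count mismatch")
        scores[name] = {}
        for lam in lambdas:
            if lam <= 0:
                if np.linalg.matrix_rank(x) < x.shape[1]:
                    raise ValueError(
                        f"layer {name} is rank-deficient; an unpenalized fit is "
                        "ill-posed — use a penalty lambda > 0"
                    )
                lam = 1e-12
            model = Ridge(alpha=lam, fit_intercept=True)
            model.fit(x, y)
            train_pred = model.predict(x).reshape(x.shape[0], -1)
            train_acc = pearson_accuracy(y, train_pred, threshold=threshold)
            score = (
                float(np.mean(train_acc.rho[train_acc.defined]))
                if train_acc.defined.any()
                else -np.inf
            )
            scores[name][float(lam)] = score
            if best is None or score > best[0]:
                best = (score, name, float(lam), model)
    _, layer, lam, model = best
    val_pred = model.predict(features.val[layer])
    val_pred = val_pred.reshape(features.val[layer].shape[0], -1)
    acc = pearson_accuracy(responses.val, val_pred, threshold=threshold)
    return RidgeResult(
        selected_layer=layer,
        selected_lambda=lam,
        train_scores=scores,
        val_predictions=val_pred,
        val_accuracy=acc,
        coefs=model.coef_,
        intercept=model.intercept_,
    )
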