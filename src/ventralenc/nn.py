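"""Minimal NumPy neural-network engine used by the encoding models.

Implements exactly what the encoders need — strided 2-D convolution
(im2col), rectifier, affine maps, mean-squared-error loss and the Adam
optimizer — with hand-written backprop. Everything is deterministic given
the weights and inputs; randomness enters only through the initializers'
`numpy.random.Generator`.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "conv_output_size",
    "conv_forward",
    "conv_backward",
    "Layer",
    "Conv2d",
    "Linear",
    "ReLU",
    "Flatten",
    "Network",
    "Adam",
    "mse_loss",
]


def conv_output_size(side: int, kernel: int, stride: int, pad: int) -> int:
    """Spatial output size of a strided convolution."""
    out = (side + 2 * pad - kernel) // stride + 1
    if out < 1:
        raise ValueError(
            f"convolution collapses: side={side}, kernel={kernel}, "
            f"stride={stride}, pad={pad}"
        )
    return out


def _im2col(x: np.ndarray, kernel: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C, Ho, Wo, k, k) view of sliding patches."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = sliding_window_view(x, (kernel, kernel), axis=(2, 3))
    return win[:, :, ::stride, ::stride]


def conv_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray | None, stride: int, pad: int
):
    """Strided 2-D convolution (cross-correlation).

    x: (N, C, H, W); w: (O, C, k, k); b: (O,) or None.
    Returns (y, cache) with y of shape (N, O, Ho, Wo).
    """
    k = w.shape[-1]
    cols = _im2col(x, k, stride, pad)
    y = np.tensordot(cols, w, axes=([1, 4, 5], [1, 2, 3]))  # (N, Ho, Wo, O)
    y = np.ascontiguousarray(y.transpose(0, 3, 1, 2))
    if b is not None:
        y += b[None, :, None, None]
    cache = (cols, w, x.shape, stride, pad)
    return y, cache


def conv_backward(gy: np.ndarray, cache, need_dx: bool = True):
    """Gradients of conv_forward. Returns (dx, dw, db); dx None if skipped."""
    cols, w, x_shape, stride, pad = cache
    k = w.shape[-1]
    dw = np.tensordot(gy, cols, axes=([0, 2, 3], [0, 2, 3]))  # (O, C, k, k)
    db = gy.sum(axis=(0, 2, 3))
    dx = None
    if need_dx:
        n, c, h, wdt = x_shape
        ho, wo = gy.shape[2], gy.shape[3]
        dcols = np.einsum("nohw,ocij->nchwij", gy, w)
        gxp = np.zeros((n, c, h + 2 * pad, wdt + 2 * pad), dtype=gy.dtype)
        for i in range(k):
            for j in range(k):
                gxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[
                    :, :, :, :, i, j
                ]
        dx = gxp[:, :, pad : pad + h, pad : pad + wdt] if pad else gxp
    return dx, dw, db


class Layer:
    """Base layer: named parameters + matching gradient slots."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def project(self) -> None:
        """Hook to re-impose parameter-domain constraints after a step."""


class Conv2d(Layer):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel: int,
        stride: int = 1,
        pad: int = 0,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
        input_grad: bool = True,
    ) -> None:
        super().__init__()
        self.stride, self.pad = stride, pad
        self.input_grad = input_grad
        fan_in = in_channels * kernel * kernel
        self.params["w"] = rng.normal(
            0.0, np.sqrt(2.0 / fan_in), (out_channels, in_channels, kernel, kernel)
        ).astype(dtype)
        self.params["b"] = np.zeros(out_channels, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        y, self._cache = conv_forward(x, self.params["w"], self.params["b"], self.stride, self.pad)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        dx, dw, db = conv_backward(gy, self._cache, need_dx=self.input_grad)
        self.grads["w"], self.grads["b"] = dw, db
        return dx


class Linear(Layer):
    def __init__(
        self, in_dim: int, out_dim: int, *, rng: np.random.Generator, dtype=np.float32
    ) -> None:
        super().__init__()
        self.params["w"] = rng.normal(0.0, np.sqrt(1.0 / in_dim), (in_dim, out_dim)).astype(dtype)
        self.params["b"] = np.zeros(out_dim, dtype=dtype)

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.params["w"].shape[0]:
            raise ValueError(
                f"feature width {x.shape[1]} does not match affine input width "
                f"{self.params['w'].shape[0]}"
            )
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["w"] = self._x.T @ gy
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["w"].T


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0)


class Flatten(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return gy.reshape(self._shape)


class Network:
    """A plain sequential stack with state-dict checkpointing."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x)
        return x

    __call__ = forward

    def backward(self, gy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gy = layer.backward(gy)
        return gy

    def parameters(self) -> Iterator[tuple[Layer, str]]:
        for layer in self.layers:
            for name in layer.params:
                yield layer, name

    def state_dict(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{name}": layer.params[name].copy()
            for i, layer in enumerate(self.layers)
            for name in layer.params
        }

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for key, value in state.items():
            idx, name = key.split(".", 1)
            layer = self.layers[int(idx)]
            if layer.params[name].shape != value.shape:
                raise ValueError(f"shape mismatch for {key}")
            layer.params[name] = np.array(value, dtype=layer.params[name].dtype)

    def project(self) -> None:
        for layer in self.layers:
            layer.project()


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(
        self,
        params: list[tuple[Layer, str]],
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(layer.params[name], dtype=np.float64) for layer, name in self.params]
        self._v = [np.zeros_like(layer.params[name], dtype=np.float64) for layer, name in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, (layer, name) in enumerate(self.params):
            g = layer.grads.get(name)
            if g is None:
                continue
            self._m[i] = self.beta1 * self._m[i] + (1 - self.beta1) * g
            self._v[i] = self.beta2 * self._v[i] + (1 - self.beta2) * g * g
            mhat = self._m[i] / b1t
            vhat = self._v[i] / b2t
            p = layer.params[name]
            new = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and name == "w":  # decoupled decay, weights only
                new = new - self.lr * self.weight_decay * p
            layer.params[name] = new.astype(p.dtype)


def mse_loss(pred: np.ndarray, target: np.ndarray):
    """Mean-squared error over all entries; returns (loss, grad wrt pred)."""
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")
    diff = pred - target
    loss = float(np.mean(diff * diff))
    grad = (2.0 / diff.size) * diff
    return loss, grad.astype(pred.dtype)
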