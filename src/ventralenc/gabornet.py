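"""Stage-1 visual encoder: a learnable Gabor convolutional front end.

The encoder is a small convolutional network whose first layer is a bank of
quadrature Gabor kernels: each of the parameter tuples (orientation theta,
wavelength lambda, envelope scale sigma, aspect ratio gamma, phase psi)
expands to an even (cosine-carrier) kernel and an odd (sine-carrier)
quadrature partner, so 64 tuples yield 128 kernels. The Gabor parameters
themselves are trained by backprop through the kernel construction. Two
regular convolutional layers follow, and a linear (or two-layer nonlinear)
readout maps the flattened final feature map to per-voxel predictions.

With the default 128x128 input the three convolutional stages produce
128x62x62, 128x31x31 and 128x16x16 activations; the flattened feature
space has 32,768 dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import (
    Conv2d,
    Flatten,
    Layer,
    Linear,
    Network,
    ReLU,
    conv_backward,
    conv_forward,
    conv_output_size,
)

__all__ = [
    "GaborParams",
    "BackboneSpec",
    "ReadoutSpec",
    "build_gabor_kernels",
    "gabor_kernel_grads",
    "GaborConv2d",
    "GaborNet",
]


@dataclass
class GaborParams:
    """Per-tuple Gabor parameters; tuple i yields kernels i (even) and
    n+i (odd, phase shifted by pi/2)."""

    theta: np.ndarray  # orientation, radians
    lam: np.ndarray  # wavelength, pixels (> 0)
    sigma: np.ndarray  # envelope scale, pixels (> 0)
    gamma: np.ndarray  # spatial aspect ratio (> 0)
    psi: np.ndarray  # phase, radians

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=np.float64) for a in (self.theta, self.lam, self.sigma, self.gamma, self.psi)]
        self.theta, self.lam, self.sigma, self.gamma, self.psi = arrays
        n = self.theta.shape[0]
        if any(a.shape != (n,) for a in arrays):
            raise ValueError("all Gabor parameter arrays must share one length")
        self.validate()

    def validate(self) -> None:
        if np.any(self.lam <= 0):
            raise ValueError("wavelength lambda must be positive")
        if np.any(self.sigma <= 0):
            raise ValueError("envelope scale sigma must be positive")
        if np.any(self.gamma <= 0):
            raise ValueError("aspect ratio gamma must be positive")

    @property
    def n_tuples(self) -> int:
        return self.theta.shape[0]

    @classmethod
    def default_bank(cls, n_tuples: int = 64) -> "GaborParams":
        """Conventional initial bank: log-spaced wavelengths in [3, 10] px,
        orientations evenly covering [0, pi), sigma = lambda/2, gamma 1, psi 0."""
        n_scales = max(1, n_tuples // 8)
        lams = np.geomspace(3.0, 10.0, n_scales)
        thetas = np.arange(n_tuples) % 8 * (np.pi / 8)
        lam = np.repeat(lams, 8)[:n_tuples]
        if lam.shape[0] < n_tuples:  # n_tuples not a multiple of 8
            lam = np.resize(np.repeat(lams, 8), n_tuples)
        return cls(
            theta=thetas,
            lam=lam,
            sigma=0.5 * lam,
            gamma=np.ones(n_tuples),
            psi=np.zeros(n_tuples),
        )


def _gabor_terms(params: GaborParams, size: int, psi: np.ndarray):
    """Common subexpressions on the centered integer grid.

    Row index is y, column index is x, both running over
    [-(size-1)/2, (size-1)/2].
    """
    half = (size - 1) // 2
    coords = np.arange(-half, half + 1, dtype=np.float64)
    y = coords[:, None]  # rows
    x = coords[None, :]  # columns
    ct = np.cos(params.theta)[:, None, None]
    st = np.sin(params.theta)[:, None, None]
    xp = x * ct + y * st
    yp = -x * st + y * ct
    sig = params.sigma[:, None, None]
    gam = params.gamma[:, None, None]
    lam = params.lam[:, None, None]
    q = xp * xp + gam * gam * yp * yp
    env = np.exp(-q / (2.0 * sig * sig))
    arg = 2.0 * np.pi * xp / lam + psi[:, None, None]
    return xp, yp, q, env, arg


def build_gabor_kernels(params: GaborParams, size: int = 9) -> np.ndarray:
    """Evaluate the quadrature Gabor bank on a size x size grid.

    Returns (2n, 1, size, size): kernels 0..n-1 carry the even (cosine)
    phase psi, kernels n..2n-1 the odd partner at psi + pi/2.
    """
    if size % 2 == 0 or size < 1:
        raise ValueError(f"kernel size must be odd and positive, got {size}")
    params.validate()
    kernels = []
    for phase in (params.psi, params.psi + np.pi / 2):
        _, _, _, env, arg = _gabor_terms(params, size, phase)
        kernels.append(env * np.cos(arg))
    return np.concatenate(kernels, axis=0)[:, None, :, :]


def gabor_kernel_grads(params: GaborParams, size: int, dk: np.ndarray) -> dict[str, np.ndarray]:
    """Backprop the loss gradient on kernel pixels to the Gabor parameters.

    dk: (2n, 1, size, size) gradient wrt the kernels from build_gabor_kernels.
    Returns per-parameter gradients of length n (even and odd contributions
    are summed, since both kernels share one tuple).
    """
    n = params.n_tuples
    out = {name: np.zeros(n) for name in ("theta", "lam", "sigma", "gamma", "psi")}
    dk = dk[:, 0, :, :]
    for half, phase in enumerate((params.psi, params.psi + np.pi / 2)):
        g = dk[half * n : (half + 1) * n]
        xp, yp, q, env, arg = _gabor_terms(params, size, phase)
        c, s = np.cos(arg), np.sin(arg)
        sig = params.sigma[:, None, None]
        gam = params.gamma[:, None, None]
        lam = params.lam[:, None, None]
        denv_dtheta = -env * xp * yp * (1.0 - gam * gam) / (sig * sig)
        dc_dtheta = -s * (2.0 * np.pi / lam) * yp
        out["theta"] += np.sum(g * (denv_dtheta * c + env * dc_dtheta), axis=(1, 2))
        out["lam"] += np.sum(g * env * s * (2.0 * np.pi * xp / (lam * lam)), axis=(1, 2))
        out["sigma"] += np.sum(g * env * c * q / (sig**3), axis=(1, 2))
        out["gamma"] += np.sum(g * (-env * c * gam * yp * yp / (sig * sig)), axis=(1, 2))
        out["psi"] += np.sum(g * (-env * s), axis=(1, 2))
    return out


# Lower bounds keeping the bank inside its parameter domain during training.
_GABOR_FLOORS = {"lam": 1.0, "sigma": 0.3, "gamma": 0.05}


class GaborConv2d(Layer):
    """Convolution whose kernels are rebuilt from Gabor parameters each pass."""

    def __init__(
        self,
        params: GaborParams,
        size: int = 9,
        stride: int = 2,
        pad: int = 2,
        *,
        dtype=np.float32,
        trainable: bool = True,
    ) -> None:
        super().__init__()
        self.size, self.stride, self.pad = size, stride, pad
        self.dtype = dtype
        self.trainable = trainable
        self.params = {
            "theta": params.theta.copy(),
            "lam": params.lam.copy(),
            "sigma": params.sigma.copy(),
            "gamma": params.gamma.copy(),
            "psi": params.psi.copy(),
            "b": np.zeros(2 * params.n_tuples, dtype=dtype),
        }

    def gabor_params(self) -> GaborParams:
        return GaborParams(
            theta=self.params["theta"],
            lam=self.params["lam"],
            sigma=self.params["sigma"],
            gamma=self.params["gamma"],
            psi=self.params["psi"],
        )

    def kernels(self) -> np.ndarray:
        return build_gabor_kernels(self.gabor_params(), self.size)

    def forward(self, x: np.ndarray) -> np.ndarray:
        w = self.kernels().astype(self.dtype)
        y, self._cache = conv_forward(x, w, self.params["b"], self.stride, self.pad)
        return y

    def backward(self, gy: np.ndarray) -> np.ndarray:
        _, dw, db = conv_backward(gy, self._cache, need_dx=False)
        self.grads["b"] = db
        if self.trainable:
            pgrads = gabor_kernel_grads(self.gabor_params(), self.size, dw.astype(np.float64))
            self.grads.update(pgrads)
        else:
            for name in ("theta", "lam", "sigma", "gamma", "psi"):
                self.grads.pop(name, None)
        return None  # first layer: input gradient not needed

    def project(self) -> None:
        for name, floor in _GABOR_FLOORS.items():
            np.maximum(self.params[name], floor, out=self.params[name])


@dataclass
class BackboneSpec:
    """Architecture of the three-stage convolutional backbone.

    Defaults reproduce the reference dimension chain for 128x128 input:
    conv1 (9x9, stride 2, pad 2) -> 128x62x62; conv2 (3x3, stride 2,
    pad 1) -> 128x31x31; conv3 (3x3, stride 2, pad 1) -> 128x16x16,
    flattening to 32,768 features.
    """

    image_size: int = 128
    n_gabor: int = 64
    channels: tuple[int, int] = (128, 128)  # conv2, conv3 output channels
    kernel_sizes: tuple[int, int, int] = (9, 3, 3)
    strides: tuple[int, int, int] = (2, 2, 2)
    paddings: tuple[int, int, int] = (2, 1, 1)
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.activation != "relu":
            raise ValueError("only the rectifier activation is implemented")

    @property
    def conv_channels(self) -> tuple[int, int, int]:
        return (2 * self.n_gabor, *self.channels)

    def output_sides(self) -> tuple[int, int, int]:
        side = self.image_size
        sides = []
        for k, s, p in zip(self.kernel_sizes, self.strides, self.paddings):
            side = conv_output_size(side, k, s, p)
            sides.append(side)
        return tuple(sides)

    def output_shapes(self) -> tuple[tuple[int, int, int], ...]:
        return tuple(
            (c, s, s) for c, s in zip(self.conv_channels, self.output_sides())
        )

    @property
    def feature_dim(self) -> int:
        c, s, _ = self.output_shapes()[-1]
        return c * s * s

    @classmethod
    def reduced(cls, image_size: int = 64) -> "BackboneSpec":
        """Desk-scale backbone for synthetic studies: 16 Gabor tuples
        (32 kernels) and 32-channel later stages."""
        return cls(image_size=image_size, n_gabor=16, channels=(32, 32))


@dataclass
class ReadoutSpec:
    """Readout head: linear affine map, or two affine maps with a rectifier
    between them (matching the hierarchical readout's structure)."""

    mode: str = "linear"
    n_voxels: int = 0
    latent: int | None = None  # nonlinear mode; defaults to n_voxels

    def __post_init__(self) -> None:
        if self.mode not in ("linear", "nonlinear"):
            raise ValueError(f"readout mode must be linear or nonlinear, got {self.mode!r}")
        if self.n_voxels < 1:
            raise ValueError("readout needs at least one output voxel")
        if self.mode == "nonlinear" and self.latent is None:
            self.latent = self.n_voxels


class GaborNet:
    """Gabor-front-end convolutional encoder with a voxel readout."""

    def __init__(
        self,
        spec: BackboneSpec,
        readout: ReadoutSpec,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
        gabor_init: GaborParams | None = None,
    ) -> None:
        self.spec = spec
        self.readout_spec = readout
        self.dtype = dtype
        gp = gabor_init if gabor_init is not None else GaborParams.default_bank(spec.n_gabor)
        if gp.n_tuples != spec.n_gabor:
            raise ValueError("Gabor bank size does not match backbone spec")
        c1, c2, c3 = spec.conv_channels
        k1, k2, k3 = spec.kernel_sizes
        s1, s2, s3 = spec.strides
        p1, p2, p3 = spec.paddings
        layers: list = [
            GaborConv2d(gp, k1, s1, p1, dtype=dtype),
            ReLU(),
            Conv2d(c1, c2, k2, s2, p2, rng=rng, dtype=dtype),
            ReLU(),
            Conv2d(c2, c3, k3, s3, p3, rng=rng, dtype=dtype),
            Flatten(),
        ]
        self._n_backbone = len(layers)
        if readout.mode == "linear":
            layers.append(Linear(spec.feature_dim, readout.n_voxels, rng=rng, dtype=dtype))
        else:
            layers += [
                Linear(spec.feature_dim, readout.latent, rng=rng, dtype=dtype),
                ReLU(),
                Linear(readout.latent, readout.n_voxels, rng=rng, dtype=dtype),
            ]
        self.net = Network(layers)

    # -- forward ---------------------------------------------------------

    def _check_input(self, images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=self.dtype)
        if x.ndim == 3:
            x = x[:, None, :, :]
        if x.ndim != 4 or x.shape[1] != 1:
            raise ValueError(f"expected (n, 1, side, side) images, got {x.shape}")
        if x.shape[2] != self.spec.image_size or x.shape[3] != self.spec.image_size:
            raise ValueError(
                f"input side {x.shape[2]}x{x.shape[3]} does not match backbone "
                f"image_size {self.spec.image_size}"
            )
        return x

    @staticmethod
    def preprocess(images: np.ndarray) -> np.ndarray:
        """Scale to [0, 1] if needed and subtract each image's mean."""
        x = np.asarray(images, dtype=np.float64)
        peak = x.max()
        if peak > 1.0:
            x = x / peak
        return x - x.mean(axis=(-2, -1), keepdims=True)

    def forward(self, images: np.ndarray, return_features: bool = False):
        """Predict voxels; with return_features, also return the per-layer
        conv activations {'conv1','conv2','conv3'}."""
        x = self._check_input(images)
        feats = {}
        for i, layer in enumerate(self.net.layers):
            x = layer.forward(x)
            if i == 0:
                feats["conv1"] = x
            elif i == 2:
                feats["conv2"] = x
            elif i == 4:
                feats["conv3"] = x
        return (x, feats) if return_features else x

    __call__ = forward

    def features(self, images: np.ndarray) -> np.ndarray:
        """Flattened final conv-stage activations (the feature space)."""
        x = self._check_input(images)
        for layer in self.net.layers[: self._n_backbone]:
            x = layer.forward(x)
        return x

    # -- training plumbing ------------------------------------------------

    def backward(self, grad_pred: np.ndarray) -> None:
        self.net.backward(grad_pred.astype(self.dtype))

    def parameters(self):
        return self.net.parameters()

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.net.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state_dict(state)

    def project(self) -> None:
        self.net.project()
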