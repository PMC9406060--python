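"""Synthetic stimulus/response generator with a known visual hierarchy.

Emulates the layout of the vim-1 experiment (grayscale stimuli with a
train/validation split, per-ROI voxel response matrices) while embedding a
genuine representational hierarchy with known noise, so hierarchical
encoding claims can be tested by construction:

* V1 voxels — rectified quadrature Gabor energy at a fixed random position,
  orientation and scale (phase-invariant complex-cell energy);
* V2 voxels — L2 pooling: the square root of a sparse nonnegative
  pooling of squared V1 signals (the classic complex-cell energy
  construction, which keeps V2 second-order but well-conditioned);
* V4 voxels — sparse signed linear mixing of V2 signals through a smooth
  saturating nonlinearity (tanh);
* LO voxels — the same construction over V4.

Each stage's signal is a deterministic function of the previous stage;
per-trial measurement noise is additive, zero-mean Gaussian, independent
across voxels and trials. Signals are standardized to unit train-split
variance, so a voxel with signal-to-noise ratio s has noise s.d.
1/sqrt(s) and an ideal predictor attains rho = sqrt(s / (1 + s)) in
expectation — the noise ceiling.

Two named configurations are provided: ``H0`` (tiny, noiseless, V1 only)
and ``H1`` (full hierarchy at desk scale: side 64, 300/60 split, ROI sizes
V1:200 V2:150 V4:100 LO:60, SNR V1:4 V2:3 V4:1 LO:0.5).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import gabor_kernel

from .datasets import DatasetBundle, StimulusSet, VoxelResponses

__all__ = [
    "SyntheticConfig",
    "GroundTruthHierarchy",
    "SyntheticDataset",
    "generate_stimuli",
    "generate_dataset",
]

_ALLOWED_SIDES = (32, 64, 128)


@dataclass
class SyntheticConfig:
    """Names the ROI sizes, SNRs and stage sparsities of one dataset."""

    name: str = "H1"
    side: int = 64
    n_train: int = 300
    n_val: int = 60
    roi_sizes: dict = field(
        default_factory=lambda: {"V1": 200, "V2": 150, "V4": 100, "LO": 60}
    )
    snr: dict = field(
        default_factory=lambda: {"V1": 4.0, "V2": 3.0, "V4": 1.0, "LO": 0.5}
    )
    v2_pool: int = 5  # nonzero pooling weights per V2 voxel
    mix_sparsity: int = 8  # nonzero mixing weights per V4/LO voxel

    def __post_init__(self) -> None:
        if self.side not in _ALLOWED_SIDES:
            raise ValueError(f"side must be one of {_ALLOWED_SIDES}, got {self.side}")
        for roi in self.roi_sizes:
            s = self.snr.get(roi)
            if s is None or not s > 0:
                raise ValueError(
                    f"{roi}: SNR must be positive (use numpy.inf for noiseless), got {s}"
                )

    @classmethod
    def h0(cls) -> "SyntheticConfig":
        """Tiny noiseless V1-only set for fast learnability checks."""
        return cls(
            name="H0",
            side=32,
            n_train=200,
            n_val=40,
            roi_sizes={"V1": 60},
            snr={"V1": np.inf},
        )

    @classmethod
    def h1(cls) -> "SyntheticConfig":
        """Full hierarchy at the default reduced scale."""
        return cls(name="H1")

    @classmethod
    def fullscale(cls) -> "SyntheticConfig":
        """vim-1-sized layout (1750/120 split, 128-px stimuli)."""
        return cls(
            name="fullscale",
            side=128,
            n_train=1750,
            n_val=120,
            roi_sizes={"V1": 1294, "V2": 2083, "V4": 1535, "LO": 928},
            snr={"V1": 4.0, "V2": 3.0, "V4": 1.0, "LO": 0.5},
        )


def generate_stimuli(n: int, side: int, seed_or_rng) -> np.ndarray:
    """n grayscale images: each a normalized sum of 5-15 random Gabor
    patches plus 1/f spectral noise, clipped to [0, 1]."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if side not in _ALLOWED_SIDES:
        raise ValueError(f"side must be one of {_ALLOWED_SIDES}, got {side}")
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    # 1/f amplitude spectrum shared across images
    fy = np.fft.fftfreq(side)[:, None]
    fx = np.fft.rfftfreq(side)[None, :]
    radial = np.sqrt(fx * fx + fy * fy)
    radial[0, 0] = np.inf
    amp = 1.0 / radial
    images = np.empty((n, side, side))
    for i in range(n):
        canvas = np.zeros((side, side))
        for _ in range(rng.integers(5, 16)):
            lam = rng.uniform(4.0, side / 3.0)
            k = np.real(
                gabor_kernel(
                    frequency=1.0 / lam,
                    theta=rng.uniform(0.0, np.pi),
                    sigma_x=lam * 0.5,
                    sigma_y=lam * rng.uniform(0.4, 0.9),
                    offset=rng.uniform(0.0, 2 * np.pi),
                )
            )
            kh, kw = k.shape
            cy = rng.integers(0, side)
            cx = rng.integers(0, side)
            y0, x0 = cy - kh // 2, cx - kw // 2
            ys, xs = slice(max(y0, 0), min(y0 + kh, side)), slice(max(x0, 0), min(x0 + kw, side))
            kys = slice(ys.start - y0, ys.stop - y0)
            kxs = slice(xs.start - x0, xs.stop - x0)
            canvas[ys, xs] += rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 1.5) * k[kys, kxs] / (
                np.abs(k).max() + 1e-12
            )
        white = rng.standard_normal((side, side))
        pink = np.fft.irfft2(np.fft.rfft2(white) * amp, s=(side, side))
        pink = pink / (pink.std() + 1e-12)
        img = canvas / (canvas.std() + 1e-12) + 0.6 * pink
        images[i] = np.clip(0.5 + img / 6.0, 0.0, 1.0)
    return images


class GroundTruthHierarchy:
    """The generative model mapping stimuli -> V1 -> V2 -> V4 -> LO.

    Built once per dataset; ``signal_responses`` is deterministic given
    the images, with standardization constants frozen from the training
    split at construction time.
    """

    def __init__(self, config: SyntheticConfig, rng: np.random.Generator) -> None:
        self.config = config
        side = config.side
        n_v1 = config.roi_sizes.get("V1", 0)
        # V1 filter bank: positions, orientations, scales
        self._v1_kernels = []
        self._v1_centers = []
        for _ in range(n_v1):
            lam = rng.uniform(4.0, side / 4.0)
            k = gabor_kernel(
                frequency=1.0 / lam,
                theta=rng.uniform(0.0, np.pi),
                sigma_x=0.6 * lam,
                sigma_y=0.6 * lam,
            )
            self._v1_kernels.append(k)
            self._v1_centers.append(
                (rng.integers(0, side), rng.integers(0, side))
            )
        self._pad = max((max(k.shape) // 2 + 1 for k in self._v1_kernels), default=0)
        centers = {"V1": np.array(self._v1_centers, dtype=float).reshape(n_v1, 2)}
        # V2: retinotopically local nonnegative pooling of squared V1
        self._pool = {}
        if "V2" in config.roi_sizes and n_v1:
            self._pool["V2"], centers["V2"] = self._local_rows(
                rng, config.roi_sizes["V2"], centers["V1"], config.v2_pool,
                side, nonneg=True,
            )
        # V4 and LO: local sparse signed mixing + tanh (larger receptive fields)
        prev = {"V4": "V2", "LO": "V4"}
        self._mix = {}
        for roi, src in prev.items():
            if roi in config.roi_sizes and src in centers:
                self._mix[roi], centers[roi] = self._local_rows(
                    rng, config.roi_sizes[roi], centers[src], config.mix_sparsity,
                    side, nonneg=False,
                )
        self._centers = centers
        self._standardizers: dict[str, tuple[np.ndarray, np.ndarray]] = {}

    @staticmethod
    def _local_rows(rng, n_rows, src_centers, nnz, side, nonneg=False):
        """Each row pools/mixes the nnz source units nearest a random
        retinotopic center; returns the weight matrix and the resulting
        per-row centers (weighted source-center means)."""
        n_cols = src_centers.shape[0]
        nnz = min(nnz, n_cols)
        m = np.zeros((n_rows, n_cols))
        out_centers = np.empty((n_rows, 2))
        for r in range(n_rows):
            c = rng.uniform(0, side, size=2)
            d2 = np.sum((src_centers - c) ** 2, axis=1)
            idx = np.argpartition(d2, nnz - 1)[:nnz]
            if nonneg:
                w = rng.dirichlet(np.ones(nnz))
            else:
                w = rng.standard_normal(nnz) * np.sqrt(1.5 / nnz)
            m[r, idx] = w
            out_centers[r] = src_centers[idx].mean(axis=0)
        return m, out_centers

    # -- stagewise signals -------------------------------------------------

    def _v1_energy(self, images: np.ndarray) -> np.ndarray:
        pad = self._pad
        padded = np.pad(images, ((0, 0), (pad, pad), (pad, pad)), mode="reflect")
        out = np.empty((images.shape[0], len(self._v1_kernels)))
        for v, (k, (cy, cx)) in enumerate(zip(self._v1_kernels, self._v1_centers)):
            kh, kw = k.shape
            y0 = cy + pad - kh // 2
            x0 = cx + pad - kw // 2
            patch = padded[:, y0 : y0 + kh, x0 : x0 + kw]
            re = np.tensordot(patch, np.real(k), axes=([1, 2], [0, 1]))
            im = np.tensordot(patch, np.imag(k), axes=([1, 2], [0, 1]))
            out[:, v] = np.sqrt(re * re + im * im)
        return out

    def _standardize(self, roi: str, x: np.ndarray, freeze: bool) -> np.ndarray:
        if freeze:
            mu = x.mean(axis=0)
            sd = x.std(axis=0)
            sd = np.where(sd > 1e-12, sd, 1.0)
            self._standardizers[roi] = (mu, sd)
        mu, sd = self._standardizers[roi]
        return (x - mu) / sd

    def signal_responses(self, images: np.ndarray, *, freeze: bool = False) -> dict[str, np.ndarray]:
        """Noiseless per-ROI signals for *images* (n, side, side).

        With ``freeze=True`` the per-voxel standardization constants are
        (re)computed from these images and stored; otherwise the stored
        constants are reused.
        """
        signals: dict[str, np.ndarray] = {}
        if self._v1_kernels:
            v1_raw = self._v1_energy(images)
            v1 = self._standardize("V1", v1_raw, freeze)
            signals["V1"] = v1
            if "V2" in self._pool:
                pooled = np.sqrt((v1_raw * v1_raw) @ self._pool["V2"].T)
                v2 = self._standardize("V2", pooled, freeze)
                signals["V2"] = v2
                if "V4" in self._mix:
                    v4 = self._standardize("V4", np.tanh(v2 @ self._mix["V4"].T), freeze)
                    signals["V4"] = v4
                    if "LO" in self._mix:
                        signals["LO"] = self._standardize(
                            "LO", np.tanh(v4 @ self._mix["LO"].T), freeze
                        )
        return signals

    def noise_sd(self, roi: str) -> float:
        s = self.config.snr[roi]
        return 0.0 if np.isinf(s) else float(1.0 / np.sqrt(s))

    def noise_ceiling(self, roi: str) -> float:
        """Expected accuracy of an ideal predictor: sqrt(SNR / (1 + SNR))."""
        s = self.config.snr[roi]
        return 1.0 if np.isinf(s) else float(np.sqrt(s / (1.0 + s)))


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    stimuli: StimulusSet
    responses: dict[str, VoxelResponses]
    hierarchy: GroundTruthHierarchy
    signals_train: dict[str, np.ndarray]
    signals_val: dict[str, np.ndarray]
    config: SyntheticConfig
    seed: int

    def bundle(self) -> DatasetBundle:
        return DatasetBundle(
            stimuli=self.stimuli,
            responses=self.responses,
            subject="synthetic",
            provenance={"config": self.config.name, "seed": self.seed},
        )


def generate_dataset(config: SyntheticConfig, seed: int) -> SyntheticDataset:
    """Generate a full dataset from (config, seed); bitwise reproducible."""
    root = np.random.SeedSequence(seed)
    rng_stim, rng_hier, rng_noise = (np.random.default_rng(s) for s in root.spawn(3))
    n = config.n_train + config.n_val
    images = generate_stimuli(n, config.side, rng_stim)
    train_imgs, val_imgs = images[: config.n_train], images[config.n_train :]
    hierarchy = GroundTruthHierarchy(config, rng_hier)
    sig_train = hierarchy.signal_responses(train_imgs, freeze=True)
    sig_val = hierarchy.signal_responses(val_imgs)
    responses = {}
    for roi in config.roi_sizes:
        if roi not in sig_train:
            raise ValueError(f"ROI {roi} requires its upstream stages in roi_sizes")
        sd = hierarchy.noise_sd(roi)
        tr = sig_train[roi] + sd * rng_noise.standard_normal(sig_train[roi].shape)
        va = sig_val[roi] + sd * rng_noise.standard_normal(sig_val[roi].shape)
        responses[roi] = VoxelResponses(roi=roi, train=tr, val=va)
    return SyntheticDataset(
        stimuli=StimulusSet(train=train_imgs, val=val_imgs),
        responses=responses,
        hierarchy=hierarchy,
        signals_train=sig_train,
        signals_val=sig_val,
        config=config,
        seed=seed,
    )
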