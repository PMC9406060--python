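"""Bottom-up hierarchical readout across visual areas.

A trained stage-1 encoder for a low-level source area provides a
representation space for a high-level target area in one of two modes:

* ``voxel`` mode — the encoder's *predicted* source voxel activity,
  restricted to the effectively encoded source voxels (accuracy above the
  validity threshold), is re-read-out into the target area
  (voxel-to-voxel model, V2VM);
* ``feature`` mode — the flattened final conv-stage activations of the
  source-trained encoder are re-read-out (feature-to-voxel model, F2VM).

Either way the readout is two affine maps with a rectifier between them;
the latent width equals the target area's voxel count. During training,
the gradient on the first affine map is gated elementwise by the squared
weights (g <- g * W^2): source connections with large weights ("intimate"
voxels) get amplified updates, weak ("distant") connections are
suppressed, and the forward map is unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .evaluation import AccuracyVector
from .gabornet import GaborNet
from .nn import Linear, Network, ReLU

__all__ = [
    "RepresentationSpace",
    "HierReadout",
    "select_effective_voxels",
    "extract_representation",
    "apply_squared_weight_rule",
]


@dataclass
class RepresentationSpace:
    """Stage-1 representation handed to the hierarchical readout."""

    train: np.ndarray  # (n_train, D)
    val: np.ndarray  # (n_val, D)
    mode: str  # 'voxel' | 'feature'
    source_roi: str
    selected_ids: np.ndarray | None = None  # voxel mode only
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("voxel", "feature"):
            raise ValueError(f"mode must be 'voxel' or 'feature', got {self.mode!r}")
        if self.train.shape[1] != self.val.shape[1]:
            raise ValueError("train/val representation widths differ")
        if self.mode == "voxel":
            if self.selected_ids is None:
                raise ValueError("voxel mode requires the selected source-voxel ids")
            if len(self.selected_ids) != self.train.shape[1]:
                raise ValueError("selected_ids length does not match representation width")

    @property
    def dim(self) -> int:
        return self.train.shape[1]


def select_effective_voxels(accuracy: AccuracyVector, threshold: float | None = None) -> np.ndarray:
    """Indices of effectively encoded voxels: accuracy strictly above the
    validity threshold, original order preserved.

    Raises if the selection is empty — a downstream voxel-to-voxel model
    would have zero inputs.
    """
    thr = accuracy.threshold if threshold is None else threshold
    mask = accuracy.defined & (accuracy.rho > thr)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(
            f"no voxel exceeds the validity threshold {thr}; "
            "cannot build a voxel-mode representation"
        )
    return idx


def extract_representation(
    stage1: GaborNet,
    stimuli_train: np.ndarray,
    stimuli_val: np.ndarray,
    mode: str,
    selected: np.ndarray | None = None,
    *,
    source_roi: str = "",
    batch_size: int = 64,
    provenance: dict | None = None,
) -> RepresentationSpace:
    """Extract the frozen stage-1 representation for both splits.

    Feature mode returns the flattened final conv activations; voxel mode
    returns the predicted source voxel matrix restricted to the selected
    columns. Stage-1 weights are read, never modified.
    """
    if mode == "voxel" and selected is None:
        raise ValueError("voxel mode requires a selection of effective source voxels")

    def run(images: np.ndarray) -> np.ndarray:
        chunks = []
        for lo in range(0, images.shape[0], batch_size):
            batch = images[lo : lo + batch_size]
            if mode == "feature":
                chunks.append(stage1.features(batch))
            else:
                chunks.append(stage1.forward(batch)[:, selected])
        return np.concatenate(chunks, axis=0).astype(np.float64)

    return RepresentationSpace(
        train=run(stimuli_train),
        val=run(stimuli_val),
        mode=mode,
        source_roi=source_roi,
        selected_ids=np.asarray(selected) if mode == "voxel" else None,
        provenance=provenance or {},
    )


def apply_squared_weight_rule(raw_gradient: np.ndarray, w1: np.ndarray) -> np.ndarray:
    """Gate a raw gradient elementwise by the squared weights: g * w^2.

    Applied to the first affine map of the hierarchical readout before the
    optimizer step. Preserves the gradient's sign; zero weights stay
    suppressed; unit-magnitude weights leave the gradient unchanged.
    """
    raw_gradient = np.asarray(raw_gradient)
    w1 = np.asarray(w1)
    if raw_gradient.shape != w1.shape:
        raise ValueError(
            f"gradient shape {raw_gradient.shape} does not match weight shape {w1.shape}"
        )
    return raw_gradient * (w1 * w1)


class HierReadout:
    """Two-layer nonlinear readout (V2VM / F2VM).

    Maps a D-dimensional representation through a latent layer whose width
    equals the target area's voxel count, a rectifier, and a second affine
    map onto the target voxels.
    """

    def __init__(
        self,
        in_dim: int,
        n_target_voxels: int,
        *,
        rng: np.random.Generator,
        dtype=np.float32,
        latent: int | None = None,
    ) -> None:
        self.in_dim = in_dim
        self.n_target_voxels = n_target_voxels
        self.latent = n_target_voxels if latent is None else latent
        self.dtype = dtype
        self.net = Network(
            [
                Linear(in_dim, self.latent, rng=rng, dtype=dtype),
                ReLU(),
                Linear(self.latent, n_target_voxels, rng=rng, dtype=dtype),
            ]
        )

    @property
    def first_affine(self) -> Linear:
        return self.net.layers[0]

    def forward(self, rep: np.ndarray) -> np.ndarray:
        rep = np.asarray(rep, dtype=self.dtype)
        if rep.shape[1] != self.in_dim:
            raise ValueError(
                f"representation width {rep.shape[1]} does not match readout input {self.in_dim}"
            )
        return self.net.forward(rep)

    __call__ = forward

    def backward(self, grad_pred: np.ndarray, *, weight_rule: bool = True) -> None:
        """Backprop; with the rule active, gate the first affine map's
        weight gradient by its squared weights."""
        self.net.backward(grad_pred.astype(self.dtype))
        if weight_rule:
            first = self.first_affine
            first.grads["w"] = apply_squared_weight_rule(first.grads["w"], first.params["w"])

    def parameters(self):
        return self.net.parameters()

    def state_dict(self) -> dict[str, np.ndarray]:
        return self.net.state_dict()

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        self.net.load_state_dict(state)
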