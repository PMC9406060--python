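"""Two-stage training of the hierarchical encoding models.

Stage 1 (epochs 1..boundary, default 1-50) fits the Gabor convolutional
encoder end-to-end on a low-level source area with Adam (lr 0.001, batch
64) and mean-squared-error loss, keeping the checkpoint with the best mean
validation accuracy. Stage 2 (the remaining epochs, default 40) freezes
stage 1, extracts its representation (predicted source voxels or the
feature space) and fits the two-layer hierarchical readout on the target
area with the squared-weight gradient rule active on the first affine map.

The direct (non-hierarchical) control is the same encoder with a nonlinear
readout trained single-stage for the full epoch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .datasets import StimulusSet, VoxelResponses, roi_rank
from .evaluation import AccuracyVector, pearson_accuracy
from .gabornet import BackboneSpec, GaborNet, ReadoutSpec
from .hierarchy import (
    HierReadout,
    RepresentationSpace,
    extract_representation,
    select_effective_voxels,
)
from .nn import Adam, mse_loss

__all__ = [
    "TrainConfig",
    "PipelineSpec",
    "TrainingDivergedError",
    "Stage1Result",
    "Stage2Result",
    "PipelineResult",
    "train_stage1",
    "train_stage2",
    "run_pipeline",
    "predict_in_batches",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""

    def __init__(self, stage: str, epoch: int, batch: int) -> None:
        super().__init__(f"{stage}: non-finite loss at epoch {epoch}, batch {batch}")
        self.stage, self.epoch, self.batch = stage, epoch, batch


@dataclass
class TrainConfig:
    """Optimization settings shared by both stages."""

    epochs: int = 90
    boundary: int = 50
    optimizer: str = "adam"
    lr: float = 1e-3
    batch_size: int = 64
    loss: str = "mse"
    seed: int = 0
    device: str = "cpu"
    dtype: str = "float32"
    weight_rule: bool = True  # squared-weight gradient gating in stage 2
    weight_decay: float = 10.0  # decoupled L2 on weight matrices (not biases)
    threshold: float = 0.27  # validity threshold for source-voxel selection

    def __post_init__(self) -> None:
        if not 0 < self.boundary < self.epochs:
            raise ValueError("need 0 < boundary < epochs")
        if self.lr <= 0:
            raise ValueError("learning rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError("only the adaptive-moment optimizer is implemented")
        if self.loss != "mse":
            raise ValueError("only mean-squared-error loss is implemented")

    @property
    def np_dtype(self):
        return np.dtype(self.dtype).type


@dataclass
class PipelineSpec:
    """Which hierarchical model to build: source ROI, target ROI, mode."""

    source: str
    target: str
    mode: str = "s2v2v"  # 's2v2v' (voxel) | 's2f2v' (feature)

    def __post_init__(self) -> None:
        self.mode = self.mode.lower()
        if self.mode not in ("s2v2v", "s2f2v"):
            raise ValueError(f"mode must be 's2v2v' or 's2f2v', got {self.mode!r}")
        if self.source == self.target:
            raise ValueError(
                f"source and target coincide ({self.source}); use the plain encoder instead"
            )
        if roi_rank(self.source) > roi_rank(self.target):
            raise ValueError(
                f"{self.source}->{self.target} runs against the ventral-stream order"
            )

    @property
    def representation_mode(self) -> str:
        return "voxel" if self.mode == "s2v2v" else "feature"


@dataclass
class Stage1Result:
    model: GaborNet
    best_state: dict
    best_epoch: int
    trace: list[float] = field(default_factory=list)
    val_accuracy: AccuracyVector | None = None


@dataclass
class Stage2Result:
    readout: HierReadout
    best_state: dict
    best_epoch: int
    trace: list[float] = field(default_factory=list)
    scaler: tuple[np.ndarray, np.ndarray] | None = None
    val_accuracy: AccuracyVector | None = None


@dataclass
class PipelineResult:
    spec: PipelineSpec
    stage1: Stage1Result
    stage2: Stage2Result
    representation: RepresentationSpace
    selected: np.ndarray | None
    target_accuracy: AccuracyVector
    val_predictions: np.ndarray


def predict_in_batches(forward, x: np.ndarray, batch_size: int = 64) -> np.ndarray:
    out = [forward(x[lo : lo + batch_size]) for lo in range(0, x.shape[0], batch_size)]
    return np.concatenate(out, axis=0).astype(np.float64)


def _epoch_score(acc: AccuracyVector) -> float:
    """Checkpoint-selection score: mean validation accuracy over defined voxels."""
    if acc.defined.any():
        return float(np.mean(acc.rho[acc.defined]))
    return -np.inf


def train_stage1(
    stimuli: StimulusSet,
    responses: VoxelResponses,
    config: TrainConfig,
    *,
    backbone: BackboneSpec | None = None,
    readout_mode: str = "linear",
    epochs: int | None = None,
    stage_name: str = "stage1",
) -> Stage1Result:
    """Fit the encoder on one ROI and return the best-validation checkpoint.

    Runs ``epochs`` epochs (default: the stage boundary); with
    ``readout_mode='nonlinear'`` and ``epochs=config.epochs`` this is the
    fine-tuned direct encoder used as the non-hierarchical control.
    """
    if stimuli.n_train != responses.train.shape[0]:
        raise ValueError("stimulus/response sample counts differ")
    n_epochs = config.boundary if epochs is None else epochs
    if backbone is None:
        backbone = BackboneSpec(image_size=stimuli.side)
    if backbone.image_size != stimuli.side:
        raise ValueError(
            f"backbone expects {backbone.image_size}-px images, stimuli are {stimuli.side}-px"
        )
    rng = np.random.default_rng(config.seed)
    dtype = config.np_dtype
    model = GaborNet(
        backbone,
        ReadoutSpec(mode=readout_mode, n_voxels=responses.n_voxels),
        rng=rng,
        dtype=dtype,
    )
    x_train = GaborNet.preprocess(stimuli.train).astype(dtype)[:, None]
    x_val = GaborNet.preprocess(stimuli.val).astype(dtype)[:, None]
    y_train = responses.train.astype(dtype)
    opt = Adam(model.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    best_state = model.state_dict()
    best_score, best_epoch = -np.inf, 0
    trace: list[float] = []
    n = x_train.shape[0]
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(n)
        for bi, lo in enumerate(range(0, n, config.batch_size)):
            idx = order[lo : lo + config.batch_size]
            pred = model.forward(x_train[idx])
            loss, grad = mse_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(stage_name, epoch, bi)
            model.backward(grad)
            opt.step()
            model.project()
        val_pred = predict_in_batches(model.forward, x_val, config.batch_size)
        acc = pearson_accuracy(responses.val, val_pred, threshold=config.threshold)
        score = _epoch_score(acc)
        trace.append(score)
        if score > best_score:  # strict: ties keep the earliest epoch
            best_score, best_epoch = score, epoch
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    val_pred = predict_in_batches(model.forward, x_val, config.batch_size)
    acc = pearson_accuracy(responses.val, val_pred, threshold=config.threshold)
    return Stage1Result(
        model=model, best_state=best_state, best_epoch=best_epoch, trace=trace, val_accuracy=acc
    )


def _standardize_rep(rep: RepresentationSpace):
    """Feature-mode inputs are standardized per dimension with train-split
    statistics; voxel-mode inputs are used as produced."""
    if rep.mode != "feature":
        return rep.train, rep.val, None
    mu = rep.train.mean(axis=0)
    sd = rep.train.std(axis=0)
    sd = np.where(sd > 1e-8, sd, 1.0)
    return (rep.train - mu) / sd, (rep.val - mu) / sd, (mu, sd)


def train_stage2(
    rep: RepresentationSpace,
    responses: VoxelResponses,
    config: TrainConfig,
    *,
    epochs: int | None = None,
    latent: int | None = None,
    stage_name: str = "stage2",
) -> Stage2Result:
    """Fit the hierarchical readout on the target ROI.

    Runs the post-boundary epochs (default epochs - boundary, i.e. 40)
    with the squared-weight rule gating the first affine map's gradient
    when ``config.weight_rule`` is set.
    """
    if rep.train.shape[0] != responses.train.shape[0]:
        raise ValueError("representation/response sample counts differ")
    n_epochs = (config.epochs - config.boundary) if epochs is None else epochs
    x_train, x_val, scaler = _standardize_rep(rep)
    rng = np.random.default_rng(config.seed)
    dtype = config.np_dtype
    readout = HierReadout(
        rep.dim, responses.n_voxels, rng=rng, dtype=dtype, latent=latent
    )
    x_train = x_train.astype(dtype)
    x_val = x_val.astype(dtype)
    y_train = responses.train.astype(dtype)
    opt = Adam(readout.parameters(), lr=config.lr, weight_decay=config.weight_decay)
    best_state = readout.state_dict()
    best_score, best_epoch = -np.inf, 0
    trace: list[float] = []
    n = x_train.shape[0]
    for epoch in range(1, n_epochs + 1):
        order = rng.permutation(n)
        for bi, lo in enumerate(range(0, n, config.batch_size)):
            idx = order[lo : lo + config.batch_size]
            pred = readout.forward(x_train[idx])
            loss, grad = mse_loss(pred, y_train[idx])
            if not np.isfinite(loss):
                raise TrainingDivergedError(stage_name, epoch, bi)
            readout.backward(grad, weight_rule=config.weight_rule)
            opt.step()
        val_pred = predict_in_batches(readout.forward, x_val, config.batch_size)
        acc = pearson_accuracy(responses.val, val_pred, threshold=config.threshold)
        score = _epoch_score(acc)
        trace.append(score)
        if score > best_score:
            best_score, best_epoch = score, epoch
            best_state = readout.state_dict()
    readout.load_state_dict(best_state)
    val_pred = predict_in_batches(readout.forward, x_val, config.batch_size)
    acc = pearson_accuracy(responses.val, val_pred, threshold=config.threshold)
    return Stage2Result(
        readout=readout,
        best_state=best_state,
        best_epoch=best_epoch,
        trace=trace,
        scaler=scaler,
        val_accuracy=acc,
    )


def run_pipeline(
    spec: PipelineSpec,
    bundle,
    config: TrainConfig,
    *,
    backbone: BackboneSpec | None = None,
    stage1: Stage1Result | None = None,
) -> PipelineResult:
    """Train the full hierarchical model source -> target.

    Composes stage-1 training on the source ROI, effective-voxel selection
    (voxel mode, on validation accuracy), representation extraction with
    frozen stage-1 weights, stage-2 readout training, and evaluation on
    the target validation split. A pre-trained ``stage1`` result for the
    source ROI may be reused across targets.
    """
    stimuli: StimulusSet = bundle.stimuli
    source_resp: VoxelResponses = bundle.responses[spec.source]
    target_resp: VoxelResponses = bundle.responses[spec.target]
    if stage1 is None:
        stage1 = train_stage1(
            stimuli,
            source_resp,
            config,
            backbone=backbone,
            stage_name=f"stage1[{spec.source}]",
        )
    frozen_before = stage1.model.state_dict()
    selected = None
    if spec.representation_mode == "voxel":
        selected = select_effective_voxels(stage1.val_accuracy, config.threshold)
    x_train = GaborNet.preprocess(stimuli.train).astype(config.np_dtype)[:, None]
    x_val = GaborNet.preprocess(stimuli.val).astype(config.np_dtype)[:, None]
    rep = extract_representation(
        stage1.model,
        x_train,
        x_val,
        spec.representation_mode,
        selected,
        source_roi=spec.source,
        batch_size=config.batch_size,
        provenance={"source": spec.source, "mode": spec.mode, "best_epoch": stage1.best_epoch},
    )
    stage2 = train_stage2(
        rep, target_resp, config, stage_name=f"stage2[{spec.source}->{spec.target}]"
    )
    frozen_after = stage1.model.state_dict()
    for key, before in frozen_before.items():
        if not np.array_equal(before, frozen_after[key]):  # pragma: no cover - invariant
            raise AssertionError(f"stage-2 training mutated stage-1 parameter {key}")
    val_pred = predict_in_batches(
        lambda b: stage2.readout.forward(b), stage2_input_val(rep, stage2), config.batch_size
    )
    acc = pearson_accuracy(target_resp.val, val_pred, threshold=config.threshold)
    return PipelineResult(
        spec=spec,
        stage1=stage1,
        stage2=stage2,
        representation=rep,
        selected=selected,
        target_accuracy=acc,
        val_predictions=val_pred,
    )


def stage2_input_val(rep: RepresentationSpace, stage2: Stage2Result) -> np.ndarray:
    """Validation-split readout input, applying the stage-2 scaler if any."""
    if stage2.scaler is None:
        return rep.val
    mu, sd = stage2.scaler
    return (rep.val - mu) / sd
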