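"""Canned desk-scale study on synthetic data.

Runs the full model zoo on one generated hierarchy-H1 dataset: direct
(fine-tuned nonlinear-readout) encoders for V2/V4/LO, stage-1 encoders for
the source areas V1/V2, and hierarchical models in both voxel (S2V2V) and
feature (S2F2V) modes, then computes Top-K average accuracies, the
pairwise advantage analysis and best-encoded-voxel proportions per target
area. This is the package's self-contained analogue of the full-data
study, at sizes a single CPU handles in minutes (64-px stimuli, 300/60
split, reduced backbone).
"""

from __future__ import annotations

import numpy as np

from .evaluation import (
    AccuracyVector,
    advantage_analysis,
    best_encoded_proportions,
    topk_average_accuracy,
)
from .gabornet import BackboneSpec
from .synthetic import SyntheticConfig, generate_dataset
from .training import PipelineSpec, TrainConfig, run_pipeline, train_stage1

__all__ = ["derive_seed", "reduced_study"]


def derive_seed(seed: int, k: int) -> int:
    """Deterministic sub-seed below 2**31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1))


def reduced_study(
    seed: int,
    *,
    config: SyntheticConfig | None = None,
    train_config: TrainConfig | None = None,
    topk: int = 50,
    include_lo: bool = True,
) -> dict:
    """Train and compare all models on one synthetic H1 dataset.

    Returns a dict with the dataset, per-target accuracy vectors
    (``accuracies[target][model_label]``), Top-K averages, the
    S2V2V-vs-direct advantage on V4, and best-encoded proportions with the
    combined hierarchical share per target.
    """
    config = config or SyntheticConfig.h1()
    base = train_config or TrainConfig()
    data = generate_dataset(config, derive_seed(seed, 0))
    bundle = data.bundle()
    backbone = BackboneSpec.reduced(config.side)

    def cfg(k: int) -> TrainConfig:
        c = TrainConfig(**{**base.__dict__, "seed": derive_seed(seed, k)})
        return c

    # Stage-1 encoders (linear readout) for the source areas.
    stage1 = {
        "V1": train_stage1(bundle.stimuli, bundle["V1"], cfg(1), backbone=backbone,
                           stage_name="stage1[V1]"),
        "V2": train_stage1(bundle.stimuli, bundle["V2"], cfg(2), backbone=backbone,
                           stage_name="stage1[V2]"),
    }

    # Direct (fine-tuned nonlinear) encoders, full epoch budget.
    direct_targets = ["V2", "V4"] + (["LO"] if include_lo else [])
    direct = {
        roi: train_stage1(
            bundle.stimuli,
            bundle[roi],
            cfg(10 + i),
            backbone=backbone,
            readout_mode="nonlinear",
            epochs=base.epochs,
            stage_name=f"direct[{roi}]",
        )
        for i, roi in enumerate(direct_targets)
    }

    # Hierarchical models, reusing the stage-1 source encoders.
    hier_specs = [("V1", "V2", "s2v2v"), ("V1", "V4", "s2v2v"), ("V2", "V4", "s2v2v"),
                  ("V2", "V4", "s2f2v")]
    if include_lo:
        hier_specs += [("V1", "LO", "s2v2v"), ("V2", "LO", "s2v2v")]
    hier = {}
    for i, (src, tgt, mode) in enumerate(hier_specs):
        spec = PipelineSpec(source=src, target=tgt, mode=mode)
        hier[f"{mode}_{src}->{tgt}"] = run_pipeline(
            spec, bundle, cfg(100 + i), backbone=backbone, stage1=stage1[src]
        )

    accuracies: dict[str, dict[str, AccuracyVector]] = {}
    for tgt in direct_targets:
        accuracies[tgt] = {"direct": direct[tgt].val_accuracy}
        for label, res in hier.items():
            if label.endswith(f"->{tgt}"):
                accuracies[tgt][label] = res.target_accuracy

    topk_aa = {
        tgt: {label: topk_average_accuracy(acc, topk) for label, acc in models.items()}
        for tgt, models in accuracies.items()
    }

    advantage_v4 = advantage_analysis(
        accuracies["V4"]["s2v2v_V2->V4"],
        accuracies["V4"]["direct"],
        labels=("s2v2v_V2->V4", "direct"),
        seed=derive_seed(seed, 500),
    )

    best_encoded = {}
    hier_share = {}
    for tgt, models in accuracies.items():
        props = best_encoded_proportions(models)
        best_encoded[tgt] = props
        hier_share[tgt] = float(sum(v for k, v in props.items() if k != "direct"))

    return {
        "dataset": data,
        "backbone": backbone,
        "stage1": stage1,
        "direct": direct,
        "hier": hier,
        "accuracies": accuracies,
        "topk": topk,
        "topk_aa": topk_aa,
        "advantage_v4": advantage_v4,
        "best_encoded": best_encoded,
        "hier_share": hier_share,
    }
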