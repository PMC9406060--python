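# ventralenc

Hierarchical ventral-stream encoding models for visual fMRI.

Voxelwise encoding models predict a voxel's response γ to a stimulus and
are scored by the Pearson correlation ρ = cor(γ, γ̂) on held-out data.
End-to-end convolutional encoders do well in early visual cortex (V1, V2)
but poorly in higher areas (V4, LO), where responses are abstract and
data are scarce. `ventralenc` implements a hierarchical alternative:
because higher ventral-stream areas receive their input from lower ones,
it first fits a Gabor-convolutional encoder to a *low-level* source area,
then re-reads that model's representation out into the *high-level*
target area:

* **S2V2V** (voxel route): the encoder's predicted source-voxel activity,
  restricted to effectively encoded voxels (ρ > 0.27 against a
  1000-shuffle null), is mapped to target voxels by a two-layer nonlinear
  readout (V2VM);
* **S2F2V** (feature route): the encoder's 32,768-dimensional final
  conv-stage feature space is mapped to target voxels the same way
  (F2VM).

During stage-2 training the first readout layer's gradient is gated
elementwise by its squared weights (g ← g ∘ W²), amplifying source
connections that matter ("intimate" voxels) and suppressing the rest.
Everything trains with Adam (lr 0.001, batch 64, MSE) on a 90-epoch
two-stage schedule (stage boundary at 50), and is evaluated with the
permutation-based statistics used in this literature: per-voxel ρ,
shuffle-null validity thresholds, Top-K average accuracy, coin-flip
advantage tests, and best-encoded-voxel proportions. A synthetic
generator with a known V1→V2→V4→LO hierarchy and known noise ceilings
makes the whole pipeline testable without any data download; the vim-1
dataset (CRCNS) is supported as an optional real input.

See `docs/methods.md` for the model, the training rules and the
generator in detail.

## Worked example

Train the hierarchical V2 → V4 model on a synthetic desk-scale dataset
and compare it with the direct encoder:

```python
import numpy as np
from ventralenc import (
    BackboneSpec, PipelineSpec, SyntheticConfig, TrainConfig,
    generate_dataset, run_pipeline, topk_average_accuracy, train_stage1,
)

data = generate_dataset(SyntheticConfig.h1(), seed=99).bundle()
backbone = BackboneSpec.reduced(64)

direct = train_stage1(data.stimuli, data["V4"], TrainConfig(seed=4),
                      backbone=backbone, readout_mode="nonlinear", epochs=90)
hier = run_pipeline(PipelineSpec("V2", "V4", "s2v2v"), data,
                    TrainConfig(seed=6), backbone=backbone)

print("direct V4 Top-50 AA:", round(topk_average_accuracy(direct.val_accuracy, 50), 3))
print("S2V2V V2->V4 Top-50 AA:", round(topk_average_accuracy(hier.target_accuracy, 50), 3))
```

Output:

```
direct V4 Top-50 AA: 0.401
S2V2V V2->V4 Top-50 AA: 0.481
```

Top-50 AA is the mean validation ρ over the 50 best-predicted voxels.
The hierarchical model predicts the synthetic V4 markedly better than the
direct fit — the high-level area is a noisy nonlinear function of V2, so
routing through a well-encoded V2 recovers structure the direct encoder
cannot learn from 300 training pairs. Running the same comparison on V2
itself shows the opposite (the direct encoder wins): hierarchy helps only
above the areas the encoder already captures.

The same workflows are scriptable from the shell:

```sh
ventralenc simulate --config-name H1 --seed 0 --out h1.h5
ventralenc run-pipeline --data h1.h5 --source V2 --target V4 --mode s2v2v --out runs/v2v4
ventralenc compare --run-a runs/v2v4/per_voxel.csv --run-b runs/direct_v4/per_voxel.csv
```

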