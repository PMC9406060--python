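# Methods

## The model

`ventralenc` predicts per-voxel fMRI responses to grayscale natural images.
Its premise is the representational hierarchy of the ventral stream: a
high-level area (V4, LO) receives its input from lower areas (V1, V2), so
an encoding model for a high-level area can be built *through* a low-level
one instead of fitting the high-level data directly.

**Stage 1 — the encoder (S2V-EM).** A small convolutional network whose
first layer is a bank of learnable Gabor kernels: 64 parameter tuples
(orientation θ, wavelength λ px, envelope scale σ px, aspect ratio γ,
phase ψ), each expanded on a 9×9 grid into an even (cosine-carrier) kernel
and its odd quadrature partner (ψ + π/2), giving 128 kernels. With

    x′ = x cos θ + y sin θ,   y′ = −x sin θ + y cos θ,
    K(x, y) = exp(−(x′² + γ² y′²) / 2σ²) · cos(2π x′ / λ + ψ),

all five parameters are trained by backprop through the kernel
construction (the analytic derivatives of K are implemented and verified
against finite differences). Two ordinary 3×3 convolutions follow, with
rectifiers between stages. For a 128×128 input the activations are
128×62×62 → 128×31×31 → 128×16×16 (strides 2, paddings 2/1/1 — the only
simple integer choices that produce this chain), so the flattened
"feature space" has 32,768 dimensions. A final affine map reads the
feature space out into voxel space; the *fine-tuned* variant replaces it
with two affine maps and a rectifier (identical in shape to the
hierarchical readout) and is the direct-encoding control for high-level
areas.

**Stage 2 — the hierarchical readout.** The stage-1 encoder is trained on
the *source* area, then frozen. Its representation is re-read-out into the
*target* area in one of two modes:

* voxel mode (S2V2V): the encoder's predicted source-voxel activity,
  restricted to "effectively encoded" source voxels — validation accuracy
  ρ strictly above the validity threshold (default 0.27);
* feature mode (S2F2V): the flattened final conv-stage activations,
  standardized per dimension with training-split statistics (the feature
  scale is otherwise unbounded; voxel-mode inputs are used as produced).

The readout (V2VM / F2VM) is affine → rectifier → affine, with the latent
width equal to the target area's voxel count. Directions must respect the
ventral-stream order V1 < V2 < V4 < LO; source = target is rejected (that
is the plain encoder).

**The squared-weight rule.** During stage-2 training the gradient of the
*first* affine map is gated elementwise by the squared weights,
g ← g ∘ W², before the optimizer step. Source connections that have grown
large ("intimate" voxels) receive amplified updates; weak ("distant")
connections are suppressed; a zero weight is permanently dead; unit
weights reduce the rule to plain descent. The forward map is unchanged.
Among the readings of "squaring the weight matrix during backpropagation"
we chose gradient gating because it realizes exactly this
enhance/suppress behavior without altering the model class; applying it
to the first map only reflects that the source-to-latent weights are the
ones interpretable as source-voxel relevance. Both choices are
configurable (`TrainConfig.weight_rule`).

## Training

Both stages use mean-squared-error loss and Adam at learning rate 0.001
with batch size 64. The default schedule is 90 epochs with the stage
boundary at 50: stage 1 runs epochs 1–50 and keeps the checkpoint with
the highest mean validation accuracy over defined voxels (ties →
earliest); stage 2 runs the remaining 40 epochs the same way. The direct
(fine-tuned) control trains single-stage for the full 90 epochs, so every
model gets the same budget. One stage-1 encoder per source area is reused
across targets.

Weight matrices (not biases, not Gabor parameters) carry decoupled
L2 decay, default 10.0 in units of the learning rate. The default was set
by sweeping stage-1 validation accuracy on a held-out generator seed:
without decay the high-dimensional readout interpolates its training set
(train ρ ≈ 0.99, validation ρ ≈ 0.07) and the sweep's optimum closely
matches what an explicitly ridge-regularized readout on frozen features
achieves, i.e. the decay is doing ridge's job inside the end-to-end fit.
Disable it (`weight_decay=0`) for noiseless recovery experiments.

Gabor parameters are clamped after each step to λ ≥ 1 px, σ ≥ 0.3 px,
γ ≥ 0.05 to stay in their domain. Non-finite training loss aborts with
the epoch and batch index. All training is implemented in NumPy
(im2col convolution, hand-written backprop); everything is deterministic
given the configuration seed.

## Evaluation

Prediction accuracy is the per-voxel Pearson correlation ρ between
measured and predicted validation responses; zero-variance columns are
flagged undefined and excluded from every summary rather than zeroed.

*Validity threshold.* The sample correspondence is shuffled (default 1000
times), ρ recomputed, and the per-voxel null quantile taken as the k-th
largest draw with k = ⌊α·n_perm⌋ + 1 (the 2nd largest at α = 0.001 — the
empirical 99.9th percentile of 1000 draws would be the maximum, which is
noisy). The conventional global threshold ρ = 0.27 is the default
constant; recomputation (median of per-voxel quantiles) is available and
yields ≈ 0.26–0.27 at n = 120, converging to the analytic
z₀.₉₉₉/√(n−1) ≈ 0.283 as permutations grow.

*Top-K average accuracy* (default K = 300 at full scale, 50 at desk
scale) is the mean ρ of the K best-predicted defined voxels.

*Advantage analysis.* Over voxels valid under both models, the proportion
(of non-tied voxels; exact ties are excluded and counted) where model A's
ρ is higher, calibrated against a coin-flip null: each voxel's pair is
swapped with probability ½, 1000 times; the cutoff is the same order
statistic as above. At α = 0.001 the cutoff tracks 0.5 + 3.09/(2√N),
which reproduces the familiar "advantage above 53% is significant" rule
at N ≈ 2500 jointly valid voxels; α and N are explicit because the rule
is N-dependent.

*Best-encoded proportions.* Voxels valid under at least one model are
assigned to the argmax-ρ model (ties to the earlier-listed model);
proportions sum to one over included voxels.

## The synthetic hierarchy

The generator emulates the layout of the vim-1 experiment (train/val
split of grayscale stimuli, per-ROI response matrices) with a known
generative hierarchy so that every claim is testable without a download:

* stimuli: 5–15 random Gabor patches plus 1/f spectral noise, clipped to
  [0, 1];
* V1: quadrature Gabor energy (complex-cell magnitude) at a fixed random
  position, orientation and scale per voxel;
* V2: L2 pooling — the square root of a nonnegative pooling of squared
  V1 energies over the `v2_pool` (default 5) V1 units retinotopically
  nearest a random image location;
* V4, LO: tanh of a sparse signed mixture of the `mix_sparsity`
  (default 8) nearest lower-stage voxels, receptive fields growing by
  composition.

Retinotopic locality matters: with spatially scattered pooling the
low-level areas compute functions a convolutional encoder cannot express,
and the direct-versus-hierarchical comparison at V2 loses the structure
it has in real data. With local pooling the generator reproduces the
target regime: V1/V2 are directly encodable by a Gabor-front-end network,
while V4/LO are noisy nonlinear functions of lower areas — the regime in
which hierarchical re-readout should win.

Signals are standardized to unit training-split variance before adding
zero-mean Gaussian noise with variance 1/SNR (independent across voxels
and trials), so an ideal predictor attains ρ = √(SNR/(1+SNR)) — the noise
ceiling, verified for SNR ∈ {0.25, 1, 4}. Named configurations: `H0`
(side 32, 200/40, V1-only, noiseless) and `H1` (side 64, 300/60 split,
V1:200 V2:150 V4:100 LO:60 voxels, SNR V1:4 V2:3 V4:1 LO:0.5). A
`fullscale` configuration mirrors the vim-1 sizes (1750/120, 128 px,
V2/V4/LO = 2083/1535/928).

What the generator does *not* emulate: BOLD hemodynamics, measurement
drift, correlated noise, retinotopic map geometry beyond locality, or
feedback. Passing the synthetic suite shows the pipeline's machinery and
the hierarchy mechanism work as designed; it does not certify accuracy
values on real cortical data.

## Desk-scale study sizes

The canned study (`ventralenc.experiments.reduced_study`) uses the `H1`
configuration with a reduced backbone — 16 Gabor tuples (32 kernels) and
32-channel later stages at 64 px, feature dimension 2048 — so the whole
model zoo (two stage-1 encoders, three direct controls, six hierarchical
models) trains in minutes on one CPU. The full 64-tuple/128-kernel
architecture is used wherever the printed dimension chain is asserted.
At this scale the expected qualitative pattern is reproduced — the
direct encoder wins at V2 while hierarchical models win at V4 and LO —
but absolute accuracies sit well below the full-data setting and seed
variability is non-negligible; the comparisons, not the absolute values,
are the reproducible quantity.

## Known limitations

* The ridge baseline's pretrained feature extractor is an interface; the
  bundled extractor is a fixed-seed random-weight stand-in of the same
  seven-layer shape (five pooling, two fully connected). Supplying real
  pretrained weights is the user's responsibility.
* Multi-source fusion (V1+V2 → V4) is out of scope.
* The numpy training loop is single-threaded BLAS-bound; full vim-1-scale
  end-to-end training is possible but slow, and the published full-scale
  accuracy tables are not reproduced here.
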