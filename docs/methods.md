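# Methods

## Problem and model

`brainage` estimates chronological age from 3-D gray-matter density maps
(GMDMs), the modulated voxelwise gray-matter images produced by standard
T1-weighted segmentation pipelines.  Native-resolution maps (169×205×169 at
1 mm isotropic) are trilinearly downsampled to 84×102×84 at ≈2 mm, and a
single-channel volume is mapped to one scalar, predicted age in years.

The regressor is a hybrid CNN–Transformer:

**CoTResNet3D backbone.**  A 7×7×7 stride-2 convolution (BN, ReLU) and a
3×3×3 stride-2 max pool reduce the input to 64×21×26×21.  Three stages of
basic residual blocks (two 3×3×3 convolutions each, channels 64→128→256,
stride-2 projection shortcuts at stage entry) produce 128×11×13×11 and
256×6×7×6 maps.  In stages 2 and 3 each block carries, between its second
batch norm and the shortcut sum:

1. a **CoT (contextual dynamic convolution) module**: a grouped 3×3×3
   convolution (4 groups) forms a context embedding; the concatenation of
   input and context passes through two 1×1×1 convolutions (hidden width
   C/8, ReLU between them) to 27 channels — one weight per position of the
   3×3×3 neighborhood.  Both the weight map and the value branch are
   average-pooled by 2 (ceil mode); the weights are softmax-normalized per
   location and shared across channels; the weighted neighborhood sum
   (zero-padded unfold) is trilinearly resized back to the block grid and
   projected 1×1×1 to C channels.  A learnable scalar gate, initialized at
   0.5, scales this contextual correction before it is added to the block
   features, so a zero gate reduces the block to a plain residual block.
2. an **SE3D channel gate**: global average pool, two 1×1×1 convolutions
   with hidden width max(8, C/4) rounded to a multiple of 8, sigmoid gate.
3. channel-wise volumetric dropout (rate 0.1).

**CrossViT fusion head.**  Stage-2 features feed the *large* stream
(embed 160) and stage-3 features the *small* stream (embed 96) through
non-overlapping 2×2×2 cube projections — 150 and 27 patch tokens on the
standard input.  Each token receives a 3-D sinusoidal positional encoding
whose width is split across the z/y/x axes (dim//3 rounded up to even for z
and y, remainder to x: 32+32+32 and 54+54+52); a truncated-normal (sd 0.02)
cls token heads each sequence and carries no positional code.  Each of two
fusion layers runs small-stream self-attention, large-stream self-attention
(4 heads, MLP ratio 4, LayerNorm pre-norm, LayerScale γ init 1e-4,
DropPath schedule 0.0/0.1, attention-output and MLP dropout 0.1), then
bidirectional cross-attention: each stream's cls is projected into the
other stream's width, attends over that stream's normalized patch tokens,
is projected back and added residually through a scalar gate (init 0.1);
a gated per-direction MLP follows.  The gate multiplies both residual
updates of its direction so that zero gates leave the cls tokens untouched
and the two streams decouple exactly.  The head normalizes both cls tokens,
concatenates them (256), and maps 256→192→1 (GELU, dropout 0.1).

**Ablation baselines.**  `resnet_only` (backbone + global average pool +
linear), `vit_only` (16³ patches of the raw volume → 150 tokens → 12-layer
encoder, default width 384/6 heads), and `resnet_vit_concat` (pooled CNN
features concatenated with the ViT cls, two-layer head, no cross-attention).

## Numerical engine

The networks run on a compact reverse-mode automatic differentiation engine
over numpy arrays (`brainage.nn`): broadcast arithmetic, batched matmul,
im2col grouped 3-D convolution, max/average pooling, separable trilinear
resampling (half-pixel centers, so the same code implements the GMDM
downsampler and the CoT resizes), neighborhood unfolding, layer/batch norm,
dropout variants and AdamW.  Every primitive is validated against central
finite differences in float64; the engine runs models in float32.

## Training recipe

AdamW (betas 0.9/0.999, eps 1e-8, weight decay 1e-5, applied to all
parameters by default with an exemption flag), batch size 8, linear warmup
from 1e-6 to 2e-4 over 5 epochs, cosine annealing to 1e-5 at the final
step, at per-step granularity.  The loss is MSE plus λ=0.005 times a
pairwise margin ranking loss (margin β=0.5) over within-batch pairs with
distinct ages; ties contribute nothing.  Training runs at most 100 epochs
with early stopping after 15 epochs without a strict (>1e-6) improvement in
validation MAE; the best-validation checkpoint is returned.  An optional
initial phase freezes the backbone (parameters excluded from optimization,
batch-norm statistics held) and trains head-only before joint fine-tuning;
the default recipe never enters it.  The output bias of the final linear
layer is initialized to the training-set mean age, which removes the long
plateau a raw-age regression otherwise spends learning its offset.  All
stochastic elements (data order, dropout, DropPath, token pruning,
initialization) derive from integer seeds.

## Evaluation metrics

Accuracy: MAE, signed ME, Pearson r, R², per-decade-bin MAE over
left-closed right-open bins [0,10)…[90,100), and mMAE — the maximum bin MAE
over bins holding at least `min_bin_n` (default 3) subjects; smaller
occupied bins are reported but excluded from the maximum, since a 2-subject
bin can dominate it by chance.  Longitudinal: per-subject change error
δ = (ŷ₂−ŷ₁) − (y₂−y₁), summarized as MdE (mean), MAdE (mean absolute) and
mMAdE (binned maximum, binned on baseline age).  Test–retest: within-subject
SD of the two predictions in sample (n−1) form, i.e. |d|/√2; mean and
sample SD of d = ŷ₁−ŷ₂; and ICC(3,1) — two-way mixed effects, consistency,
single measurement — computed from the two-way ANOVA mean squares and
cross-checked in tests against an independent from-scratch ANOVA and
against `pingouin`.  Statistics that are undefined (single sample, zero
variance, all-identical subjects) are flagged rather than propagated as NaN.

## Synthetic cohorts

The generator produces the statistical structure the model must learn, not
MRI physics.  Each volume is a smooth radial template × low-frequency site
bias field × sex factor × per-subject scale, plus 8 Gaussian regional
structures whose amplitudes follow a piecewise-linear age trajectory
(slope +0.03 density/year per unit multiplier before age 18, −0.004 after,
with fixed per-region multipliers in [0.5, 1.5] so the amplitude *pattern*
identifies age even though the total is non-monotone), plus zero-mean
Gaussian voxel noise (sd 0.02, per-site multiplier in [0.75, 1.25]).
Ages are uniform on [0, 96].  Longitudinal pairs reuse all subject factors
with the latent age advanced by a known interval; retest pairs differ only
in the noise draw.  Cohort-level anatomy (blob layout, slope multipliers,
site fields) is seeded by `template_seed` separately from subject draws, so
evaluation cohorts can share anatomy with a training cohort while
containing new subjects.  Optional label noise (`age_label_noise_sd` = σ)
perturbs recorded ages only, making the Bayes-optimal MAE against recorded
ages σ·√(2/π) — an analytic yardstick for trained models.

What the generator does *not* emulate: real anatomy, acquisition physics,
motion artifacts, nonlinear inter-subject registration error, or the
age-heteroscedastic signal of real development.  Passing tests therefore
demonstrate that the architecture, optimization and metric layers are
correct and can extract a known multivariate age signal at realistic noise
levels — not that the model reaches any particular accuracy on real MRI.

## Problem sizes used in tests and the acceptance script

Exercising the full-scale model (84×102×84, widths 64/128/256, ~11.9 M
parameters) end-to-end is used only for shape and architecture checks;
learning experiments run a narrow configuration (widths 16/32/64, embed
24/40) on 20×24×20 grids, which preserves every architectural mechanism
(all stage transitions, CoT, SE, dual-stream fusion) at tractable cost.
The two learning checks are:

* **Overfit capacity**: 16 noise-free scans memorized to train MAE < 0.5 y
  within 300 epochs.  This check runs without stochastic regularization
  (it probes capacity, not generalization) and with peak LR 1e-3: 300
  epochs on 16 scans is only 600 optimizer steps, where the production
  schedule has barely left warmup.
* **Bayes-bound recovery**: a 512-subject cohort with σ = 2 y label noise,
  split 70/15/15 at subject level, trained with the production recipe
  (peak 2e-4, patience 15, capped at 40 epochs); held-out MAE must land
  within 2× the 1.60 y bound.  Typical runs land at 2.8–3.1 y, i.e. the
  model recovers most of the attainable signal after ~30 epochs.

## Design choices where the architecture description was open

* Max-pool padding 1 in the stem (required to reproduce 21×26×21) and
  projection shortcuts (1×1×1 stride-2 conv + BN) for downsampling blocks.
* A single ReLU after the shortcut sum (standard residual placement);
  none between the gated CoT addition and SE.
* CoT aggregation happens on the pooled grid; the aggregated correction is
  resized to the block grid before the final projection.  Average pooling
  uses ceil mode (11→6) averaging over valid elements only; unfolding uses
  zero padding so borders keep 27 nominal neighbors.
* Positional encodings use geometric frequencies with base 10000 per axis
  subspace.
* Cross-attention uses 4 heads, matching self-attention.
* `resnet_vit_concat` uses a two-layer head (concat→192→1) mirroring the
  main head; the description fixes only "feature concatenation".
* Weight decay applies to all parameters unless `decay_all_params=False`.

## Known limitations

* CPU-only and sized for small grids; full-scale training of the 11.9 M
  parameter model on tens of thousands of volumes is out of scope.
* BatchNorm statistics at batch size 8 make eval-mode predictions depend
  mildly on training-batch composition; seeds make this reproducible.
* The synthetic age signal is globally linear-in-features within each life
  phase; real lifespan signal is far less identifiable, so synthetic MAEs
  should not be compared to published MAEs on real cohorts.
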