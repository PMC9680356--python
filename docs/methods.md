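# Methods

## Problem and approach

Single-cell cervical cytology classification assigns one of five
morphological categories (superficial–intermediate, parabasal,
metaplastic, koilocytotic, dyskeratotic) to a pre-cropped cell image.
Deep classifiers for this task are typically large and generalize poorly
on the small labelled datasets available. `cytodistill` implements a
compact-student approach that combines three transfer mechanisms:

1. **Transfer learning** — the student backbone is pretrained on a
   source domain (stage 1) and fine-tuned on the cell images (stage 2).
2. **Knowledge distillation (KD)** — a larger frozen teacher supplies
   temperature-softened class probabilities ("soft labels") that carry
   inter-class similarity information; the student matches them via a
   temperature-scaled KL divergence.
3. **Self-distillation (SD) in a multi-exit student** — classifier
   branches ("exits") are attached after each backbone stage; the
   deepest exit acts as an internal teacher for the shallower ones, via
   both softened-logit KL and a feature-matching MSE. At test time the
   exits' softmax outputs are averaged into an ensemble prediction.

## Model

The student is a staged residual network (ResNet-18-class by default)
with an exit branch after each of the last `n_exits` stages (default 4).
Each branch is: **global-context (GC) block → scale-unifying bottleneck
μ_m → global average pool → fully connected head**. The deepest exit is
the backbone's own head path (identity bottleneck).

**GC block.** (i) *Context modeling*: a 1×1 convolution produces a
1-channel spatial map, softmax-normalized over all H·W positions, which
pools the input into one global context vector per image. (ii)
*Transform*: a two-layer channel bottleneck (reduce by `gc_reduction_ratio`,
default 16; layer norm + ReLU; expand back). (iii) *Fusion*: the
transformed vector is broadcast to every spatial position and combined
with the input. Broadcast **addition** is the default; element-wise
multiplication is available via `fusion_mode="multiply"` (the two
descriptions of the fusion operator in the source material conflict, and
addition is the variant that admits an exact identity-at-initialization:
the final transform layer is zero-initialized, so a freshly built GC
block is the identity map, which both stabilizes early training and
gives a sharp unit test).

**Bottleneck μ_m.** Exit m's feature map is 2^(n−m) times larger
spatially than the deepest exit's and proportionally narrower. μ_m is a
stack of stride-2 3×3 conv + BN + ReLU units, one per factor of two
(depth = log₂ of the spatial ratio), with channels projected to the
deepest stage's width, so every exit's feature map can be compared to
F_n elementwise. μ_n is the identity.

## Losses

With `soften(z, τ)_k = exp(z_k/τ)/Σ_j exp(z_j/τ)`, teacher soft labels
`t = soften(z_teacher, τ)`, exit logits S_m and unified features
μ_m(F_m), the per-exit terms are

    KD_m = τ²·KL(soften(S_m,τ), t) + CE(softmax(S_m), y) + CE(softmax(S_n), y)
    SD_m = τ²·KL(soften(S_m,τ), soften(S_n,τ)) + λ·MSE(μ_m(F_m), F_n)   (m < n)

and the objective is `Loss = Σ_{m=1..n} (KD_m + SD_m)`.

Deliberate conventions, each exposed as a switch:

* **KL direction.** The default places the *student's* softened
  distribution in the log numerator (`Σ p_s log(p_s/p_t)`), following
  the source formulation; the conventional distillation direction
  (`teacher_to_student`) is selectable via `kl_direction`.
* **Deep-supervision duplication.** Summed literally, the term
  `CE(softmax(S_n), y)` recurs in every KD_m. The default keeps the
  literal sum; `dedup_deep_ce=True` counts it once (the two differ by
  exactly `(n−1)·CE(softmax(S_n), y)`).
* **Stop-gradient.** S_n and F_n enter SD_m as constants, so the deep
  classifier teaches the shallow ones without being pulled toward them.
* **MSE reduction** is the mean over elements, making λ independent of
  feature-map resolution.
* Probabilities are clamped at 1e-12 before logs; softmax is stabilized
  by row-max subtraction.

**Inference** uses the unweighted average of the exits' τ=1 softmax
rows, `f = (1/n) Σ_m S_m` (temperature is a training device only).
Averaging near-independent exit classifiers reduces the variance of the
predicted probabilities, which is the mechanism behind the ensemble's
gain and is asserted as a property test on synthetic probability draws.

## Training procedure and defaults

Momentum SGD throughout. Full-scale defaults (`DistillConfig`): 180
epochs, batch 128, lr 0.1 decayed ×0.1 at epochs 100 and 150, weight
decay 1e-4, momentum 0.9, τ = 3, λ = 0.03. Stage 1 is plain CE
training; `transfer_load` then copies stem/stage tensors into a fresh
student (heads re-initialized for the target class count). Stage 2
optimizes the combined objective with a single optimizer over all
student parameters; the teacher is frozen (verified by parameter hash
before/after) and may itself have been produced by the same `pretrain`
path. Model selection is by best ensemble validation accuracy.
Augmentation (train split only): random area-scaled crop (0.7–1.0),
rotation ±15°, horizontal and vertical flips at p=0.5 — the operations
named for this task, with conventional mild magnitudes since none are
prescribed; "mirror flip" is read as vertical flip, configurable.
Normalization stats are computed from the training split rather than
fixed constants, because synthetic and real cytology differ strongly.

The implementation runs on a compact numpy reverse-mode autodiff engine
(`cytodistill.nn`) with im2col-based convolution; it is single-threaded,
CPU-only, and fully deterministic — identical seeds reproduce final
weights bit-exactly, which the test suite asserts.

## Synthetic data generator

The generator renders one "cell" per image: a perturbed-circle cytoplasm
(low-order harmonic boundary noise) containing a concentric nucleus
disk, radial ring texture inside the cytoplasm, on a bright background
with clipped Gaussian intensity noise (σ = 0.03 by default), grayscale
replicated to 3 channels so synthetic and RGB pipelines share one code
path. The five default classes differ in nucleus radius, cytoplasm
radius (hence N/C ratio, ordered low→high to mimic the
normal→abnormal gradient), boundary irregularity, mean intensities and
texture frequency. Every image is a pure function of (morphology
parameters, seed).

What it does *not* emulate: staining color and its variability,
overlapping/clumped cells, debris, focus blur, or intra-class
morphological diversity beyond the sampled parameter ranges. Passing the
desk-scale tests therefore shows that the training machinery (losses,
architecture, optimization, ensembling) works end to end on a separable
5-class problem of realistic geometry — not that the reported accuracy
transfers to real cytology.

## Desk-scale experiment

The reference experiment (`cytodistill.experiments`, also the basis of
`scripts/acceptance.py`) uses 84 images per class at 64×64 (stratified
3:1:1 → 250 train / 85 val / 85 test), a reduced-depth student
(`resnet8`: one residual block per stage, 8–64 channels, stride-2 stem,
GC reduction 4) and a wider frozen teacher (`resnet8w`) trained on the
same split. The schedule is the full-scale recipe rescaled to this
regime: 30 epochs, batch 50, lr 0.03, decays at the same relative
positions (epochs 17 and 25); at the full-scale lr of 0.1 the tiny
student's batch-norm running statistics lag the fast-moving weights and
evaluation accuracy collapses, so the lower rate is the package's
default for this regime. These sizes keep every training-based check
within single-CPU minutes.

## Numerical and degenerate-input choices

* Softmax stabilization by row-max shift; log clamp at 1e-12 (clamped
  true-class probabilities are logged).
* Split apportioning by largest remainder, with a guarantee of at least
  one item per split per class; classes smaller than the ratio total are
  rejected by name.
* A degenerate augmentation policy (unit crop, 0°, zero flip
  probabilities) reduces exactly to resize; resize to the identical size
  is the identity.
* Zero-support classes are excluded from macro metric means (logged).
* `tau=1, lam=0`, no teacher, self-distillation off reduces stage 2 to
  multi-head cross-entropy training (asserted by loss equality).

## Known limitations

* The exit-branch design (bottleneck layout, GC placement on the deepest
  exit, whether F_n is taken after its GC block — here: after) is
  under-determined by the source description; parameter totals are
  therefore checked by ordering (plain student < multi-exit student <
  teacher), not by absolute value.
* The teacher family ships as plain residual classifiers; split-attention
  teachers are out of scope, but any frozen logit-producer (or a
  checkpoint) plugs in.
* Full-scale (224 px, 180-epoch) training is supported by the same code
  paths but is far outside single-CPU test budgets; no claims are made
  about real-data accuracy.
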