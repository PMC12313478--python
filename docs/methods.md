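# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `smfnet`, and what the synthetic-phantom studies do and do
not demonstrate.

## Model

### Image branch (U-CNN)

A conventional U-Net encoder/decoder. Each stage is two Conv3×3–BatchNorm–
ReLU blocks; downsampling is 2×2 max pooling, so pyramid level *i* has
spatial extent H/2^(i−1) and C·2^(i−1) channels (depth 4 by default, so
inputs must be divisible by 16). Upsampling is nearest-neighbour ×2 followed
by Conv3×3 — interpolation-then-convolution avoids the checkerboard
artifacts of transposed convolutions; the choice between the two was open
and this is the one we fixed. The decoder ends in a 1×1 convolution to K=3
class logits (background / organ / lesion) and a per-pixel softmax.

### Text encoder

Reports are tokenized by lowercasing and splitting on non-alphanumerics,
padded to a fixed length (16). The encoder is deliberately small and
trainable from scratch: an embedding table (dim 64 by default), learned
positions, and 2 transformer-encoder layers (4 heads) shared between two
granularities — the token stream, and a phrase stream built from
non-overlapping sliding windows of w=2 tokens (group-mean embeddings). No
segmentation rule for phrases is canonical here, so fixed n-gram windows
keep the behaviour deterministic and testable. The pooled text vector is
the mean of the two streams' masked means; pad positions are masked out of
attention and means, so padding content cannot leak into the output. An
`external_embedder` hook accepts embeddings computed by any pretrained
multi-granularity language model with the same interface, for users who
have one.

### Multimodal fusion (CTBN + MTT)

At every pyramid level the pooled text vector is linearly projected to the
level's channel count, broadcast over the feature grid, and passed through
Conv1×1–BN–ReLU (the CTBN map). The image features are multiplied
elementwise by this map — multiplicative gating rather than concatenation,
so disabling text reduces cleanly to a bias pathway — then flattened to h·w
spatial tokens, projected to the transformer width, summed with a **fixed
2-D sine/cosine position encoding**, refined by one transformer-encoder
block (multi-head self-attention + MLP, post-norm residuals), projected
back and reshaped. The position encoding matters: the text's contribution
is spatially uniform by construction, and only a position-aware token mixer
can convert "upper left" into a spatially localized change of prediction.

The down-chain fuses level 1 first, then propagates: the fused output of
level *i* is max-pooled, lifted to the next channel width by a 1×1
convolution (the two pyramids disagree on channel counts, so a lift is
required), added to the CNN features of level *i+1*, and fused again. The
up-chain mirrors it with upsampling convolutions and per-level transformer
blocks; text enters only on the way down. At every skip connection the CNN
and transformer-branch features are summed and gated by MEAM.

### MEAM

Conv3×3+ReLU, then two parallel 1-channel maps — channel-wise average
pooling (AP) and channel-wise max pooling (MP) — each passed through a
stride-1 3×3 spatial max pool P_M, plus a third stream P_M(AP+MP). The
three streams are summed, a 1×1 convolution + sigmoid ("simplified CLAB")
turns them into a gate in (0,1), and the input is multiplied by the gate.
Consequences used as tests: zero input gives zero output, and |out| ≤ |in|
elementwise. Whether the pooling axis should be channels (spatial
attention, CBAM-style) or space (channel attention) is not determined by
the formula; channels is the default because the gate must broadcast over
channels to multiply X, and a `meam_pool_axis="spatial"` variant is kept
for comparison.

### Presets

Channel widths and transformer dimensions are not canonical; we use U-Net
conventions with three presets:

| preset | input | C1 | ViT dim / heads | d_text | use |
|---|---|---|---|---|---|
| `paper` | 256×256 | 64 | 64 / 4 | 64 | full-size runs (needs real compute) |
| `tiny`  | 32×32 | 16 | 64 / 2 | 64 | memorization study, CI |
| `nano`  | 32×32 | 8  | 32 / 2 | 32 | repeated training studies |

Self-attention over level-1 tokens costs O((HW)²); on a single CPU with the
NumPy engine this is the binding constraint, which is why the small presets
run at 32×32 (the phantom geometry is scaled by ½ accordingly) and why
`tiny` uses 2 heads. The architecture itself is resolution-agnostic.

## Training (DAS-Net)

Two students with independent initializations are trained side by side.
Per step and per student the objective is

    L = L_seg + r(t)·(λ1·L_cons + λ2·L_sta + λ3·L_adv)

* `L_seg = (CE + soft-Dice-loss)/2` on the labeled batch. Summing a Dice
  *similarity* into a loss (one literal reading of the source formula) is
  contradictory, so the Dice loss 1−Dice is used; the literal variant is
  available as `eq15_dice_as_similarity`.
* `L_cons`: a random label-preserving spatial transform T (90° rotations,
  horizontal flip) is drawn per step; the per-pixel squared difference
  between S(T(x_u)) and T(S(x_u)), summed over classes and averaged over
  pixels.
* `L_sta`: per-pixel squared difference between the two students'
  predictions on T(x_u), gated per sample by stability flags r (argmax
  agreement ≥ 90% between prediction and its transported counterpart AND
  mean max-class probability ≥ τ=0.6). When both students are stable the
  pixel mask [ε_a < ε_b] applies (printed indicator direction; a
  `flip_stability_indicator` switch reverses it, since the direction is
  arguable); otherwise the term is multiplied by the student's own flag.
  Gradients flow only into the student that owns the term.
* `L_adv`: −log D(x_u, ŷ_u) against the student's own discriminator — a
  strided PatchGAN-style CNN with one MEAM gating block and a scalar
  sigmoid realness output. Discriminators train on (labeled image,
  prediction) as real vs (unlabeled image, prediction) as fake; when the
  EMA teacher is enabled, the second discriminator's real pairs are teacher
  predictions on noise-perturbed unlabeled images.
* `r(t) = δ·exp(−5(1−I)²)`, I = epoch/ramp_epochs clipped to 1. δ = 1 and
  ramp_epochs = 50 (10 in the small studies); δ is not given anywhere, so
  1.0 keeps the plateau weights at their nominal (λ1, λ2, λ3) =
  (0.5, 0.2, 0.05), the baseline configuration. Whether the three-term
  objective is ramped at all is unstated; we ramp all three unsupervised
  weights, matching the single-λ mean-teacher formulation.

Update order per step: both students (the cross-student terms use
pre-update predictions computed without graphs; train-mode batch-norm
depends only on batch statistics, so these are bit-identical to the
graph-building forwards), then the discriminators, then the EMA teacher
(α = 0.999). Optimizer: Adam, β = (0.9, 0.99) — the stated "momentum 0.99"
is read as the second-moment coefficient — lr 3e-4 by default, 1e-3 in the
phantom studies (the rate used for the primary-dataset experiments the
architecture targets).

**Model selection.** Validation mean Dice is tracked for both students each
epoch; the checkpoint kept is the best (student, epoch) pair. With small
data one student occasionally stalls from an unlucky initialization while
its sibling converges; the framework's deliverable is a single model, and
which of the two structurally identical students to deploy is a free
choice.

**Reduction.** When every unsupervised weight is zero the unlabeled branch,
discriminators and teacher are skipped entirely, so a dual-student run is
bit-identical to two independent supervised runs — this is tested at the
parameter level after 5 steps.

A `mean_teacher` framework implements the single-λ objective
L_s + λ(L_semi + L_adv1 + L_adv2) with the Dice loss as L_s, MSE to the
EMA teacher's prediction on noise-perturbed inputs as L_semi, and the same
discriminator pairs.

## Metrics

Dice and mIoU are computed per class on argmax label maps; classes empty in
both maps are excluded from class means (the convention is not universal;
this one avoids rewarding trivially empty predictions). HD95 uses
4-connectivity boundary pixels, exact Euclidean distance transforms, and
the linear-interpolation 95th percentile of the pooled directed distances;
an empty boundary on either side yields NaN, never a silent 0. MAE compares
the probability map against the one-hot truth over all pixels and classes —
probabilities rather than hard labels, because the network's raw output is
a probability map.

## Synthetic phantoms

Each sample is an ellipse ("organ", fixed +0.10 intensity over a 0.40
background) containing one disk ("lesion", organ + `contrast`, default
0.15), with i.i.d. Gaussian pixel noise (sd 0.05) and a templated sentence
`"{count} lesion(s) in the {vertical} {horizontal} of the organ"`, where
the location is the lesion centroid's ninth of the organ bounding box.
Organ pose and lesion placement are jittered per sample; all randomness
derives from explicit seeds, and regeneration is byte-identical. The
default grid is 64×64 with organ semi-axes (20, 12) px and lesion radius
3–6 px; the 32×32 `tiny_spec` halves all geometry.

What the phantoms do **not** emulate: anatomical texture, multi-phase
contrast, partial-volume boundaries, annotation noise, inter-observer
variability, or any correlation structure between text style and image
appearance. Passing the phantom studies therefore shows that the
*mechanisms* work — the fusion path can exploit location text, the
semi-supervised machinery extracts signal from unlabeled images, the
network has enough capacity to memorize — not that the method reaches any
particular accuracy on clinical data.

## The three studies

* **Memorization** — tiny preset, 4 phantoms, full-batch Adam, at most 300
  steps, early exit once training mean foreground Dice ≥ 0.95. Verifies
  end-to-end trainability of the full architecture.
* **Text utility** — contrast lowered to 0.05 (the lesion sits at 1 sd of
  the noise, nearly invisible), 8 labeled + 8 validation, nano preset,
  20 epochs, 3 seeds. Compares real annotations against the constant
  "no finding" string (the text-disabled configuration). Only the
  direction of the difference is asserted.
* **Semi-supervised gain** — default contrast, 8 labeled + 32 unlabeled +
  8 validation, nano preset, dual-student with (0.5, 0.2, 0.05) and a
  10-epoch ramp vs the same-data supervised baseline, 3 seeds, unlabeled
  batch 2. Again directional: mean validation Dice of the selected DAS-Net
  model must not fall below the baseline.

Runtimes are minutes each on one CPU; `scripts/acceptance.py` runs all
three and writes the numbers it computed.

## Numerical conventions and degenerate inputs

* float32 activations/parameters; Adam moments in float64. Fixed seeds make
  runs bit-reproducible on a given platform.
* Soft Dice smoothing 1e-6 in numerator and denominator; probabilities
  clipped to [1e-7, 1] inside logs; softmax is shift-stabilized.
* Max-reduction gradients go to the first maximal entry; pairwise maxima
  route ties to the left operand (deterministic subgradients).
* Empty text encodes to a zero pooled vector (masked means over an empty
  set are defined as 0). Empty labeled batches and non-divisible image
  sizes raise immediately; a NaN in any loss component aborts the step
  naming the component.

## Known limitations

* Full self-attention over level-1 tokens makes 256×256 inputs impractical
  in the bundled NumPy engine; the `paper` preset is provided for users who
  connect real accelerator compute, and the studies characterize 32×32.
* The "shared information channel" between students is realized exactly by
  the cross-student loss terms; no additional feature exchange is
  implemented, as none is specified concretely.
* Which batch feeds the teacher-side discriminator pair is underdetermined;
  we use the unlabeled batch plus Gaussian noise.
* With `n_lesions > 1` the text names the aggregate centroid's ninth, which
  can be misleading for widely separated lesions; the studies use one
  lesion per phantom.
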