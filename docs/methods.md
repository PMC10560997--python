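# Methods

## Model

The framework couples three ingredients.

**Dynamic MC dropout.** A network with per-layer parameters θ = {θ₁,…,θ_d}
is expanded into an ensemble of configurations θ̂ᵢ = θ·δᵢ, with δ drawn
elementwise from N(1, σ²).  Sampling is pure and counter-based: member i of
a `DropoutConfig(seed, N)` is a deterministic function of `(seed, i)`, so
ensembles are reproducible and members are mutually independent draws.  The
perturbation acts on **weights**, not activations; multiplicative noise is
relative, so it is well defined at any weight scale and annihilates on zero
parameters.  "Dynamic" is exposed as a σ-schedule hook (`constant` default,
`linear_decay` optional); σ itself is constant unless the schedule is
enabled.  Dropout is active during training (a fresh δ per batch, gradients
chain through δ: ∂L/∂θ = ∂L/∂θ̂ · δ) and at test time, where test-time
sampling produces the MC moments.

**Predictive moments.** For one input x and N member predictions ŷᵢ (each a
per-pixel probability simplex),

- first moment: E[y] ≈ (1/N) Σ ŷᵢ (the prediction);
- second moment, per pixel: u ≈ τ⁻¹I_C + (1/N) Σ ŷᵢᵀŷᵢ − E[y]ᵀE[y].

τ is the vector of normalized class frequencies pooled over the *training
split* (not per batch), so u is stable across evaluation batches.  τ⁻¹I_C
is interpreted as diag(1/τ_c): τ is defined as a frequency vector, and the
diagonal reading gives each class an offset inversely proportional to its
frequency — the mechanism by which rare classes carry intrinsically higher
uncertainty.  A `tau_mode="scalar"` switch supports the alternative
scalar-precision reading (1/mean τ)·I_C for users who want the
Gaussian-process-approximation convention; the vector reading is the
default.  The covariance part of u is PSD by construction and u is exactly
symmetric.

**OOD score.** The per-image score is a spatial reduction (mean by default;
max and quantile available) of trace(u) − trace(τ⁻¹I_C), i.e. of the MC
total variance with the constant rarity offset removed.  Removing the
offset makes the score reflect *model disagreement* only: a confident
in-distribution prediction scores ~0 regardless of the class composition of
the image.  z is held fixed across ensemble members during MC sampling
(`z_policy="fixed"`), isolating the weight-noise contribution; resampling z
per member is available as a flag.

**Ensemble GAN.** One conditional generator G(z, x) faces K patch
discriminators D_k(x, y) scoring local patches of an (image, label-map)
pair.  Per discriminator, V(D_k,G) = E[log D_k(x,y)] + λ_k E[log(1 −
D_k(G(z,x),x))] (patch scores averaged to the batch expectation; λ_k = 1 by
default, the source material leaves them unstated).  The generator's
adversarial feedback is F over the *active* discriminators, where F ∈ {sum,
average, maximum} is redrawn each batch from `mode_probs` (uniform by
default) and each discriminator is dropped for the batch with probability
`drop_prob` (0.1 default; the sampler redraws if all K would drop).  The
interaction between aggregation and dropping is resolved as: aggregate over
the non-dropped subset.  The generator loss adds, to the aggregated
adversarial term, the auxiliary segmentation losses (ℓmae, ℓcce, ℓDice)
assigned to the active discriminators, unweighted by default with per-loss
weights exposed — the simplest reading of "a combination of losses".  The
generator uses the non-saturating −log D(fake) form internally (standard
practice; the literal saturating form is selectable via
`ObjectiveConfig(saturating=True)`).

## Architectures

- Generator: stacked hourglass — a stem convolution, S=2 hourglass stages
  (3 stride-2 downsamplings, bottleneck, nearest-neighbour upsampling with
  additive skips) applied residually, and a 1×1 head that sees both the
  refined features and the raw input before a per-pixel softmax.  z
  (noise_dim 16) is broadcast and concatenated at each bottleneck.  Weights
  are initialized from N(0, 0.001); biases zero.  The tiny initialization
  makes early training a bootstrap phase (Adam's scale-invariant steps grow
  the weights before the loss falls), visible as 3–4 flat epochs in the
  worked example before the segmentation snaps in.
- Discriminators: PatchGAN-style stacks of stride-2 convolutions (receptive
  field ≈ `patch_receptive_field`, default 16 px — the classical 70-px
  design scaled to 64×64 inputs), sigmoid patch scores in (0,1), He
  initialization (random; no pretraining).
- Engine: both are compact numpy CNNs (im2col convolutions with explicit
  backward passes) — float64, single image at a time, verified against
  finite differences.  Inputs must be divisible by the 2³ downsampling
  factor; violations raise a shape error.

## Training protocol

Adam with lr 2e-4 (constant; a linear-decay flag exists), β₁=0.9, β₂=0.999,
weight decay 1e-4 folded into the gradient, mini-batch size 1, alternating
one discriminator step (each active D_k, BCE on real and generated pairs)
and one generator step per batch, 1:1 update ratio.  Every stochastic
control — data order, z, dropout δ, aggregation mode, discriminator drops,
validation z — draws from its own stream derived from the master seed, so
(a) runs are bit-reproducible, and (b) the K=1, σ=0 configuration consumes
exactly the streams the standalone conditional-GAN baseline does, making
the degenerate-case equivalence checkable bitwise rather than
approximately.  Per-batch loss breakdowns, the drawn mode, the active mask
and the sample ids are logged in `TrainHistory` (the sample-id trail lets
tests audit that validation images never reach a parameter update).
Divergence (non-finite loss) aborts with the last end-of-epoch parameters
attached to the exception.

Cross-validation follows the stated protocol of three seeded random 80/20
splits.  (Three-fold partitioning and 80/20 splitting are mutually
inconsistent; the repeated-split reading matches the stated percentages and
is flagged in every report's settings.)  Best-epoch selection uses
validation F1 with a plain (σ=0, N=1) forward pass; final evaluation uses
the full MC predictive mean.

## Synthetic phantoms

The generator emulates the *statistical* structure of abdominal-CT style
long-tailed benchmarks, not their anatomy: per image one elliptical "organ"
and 0–3 small "lesion" blobs placed inside it, per-class Gaussian
intensities (background 0.25, organ 0.55, lesion 0.85; σ 0.06) plus smooth
low-frequency texture, clipped to [0,1].  Class ratios are enforced *pooled
over the dataset*: per-image organ areas and lesion counts are drawn
against the running pooled deficit, so composition converges tightly (the
1:1400 preset lands within ~1% at n=200) while individual images vary and
many contain no lesion at all — as at a 1:1400 ratio they must.  Presets:
`lits_like_spec` (1:400 organ, 1:1400 lesion), `chaos_like_spec` (four
organs at 1:40…1:400), `desk_spec` (1:10 organ, 1:100 lesion — the
reference desk-scale condition), plus a 1:30 binary classification set
whose minority class carries a faint ring signature.  Per-image RNG streams
are counter-derived from the master seed, so growing n never reshuffles
earlier images.  Domain shift composes brightness offset (+0.15), contrast
scale (×1.2), stationary noise (σ 0.05) and an optional resolution
round-trip; labels are never altered, the identity shift is short-circuited
to bit-identical pixels, and out-of-range intensities are clipped and
counted (>50% clipped warns).

What passing tests on these phantoms do **not** show: robustness to
anatomical variability, 3D context, annotation noise, or real
scanner physics.  The phantoms establish that the mechanisms work — the
moments obey their formulas, tail classes accumulate uncertainty, shifted
inputs score higher — not that the reported desk-scale metric values
transfer to clinical data.

## Parameters that matter

| parameter | default | why |
|---|---|---|
| σ (weight-noise std) | 0.1 | relative perturbation strong enough to spread the ensemble without destroying predictions; unstated in the source material, chosen once |
| N (MC samples) | 5 | desk-scale default; variance estimates stabilize by N≈5 on these phantoms |
| K (discriminators) | 3 | one per auxiliary loss (mae/cce/dice) |
| λ_k | 1.0 | unstated; uniform |
| mode_probs | uniform | unstated; uniform over {sum, average, maximum} |
| drop_prob | 0.1 | light per-batch heterogeneity |
| lr / β / wd / batch | 2e-4 / 0.9, 0.999 / 1e-4 / 1 | stated optimizer configuration |
| generator init std | 0.001 | stated initialization |
| ECE bins | 10 | conventional |

## Numerical choices

- Scores are clamped to [1e-12, 1−1e-12] before logs; probabilities clamped
  at 1e-12 in CCE/NLL (the clamp zone has zero gradient).
- Dice uses ε=1e-6 in numerator and denominator, averaged over foreground
  classes (class 0 is background); for C=2 this is plain foreground Dice.
- ASSD surfaces are 4-connectivity boundary pixels; empty surfaces return
  +inf as an explicit sentinel; distances via KD-tree, verified against an
  all-pairs oracle.
- AUROC is the midrank Mann–Whitney statistic (ties count ½), exact and
  monotone-invariant.
- ECE bins are equal-width on (0,1]; confidence 0 falls in the first bin.
- Aggregation `maximum` backpropagates through the argmax member only;
  `average` scales by 1/|active|.
- Multi-class reports macro-average over foreground classes with
  pixel-pooled counts per class; degenerate cases (absent class, no
  predicted positives) are flagged, not silently zeroed.

## Design decisions in open territory

- No classifier trainer is included: the 1:30 classification phantoms are
  generated and evaluated (F1/ECE/NLL) through the metrics API; the
  adversarial trainer is a segmentation model.
- The rare-class uncertainty property is asserted on the true-class
  diagonal entry u_cc of the pixel's own class, i.e. on u as defined —
  including the 1/τ_c offset that encodes rarity.  The offset-free MC
  variance comparison (tail vs background) is reported alongside but not
  asserted: at desk scale it fluctuates across seeds (the five-epoch model
  is still mid-bootstrap on the tail class), and `scripts/acceptance.py`
  prints both ratios so the distinction stays visible.
- A "dual output of the generator (global and local feature vectors)" is
  mentioned in the source material's discussion but never formalized; it is
  not implemented rather than guessed at.
- Desk-scale problem sizes (64×64 images, 200 training images, 5 epochs,
  base width 8) are the package's reference configuration: the smallest
  sizes at which every mechanism — adversarial training, ensemble
  aggregation, MC uncertainty, OOD separation — is measurable in seconds on
  one CPU.

## Known limitations

- 2D only; no volumetric convolutions or 3D deformation models.
- The numpy engine is single-threaded per image and float64; it is built
  for desk-scale experiments, not for training on full-resolution clinical
  datasets.
- Lesion-level (instance) detection metrics are out of scope; all
  precision/recall figures are pixel-level.
- GAN training at batch size 1 is noisy; per-epoch loss means fluctuate,
  and the lesion tail typically needs more than the reference five epochs
  to be segmented (its uncertainty, however, is measurable from the start).
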