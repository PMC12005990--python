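# Methods

## The model

`dcef` classifies two-class grayscale lesion images (benign vs malignant,
malignant = positive class 1) with an ensemble of K sub-networks trained
under a single *fused cross-entropy* objective. Sub-network k maps an image
to a feature vector x_k ∈ R^{d_k}; a linear softmax head w_k ∈ R^{d_k × C}
turns features into class probabilities, and the per-network loss is the
multinomial cross-entropy

    L_k(w_k) = − Σ_i log softmax(x_{i,k}ᵀ w_k)[y_i].

The fused objective is the convex combination

    L(π, w) = Σ_k π_k L_k(w_k),   subject to  Σ_k π_k = 1, π_k > 0,

with the ensemble weights π living on the open probability simplex. The
constraint is handled with an augmented Lagrangian: a scalar multiplier η
for the equality constraint, a vector multiplier ξ for positivity, and a
quadratic penalty with coefficient τ.

### Optimization schedule

Each training epoch alternates three steps:

1. **Head updates.** Minibatch SGD on every w_k with π fixed (momentum,
   weight decay, cosine-annealed learning rate). The gradient of π_k L_k is
   the standard softmax-regression gradient scaled by π_k:
   −π_k Σ_i x_{i,k}(y_i − p_i)ᵀ with p_i the predicted probability row.
   Heads start at zero — the objective is convex in each head, so nothing
   needs symmetry breaking, and zero initialization makes runs trivially
   reproducible.
2. **Fusion-weight update.** With ℓ the vector of epoch-mean per-network
   losses, stationarity of the Lagrangian in π gives the K×K linear system
   τ(11ᵀ + I)π = τ1 − (ℓ + η1 + ξ). The solution is then **Euclidean-
   projected onto the simplex**. This is exact, not a heuristic: restricted
   to the simplex the objective equals π·(ℓ+ξ) + (τ/2)‖π‖² up to a
   constant, i.e. a scaled squared distance to the point −(ℓ+ξ)/τ, and the
   unconstrained stationary point differs from that center only by a
   multiple of the ones vector — a direction simplex projection ignores.
   Projecting the closed-form point therefore lands exactly on the
   constrained minimizer. The minimizer is anti-monotone in ℓ: networks
   with larger losses can never receive larger weights, which is the
   down-weighting behavior the fusion is designed for. A floor of 1e−6
   with renormalization keeps every π_k strictly positive (perturbation at
   most K·1e−6).
3. **Multiplier updates.** η += θ₁(1ᵀπ−1), ξ += θ₂π, and
   τ += (θ₃/2)(|1ᵀπ−1|² + ‖π‖²). τ is strictly increasing, so over many
   epochs the penalty slowly dominates and π stabilizes.

After the final epoch one extra π/multiplier update is performed on losses
evaluated at the final heads, so the reported π corresponds to the reported
weights. A consequence worth noting: because the final π is anti-monotone
in the final per-network losses, the fused loss under the optimized π is
never worse than under uniform weights (Chebyshev's sum inequality) — the
adaptive weighting provably cannot hurt the training objective it
minimizes.

### Hyperparameters

| Parameter | Default | Meaning |
|---|---|---|
| lr | 0.1 | initial SGD rate, cosine-annealed |
| momentum | 0.9 | SGD momentum |
| weight decay | 5e−4 | L2 coefficient on heads |
| batch size | 128 | minibatch size |
| epochs / T_max | 100 / 100 | training length and cosine period |
| θ₁, θ₂, θ₃ | 0.1 each | multiplier step sizes |
| τ₀, η₀, ξ₀ | 1, 0, 0 | augmented-Lagrangian warm start |

The cosine schedule is lr(e) = lr_min + (lr_max−lr_min)(1+cos(πe/T))/2.
Desk-scale tests shrink epochs and batch size but never alter the update
formulas. The multiplier step sizes and warm start are conventional
augmented-Lagrangian choices; all are configurable. π updates happen on
the epoch timescale using epoch-mean losses because batch-level loss
summaries are too noisy to drive a closed-form reweighting.

## Sub-networks

A sub-network is an opaque map from an image batch to a feature batch.
Three pure-NumPy families are provided: `identity` (flattened pixels),
`tiny-conv` (two layers of frozen seeded random 3×3 filters with ReLU and
2×2 average pooling, pyramid-pooled and randomly projected), and
`tiny-attention` (8×8 patch embedding, one frozen softmax self-attention
layer, mean-pooled). The extractors are *frozen random features*; all
learning happens in the linear heads, which is exactly the part of the
model the fused objective's gradients cover. The six conventional slot
names (vgg16, resnet18, resnet50, densenet121, inceptionv3, vit) are
registered as tiny stand-ins with distinct parameter draws (the name
enters the seed), so the five-slot ablation design runs on any CPU with no
downloads or GPU.

## ROI mechanisms

Two feature-map refinements sit around the backbone/classifier boundary:

- **Pyramid pooling:** adaptive average pooling at grid sizes 1, 2, 3, 6
  concatenated per channel (50 cells per channel); max pooling is an
  option. Bin 1 reproduces the global mean.
- **ROI weight enhancement:** softmax attention over feature responses
  inside the lesion mask, W_i = exp(F_i)/Σ_j exp(F_j), followed by the
  weighted sum Σ_i W_i F_i — a convex combination of ROI responses,
  computed per channel and with max-shift stabilization. Without a mask
  the whole map is the ROI (documented fallback).

In the experiment pipeline the enhancement enters as three ROI summary
features appended to every network's feature vector: the
attention-weighted response, the plain masked mean, and the ROI fill
fraction (a compactness/irregularity cue). This placement — between
backbone features and the classifier — keeps the mechanism architecture-
agnostic. It is config-controlled (`roi_feature`); the fusion-math unit
tests never enable it.

## Preprocessing and imbalance handling

Images are cropped to the ROI bounding box plus a 25% margin (lesion-patch
classification: background gain carries no class information), min-max
normalized to [0,1], and resampled to 64×64 (masks nearest-neighbor).
Per-network features are z-scored with training-split statistics, stored
alongside the trained bundle.

The benign class is scarce (27 benign vs 68 malignant in the default
cohort shape), so the training split — and only the training split — is
balanced in a fixed order:

1. **Augmentation** of benign images (right-angle rotations plus ±15°
   tilts with reflection padding, horizontal/vertical flips, translations
   within ±10%) up to 80% of the malignant count;
2. **SMOTE** in feature space for the remainder: synthetic rows are convex
   combinations x_i + γ(x_j − x_i) of a minority row and one of its k=5
   nearest minority neighbors, γ ~ U(0,1). SMOTE runs on the concatenated
   per-network feature matrix so each synthetic sample is consistent
   across sub-networks. Feature-space SMOTE avoids the ghosting artifacts
   of pixel-space interpolation;
3. optional **undersampling** of the malignant majority (off by default —
   the cohort is already small);
4. **class weights** at a 2:1 benign:malignant ratio, normalized to mean 1
   (weights 4/3 and 2/3) and injected as per-sample multipliers on the
   log-likelihood terms.

Splitting is stratified 50/20/30 (train/validation/test) at the *source*
level: images sharing a `source_id` always land in the same split, so a
patient can never leak across splits. With 38 benign and 97 malignant
sources the test split receives 11 and 29.

## Metrics

Malignant is positive. Accuracy, sensitivity TP/(TP+FN), specificity
TN/(TN+FP), precision TP/(TP+FP), F1 = 2TP/(2TP+FP+FN), and balanced
accuracy (mean of sensitivity and specificity) are computed from the
confusion matrix at a threshold (default 0.5; the Youden-optimal threshold
is also reported since small cohorts rarely calibrate well at 0.5). A
metric with a zero denominator is reported as NaN and flagged, never
silently zeroed. AUC is the Mann–Whitney concordance computed from average
ranks (ties count half); the test suite verifies it against trapezoidal
integration of the ROC curve to 1e−9 on hundreds of random instances.

## Synthetic data

The generator emulates the statistical structure of lesion-bearing
B-mode-like frames: a smooth background field (Gaussian-filtered uniform
noise mapped to [0.15, 0.40]) carrying multiplicative Rayleigh speckle
with unit mean (blended by `noise_level`, default 0.3 — the standard
first-order ultrasound texture model), plus one bright elliptical lesion
whose boundary is perturbed by low-order radial harmonics. The ROI mask
equals the exact lesion support.

Class differences are controlled by a single standardized effect size,
`separability` (default 3.0):

- lesion mean intensity: benign 0.55, malignant 0.55 + separability×0.05,
  with within-class SD 0.05 — so separability is the gap in SD units;
- equivalent diameter: class means 22.4 px (benign) and 23.8 px
  (malignant), with the gap scaled by min(separability, 1);
- boundary irregularity: harmonic amplitude 0.04 for benign, plus
  0.03×min(separability, 3) for malignant.

At separability 0 the class-conditional distributions coincide exactly and
any classifier sits at chance; at 3 the classes overlap realistically; at
5 they are cleanly separable (the regime used for the end-to-end smoke
checks). "Pixels" for lesion size is interpreted as mean equivalent
diameter; the realized mask diameters run ~6% below the drawn diameters
because of elliptical aspect (0.75–1.0), still within 10% of the
configured means.

What the generator does **not** emulate: acoustic shadowing and
enhancement, depth-dependent attenuation and focus, operator and probe
variability, anatomical context, and inter-observer annotation noise.
Passing tests on this data demonstrate the correctness of the optimization
and pipeline machinery and the qualitative behaviors of the fusion
(down-weighting, ensemble benefit) — not clinical performance on real
ultrasound.

A second fixture bypasses images entirely: `generate_feature_ensembles`
builds K feature batches where chosen networks carry a Gaussian class
shift along a random unit direction and the rest are pure noise, giving a
direct, fast test bed for the fusion optimizer's down-weighting behavior.

## Numerical choices and degenerate inputs

- All softmax computations (classification, ROI attention) subtract the
  row max before exponentiation.
- Simplex membership is enforced to 1e−9; the π floor is 1e−6.
- A constant image min-max-normalizes to all zeros with a warning, not an
  error.
- K = 1 forces π = [1] regardless of losses; τ = 0 is rejected at
  construction (the closed-form system would be singular).
- Duplicate backbone names in an ensemble are allowed (each gets the same
  frozen parameters) and logged.
- Determinism: every stochastic component (generator, shuffling,
  augmentation, SMOTE, undersampling, splitting) draws from
  `numpy.random.default_rng` seeded from the run configuration; two runs
  with the same config are bit-identical.

## Problem sizes

Unit and property tests run at n ≤ a few hundred samples and 64×64 images.
The end-to-end checks use the cohort shape (27 benign + 68 malignant,
50/20/30 split), K = 3 tiny backbones, 30 epochs, and 5–10 seeds — sizes
chosen so the full suite and the acceptance script each complete in well
under a minute of CPU apiece while still exercising every pipeline stage.

## Known limitations

- The named large-architecture slots are tiny random-feature stand-ins;
  only the linear heads train. Conclusions about relative slot quality on
  real data do not transfer.
- SMOTE in joint feature space assumes per-network features are extracted
  from the same preprocessing; mixing backbones with different input
  normalizations would interpolate inconsistently.
- The augmented-Lagrangian multiplier ξ grows monotonically (ξ += θ₂π with
  π > 0), which slowly biases the closed-form update against persistently
  high-weight networks; with the default step sizes the effect is
  negligible over 100 epochs but matters for very long runs.
- AUC confidence intervals (DeLong) and calibration analysis are out of
  scope.
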