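# Methods

## Problem setting

Dynamic renal scintigraphy with 99mTc-MAG3 records tracer transit through
the kidneys as 120 frames of 128 × 128 pixels, one frame every 10 s for
20 min. The clinical static image is the sum of all frames. Because count
statistics are Poisson, summing only half of the frames is statistically
equivalent to halving the administered activity: the expected counts halve
and the relative noise grows by √2. The package asks whether a
convolutional denoiser applied to the 50 %-count summed image can recover
the image quality of the 100 % sum, quantified by kidney-ROI SNR and
MS-SSIM.

## Synthetic renogram phantom

The phantom stands in for a clinical cohort so that every stage is testable
without data downloads.

* **Geometry.** Two elliptical kidneys with semi-axes interpolated linearly
  between newborn (6 × 4 px) and adolescent (13 × 8.5 px) anchors on the
  128-px grid, jittered centres, plus a bladder disk that fills late in the
  study. Anchors correspond to ~4.5 cm and ~10 cm renal lengths at the
  native pixel pitch.
* **Kinetics.** Each kidney follows a gamma-variate time–activity curve
  a(t) = (t/tp)^k · exp(k(1 − t/tp)) with shape k ∈ [2, 3.5] and peak time
  tp ∈ [180, 300] s, the standard renogram shape: zero at injection, a
  single peak, exponential-tail washout. The curve is normalised to 1 at
  tp, so `kidney_peak_amplitude` is the peak kidney excess in
  counts/pixel/frame.
* **Counts.** Every pixel of every frame is an independent Poisson draw
  with mean `count_scale × (background + organ excess)`. Absolute count
  levels are free parameters of the model (the source cohort's injected
  activities are unknown); the defaults — background 0.5 counts/px/frame
  and a 12:1 peak kidney contrast — give summed images in the count regime
  typical of a paediatric MAG3 study. `count_scale` models proportional
  dose reduction.
* **ROIs.** Kidney masks are the exact phantom ellipses; the background
  mask is a 4-px-wide band starting `margin_pixels` (default 2) outside
  each kidney, excluding every organ — mirroring the red kidney / blue
  surround convention of clinical ROI drawing.
* **Not modelled:** patient motion, scatter, attenuation, dead-time,
  kidney–bladder overlap. Passing tests therefore demonstrate the method's
  behaviour under pure Poisson statistics with known geometry, not
  performance on clinical images.

## Dose simulation and dataset

`sum_frames` selects `round(fraction × n_frames)` frames and sums them.
The default `alternating` scheme takes every other frame so the reduced
sum still spans the full 20-min envelope; a first-half block would bias
uptake against washout. Each study yields one (50 % input, 100 % reference)
pair; the inventory counts both members, so 100 studies are 200 images.
Splits use floor(n·fraction) for train and validation with the remainder
to test, giving 134/32/34 at n = 200 under 67/16/17 %. Counting is done
over images while assignment is grouped by study, so no study straddles a
split boundary. Preprocessing resizes to the working resolution and
divides by the image maximum (all-zero images pass through unchanged).

## Networks

All four models are built on the package's own channels-last numpy engine
(`renodenoise.nn`): a tape-based reverse-mode autodiff with tap-wise
BLAS-lowered convolutions, index-storing max pooling, transposed
convolution, batch normalisation and Adam/SGD. Every operation's backward
pass is validated against central finite differences in the test suite.

* **DnCNN** — eight 3 × 3 convolutions, 64 filters: input conv + ReLU, six
  conv+BN+ReLU blocks, output conv; padding preserves size; no pooling.
  The network predicts the denoised image directly (no residual head).
* **UDnCNN** — the same backbone bent into a U: 2 × 2 index-storing max
  pooling after convs 2 and 3, index-based unpooling after convs 5 and 6,
  skip features merged as (up + skip)/2.
* **DUDnCNN** — identical parameterisation with pool/unpool replaced by a
  dilation schedule. Layer dilation is 2^(κ−ι), where κ/ι count the
  pooling/unpooling stages crossed so far, giving (1,1,2,4,4,2,1,1) for
  the default placement. A 3 × 3 kernel at dilation 2 covers 5 × 5, at
  dilation 3 covers 7 × 7; receptive-field growth is achieved with zero
  extra parameters, so the three backbones have identical counts.
* **AttnGAN** — a U-shaped generator with four down/up stages (feature
  depth 64→128→256→512→1024 and back), each stage gated by CBAM (shared
  two-layer MLP channel attention over global average/max descriptors,
  then a 7 × 7 spatial gate), with skip concatenation in the decoder, and
  a patch discriminator of five 4 × 4 convolutions (strides 2,2,2,1,1)
  mapping a 256 × 256 input to a 30 × 30 score map.

Design points that were genuinely open and were fixed once:

* The printed dilation rule is ambiguous; the 2^(κ−ι) reading is the one
  consistent with "dilation factor 2" after a single pooling replacement
  and with receptive-field equivalence to 2 × 2 pooling, so it is the
  default (`dilation_for_layer`).
* Single-channel images are the native mode (scintigraphy is
  single-channel); `in_channels=out_channels=3` is available as an
  RGB-replication compatibility mode.
* Two pooling stages sit symmetrically in the six middle layers; two
  stages keep 128- and 64-px inputs trivially divisible.
* Weight init is the standard Kaiming-uniform conv default
  (bound 1/√fan_in); BN starts at γ=1, β=0 with momentum 0.1.

## Training and selection

MSE between the denoised 50 % image and the 100 % reference is the loss.
The hyperparameter grid is batch ∈ {4, 16, 32} × learning rate
∈ {1e-3, 1e-4, 1e-5} with Adam, plus one SGD (momentum 0.9) comparison; no
augmentation, no schedule, no early stopping. The adversarial generator
loss adds λ·BCE(D(ŷ), 1) with λ = 0.01, small enough that the pixel loss
dominates; generator and discriminator update in alternation. Loss
histories record epoch 0 as the pre-training loss. Grid search ranks
configurations by the mean relative error of the metric values
(SNR left/right, MS-SSIM) on the held-out test images, matching the use of
the test patients for selection; runs that diverge rank last rather than
aborting the search.

## Metrics

* **SNR** = (μ_L − μ_B)/σ_B with masked means and the population standard
  deviation. It is invariant under positive affine intensity maps, which
  the tests verify numerically.
* **MS-SSIM** uses the canonical five-scale weights (0.0448, 0.2856,
  0.3001, 0.2363, 0.1333) with equal luminance/contrast/structure
  exponents per scale, an 11 × 11 Gaussian window (σ = 1.5), C1 = (0.01L)²,
  C2 = (0.03L)², L = 1 for normalised images, valid-region statistics, and
  2 × 2 average-pool downsampling. The luminance term enters only at the
  coarsest scale, via the mean of the full per-pixel similarity map, so at
  M = 1 the metric reduces exactly to SSIM (verified against scikit-image).
  Images too small for the requested scales reduce M with a warning
  (strict mode raises); at 128 px the 11-px window supports four scales.
  Contrast/structure terms can be negative; sign-preserving powers keep
  the value defined, and the [0, 1] contract is asserted only for the
  non-negative normalised inputs the pipeline produces.
* **Relative error** is the mean over pixels of |a − b|/max(a, b) in
  percent, with both-zero pixels contributing zero.
* The gain/loss summary reports, per metric and method, the signed mean
  percent change against the un-denoised 50 % baseline (positive = gain),
  since denoising is applied to the 50 % images.

## Statistics

Per-image metric differences between two methods are tested pairwise:
Shapiro–Wilk at α = 0.05 on the differences chooses between the paired
t-test and the Wilcoxon signed-rank test (exact null for n ≤ 25 after
dropping zero differences, normal approximation with continuity correction
above). Tables are upper-triangular over all unordered method pairs with
no multiplicity correction by default (a Holm-corrected view is behind a
flag). All-zero difference vectors are flagged as degenerate rather than
tested. The full selection-then-test path holds its nominal type-I error
(0.05 ± 0.02 at n = 17 over 2000 null simulations) and detects a
one-within-pair-sigma shift with > 90 % power.

Age stratification groups reports into [0, w), [w, 2w), … year bins
(default width 3) and reports per-group mean and standard deviation of
each metric per method; empty groups are absent, not errors.

## Problem sizes

Test and acceptance runs use reduced problem sizes chosen as the package's
own desk-scale defaults: cohorts of 8–100 studies at 32–64 px, 6–120
frames, and trainings of 3–200 epochs. The headline desk-scale experiment
trains the UDnCNN on 32 studies at 64 × 64 for 200 epochs with batch 16,
learning rate 1e-3 and Adam — the published optimal setting for that
network — and evaluates on the held-out test studies. At this scale the
absolute SNR values are not comparable to clinical ones; only directions
and orderings (denoised > noisy, 100 % > 50 %) are asserted.

## Known limitations

* The numpy engine is single-threaded and CPU-bound; it is intended for
  desk-scale experiments, not full-scale training.
* The phantom's uniform background makes ROI statistics analytically
  checkable but is more benign than clinical backgrounds (liver, spleen,
  scatter gradients).
* BN running statistics make eval-mode outputs depend on the training
  trajectory; determinism is guaranteed only for fixed seeds on one
  platform/BLAS build.
* The AttnGAN is exercised at reduced spatial scale; its 256 × 256
  behaviour is verified for shapes, not for denoising quality.
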