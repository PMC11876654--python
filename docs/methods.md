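# Methods

`dermavec` implements a latent-direction editing pipeline for skin-lesion
imagery: a style-based generative model produces synthetic psoriasis plaque
images, labelled groups of generated images identify semantic directions in
the model's intermediate latent space, and applying fractions of those
directions simulates the progressive visual improvement of a plaque under
treatment. Because clinical photograph sets of psoriasis are
access-restricted, the package ships a procedural simulator whose
ground-truth generative factors stand in for patient data, and an analytic
"oracle" decoder that makes latent-direction recovery exactly testable.

## The plaque simulator

`simulate.render` draws a skin-toned background carrying an elliptical
plaque. The generative factors are:

| factor | range | default | meaning |
| --- | --- | --- | --- |
| severity | 0–4 | 2 | PASI-style component scale (0 none … 4 very severe) |
| area_fraction | (0, 1] | 0.3 | exact fraction of frame pixels covered |
| skin_tone | RGB 0–255 | (196, 158, 138) | background colour before illumination |
| hair_density | 0–1 | 0 | density of dark hair strokes |
| illumination | 0.5–1.5 | 1 | global brightness multiplier (+ mild gradient) |
| eccentricity | 0–1 | 0 | ellipse axis ratio sqrt(1−e²) |

Severity maps *linearly* to two visual signs: the redness contrast of the
plaque interior (+13 on red, −6 on green and blue per severity unit, scaled
by illumination) and the density of white "scale" speckles (up to 22% of
plaque pixels at severity 4). Linearity makes the ground-truth severity
axis a straight line in factor space — the regime in which a mean-difference
latent direction is exact.

One deliberate construction: texture noise, hair darkening and speckle
brightening shift all three channels *equally*, so the erythema index
(mean of R − (G+B)/2 over the plaque mask) responds only to the
severity-driven redness term. Severity monotonicity of the erythema index
is therefore exact by design rather than statistical.

The plaque boundary is an ellipse with low-order periodic radius roughening;
the semi-axes are binary-searched so that the in-frame pixel count matches
`area_fraction` even when the ellipse is clipped by the frame. Plaque area
is recovered from rendered images by Otsu thresholding of the redness map;
recovery is within ~1% for areas in [0.1, 0.8] at severities ≥ 1 (it cannot
work at severity ≈ 0, where the plaque is invisible by construction).

`sample_factors` draws severity ~ U[0,4] and area ~ Beta(2,2) scaled to
[0.05, 0.9], coupled through a Gaussian copula. The copula parameter uses
the uniform-marginal correction 2·sin(πρ/6), so the sample Pearson
correlation approaches the requested value (residual bias from the Beta
transform ≲ 0.01). The severity↔size correlation knob models the
training-data bias that makes a severity edit drag plaque size along with
it; its default, 0.3, is a package choice of a "slight" correlation — the
bias is observed qualitatively in real training sets, not quantified.

Simulated raters report the true severity plus Gaussian noise (sd 0.35
score units), rounded to the 0–4 integer scale, independently for the
erythema and scale components and per rater.

## Augmentation

A small photograph set expands to a training set by, in order: random
square crop (scale 0.7–1.0), rotation (±180°), optional horizontal/vertical
mirror flips, perspective warp (corner jitter up to 10% of the side),
per-channel RGB gain (0.7–1.3, clipped at 255, emulating lighting changes)
and bilinear resize to the output resolution (default 256). The default
target count is 25,000 from 375 sources, assigned round-robin so each
source contributes ⌊·⌋ or ⌈·⌉ draws. Every draw is a pure function of
(config, draw_seed). The crop/rotation/gain ranges are package defaults
chosen to plausibly span clinic lighting and viewpoint variation; "flips"
is the mirror reading of photographic inversion (both axes exposed as
flags).

## The compact style-based GAN

The generator splits into a *mapping* network (z → w: per-sample
normalisation, two 512→512 dense + leaky-ReLU layers) and a *synthesis*
network (w → image: a learned 4×4 constant, style-modulated 3×3
convolutions with 2× nearest-neighbour upsampling per block, and a linear
1×1 to-RGB head). The style s = affine(w) multiplies input channels before
each convolution; weight demodulation and the path-length regulariser are
omitted at this scale. The discriminator mirrors the synthesis network
with 3×3 convolutions and average-pool downsampling.

Training is non-saturating logistic adversarial training (Adam, lr 0.0025
for both networks, β₁ = 0, β₂ = 0.99, batch 64) with an R1 gradient penalty
(γ = 0.2048) on real batches every step. All networks are plain numpy
(float32) with hand-written backprop; the R1 term — a second-order
quantity — is computed by a finite-difference Hessian-vector product
(two extra discriminator passes), which is exact almost everywhere for
piecewise-linear networks.

Both real and generated discriminator inputs pass through the same
stochastic augmentation pipeline (mirror flips, 90° rotations, integer
wrap-around translations up to 4 px, per-channel gain 0.8–1.25), each
applied with probability p per image. Every 4 batches, p moves up by 0.05
if the fraction of positive real logits exceeds 0.6, down otherwise,
clamped to [0, 1] — the adaptive-augmentation controller in its simplest
form. The pipeline is linear in its input per draw, so generator gradients
pass back through it exactly (inverse permutation plus gain).

Sampling uses an exponential moving average of the generator weights
(per-step decay 0.5^(batch/2000)); the raw weights keep training. A
training log records per-step losses and p, plus a Fréchet feature
distance (below) between 256 generated and 256 real images at the first
and final step.

Desk-scale defaults are 32×32 resolution, channel_base 128 (8–32 channels
per stage), 10 kimg ≈ 156 batches — sized for single-CPU runs of well under
a minute while still moving the generated distribution visibly toward the
data. `TrainConfig.full_scale()` carries the reference full-scale settings
(256×256, channel_base 16384, 5000 kimg); nothing in the test surface runs
them beyond construction.

## Oracle decoder

The oracle generator mode replaces trained synthesis with an analytic map:
the mapping network is the identity, and the decoder reads
severity = clip((w₀+3)·4/6, 0, 4), area_fraction = 0.05 + 0.85·σ(w₁), with
w₂…w₇ driving tone, hair, illumination and eccentricity through bounded
smooth maps and w₈…w₁₃ hashed (after 0.1-quantisation) to the texture seed.
The ground-truth severity and size axes are therefore literally e₀ and e₁
of w-space, and `synthesize(map_z_to_w(z))` is bit-identical to rendering
the decoded factors. The coarse quantisation of the texture-seed hash
means a sufficiently large edit can flip the texture realisation; texture
is zero-mean and channel-balanced, so mask-averaged statistics barely move.

## Directions

A direction is the difference of per-group means of w vectors —
deliberately the plain estimator, with no covariance whitening or per-pair
differencing. Severity groups use a consensus rule: per image, the mean
over raters of the combined (erythema+scale)/2 score, rounded half-up;
"severe" is consensus 3–4, "moderate" exactly 2 (the aggregation is a
package decision; only the categories themselves are given). Coverage
groups threshold per-image area fraction at 0.5.

Sampling noise of the estimator: from an isotropic d-dimensional pool with
groups of n₁ and n₂, the orthogonal noise norm is ≈ sqrt((d−1)(1/n₁+1/n₂))
against a severity-axis signal of ~1.3–2.0 (truncated-normal group means).
At d = 512 with 55/54 images per group the expected cosine to the true
axis is ≈ 0.3; it passes 0.9 only for thousands of images per group, or
for small nuisance dimension. The estimator is consistent — the test suite
verifies both the small-dimension and the large-n recovery — but group
sizes in the hundred range identify the axis only coarsely at full
dimensionality. Usefully, the noise is orthogonal to the signal: the
severity component of the treatment vector is unbiased, which is why the
fractional-application experiments behave well even with noisy vectors.

Fractions are real-valued and unclamped: adding f·treatment reduces
severity by f times the group gap; negative f increases it. Composition is
linear. When the training distribution correlates severity with size, the
treatment vector acquires a size component; the compensation scale s for
the composite (treatment + s·size) is found by a coarse-then-fine 1-D grid
search minimising the mean absolute segmented-area change at fraction 1.0
over a set of example images (the compensation behaviour is shown
qualitatively in the source work; the scale rule is a package choice).

## Evaluation statistics

Four set-comparison statistics: pooled per-channel 256-bin RGB histograms;
the radially averaged power spectrum (grayscale via (0.299, 0.587, 0.114),
unitary-normalised 2-D DFT, integer-radius bins from the spectrum centre,
DC reported as bin 0, Nyquist-truncated for display but with full-spectrum
bins available so Parseval's identity closes); per-image mean HSV
saturation vs mean value; and a Fréchet distance
‖μ₁−μ₂‖² + Tr(Σ₁+Σ₂−2(Σ₁Σ₂)^{1/2}) between Gaussian fits of per-image
features. The default feature extractor is self-contained — per-channel
mean and standard deviation, mean saturation, mean luminance, and log
power in 8 geometric radial bands (16 dimensions) — so no pretrained
network or download is involved; an `extractor` argument accepts an
external deep-feature function for conventional FID. Covariances are
shrunk by εI (ε = 10⁻⁶·tr(Σ)/d) only when near-singular, so well-posed
closed-form cases are reproduced exactly. sqrtm's occasional small
imaginary residue is discarded and the result floored at 0.

Blinded-assessment scoring reports real-image accuracy, generated-image
accuracy and the fraction of generated images judged real (their
complement), both per rater and pooled over judgments — the pooled/per-rater
distinction is reported rather than resolved. Severity summaries give
per-group mean and standard error (sample sd over per-image consensus
scores / √n) for erythema and scale separately.

## Pipeline and reproducibility

`dermavec run` executes pool → directions → application strips → realism
report in oracle mode, hashing each stage's configuration and outputs into
a manifest; unchanged stages are skipped on rerun. The global seed fans out
to stages via `SeedSequence(global_seed, stage_index)`. Every stochastic
component in the package takes an explicit seed, and rendering, training
and augmentation are bit-reproducible for fixed inputs on a fixed platform.

## Problem sizes and limitations

Study-scale numbers used throughout: 375 source images augmented to
25,000; labelled pools of a few thousand generated images; 55-vs-54 and
153-vs-151 group analyses; GAN smoke runs of 5 seeds × 10 kimg at 32×32 on
1,000 simulator images, scored by whether the final Fréchet feature
distance drops below its value at initialisation.

The simulator is a caricature: one elliptical plaque per frame, linear
severity signs, channel-balanced nuisance structure, no subtype morphology
(plaque vs guttate vs flexural), no specular highlights or camera noise.
Passing tests therefore demonstrate the correctness of the pipeline's
machinery — direction identification, fractional editing, compensation,
statistics — not clinical realism of any generated image. The compact GAN
is sized for CPU smoke training; it makes no claim toward the image
fidelity of a full-scale run, and the self-contained Fréchet features are
not comparable to Inception-based FID values.
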