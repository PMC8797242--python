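# Methods

## Model

`statcell` implements a stacked conditional β-variational-autoencoder over
multi-channel fluorescent single-cell images. An observed image decomposes
into two *reference* channels `x_r` (plasma-membrane dye, DNA dye) that
define cell geometry, and one *target* channel `x_t` showing a tagged
subcellular structure whose class `t` is one of 24 labels (19 biological
structures plus 5 synthetic controls). The joint density is factorized as

    p(x_r, x_t | t) = p(x_r) · p(x_t | x_r, t)

and each factor is modelled by its own VAE: the **reference model** `M_R`
(unconditional, 2 input/output channels) and the **target model** `M_T`
(1 channel, conditioned at every layer on a resized copy of `x_r` and on
the one-hot label). The two sub-models are trained independently; no
gradient flows from `M_T` into `M_R`.

Modelling assumptions worth stating explicitly:

* structure channels are conditionally independent of one another given
  the reference — co-localization between two structures is *not* modelled;
* the diagonal-Gaussian posterior and standard-normal prior mean each
  latent dimension is an independent axis of variation;
* the Gaussian (MSE) likelihood weights every pixel equally, so bright
  artifacts are penalized in proportion to intensity, not biology.

## Architecture

Every layer is a residual block. Downsampling block (encoder):

    main:   conv k=4 s=2 (c_in -> c_in) -> BN -> ReLU ->
            conv k=3 s=1 (c_in -> c_out) -> BN -> ReLU
    bypass: conv k=1 (c_in -> c_out) -> 2x average pooling
    output: main + bypass

The upsampling block replaces the 4-kernel convolution with its transposed
counterpart and the pooling with separable linear interpolation (the
`align_corners=False` convention). In conditional blocks two projections
are added to the output: the reference image linearly resized to the
block's output size through a 1-kernel convolution + BN, and the one-hot
label through a 1-kernel convolution + BN broadcast to every pixel.
Spectral weight normalization (one power-iteration step per training
forward pass; u/v are non-trainable buffers) wraps every convolutional and
fully connected weight.

The encoder stacks five downsampling blocks (channels 32, 64, 128, 256,
512), flattens, and feeds two parallel fully connected heads for the
posterior mean and log-variance (the scale head exponentiates half the
log-variance, guaranteeing σ > 0). The decoder applies batch normalization
to the latent vector, expands it with one fully connected layer to the
512-channel bottleneck map, and stacks five upsampling blocks
(512→256→128→64→32→output channels); the final block upsamples like the
others, which exactly restores the input size after five halvings. A
`final_stride1` switch implements the alternative reading in which the
last block only reduces channels; it is off by default because only the
default reading reproduces both the spatial arithmetic and the published
parameter totals.

At full scale the bottleneck is 5×3 (2D) or 5×3×2 (3D), i.e. input sizes
160×96 and 160×96×64: five exact halvings of each axis. With 24 classes
and latent size 512 the trainable parameter totals are **122,627,829** for
the 3D pair `M_R + M_T` and **22,279,054** for the 2D reference model —
the published sizes; `statcell.paper_scale_parameter_counts()` rebuilds
and recounts them. These totals pin several otherwise-open details: biases
everywhere, batch-norm affine parameters after each body convolution and
each conditional projection, no 512→512 first decoder block, and the
1024-parameter latent batch norm per sub-model. The activation function is
not count-relevant; ReLU after each branch-sum was chosen, with no
nonlinearity on the posterior heads or the final output.

Desk-scale configurations are first-class: any channel progression,
latent size and input shape divisible by 2^(number of blocks) builds the
same way; the test suite exercises 2–4 block networks on 32×32 images.

## Objective

Per image,

    ELBO_β(x) = (1-β) · E_q[log p(x|z)] − β · KL(q(z|x) ‖ N(0, I)),  β ∈ [0, 1]

with the reconstruction likelihood approximated by negative pixel-wise
squared error and the KL in closed form per dimension,
`KL_d = ½(μ_d² + σ_d² − 1 − 2 ln σ_d)`. At β = 0.5 this is half the
standard ELBO; the weighting keeps the objective's magnitude roughly
constant across β so one optimizer configuration serves a whole sweep.

**Reconstruction scaling.** The error may be summed over pixels
(`reduction="sum"`, the default) or averaged (`"mean"`); the choice is
recorded in every checkpoint and run configuration. The sum is the default
because with the mean the summed KL dominates at small image sizes and
every model collapses to the prior immediately; the sum restores the
standard VAE balance in which one KL nat trades against one unit of summed
squared error.

**Estimator.** The reported ELBO is the unweighted bound
(recon − KL) with the reconstruction averaged over **ten** posterior
draws, seedable and deterministic. One ε draw per Monte-Carlo sample is
shared across the batch (common random numbers): each image's estimate is
unchanged in distribution, but estimates become independent of batch
composition — which makes paired comparisons such as the channel-swap
statistic exact in their no-op cases.

**Gradients.** Reparameterization (z = μ + σ·ε) for the reconstruction
path; the KL gradient is analytic in (μ, log σ²). At exactly β = 1 the
decoder receives no gradient by construction — the endpoint trains a pure
prior-matching encoder.

## Training

Adam (moments 0.9/0.999), fixed epoch count, no early stopping by default
(an optional `patience` flag exists but is off). Splits are
80/10/10 train/validation/test, stratified by structure label so every
label appears in every split even for small populations. After every epoch
the unweighted ELBO is evaluated on the validation split with a fixed
seed, and the best-validation checkpoint is restored at the end; gradient
steps use the β-weighted objective, selection the β-free bound, so
checkpoints are comparable across a sweep.

Full-scale defaults follow the published recipe (batch 32, learning rate
2e-4, 300 epochs). The desk-scale studies in the tests and examples use
batch 8 and learning rate 2e-3 for 30–150 epochs — at a few hundred
gradient steps the published learning rate has barely moved a 32×32 model,
and these sizes keep every study within a CPU-minutes budget (5-model
sweep ≈ 2 min; conditional coupling study ≈ 2.5 min; shift study ≈ 1 min).

The β-sweep harness trains one model per β on an identical split and
reports test-split rate (mean KL), distortion (mean negative
reconstruction), and the active-dimension count.

## Phantom generator

The generator emulates the statistical structure of the real corpus at
arbitrary scale: an ellipsoidal cell (membrane channel = interior fill
plus a brighter cortical rim) containing a strictly smaller ellipsoidal
nucleus (filled), plus a structure channel produced by a stated rule —
a shell hugging the nucleus boundary (`envelope`), a band just inside the
cell boundary (`cortex`), random cytoplasmic blobs
(`cytoplasmic_puncta`), and the five controls: blank, duplicated DNA,
duplicated membrane, Gaussian noise clipped to [0,1] on the union of the
dye supports, and a random swap of another cell's structure channel
(resolved at population level; swap cells carry a puncta channel before
the exchange).

Intensity profiles are smooth ramps/bumps of the implicit ellipse
coordinate `f(p) = Σ (p_i/a_i)²`, so with zero additive noise every
channel's support is *exactly* its analytic mask — the property the
generator's tests integrate against. (A Gaussian-blurred boundary was
considered and rejected: blur leaks intensity outside the analytic mask.)

Populations jitter geometry (±12% semi-axes, ±0.35 rad orientation,
±2 px center, ±3 px nucleus offset) and dye brightness (±15%,
independently per channel — labeling efficiency varies cell to cell);
a `mitosis_fraction` (default 10%, matching the rough interphase/mitosis
ratio of the real corpus) of cells get rounder, taller geometry as the
mitotic proxy. One master seed drives everything through a counter scheme
(`SeedSequence(master, spawn_key=(i,))`), so populations are reproducible
and stable under subsetting.

What the phantoms do **not** emulate: point-spread blur, depth
attenuation, spectral bleed-through, textured organelles, cell crowding,
or segmentation errors. Tests passing on phantoms therefore validate the
statistical machinery (objective, coupling logic, latent analytics), not
robustness to real microscopy artifacts.

## Preprocessing

Per channel: subtract the most populous intensity (exact value counts for
integer data; for float data the mean of the most populous of 256
histogram bins), zero negative values, rescale the maximum to 1. Then
rotate so the cell mask's second-moment major axis lies along x, center
the nucleus channel's center of mass (sub-pixel linear shift), flip any
axis whose cell-mask third central moment is negative, and zero-pad (or
center-crop, with a logged warning) to the target shape. 2D images are
maximum-intensity projections along z taken *after* normalization.
Rotation uses linear interpolation; masks are re-binarized at 0.5.

## Coupling statistic

For cell i with structure s and reference channel r ∈ {membrane, nucleus}:

    c_i^{rs} = ELBO(x_i) / mean_j ELBO(x_i with channel r ← cell j's r)

where j runs over the N_s other cells with the same structure label
(optionally a seeded subsample of at most K partners, with K recorded).
Swaps are performed on preprocessed, aligned images. ELBOs are negative,
so a swap that hurts the fit drives the printed ratio *below* 1; the
auxiliary `strength = 1 − c` is positive exactly when the swap hurts. The
per-structure, per-phase summary is

    d_s^p = mean_i (c_i^{ms} − c_i^{ns}) / (c_i^{ms} + c_i^{ns})  ∈ [−1, 1]

computed separately for interphase and mitotic cells; under the printed
convention d > 0 leans nucleus-ward (the duplicated-DNA control anchors
that side, the duplicated-membrane control the other), and exchanging the
two channels negates d exactly. Cells with a zero denominator are excluded
with a warning; undefined ratios propagate as missing values.

## Latent-space analytics

Embeddings are posterior means (no sampling) — deterministic given a
checkpoint. Dimension importance: mean absolute deviation from zero
(ties broken by index), and the mean per-dimension KL with an activity
threshold of 0.6 nats. Latent walks decode a single dimension swept across
±2 population standard deviations (computed on the test split) in nine
steps with all other dimensions at zero. Feature correlations are Spearman
by default, with constant columns reported as missing, not zero. The
feature-space regression z-scores the 14 morphology features, takes their
top five principal components, fits each PC from the active latent
dimensions by ordinary least squares on 90% of rows and reports held-out
R². Population shifts are centroid differences; per-cell scalar
projections onto the shift direction are centered on the control centroid.

## Morphology features

Per channel: segmentation by local arithmetic-mean thresholding (block
size 199, odd-only) on the image rescaled to 8-bit, keeping the largest
connected component; area (pixel count), circumference (4-direction
Crofton perimeter, which corrects staircase bias), circularity
4πA/P² (the 2D reading of sphericity, clipped to 1); median, mean,
standard deviation and Shannon entropy (bits, 256-bin histogram) inside
the mask. Empty masks yield zero features with a warning rather than an
error.

## Numerical choices

* float32 weights and activations; analytics in float64.
* Kaiming-normal initialization scaled by fan-in; zero biases.
* Batch-norm momentum 0.1, eps 1e-5; evaluation uses running statistics.
* Spectral norm: one power-iteration step per training forward; u, v held
  constant in the backward pass (the standard estimator).
* Stride-2 layers require even spatial sizes and raise otherwise; network
  input shapes must be divisible by 2^(number of blocks).
* Constant normalization input → all-zero output (not an error); NaN → error.
* KL values are clamped at zero against float rounding.

## Known limitations

* The desk-scale sample-diversity collapse near β = 1 is partial: the
  decoder's ability to ignore z trains at rate (1−β), so the suite asserts
  a strong monotone shrinkage (β = 0.95 vs β = 0.1) rather than visually
  identical samples.
* Alignment rotates only in-plane; 3D stacks are assumed axially upright.
* The numpy network core is tuned for correctness and small models; at
  full scale it builds and counts parameters quickly, but training the
  122M-parameter 3D stack is outside its intended envelope.
* Coupling ratios divide two negative numbers of modest magnitude; for
  structures whose ELBO is near zero (e.g. blank controls) the ratio is
  intrinsically noisier than its components.
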