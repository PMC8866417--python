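# Methods

This note documents the models, operators, estimators, and design choices
behind `ambientsom`, in the order data flows through the package.

## The problem

Task-based assessment of imaging systems requires a *stochastic object
model* (SOM): a generative model of the objects being imaged, independent of
any particular scanner, noise level, or reconstruction algorithm.  Real
training data, however, are measurements — noisy, possibly incomplete, and
already filtered through a reconstruction.  A GAN trained directly on
reconstructed images therefore learns the measurement process along with the
anatomy.  The ambient strategy implemented here inserts a known measurement
operator `H_n` and a reconstruction operator `O` between the generator and
the discriminator, so the generator is asked to produce *objects* whose
simulated reconstructions are indistinguishable from the real ones.  The
package implements that training strategy for a stylized Fourier (MRI-like)
imager, together with the synthetic object ensembles, noise estimators, and
task-based figures of merit needed to validate it quantitatively at desk
scale on a single CPU.

## Synthetic objects: the lumpy background

Objects are draws from the classic lumpy background process: `N ~
Poisson(Nbar)` isotropic Gaussian lumps with amplitude `a`, width `w`
(pixels), at uniformly random continuous positions on the torus, plus a
constant offset.  Defaults (`grid 32x32, Nbar = 60, a = 1, w = 1.8`) give
smooth, overlapping texture with roughly unit dynamic range — the scale of
texture a 32x32 crop of soft tissue presents, and large enough `Nbar` that
pixel statistics are near-Gaussian.  With periodic boundaries and no
normalization the process is strictly stationary with closed-form moments

    E[f] = Nbar * I1 / A + dc,        Cov(lag) = (Nbar / A) * (l * l)(lag),

where `I1` is the lump integral, `A = grid^2`, and `(l * l)` the circular
autocorrelation of the lump profile.  These closed forms are used as oracles
for the Monte Carlo tests and for the analytic Hotelling-observer
covariance.  The autocorrelation is evaluated on the pixel grid; for `w >=
1` pixel the difference from the continuous form (a Poisson-summation tail)
is below 1e-8 relative and far inside every test tolerance.  GAN training
uses the `per_image_minmax` normalization (each object mapped to [0, 1]),
mirroring how clinical slices are normalized before training; normalization
destroys exact stationarity, so all analytic-oracle tests use the
unnormalized process.

What the generator does *not* emulate: anatomy (organ boundaries, bilateral
symmetry), spatially varying texture, inter-slice correlation, scanner
artifacts.  Passing tests therefore demonstrate that the machinery — the
operators, the training dynamics, the estimators — behaves correctly on a
controlled stationary ensemble, not that any particular clinical ensemble is
learnable.

## The stylized imager

The forward model is `g = mask o DFT(f) + n` with i.i.d. zero-mean complex
Gaussian noise of per-component standard deviation `sigma` on each sampled
k-space entry.  Conventions, fixed everywhere:

* **DFT scaling**: forward transform unscaled, inverse carries `1/(H W)`.
  Pure k-space noise then reconstructs to image-domain noise of std
  `sigma / N` on an N x N grid — so `sigma = 4` and `16` on [0, 1]-scaled
  256 x 256 images correspond to 1.5625% and 6.25% image noise, and the
  background of a magnitude image is Rayleigh with scale `sigma / N`.
* **k-space layout**: stored with DC centered; masks are defined on
  centered phase-encode coordinates and shifts are internal.
* **Cartesian undersampling**: whole phase-encode lines (rows) are dropped;
  the readout direction stays fully sampled; the DC line is always kept.
  Lines are selected in conjugate-symmetric units (mirror pairs {k, -k}
  plus the self-mirrored DC and Nyquist lines).  For real-valued objects
  this makes the masked spectrum Hermitian, so zero-filling + inverse DFT +
  real part is the exact Moore-Penrose pseudoinverse on real image space
  and `H^dagger H` an orthogonal projector — the operator algebra
  (`H H^dagger H = H`, idempotence of the measurement-component projector)
  holds to float64 precision rather than approximately.  Two selection
  schemes are provided (`uniform_random`, default, and
  `center_band_random`, which always keeps the central ~8% of lines); the
  choice is recorded in the mask manifest.
* **Noise placement**: noise is added only to sampled entries — measurement
  noise exists only where data are acquired.

Reconstructions: `real_part` (zero-filled pseudoinverse, real component),
`magnitude` (complex modulus, the clinical MR convention), and the
training-only `corrected_magnitude`

    f_r = f + e,   e = |F^-1(F(ReLU(f)) + n)| - ReLU(f).

For nonnegative objects this equals the true magnitude reconstruction of a
noisy measurement (bitwise, given the same noise draw); where the object is
negative, the negativity survives into `f_r` and the discriminator can see
it, so adversarial training pushes generated objects nonnegative — the
mechanism that makes magnitude-domain training produce physical objects.
The correction is defined for fully sampled data only; composing it with an
undersampled mask is refused rather than guessed.

## Ambient adversarial training

The generator `G(z)`, `z ~ N(0, I)`, maps a latent vector to an object.
Training alternates single discriminator and generator steps on minibatches:

* real branch: stored measurements `g -> O(g)`;
* fake branch: `z -> G -> upsample to final resolution -> H_n` with a
  *fresh* noise realization per sample per step `-> O -> downsample to the
  current stage resolution -> D`.

Gradients flow through `O o H_n` into the generator (the operators are
differentiable: the DFT pair is linear, the magnitude correction
subdifferentiable).  Fresh per-step noise is essential: a reused realization
would let the discriminator key on the specific noise pattern.

The plain (baseline) GAN is the identical loop with an exact identity
channel, so "ambient with identity operators" and "plain" agree bitwise
step for step.  A Fourier channel with full mask and zero noise equals the
identity channel only to float rounding (~1e-15), because `ifft(fft(x))`
is not exact; the two are asserted equal to 1e-12 in the tests.

### Networks

No deep-learning framework is used: the package carries a small
reverse-mode autodiff engine (`autograd.py`) whose operations express their
vector-Jacobian products in terms of other traced operations, so gradient
penalties (which differentiate the discriminator's input gradient) get
exact second derivatives.  On top of it, the generator and discriminator
are deliberately compact *dense* multiresolution networks implementing the
two architectural ideas that matter for the method:

* **progressive growing**: one block per resolution in the chain
  4 -> 8 -> ... -> final; stages are trained in order, each new resolution
  faded in by blending with the upsampled previous-stage image (fade
  fraction 0.5 of the stage budget by default);
* **skip summation**: all resolutions active from the start, the output
  image being the sum of per-resolution images bilinearly upsampled to the
  final resolution, with a residual discriminator and no growing.

Three further design choices compensate for what dense layers lack relative
to the convolutional originals:

* **smoothed image heads** — each per-resolution image head is followed by
  1-2 separable [1, 2, 1]/4 filter passes (periodic).  Dense heads have no
  local-smoothness bias, and without the filter the deterministic output
  carries spurious pixel-scale roughness that contaminates noise-level
  comparisons.
* **noise injection at the rendered resolution** — a fresh standard-normal
  map scaled by a learned gain (initialized 0) is added to the output
  image.  A deterministic map of a 64-dimensional latent cannot represent
  pixelwise stochastic texture; the noise input gives the generator an
  explicit channel for it, which the baseline GAN needs in order to
  represent the measurement noise it is (correctly) learning.  The gain is
  a scalar per resolution and is injected only at the resolution being
  rendered, so it models noise at the scale the discriminator sees rather
  than acting as extra latent dimensions.  Because sample noise adds in
  quadrature, the gain's gradient vanishes at zero and Adam's normalized
  updates would otherwise random-walk it; a weak multiplicative decay
  (1e-2 per generator step) prefers the deterministic explanation unless
  the data actively demand stochastic texture.
* **high-pass discriminator input** — each discriminator head sees the
  image together with its fine-detail residual `x - blur(x)`.  This makes
  fine-scale amplitude statistics directly visible to a dense critic,
  giving the noise-gain dynamics a genuine two-sided restoring force.

Layers use the equalized-learning-rate parameterization; Adam runs with
`(beta1, beta2) = (0, 0.99)`, learning rate 2e-3.

### Loss

Both the non-saturating logistic loss with R1 penalty (`logistic_r1`) and
WGAN-GP are implemented.  The package default is `logistic_r1` (gamma = 1)
for both architectures: in the dense re-implementation the WGAN-GP critic
never drove the generated noise statistics to match the data even at three
times the training budget, while the R1-regularized logistic loss
calibrates well.  The training manifest records per-step losses and
(optionally) FID-versus-step so a stopping point can be selected after the
fact; the default stopping rule is simply a fixed images-seen budget per
stage (8,000-12,000 at desk scale).

### Seeds and reproducibility

Every stochastic component draws from a named stream (parameter init,
latents, measurement noise, data order, penalty interpolants) derived from
one training seed, so identical configurations reproduce identical loss
trajectories bitwise.  Sampling from a trained model is likewise a pure
function of its seed.

## Noise estimation

* **k-space noise from magnitude backgrounds**: background pixels pooled
  across images and patches, Rayleigh scale fitted with the closed-form MLE
  `sqrt(mean(x^2)/2)`, then rescaled by `N` (background magnitude ~
  Rayleigh(sigma/N)).  Pooling across images rather than fitting per image
  minimizes estimator variance; the pixel count is logged.  This estimator
  closes the loop for experimental-style data: the `magnitude_experimental`
  workflow calibrates its forward model's noise from the training images
  themselves.
* **blind image-domain noise**: median absolute deviation of the finest
  diagonal wavelet detail coefficients (db2, periodized) divided by 0.6745,
  averaged over images.  It is scale-equivariant, has bias < 0.005 on
  noiseless smooth lumpy content on the unit scale, and recovers additive
  white noise within a few percent.  Constant images return 0 with a
  degenerate-input flag.  Reported percentages are relative to the [0, 1]
  normalization range.

## Evaluation

* **FID**: squared Fréchet distance between Gaussians fitted to feature
  embeddings of two image sets.  The matrix square root uses an
  eigendecomposition of the symmetrized product with tiny negative
  eigenvalues clipped (tolerance 1e-8 relative); significantly negative
  spectra raise.  The default extractor is a deterministic pixel-pooling
  embedding (block-average to 8 x 8, flatten): 64 dimensions keeps the
  moment estimates full-rank at desk-scale sample counts and makes the
  metric download-free and exactly reproducible.  A pretrained-network
  extractor can be plugged in through the same interface.
* **Hotelling observer**: signal-known-exactly / background-known-
  statistically detection on an ROI around the signal.  `K` is decomposed
  as the empirical background-ROI covariance plus the exact task-noise
  diagonal (`sigma_t = 2%` of the unit range by default), guaranteeing
  positive definiteness; the figure of merit is reported as
  `SNR_HO = sqrt(s^T K^-1 s)` via a Cholesky solve (never an explicit
  inverse).  The quadratic form itself is also exposed, and every report
  names the convention, since the square root is occasionally omitted in
  the literature's notation.  Background ROIs come from signal-absent
  images only.  Desk-scale defaults use an 8 x 8 ROI (64-dimensional
  covariance, well-estimated from 20,000 backgrounds); the full-scale
  64 x 64 ROI is a parameter away but needs correspondingly more samples.

## Desk-scale study sizes

The synthetic studies run at 32 x 32 with 1,024-object training ensembles,
latent dimension 64, and 8,000-12,000 images per progressive stage; sample-based
metrics use 1,024-2,000 draws, and Monte Carlo oracles 10,000-20,000.
These sizes put a complete simulate-train-evaluate comparison within
minutes on one CPU core while leaving every qualitative phenomenon intact:
the ambient model's samples carry several times less noise than the plain
baseline's, the baseline's noise estimate tracks the true reconstruction
noise, and under 4x undersampling the measurement components of generated
objects match the true measurement components far better than the objects
themselves do.  The full-scale settings (256 x 256, 15,000 objects, latent
512) are reachable through the same configuration surface but are not
exercised by the test suite.

## Known limitations

* Dense generators cannot express translation equivariance, so sample
  fidelity saturates well above what convolutional models reach; FID
  against the clean ensemble plateaus around 1 (pixel-pool features)
  rather than approaching 0.
* The noise-gain decay embodies a mild Occam prior; a generator asked to
  model an ensemble whose *objects* genuinely contain white pixel-scale
  texture would need the decay reduced.
* Single-coil, Cartesian, 2-D Fourier imaging only; no coil maps, field
  inhomogeneity, or non-Fourier physics.
* The magnitude correction is defined for fully sampled data;
  undersampled magnitude-domain training is out of scope.
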