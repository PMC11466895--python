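# Methods

## Model

A cryo-EM density map is represented by `N_g` isotropic Gaussian
pseudo-atoms,

    f(x) = sum_j sum_i d_{j,i} a_j exp(-||x - c_i||^2 / s_j^2),

with centers `c_i` (Å), `N_c` width classes `s_j` (Å), per-class
amplitudes `a_j`, and per-Gaussian class weights `d_{.,i}` on the
simplex.  With the default single class every Gaussian shares one width
and amplitude; coarse-grained atomic models use one-hot classes so that
per-group amplitudes stay exactly proportional to summed atomic numbers.
The negative, squared exponent is the standard isotropic Gaussian; the
width parameter `s` enters as `exp(-r^2/s^2)` (no factor 2), a choice
that is exposed in configuration because several conventions circulate.

Each particle image `y_i` is modelled as the CTF-filtered projection of
a per-particle deformation of this consensus: the deformation field is
evaluated at the Gaussian centers only (locally-constant approximation),
so a particle is described by displaced centers `c_j + delta(z_i, c_j)`.
The mass of each Gaussian is fixed across the dataset: the model is
restricted to mass-conserving (conformational) heterogeneity by design
and cannot express compositional heterogeneity.

## Image formation

Projections are formed in Fourier space: deformed centers are rotated
and projected by the particle pose (ZYZ intrinsic Euler angles, shifts
in Å applied in the image plane), splatted with bilinear interpolation
onto a 2x-oversampled grid, FFT-ed, and multiplied by the analytic
transform of the projected Gaussian and by the CTF, then cropped to the
output band.  All FFTs are orthonormal, so Parseval holds without
constants and white noise of variance v has spectral power v per
coefficient.  Bilinear splatting is exact for points on the oversampled
sub-pixel grid and carries an O(1%) interpolation error off-grid at
oversample 2 (shrinking roughly quadratically with the oversampling
factor); the image-formation test suite checks a >0.99 normalized
cross-correlation against a real-space render -> rotate -> project ->
FFT oracle.

The CTF is the standard weak-phase model
`-(sqrt(1-A^2) sin(chi) + A cos(chi))` with defocus/astigmatism, Cs and
optional phase shift, no envelope; the value at DC is `-A`.

## Training

Two VAEs are trained independently, one per half set, for gold-standard
validation.  The encoder (three linear layers, ReLU) maps a flattened
image to `(mu, sigma)` in a 10-dimensional latent space; the decoder
(eight linear layers, ELU, additive residual) maps a positionally
encoded coordinate (ten sin/cos octaves plus the raw coordinates, 63
features) and the latent sample to a displacement.  The final decoder
layer is zero-initialized so training starts from the identity
deformation.

The data loss is the Sigma-weighted Fourier-space squared error, with
Sigma estimated as the radially averaged residual power on a particle
subset and floored at a small positive value.  Deformations are
regularized by a local-isometry penalty and a repulsion penalty on a
neighbor graph (all pairs closer than 1.5x the mean 2-nearest-neighbor
distance, rebuilt from the reference after every epoch; the repulsion
distance tau equals that mean).  The regularization weight lambda is
recomputed every epoch so that the regularizer's decoder-gradient norm
is `r = 0.9` of the data term's.  Two implementation choices matter
here:

* **Detached reference.**  The regularizers constrain the deformation
  field only: their gradients are blocked from the reference positions.
  When the reference is not detached, the balanced repulsion/isometry
  gradients push the consensus model away from the data fit and the
  data loss climbs steadily.
* **Probe-subset lambda.**  Gradient norms are measured on a fixed
  ~100-particle probe subset rather than a single batch; per-batch
  estimates make lambda oscillate by more than an order of magnitude
  between epochs, which suppresses the deformation amplitude.

Schedule: a warm-up phase optimizes only the Gaussian reference
parameters; afterwards encoder/decoder/reference are optimized jointly
(ADAM).  After every 30 network epochs the networks are frozen for 5
epochs; at every 10th unfrozen epoch the reference positions are
replaced by the predicted conformation with the smallest mean
displacement over the probe subset, keeping the reference inside the
distribution of predicted states.  The half-2 reference is periodically
re-synchronized to half 1 by averaging the 100 predicted conformations
with the highest Gaussian count inside a 6 Å mask around the half-1
positions, so the two references describe the same conformation and
share indices.  Training stops when the epoch-mean data loss has
increased a cumulative `k = 40` times (the accounting is cumulative,
not consecutive) or at the epoch budget.  The held-out validation
subset (default 10%) is embedded by the encoders each epoch but
contributes no decoder or reference gradients.

### Units and learning rates

Positions handed to the optimizer and the networks live in normalized
box units (the box maps to [-1, 1]); the stated ADAM learning rates are
therefore unitless.  The defaults follow the reference protocol
(reference and decoder 1e-4, encoder 1e-3), which is tuned for runs of
hundreds of thousands of ADAM steps.  `TrainingConfig.for_small_problem`
provides the package's desk-scale settings used by the test-fixture
studies (batch 8, warm-up 40 epochs, reference lr 2e-3 during warm-up /
2e-4 after, encoder 2e-3, decoder 5e-4, KL weight 1e-4): only step
sizes, batch size and warm-up length differ; all schedule constants are
unchanged.  The KL term is weighted so that a unit-Gaussian-scale KL
contributes roughly the configured fraction of the data loss; at high
noise a weaker KL (1e-4) lets the posterior scale sigma shrink below
the latent signal spread, which is necessary for the decoder to use the
latent code at all when each epoch provides few gradient steps.

## Improved reconstruction

The inverse deformation is a six-layer coordinate MLP with one additive
residual connection, trained for 200 epochs (ADAM) to regress the
consensus position from (latent mean, deformed position) pairs produced
by the trained decoder; smoothness comes from the bounded positional-
encoding bandwidth.

Reconstruction accumulates, per particle, the CTF-multiplied image
backprojected into the box in real space (smeared along the viewing
direction), optionally warped by a per-particle sampling field, and
divides the accumulated volume in Fourier space by the accumulated
squared CTFs gridded onto central slices, with a Wiener-style floor of
1e-3 times the denominator maximum.  Standard and deformed
backprojection share the same numerator code, so identity fields reduce
the deformed path to the homogeneous case exactly.

Warping uses trilinear pull-back: the warped volume is sampled at
`x + w(x)`.  Correcting a deformation requires `w(x) ~ D(z, x) - x`
(the forward displacement); it is obtained from the trained inverse
network by negating its displacement field, a first-order field
inversion that is exact for locally constant fields.  The field is
evaluated on a 2x-coarsened lattice (including the boundary) and
upsampled trilinearly, which is exact for affine fields.

## Error estimation

Validation particles are passed through both encoders; each decoder is
evaluated on its own consensus model (the two models share indices
after synchronization; if sizes differ the package falls back to
nearest-neighbor correspondence after centroid alignment and flags the
report).  The per-Gaussian norm of the difference between the two
displacement estimates is the reported deformation-error estimate.  The
construction is symmetric in the half sets and invariant to a common
rigid transform of both models.

## Synthetic data

The generator builds a two-domain Gaussian scene in which a mobile
domain rotates rigidly about a hinge axis by a per-particle angle; the
same Fourier code path as training forms the images (no train/test
mismatch), with uniform poses, small random shifts, per-particle
defocus, and white (optionally colored, `1/(1+(k/k0)^2)`) noise scaled
to a target SNR measured inside a circular mask of radius 0.45x the box.

Default study conditions: 60 Gaussians (40 static / 20 hinged), hinge
angles uniform in [-20°, 20°], 1,000 particles, box 48 at 3 Å/pixel,
defocus 0.8-2.5 µm, SNR 0.1.  The SNR follows the per-pixel
signal-to-noise scale typical of single-particle data; it was fixed
when the generator was written.  What the fixtures do not emulate:
solvent/ice background, beam-induced motion, pose errors from a real
consensus refinement, non-rigid intra-domain flexibility, and
compositional heterogeneity.  Passing tests therefore demonstrate that
the estimation and reconstruction machinery recovers known
mass-conserving deformations under realistic noise and CTF corruption,
not that it resolves the additional nuisances of real micrograph data.

Deformation-recovery error is computed by evaluating the trained
decoder as a field at the ground-truth Gaussian positions and removing
the best global rigid transform per particle (Kabsch), since
deformations are identifiable only up to the consensus gauge.

## Numerical choices and degenerate inputs

* Orthonormal FFTs everywhere; full-spectrum complex images with DC at
  index (0, 0).
* Noise spectrum floored at `max(1e-12, 1e-6 x max shell power)`.
* Out-of-bounds splat points are clipped to the grid edge and counted;
  forming an image from exclusively out-of-bounds points raises.
* Duplicate points in the neighbor graph are allowed (zero-length
  edges); `N_g = 2` degenerates to a single nearest neighbor.
* The graph edge threshold is strict (`< 1.5 c_mean`), with candidate
  pairs post-filtered to avoid boundary ties from the KD-tree query.
* Zero regularizer gradient keeps the previous lambda and logs a
  warning (the identity deformation is a stationary point of both
  regularizers).
* A NaN loss aborts training with the trainer state intact.

## Problem sizes used by the test suite and acceptance script

The study fixtures are sized for a single CPU: image-formation and
gradient checks run on 32-boxes with 8 Gaussians; backprojection
equivalence on 200 particles at box 48; end-to-end recovery on the
default 1,000-particle hinge scene with `for_small_problem` training
(40 warm-up + up to 120 epochs per half); the two-decoder error-estimation
study uses 20 seeds of a reduced scene (box 32, 40 Gaussians, 200
particles, short training) whose per-seed medians feed a one-sided
Wilcoxon signed-rank test.

## Known limitations

* The deformed-backprojection denominator uses the homogeneous
  (diagonal) filter; artifacts can appear at boundaries between domains
  moving in opposite directions.
* The encoder is a plain MLP on raw pixels; as in the reference
  protocol, most of its value is as a per-particle embedding rather
  than an image-feature extractor.
* The atomic-bond regularization route (fixed coarse-grained graph) is
  implemented but disabled by default: regularizing against an atomic
  model can imprint that model's features on the reconstruction (model
  bias), so only the smoothness prior is exposed on the main path.
* Half-set synchronization assumes the two references are roughly
  aligned; it corrects conformational, not orientational, divergence.
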