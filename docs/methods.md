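# Methods

## Problem and model

`paravae` estimates chronological age from paired grayscale tooth images
(a molar-like and a canine-like view of the same subject) and visualizes
*where* in the images the age signal lives. The pipeline has three parts.

**1. VAE feature extraction.** A convolutional variational autoencoder
maps an image x to a diagonal-Gaussian posterior q(z|x) = N(mu,
diag(sigma^2)) and reconstructs it from a latent draw z = mu + sigma * eps.
The single-VAE objective is

    L = gamma_KL * D_KL(q(z|x) || N(0,I)) + gamma_rec * L_rec(x, x_hat),

with default weights gamma_rec = 1 and gamma_KL = 1e-5. In the *parallel*
variant two VAEs are trained jointly on the paired images; each branch's
latent vector of length n = 2k is split into a unique half (first k
coordinates) and a common half (last k), and a coupling term

    L_separate = L_common / L_unique,
    L_common = (1/k) * sum_i (z_Ac_i - z_Bc_i)^2   (L_unique analogous),

drives the two common halves to agree while pushing the unique halves
apart. The joint objective weights the per-branch KL and reconstruction
terms with gamma_1..gamma_4 (five named presets `loss1`..`loss5` are
bundled) and L_separate with gamma_5.

**2. Linear age readout.** Age is fit by least squares on the posterior
means: y = beta . z + alpha. Parallel mode uses n + k features per subject
pair — both unique halves plus one copy of the common half (the
elementwise mean of the two branches' common halves; they are
near-identical after training, and the mean is symmetric in the branches).

**3. Coefficient traversal.** Because the readout is linear, beta is the
latent direction of fastest age change; decoding z + s*beta yields virtual
"older" (s > 0) / "younger" (s < 0) images, and the signed pixel
difference against the s = 0 reconstruction, rendered with a diverging
red/blue map, localizes the age-driven image regions. The identity
predict(z + s*beta) - predict(z) = s * ||beta||^2 holds exactly.

## Architecture and numerics

The encoder is five stride-2 4x4 convolutions with LeakyReLU(0.2)
(default widths 8, 16, 32, 32, 32), taking a 64x64 input to a 32 x 2 x 2
map read out by two linear heads (mu, log-variance); the decoder mirrors
it with transposed convolutions and a sigmoid output so pixels stay in
[0, 1]. The network stack is written directly in numpy (im2col
convolutions with analytically derived adjoints, Adam with bias
correction, float64 throughout); the layer gradients are verified against
central finite differences in the test suite, and the conv/transposed-conv
pair is verified to be an exact adjoint pair. Training is fully
deterministic given the seed.

Numerical choices:

- Reconstruction loss defaults to the per-pixel *mean* squared error
  (a fixed-variance Gaussian decoder likelihood up to an affine constant);
  a per-image summed reduction is available (`rec_reduction='sum'`). The
  KL term is summed over latent coordinates and averaged over the batch.
- L_separate's denominator carries eps = 1e-8 and the ratio is clamped at
  1e6 during training (with zero gradient when clamped), since both
  branches start near-identical latent statistics.
- The unique/common split convention is fixed: first k coordinates unique,
  last k common, everywhere (training, features, traversal).
- gamma_5 defaults to 1.0: L_separate is a dimensionless ratio of order
  one, so unit weight puts it on the scale of the reconstruction terms.
- Latent features for regression and traversal are the posterior means mu
  (deterministic); sampling is used only inside the training objective.
- Age regression defaults to minimum-norm least squares on centered
  features (well-defined when features outnumber samples); ridge
  (lambda configurable) is available and is the default of the
  *attribution* pipeline — with near-noise-free features an exact
  least-squares fit concentrates beta on tiny-variance latent directions
  that the decoder barely uses, which inflates ||beta|| and delocalizes
  the traversal, while a modest ridge penalty (lambda = 10) aligns beta
  with the dominant age direction.
- Traversal step: a raw +-beta step moves the predicted age by ||beta||^2
  years, which can be arbitrarily large depending on the latent scale;
  `step_years` rescales the step so one unit of s equals a chosen age
  change (the attribution analysis uses +-20 years, about the span the
  per-decade error tables resolve).
- Difference-map color scales are symmetric per map (+- max |value|); a
  shared scale across a series is used in the exported figures.

## Synthetic phantoms

Clinical panoramic radiographs cannot be redistributed, so the package
ships a seeded phantom generator. Each subject has an integer age drawn
uniformly from 10-79 (optional per-decade weights emulate skewed clinic
demographics), a side L/R (left images are mirrored at load time), and two
images: type A, a broad two-rooted silhouette, and type B, a narrow
single-rooted one. Both contain a bright central "pulp cavity" whose mean
intensity rises affinely with age (0.30 + 0.008/yr) and a dark "cervical"
band that falls affinely (0.78 - 0.008/yr) — identical laws in both images
(the common factor). Per-type position/scale jitter (sd 0.02 image units)
and additive pixel noise (sd 0.02) are the nuisance factors; ground-truth
masks of the cavity and band are exported. Age affects *only* the masked
intensities, never the geometry, so the correct attribution region is
unambiguous.

What the phantoms do not emulate: anatomical texture, occlusions and
neighboring-tooth overlap, eruption-stage changes in children, sex
effects, scanner variation. Passing the synthetic tests therefore shows
that the method recovers a known age signal and localizes it correctly
under controlled conditions — not that it attains clinical accuracy on
real radiographs.

## Study configurations

All defaults were fixed when the studies were designed:

- **Disentanglement / age recovery:** 500 training + 100 held-out subject
  pairs, 64x64 phantoms (default noise), n = 32, k = 16, preset `loss2`,
  20 epochs, batch 32, Adam lr 1e-3. Measured: the ratio of mean common
  to mean unique latent disagreement on held-out pairs (also against a
  gamma_5 = 0 ablation at the same seed), and the held-out median/mean
  absolute age error. The no-skill floor for uniform ages on [10, 79] is
  ~17.25 years (median distance to the median age).
- **Attribution:** same sizes on the noise-free phantom config, preset
  `loss1` (symmetric reconstruction weights) for 80 epochs — the
  attribution readout needs a well-converged decoder — with the ridge
  (lambda = 10) readout and +-20-year steps; localization is summarized on
  branch A over 8 held-out subjects as the fraction of absolute
  difference-map mass inside the ground-truth age-region mask, together
  with the mean signed difference inside the cavity and cervical masks.

The 64x64 resolution and channel widths keep each training run to a few
minutes on one CPU; the architecture scales to 256x256 via the config.

## Known limitations

- The numpy stack trains small models well but is not suited to
  256x256-scale runs at realistic dataset sizes.
- The linear readout can extrapolate outside the plausible age range for
  far-off-manifold latents; predictions are deliberately not clipped.
- With min-norm least squares on nearly noise-free features the
  coefficient traversal is not a reliable attribution tool (see above);
  the ridge readout should be used for visualization.
- Unpaired images are dropped in parallel mode rather than used
  semi-supervised.
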