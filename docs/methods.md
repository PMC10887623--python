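# Methods

This note records the models, numerical choices, and open design decisions
behind `polarct`, and what the desk-scale experiments do and do not show.

## Fan-beam simulation (`polarct.ctsim`)

Geometry: equidistant-detector fan beam, 720 views over 2π by default.
All detector arithmetic is done on the virtual detector through the
isocenter.  Defaults for a square image of side `S` (pixel size 1):
source-to-isocenter distance `2√2·S` (a mild fan), isocenter-to-detector
equal to it, `⌈1.5·S⌉` channels whose span covers a field-of-view (FOV)
disk of radius `S/2`.  A phantom body kept inside a 5% border margin is
covered with headroom.

Forward projection integrates along each source-channel ray with bilinear
sampling at 0.5 px steps (a numba kernel; the analytic disk chord is
reproduced to <1%).  Truncation deletes — not zeroes — the lateral
channels, keeping the central `round((1−ratio)·n_det)` (the stated 30%
is read as the *total* fraction removed, split evenly over both sides).
FBP uses cosine pre-weighting, the band-limited spatial Ram-Lak kernel
(with the ½ full-scan normalization), and distance-weighted pixel-driven
backprojection onto a grid that exactly covers the *retained* FOV disk, so
truncated reconstructions zoom to the interior region.  The paired
reference is the phantom resampled onto that same grid.

## Phantoms (`polarct.phantoms`)

One outer body ellipse (attenuation 1.0) with interior ellipses of uniform
random contrast, optionally smoothed with σ = 0.5 px; piecewise-constant
anatomy matches the assumption under which the TV baseline is meaningful.
The body semi-axes default to 0.90/0.84 of the half-side: truncation
scanning is interior scanning, so the object must extend well beyond the
retained FOV (at 30% truncation the retained FOV radius is ≈ 0.70 of the
half-side).  Train split: disjoint phantom seeds for the two domains
(genuinely unpaired).  Test split: pixel-aligned (artifact, reference)
pairs used only for scoring.  Every image is a pure function of the seeds
recorded in the JSON manifest.

What the phantoms do **not** emulate: anatomical texture, noise, scatter,
beam hardening, polychromatic physics.  Passing the toy study shows the
method removes the geometry-induced cupping bias on simple objects; it
does not certify performance on clinical data.

## Polar transform (`polarct.polar`)

Rows are angles uniform on `[0, 2π)`, columns radii up to the inscribed
circle (corners carry no signal in FOV-limited CT).  Bilinear interpolation
both ways; the inverse pads one wrapped row so interpolation across the
2π seam is exact.  Defaults: 360 angles, `S/2` radii (the desk-scale
study uses 64×32 for 64² images).

## Network (`polarct.model`, `polarct.nn`)

Encoder: five conv layers, exactly three stride-2 (k = 4, pad 1; k = 3 for
the unit-stride layers), channels `c·(1,2,4,4,4)`, instance norm, plain
ReLU.  Decoders mirror it (three transposed-conv upsamplings, LeakyReLU
0.2, tanh output); content and full decoders share no weights.
Discriminators: 70×70-receptive-field PatchGANs (four stride-2 convs plus
an output conv).  On polar images, convolutions pad **circularly along the
angle axis** and reflectively along the radius — the angle is
topologically a circle, and the encoder is seam-free under row rolls.  In
Cartesian mode both axes reflect.  Weights are drawn from N(0, 0.02²),
seeded.  Latent "content" and "artifact" subspaces are *not*
dimension-partitioned: disentanglement is enforced purely by the losses.

The engine underneath is a small reverse-mode autograd on float32 numpy
arrays (`polarct.nn.autograd`): broadcast arithmetic, reductions, im2col
convolution and its transpose, mixed-mode padding, and Adam with the GAN
moments (0.5, 0.999).  All gradients are finite-difference tested.

## Losses (`polarct.losses`)

Least-squares adversarial terms by default (real → 1, fake → 0); the
printed logistic form of the source objectives is ambiguous, and LSGAN is
the de-facto stabilizer for cycle-consistent translation, so the logistic
(`bce`) form is an option, not the default.  All L1 terms are means over
batch and pixels, making the λ weights resolution-independent.  The
horizontal TV term is the mean squared forward difference along the radial
axis of the artifact residual (the integrand is a squared derivative, so
squared — not absolute — differences).  With one unit of each loss
(adversarial parts summing to one) the default weights give a total of 121.

## Training (`polarct.train`)

Alternating Adam updates: one generator step (shared encoder + both
decoders), then a discriminator step.  Two stabilizers depart from the
plain 1:1 recipe, both standard GAN practice adopted after the desk-scale
runs showed discriminator dominance (discriminator loss → 0.05 while the
generator's adversarial terms saturated): the discriminator objective is
halved (`disc_loss_scale = 0.5`, the CycleGAN convention), and
`disc_every` allows updating discriminators every k-th iteration.
Images are normalized to [−1, 1] by a linear map of the 0.5–99.5
percentile window of the training pixels; the window is stored in the
checkpoint (a single zip of weights + full config + seeds).  The
checkpoint carries Polyak-averaged generator weights (EMA decay 0.998):
held-out quality oscillates with the adversarial game over the final
iterations, and the running average is a steadier iterate than the last
one.

**Inference applies the correction as a residual.**  The network's polar
output estimates the artifact as `input − cleaned` in polar space; that
smooth field is inverse-transformed and subtracted from the original
Cartesian image.  Resampling the *cleaned image* itself through the polar
round trip blurs fine content enough to dominate the error budget (at 64²
with 64 angles, the round-tripped input scores below the raw input);
resampling the *artifact*, which is smooth by construction, does not.
Before subtraction the artifact estimate is low-pass filtered along the
angular axis (Gaussian, σ = n_phi/16 rows, wrap-around): cupping is
quasi-circular, so the true artifact varies slowly with angle, and the
angular high frequencies in the estimate are network noise — filtering
them returns that detail to the corrected image (at desk scale this is
worth roughly +0.08 median SSIM).  Pixels outside the inscribed circle
pass through unchanged.

Ablations `Var1`–`Var6` cumulatively enable: adversarial only → +
reconstruction → + artifact consistency → + cycle → + polar transform →
+ TV (the full model).  `Var1`–`Var4` train on Cartesian images.

## Desk-scale study (`polarct.experiments`)

Conditions (fixed; only the seed varies): 64² phantoms, 30% truncation,
720 views, 200 unpaired training images per domain, 24 held-out pairs,
polar grid 64×32, base width 16, batch 2, 2000 iterations, LSGAN,
discriminator every 2nd iteration, learning rate 2·10⁻⁴.  The full-scale
configuration keeps the published operating point (lr 10⁻⁴, 1:1
updates, base width 64, 360 angles); the desk-scale solver settings are
the stable operating point for a network ~16× smaller trained ~100×
shorter, chosen from the loss curves of the scaled runs.  Problem sizes
were picked so the whole study runs in minutes on one CPU.

## Classical baselines (`polarct.baselines`)

*Extrapolation*: each view's truncated sides are completed by mirroring
the retained profile about the boundary with a raised-cosine⁴ taper to
zero over the full missing width (continuous at the boundary by
construction; the sharper-than-cosine decay compensates the mirror's
overestimate of the object's outer falloff), followed by standard FBP
cropped to the retained FOV.

*TV*: SART + total variation.  The unknowns live on an extended grid
covering the scanner's nominal FOV — retained rays integrate through the
whole object, so solving only the retained-FOV disk forces exterior mass
inside it — with a circular support mask and nonnegativity.  SART updates
are coverage-normalized (pixels seen by few retained rays take larger
steps); each outer iteration runs 20 isotropic-TV descent steps whose step
size adapts to the mean magnitude of that iteration's SART update
(`tv_weight = 0.3` of it), the usual fidelity-coupled schedule.  200 outer
iterations by default, zero initialization, divergence guard at 10× the
best residual.

## Metrics (`polarct.metrics`)

PSNR is peak-referenced (`20·log10(√(MN)·max|f_gt| / ‖f_gt − f_p‖₂)`,
algebraically MAX/√MSE).  SSIM defaults to the global-statistics form with
`k₁ = k₂ = 0.03` and `L = max(f_gt)` — note the common library convention
is `k₁ = 0.01`, available via argument, and a windowed (11×11 Gaussian,
σ = 1.5) mode backed by scikit-image serves as a cross-check.  Metrics are
computed on physical-value images restricted to the inscribed FOV circle.
The radial bias profile (mean residual per concentric annulus) is the
quantitative handle on cupping.

## Known limitations

* Ellipse phantoms only; no noise model beyond optional sinogram Gaussian.
* The toy study's SSIM gain is seed-stochastic; medians over ≥ 20 held-out
  images are compared, not individual images.
* The TV baseline is a representative implementation, not a reproduction
  of any specific published solver; its absolute scores depend on its
  solver parameters.
* 2D fan-beam only; no cone-beam reconstruction.
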