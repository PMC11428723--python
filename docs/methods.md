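# Methods

## Problem

Registering a preoperative brain MRI to a post-resection follow-up scan is a
deformable registration problem with a twist: some tissue simply has no
counterpart in the other image.  The resected tumor exists only in the
preoperative scan; the fluid-filled cavity exists only in the follow-up.  A
conventional similarity-driven registration will try to explain those voxels
anyway and drag the surrounding anatomy into implausible configurations.
`stepreg` implements an unsupervised, bidirectional, coarse-to-fine
convolutional registration framework that (a) estimates dense displacement
fields in both directions, (b) detects non-correspondence regions from the
forward-backward consistency of those fields and removes them from the image
similarity term, and (c) focuses each refinement level on large-deformation
and pathological areas through a corrected attention map.

## Model

### Displacement fields and warping

A displacement field `u` lives on the fixed image's voxel grid and maps the
fixed coordinate `x` to the moving coordinate `x + u(x)` (0-based continuous
voxel indices, axis order equal to the array axes).  Warping samples the
moving image at `x + u(x)` by trilinear interpolation with clamp-to-edge
borders; clamping avoids pulling background values into the brain.
Displacements are stored in voxel units of the field's own grid.  When a
field is transferred to a finer grid, each component is trilinearly resampled
and multiplied by the axis shape ratio so it remains in target-grid voxel
units.

Two fields combine as `c(x) = inner(x) + outer(x + inner(x))`: warping by
`c` equals warping by `outer` and then refining by `inner`.  This is the
update rule of the cascade.

### Stepwise cascade

Both images are min-max normalized to [0, 1] at pipeline entry and reduced
to a three-level pyramid (downsampling factors 4, 2, 1; trilinear, optional
Gaussian pre-smoothing).  Each level has its own convolutional displacement
estimator.  The coarsest network sees the concatenated fixed/moving images
and uses the largest kernels (default 7) to capture bulk deformation; kernel
size then shrinks (5, then 3) as refinement becomes local.  At each finer
level the upper level's field is upsampled, the moving image is warped by
it, an attention map is computed (below), and the network predicts a
residual field from (fixed, warped, attention); the residual is composed
with the upsampled field.

Each level network is a small encoder-decoder with skip connections and
leaky-ReLU activations.  The final convolution is zero-initialized, so a
fresh network implements the identity transform exactly — the cascade
degrades gracefully to "no deformation" rather than to noise.  On grids
large enough to pool, the decoder stops at half resolution and the
three-channel flow head runs there, after which the field is trilinearly
upsampled (with displacement scaling) to the level grid.  The smoothness
penalty makes the field spatially smooth by construction, so a
half-resolution head loses little accuracy while the most expensive
convolutions run on one eighth of the voxels.

### Corrected attention

The attention map for a level is derived from the upper level's upsampled
field by a two-layer convolution block squashed through a sigmoid, then
combined with the preoperative pathology mask `M_p` by elementwise maximum:
`A = max(block(u_up), M_p)`.  The union rule guarantees `A = 1` wherever
`M_p = 1` — pathological tissue always receives full attention — while the
rest of the map stays learnable.  A clamped-addition combiner
(`min(block + M_p, 1)`) is available behind a config switch.  The attention
map enters the level network as an extra input channel.  The coarsest level
has no upper field and hence no attention input.  The pathology mask is an
*input* to the framework (in clinical use it comes from a tumor
segmentation tool); this package never computes it from images.

### Non-correspondence masking

For the forward field `u_fwd` (preop fixed) and backward field `u_bwd`
(follow-up fixed), the inverse-consistency residual is

    delta(x) = || u_fwd(x) + u_bwd(x + u_fwd(x)) ||_2   (voxels),

with `u_bwd` sampled trilinearly.  Where anatomy corresponds, the round trip
nearly cancels; where it does not, the two unsupervised fields disagree
freely and `delta` is large.  The threshold is `tau = mean(delta) + Const`,
computed per direction (each direction has its own moving image), and the
mask is the strict exceedance `delta > tau`.

`Const` is configured as 0.015 in **normalized grid units** — fractions of
the mean grid half-extent — and converted internally to voxels
(`0.015 * mean(L, W, D) / 2`, about 0.3 voxels on a 48-voxel grid and 1.2
voxels at 160).  The constant originates from work that represents sampling
grids in a normalized [-1, 1] coordinate convention; read in raw voxel
units it would be negligible against `mean(delta)`, and the mask would
degenerate to "everything above the mean", flagging nearly half the volume.
We verified this empirically: voxel-units `Const` yields background
false-positive rates near 45 %, the normalized reading near 15 % with
unchanged cavity recall.  A `const_units: voxel` switch preserves the
literal reading.

During training the masks are recomputed from the current bidirectional
fields at every optimization step and treated as constants (no gradient
flows through mask construction, which would otherwise reward mask
inflation).  Morphological cleanup of the mask (closing then opening) is
available but off by default.

## Loss

    L = L_sim(I_f, I_w, Mask) + lambda * L_reg(u),  lambda = 0.1

`L_sim` is minus the masked mean of windowed squared normalized
cross-correlation: for each voxel, `cc = cross^2 / (var_f * var_w + eps)` is
computed over a cubic window (default 9^3, `eps = 1e-5`), windows truncated
at the image border with true in-bounds counts so affine-intensity
invariance holds up to the edges.  The masked mean divides by the count of
unmasked voxels, keeping the loss scale independent of mask size.  An
all-ones mask leaves nothing to score and returns 0 with a warning.

`L_reg` is the mean squared forward-difference gradient of the field over
the common interior, applied to the finest-level field of each direction
and *not* masked (smoothness is desirable everywhere, including
non-correspondence regions).  Mean normalization (rather than a raw sum
over voxels) keeps `lambda` transferable across grid sizes.  The two
directional losses are weighted equally.  Per-level deep supervision exists
behind a flag and is off by default.

## Training

Adam, learning rate 1e-4, batch size 1, 1000 epochs, lambda 0.1 — the
published schedule — are the package defaults ("paper" profile, 160x160x80
grids, feature widths 16/32/32).  The "desk" profile is the CPU-feasible
surrogate used by the test suite and the acceptance script: 48x48x24 grids,
8 training pairs, 50 epochs, per-level feature widths (16,32)/(12,24)/(8,16)
(the coarse levels are nearly free, so they get more features), and a
half-cosine learning-rate decay from a peak of 4e-3.  The raised, decaying
learning rate compensates for the 20x shorter schedule.  Training pyramids
are built with Gaussian anti-alias pre-smoothing (plain decimation at factor
4 aliases the texture away and starves the coarse level), and each pyramid
level is standardized to zero mean / unit variance before entering the
networks — NCC is affine-invariant, so the loss is unchanged; only the
conditioning of the convolutions improves.  The two directions share network
weights by default: with shared weights every optimization step supplies
each network two gradient samples (one per direction), which measurably
improves held-out accuracy at small cohort sizes; a `share_weights: false`
switch restores fully independent directions.  Decoupled weight decay and
Polyak (EMA) weight averaging are available in `TrainConfig` and off by
default — neither improved held-out accuracy at desk scale.

One model is trained across all provided pairs (cohort mode).  The CLI's
`--per-pair` flag trains a separate model per pair (instance optimization),
which is the same loop with a one-pair cohort.

Everything is deterministic for a fixed seed on a fixed device: parameter
initialization, data order, and every update derive from the configs alone.

## Synthetic gold standards

Real longitudinal glioma MRI provides no ground-truth deformation field and
no non-correspondence labels, so quantitative evaluation of exactly the
outputs this method adds is impossible on real data.  The generator builds
fully annotated surrogates:

* **Phantom** — ellipsoidal "brain" support (smooth sigmoid edge) filled
  with Gaussian-smoothed random intensity blobs over a low-frequency
  background, intensities in [0, 1].  Default 40 blobs on a 48x48x24 grid.
* **Deformation** — per-component Gaussian-filtered white noise (sigma 6
  voxels), tapered to zero near the borders *before* filtering, scaled to a
  peak magnitude of 3 voxels.  A guard rejects amplitude/sigma ratios above
  0.6 and the Jacobian is checked explicitly: the generator re-draws from
  its own deterministic stream (at most 20 times) until the field is
  fold-free, so every delivered field has folding fraction 0.  The inverse
  is computed by fixed-point iteration (at most 50 iterations, tolerance
  1e-3 voxels).
* **Pathology and cavity** — a spherical "tumor" texture (radius 2x cavity
  radius, default cavity radius 4) is added to the preoperative phantom;
  the follow-up image is the phantom warped by the inverse field with the
  mapped inner sphere replaced by a CSF-like constant (0.04) plus noise.
  The cavity is therefore genuine non-correspondence present in one image
  only, and the pathology mask is a strict superset of it, encoding the
  clinical containment assumption the corrected attention relies on.
* **Landmarks** — 10 pairs (mirroring the ~10 expert landmarks per patient
  in the public benchmark this emulates) at high-gradient voxels outside
  the dilated cavity, with the follow-up landmark obtained by mapping the
  preoperative one through the true field.  Landmark error of the true
  field is zero up to interpolation (< 0.1 voxels).
* **Noise** — additive Gaussian, sd 0.005 in normalized intensity units on
  both images.

What the phantoms do **not** emulate: MR physics (bias fields, modality
contrast), mass effect and tissue relaxation around the cavity, topology
change, anatomy-specific texture statistics.  Passing the synthetic
evaluations therefore demonstrates the machinery is correct and the method
behaves as designed under known ground truth — not clinical-grade accuracy
on real BraTS-Reg pairs, which requires full-scale training on real data.

## Evaluation

Target registration error maps each fixed-image landmark through the
estimated field (sampled at the landmark; no field inversion) and takes the
Euclidean distance to the matched moving-image landmark — reported in mm
when a spacing is supplied, voxels otherwise, with the unit recorded.
Non-correspondence masks are scored against the true cavity by Dice,
precision and recall (Dice of two empty masks is 1 by convention).  Field
plausibility is summarized by the fraction of interior voxels with
non-positive Jacobian determinant of `x + u(x)` (central differences).

## Numerical choices

* float32 parameters and activations in the networks; float64 in the
  reference NumPy operators and everywhere exactness is asserted.
* Trilinear interpolation throughout; nearest-neighbour only for resampling
  binary masks across pyramid levels.
* NCC stabilized by `eps = 1e-5` in the denominator; windows truncated at
  borders with true counts.
* Strict inequality at the mask threshold (`delta == tau` is not masked).
* Zero-initialized flow heads; He-normal initialization elsewhere, seeded.
* All gradients are hand-derived adjoints verified against central finite
  differences in the test suite (relative error < 1e-5 on probe points).

## Problem sizes

The test suite and acceptance script run the desk profile: 48x48x24 voxel
grids, 3 pyramid levels (12x12x6 / 24x24x12 / 48x48x24), 10 synthetic cases
(8 train / 2 held out), 50 epochs.  One training step (both directions,
forward and backward passes, mask recomputation, Adam update) takes under a
second on one CPU core; the full desk experiment runs in a few minutes.

## Known limitations

* The desk-scale cohort (8 pairs, 50 epochs) is a deliberately small
  surrogate; accuracy there underestimates what the paper-scale schedule
  reaches on real data, and a cohort this small generalizes imperfectly to
  held-out pairs.
* The half-resolution flow head bounds the spatial detail of each level's
  residual; for the smooth synthetic deformations this is negligible.
* The inverse-consistency mask conflates genuine non-correspondence with
  plain misregistration early in training; it sharpens as the fields
  converge.
* No affine pre-alignment, skull-stripping or bias correction: inputs are
  assumed pre-processed, as in the public benchmark this targets.
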