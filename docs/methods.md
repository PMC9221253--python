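# Methods

This note documents the models implemented in `lnnb-flowscore`, the
parameters that matter, the synthetic fixtures the tests run on, and the
design choices made where the problem was genuinely open.

## Video normalization

Recordings of different devices and durations are mapped onto a common
grid before any motion analysis: bilinear spatial resampling (anti-aliased
when downsampling), linear temporal interpolation at instants uniformly
spanning the original duration, and a robust intensity rescale (clip at
the 1st/99th percentile of the whole clip, then min–max to [0, 1]).
Defaults are 240×320 px, 300 frames, 10 s (30 fps): the tasks last 10 s by
protocol, and the spatial/temporal targets are configurable because no
single recording standard is assumed. The percentile clip makes the
rescale insensitive to specular highlights; an exactly constant clip is
passed through unchanged. The focal length (pixel units) is scaled by the
width ratio during resampling so angular conversions are preserved; when
no calibration is available it defaults to the image width, i.e. roughly
a 53° horizontal field of view. Subject distance is carried as metadata
only — it never enters a computation.

"Resolution" here means the H×W×T intensity grid; no volumetric data is
involved.

## Phase-based optic flow

Each frame is filtered with complex Gabor kernels (even/odd quadrature
pairs) at `n_orientations = 8` evenly spaced angles in [0, π), spatial
wavelength `wavelength_px = 8`, envelope `sigma_px = 4`, with the residual
DC of the even kernel removed so blank regions respond with (numerically)
zero amplitude. Filtering is circular by default (`boundary='wrap'`),
which matches the periodically warped synthetic fixtures; oracle
comparisons on those fixtures additionally exclude a border of one filter
half-width (13 px), where wrap-around content breaks the motion model.

Phase is never unwrapped globally. The temporal derivative φ_t at a pixel
is the least-squares slope of the unwrapped phase over a centred
`temporal_window = 5` frames, where unwrapping accumulates pairwise
wrapped differences; the spatial gradient averages the forward/backward
one-pixel wrapped differences. The component (normal) velocity of a
channel is v_n = −φ_t/‖∇φ‖ along the per-pixel gradient direction — the
exact phase-constancy constraint ∇φ·v + φ_t = 0 — rather than along the
nominal filter orientation, which is only the tuned approximation.

A channel is *reliable* at a pixel when all of the following hold:

| test | default | purpose |
|---|---|---|
| amplitude ≥ 5% of the frame's max (per channel) | `amplitude_frac = 0.05` | signal present |
| temporal-fit RMS residual ≤ 0.5 rad | `residual_max_rad = 0.5` | phase evolves linearly (velocity constancy) |
| slope ≥ 4 standard errors | `slope_tsig = 4.0` | the drift is distinguishable from noise |
| ‖∇φ‖ ≥ 0.05 rad/px | `grad_min_rad_px = 0.05` | gradient usable as a constraint direction |
| implied speed ≤ 10 px/frame | `v_max_px = 10` | reject wrap/aliasing blow-ups |

The slope-significance test deserves a comment. With a 5-frame window the
slope/SE statistic has only 3 residual degrees of freedom, so its null
distribution is heavy-tailed (t₃); at 4 SE a noise-only channel passes
rarely, while genuine motion — whose phase drift is orders of magnitude
above the fit noise — always does. An exactly static, noise-free channel
(slope 0, residual 0) passes by construction.

The full velocity solves the weighted over-determined system
min_v Σ_k w_k (n̂_k·v − v_{n,k})², weights w_k = channel amplitude. Pixels
with fewer than 2 reliable channels, or a 2×2 normal matrix with
condition number above 10³ (the aperture problem), are invalid; valid
speeds are clipped to `v_max_px`.

Finally a spatial-coherence pass, in the spirit of outlier rejection in
particle-image velocimetry, requires each valid pixel to have at least 4
valid 3×3 neighbours and to deviate from their median velocity by at most
max(0.25 px/frame, 0.5·‖median‖). Genuine motion is locally smooth;
isolated noise vectors that survive the per-channel tests are not. The
combination of slope significance and coherence is what keeps the score
of a static-but-noisy video near zero (measured < 2% of a 1 Hz clench
score) without biasing the estimates on moving content.

A single spatial scale is used: at wavelength 8 the phase model is
trustworthy to roughly λ/4 = 2 px/frame, which covers the hand-task
regime at the default geometry. Measured accuracy on translating
band-limited textures at 0.25–2 px/frame is a mean endpoint error of
about 0.03 px/frame with ~96% of pixels valid.

## Camera ego-rotation model and stabilization

Hand-held recording superimposes a rotational camera component on the
flow. For rotation ω = (ω_x, ω_y, ω_z) (rad/frame) and focal length f
(px), the induced image velocity at principal-point-centred coordinates
(x rightward, y downward) is linear: v(x) = B(x)ω. Two dialects of B are
implemented and selectable via `bmatrix_dialect`:

- `printed` (default): rows `[xy/f, (−f−x²)/f, y]`, `[(f+y²)/f, −xy/f, −x]`.
- `classical`: the standard rotational-flow Jacobian with `f²` in the two
  pure-tilt entries; the dialects coincide at f = 1.

The printed form is the package default; note that under it the tilt
components (ω_x, ω_y) produce an O(ω) response at the image centre rather
than the classical O(fω), so they are weakly observable when the roll
field dominates — parameter-recovery fixtures therefore use rotations
whose components induce fields of comparable magnitude.

Per frame, ω is fitted by linear least squares over valid flow pixels;
with `robust=True` (default) a Tukey-biweight IRLS (c = 4.685, scale =
1.4826·MAD of the per-pixel residual norms, 5 iterations) downweights
independently moving regions, i.e. the hand, so the camera term is
estimated from the static background. The per-frame track is then
median-smoothed (window 5) so that only the unstable jitter component is
attributed to the camera, and B(x)ω is subtracted from the flow. The
residual is the subject-motion signal. Camera translation is not
modelled, and no re-rendering/warping is performed — compensation lives
entirely in the flow domain, which is all that scoring needs.

Noiseless model flow yields ω to machine precision; end-to-end
(video → flow → fit → residual) on pure camera-rotation sequences the
residual mean speed is ~6–9% of the unstabilized mean speed.

## Scoring

Per-pixel speed in degree/s is ‖v‖ · frame_rate · (180/π)/f, the
small-angle pixel-to-degree conversion at the principal point (no
per-pixel angular correction). The per-frame value averages speed over
pixels; by default invalid pixels count as zero and the mean runs over
the full frame (`mask_policy='all_pixels'`). The alternative
(`'valid'`) averages over valid pixels only, but makes the frame value a
conditional mean whose scale depends on mask density and which is
dominated by a handful of survivors when the mask is nearly empty (e.g. a
static video); the all-pixels mean is a true motion-energy density and is
the default for that reason. The policy is stamped into every output.
The video-level score is the arithmetic mean of the per-frame values:
nonnegative, zero exactly when the residual flow is zero on all
contributing pixels, and positively homogeneous under flow scaling.

The score is *not* a movement count and no cycle segmentation is
attempted; agreement with the administrator's counts is a statistical
question, answered by the validation layer.

## Validation layer

- **Pearson agreement** per task, two-sided p from the t transform with
  n−2 degrees of freedom.
- **Low motility**: label positive iff the score is *strictly* below the
  sample mean of the population analysed; ties at the mean are negative.
  Labels are derived from the conventional count; the image-derived score
  is the continuous classifier.
- **ROC/AUC**: thresholds sweep the unique scores with the decision rule
  "image-derived score ≤ threshold ⇒ low motility" (lower scores indicate
  the positive class); AUC by the trapezoidal rule, which equals the
  Mann-Whitney U/(n₁n₀) statistic with ties counted ½ — verified exactly
  against a brute-force pairwise oracle in the tests.
- **Specificity at a sensitivity target** (default 70%): among thresholds
  achieving the target, the one with maximal specificity, ties broken
  toward the lower (more conservative) threshold; if no threshold reaches
  the target, specificity 0 is reported with a warning.
- **Bootstrap bands**: stratified (within-class) percentile bootstrap,
  default 2000 replicates, TPR interpolated on a fixed 101-point FPR
  grid; deterministic given the seed.
- **Summary rows**: mean, SD (n−1), quartiles (linear interpolation),
  extremes, the conventional CV = SD/mean, and the *index of dispersion*
  SD²/mean reported as `dispersion` — the variance-to-mean ratio that the
  reference score tables tabulate under a "CV" heading (SD²/mean
  reproduces those printed values to 2 d.p.; SD/mean does not). It is
  undefined (reported missing) when the mean is zero.

No multiple-testing correction is applied; correlations are reported raw.

## Synthetic fixtures

Every generator is bit-reproducible given its seed, and each emulates one
ingredient of real recordings:

- `gen_translating_sequence`: band-limited Gaussian random texture
  (correlation length 3 px) shifted by exact sub-pixel Fourier
  translation with periodic boundary; ground truth is the constant
  velocity. Periodic warping avoids border invalidity confounds; border
  crops handle the wrap seam in oracle comparisons.
- `gen_camera_rotation_sequence`: each frame is warped from its
  predecessor by the displacement field B(x)ω (cubic resampling,
  periodic), so the inter-frame flow equals the model field.
- `gen_task_video`: a textured blob over a textured background. For the
  clench, the blob radius breathes sinusoidally (radial expansion/
  contraction, speed ∝ frequency × amplitude); for finger–thumb, two
  blobs translate rigidly with an oscillating gap. Defaults: 10 s at
  30 fps, amplitude 4 px, additive Gaussian sensor noise SD 0.01 (≈1% of
  full scale, a typical consumer-camera level), optional per-frame
  camera-jitter rotation. Cycle frequency is capped at frame_rate/4 for
  temporal sampling adequacy.
- `gen_paired_scores`: bivariate Gaussian copula; the conventional
  marginal is a rounded, zero-clipped normal and the image-derived
  marginal a zero-clipped normal, with per-task (mean, SD) defaults
  mimicking the reference score tables. Because rounding and clipping
  attenuate correlation, the latent correlation is calibrated by
  monotone bisection (100 000-sample evaluations with a fixed internal
  generator) so the *output* Pearson correlation matches the target; the
  calibration is a deterministic function of (target, marginals) and is
  cached.

What the fixtures do **not** emulate: photorealistic hands, articulated
finger motion, illumination changes, occlusions, depth-dependent
parallax from camera translation, and rolling-shutter effects. Passing
tests therefore demonstrate that the estimation machinery recovers known
ground truth under controlled conditions, not clinical performance on
real adolescents — the original cohort's videos are not distributable,
so cohort-level correlations and AUCs are assessed only as simulation
plausibility checks.

## Problem sizes and numerics

Tests and the acceptance script run the flow pipeline on reduced spatial
grids (96×128 to 120×160) while keeping the protocol's 10 s duration and
30 fps for task videos; these sizes exercise every code path with
comfortable interior-to-border ratios. Flow volumes are processed one
orientation at a time in float32 to bound memory. The least-squares
solves use closed-form 2×2 inversion (flow) and `lstsq` (ego-motion);
degenerate inputs are encoded in validity masks rather than raised,
except where the contract is genuinely violated (too few pixels to
identify a 3-parameter rotation, single-class ROC input, zero-variance
correlation input). Temporal resampling maps target sample j to source
index j·T_src/T_target so an already-normalized clip is a fixed point of
normalization.

## Known limitations

- Single-scale flow: speeds beyond ~λ/4 per frame (2 px/frame at the
  default wavelength) degrade; the generators enforce this envelope, and
  a coarse-to-fine pyramid is deliberately out of scope.
- The printed B(x) dialect is dimensionally odd for f ≠ 1 (tilt entries
  scale as 1/f where the classical Jacobian scales as f); both dialects
  are exposed and the default is a documented choice, not a claim of
  physical correctness.
- The degree/s conversion uses a single focal length at the principal
  point; wide-angle lenses would need a per-pixel angular model.
- The low-motility rule depends on the analysed sample's own mean, so
  labels (and downstream ROC points) are cohort-relative by design.
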