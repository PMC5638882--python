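# Methods

This note documents the models, algorithms and numerical choices behind
`paradic`, what the synthetic data do and do not emulate, and the known
limitations.

## Coordinate and angle conventions

Image arrays are `[row, col]`; the parallax split axis is the row
(vertical) axis.  Physical y maps to rows and x to columns through the
pixel size (160 nm/px by default, configurable), with the frame centre at
(x, y) = (0, 0).  z is signed, positive toward the objective; moving the
probe up increases the half-plane pair separation.  The azimuth φ is
measured from the bright polarization axis with a 180° period (a rod is a
headless axis); the elevation ψ runs from 0° (along the optical axis) to
90° (in the focal plane).  Canonicalization folds any input angles into
[0, 180) × [0, 90] and is idempotent.

## Forward image model

A rod behaves as a transition dipole whose normalized bright/dark channel
intensities follow the fourth-power projection law

    I_B = (sin ψ cos φ)⁴,   I_D = (sin ψ sin φ)⁴.

This exponent reproduces the characteristic periodicity of the measured
bright/dark intensities versus azimuth (extrema at 0°/90°, crossing at 45°)
and makes the two channels independent measures of the projections on the
two polarization axes.  The two intensities satisfy √I_B + √I_D = sin²ψ ≤ 1
and swap exactly under φ → 90° − φ.

The DIC point-spread function is modelled as an anti-symmetric pair of
offset Gaussian lobes on a gray background b₀:

    image = b₀ + A·I_B·f·G₊ − A·I_D·f·G₋,

with unit-peak Gaussians G± centred at ±shear/2 from the spot position.
No closed-form DIC PSF is standard; the offset-Gaussian form is the
simplest that preserves everything the tracking stack relies on
(anti-symmetry, orientation-dependent lobe amplitudes, diffraction-limited
width).  Defocus broadens the width as σ(z) = σ₀(1 + c·|z|/1000 nm) and
the amplitude factor f = (σ₀/σ)² conserves the integrated signal.

In parallax mode two half-plane images of the spot are rendered, separated
by d = d₀ + g·z along the split axis, each stretched by κ (default 1.6)
along that axis (the half-aperture PSF elongation), the lower being the
mirror image of the upper.  Out-of-range |z| > 500 nm is still rendered
with the linear law; range validity is flagged at localization time, not in
the renderer.  Noise is Poisson on expected counts plus Gaussian read
noise, reproducible under a seed.

Default geometry: 160 nm/px, b₀ = 2000 counts, A = 1500 counts, σ₀ = 1.2 px,
shear 3.2 px, d₀ = 20 px, dimensionless gain g = 0.626 (the calibrated
value of the reference instrument), range ±500 nm.  The polarization axes
are taken at ±45° to the image axes so that the shear — at 45° to the
polarization axes — is purely horizontal, i.e. perpendicular to the split
axis.  This choice makes each half-plane spot exactly mirror-symmetric
about the split axis, which the pair localizer exploits (below).

## Localization

All correlation maps are zero-mean normalized cross-correlations (ZNCC,
scores in [−1, 1]) so the conventional 0.4–0.6 score threshold is
meaningful; the default threshold is 0.5.

**Mirror-template pair localization.**  A crop around one half-plane spot
is used as the model for the other.  Two matched correlations are run: the
*mirrored* crop measures the sum of the two spot rows (the centre of
symmetry of the pair), the *unmirrored* crop measures their difference (the
separation d).  Solving the two linear relations gives both split-axis
centres model-free, with no assumption beyond the mirror relation between
the two half-plane PSFs.  (With the default geometry both correlations are
exact matched-template correlations; with a shear that has a split-axis
component the unmirrored match acquires a small pattern mismatch, which is
documented rather than corrected.)  The coordinate perpendicular to the
split axis carries no mirror constraint, so it is recovered by model-based
correlation: a rendered template of the whole pair at the measured
separation is matched against the frame.  z follows from the calibration
line as z = (d − d₀)/g, flagged when |z| exceeds the calibrated range.

**Model-based correlation (full-plane DIC).**  The anti-symmetric DIC PSF
cannot be fitted with a single peak function, so the frame is correlated
against a bank of rendered model PSFs spanning the azimuth in 5° steps
(ratio I_D/I_B = tan⁴φ covers all amplitude ratios), the best-scoring
template is kept, and the match is refined iteratively: the two lobe
amplitudes are re-estimated by linear least squares on the lobe basis
patterns rendered at the current subpixel offset, and the correlation is
repeated with the matched template at that offset.  A template that matches
both the amplitude ratio and the subpixel position makes the ZNCC map an
exact sampled autocorrelation — even about the true shift — so the peak
estimate is unbiased; three refinement iterations suffice for sub-0.01 px
convergence on noiseless frames.

**Subpixel peaks.**  The peak of every correlation map is a score-weighted
centroid over the pixels exceeding the threshold, with weights
(score − τ)² so the weight vanishes smoothly at the cut.  The centroid is
evaluated on an 8× cubic-spline upsampled copy of the blob's bounding box
(3 px margin), which removes pixel-grid discretization bias; when fewer
than 4 pixels pass, a 3×3 parabolic fit around the integer peak is used
instead.  Several disjoint above-threshold blobs raise an ambiguity flag;
the blob with the largest integrated excess score wins, ties resolved
toward the previous frame's position (first frame: first blob).

**Pre-smoothing.**  A mild Gaussian blur (σ = 0.7 px) is applied
identically to search regions and to all templates (frame crops are taken
from the smoothed frame; rendered templates are rendered wide, smoothed,
then cropped, so their boundaries match the smoothed field).  Matched
correlations stay exactly matched, so this introduces no bias, while the
correlation scores become far more stable at low signal-to-noise.

**Lobe intensity readout.**  B_raw is the mean of the k largest pixels in a
box around the bright-lobe position (centre + shear/2), D_raw the mean of
the k smallest around the dark lobe, with k the number of pixels within one
σ of the lobe centre.  The readout is linear in (I_B, I_D) for a stationary
pose, which is what makes the rotational-mode Pearson signatures exact;
overlapping lobes contribute a small cross-talk (the bright window sees a
little of the dark lobe and vice versa) quantified by the renderer's
unit-lobe response matrix.

Noiseless end-to-end accuracy with the default geometry is ≤ 2 nm in x, y
and z across the calibrated range (typically ≤ 0.5 nm laterally); the
Monte-Carlo precision under the default noise model is of order 10 nm
laterally and a few tens of nm axially, and degrades monotonically as the
signal amplitude drops.  Absolute precision values are a property of the
configured photon budget, not of the method.

## Axial calibration

The calibration scan steps a stationary rod through ±500 nm in 20 nm steps
(51 planes), optionally sweeping the azimuth through 0–175° in 5° steps
(n = 36) within each plane; the pair separation is measured per frame and
an ordinary least-squares line d = d₀ + g·z is fitted to the per-plane
means.  Planes outside the calibrated range are excluded (logged), one
round of > 5σ residual rejection is applied (logged), and the fit errors
out with fewer than 3 usable planes or more than 20% localization failures.
The slope is reported both in px/nm and as the dimensionless length ratio
d/Δz (slope × pixel size); d is orientation-independent in the model, and
the orientation-robustness sweep verifies the measured spread stays below
0.05 px per plane.

## Autofocus loop

A virtual piezo scanner holds the focal-plane position (sample
coordinates); the measured separation error maps to a defocus
(d − d₀)/g and a pure proportional controller moves the focal plane by
gain_k ∈ (0, 1] times that error, subject to a deadband (default 1 nm,
meant to sit below the measurement noise floor), a response latency of
≥ 1 frame, and ±5 µm travel with a saturation flag.  On a static target the
error decays geometrically as (1 − k)ⁿ; a ramp of speed v is tracked with
steady-state lag ≤ v·dt/k.  Engagement is continuous or intermittent
(every N seconds), matching the two operating modes (always-on feedback for
intracellular transport; intermittent refocusing during membrane-bound
phases).  The absolute axial trace is reconstructed as

    z(t) = command(t) + (d(t) − d₀)/g,

where "command" is the focal-plane position in sample coordinates
(stage-up = sample-up = Δz > 0); this sign convention differs from writing
the scanner axis inverted but describes the same physics, and the
reconstruction is exact under perfect measurement by construction.

## Orientation inversion

Raw traces are normalized per trace: the background b₀ is estimated as the
midpoint of the opposing 1st/99th percentiles of the bright and dark traces
(each channel touches the background whenever its projection vanishes), and
the normalization constants are the 99th-percentile excursions — robust to
isolated noise spikes.  Per-frame normalization is not used, as a single
frame does not constrain the excursion scale.  The closed-form inversion is

    φ = arctan((I_D/I_B)^{1/4}),   sin²ψ = √I_B + √I_D.

Within one 180° period, φ and 180° − φ give identical intensities (four
solutions over the full circle), so canonical angles in [0, 90] are
reported with the degeneracy made explicit; resolving it from a single
frame is physically impossible under this intensity law.  Noise can push
√I_B + √I_D above 1; such pairs are projected radially onto the boundary
and counted.  A zero-intensity pair (rod axial, or signal lost) is flagged
invalid rather than guessed.

## Rotational-mode analytics

The Pearson statistic is computed on the **raw** lobe intensities — bright
above background, dark below — which fixes the sign convention: in-plane
rotation (azimuth changing at ψ ≈ 90°) drives both traces in the same
direction (r near +1), while out-of-plane rotation (elevation changing)
drives them apart (r = −1 exactly for a noiseless swing, because both
channels are affine in sin⁴ψ with opposite signs).  Two analytic anchors
pin the statistic: a noiseless elevation swing at φ = 45° gives r = −1 to
machine precision through the full rendering pipeline, and a uniform
in-plane sweep gives r = corr(cos⁴φ, −sin⁴φ) = +15/17 ≈ 0.882 (moments:
cov(cos⁴, sin⁴) = −15/128, var = 17/128 over uniform φ), consistent with
the field's "close to 1" characterization of in-plane rotation.  The
in-plane anchor is checked on dipole-model traces; through the windowed
readout the overlapping-lobe cross-talk shifts it up by a few hundredths,
which is a property of the readout, not of the law.

Sliding windows default to 16 frames (about half a second at the 33 ms
working exposure) with half-window stride; zero-variance windows are
"static".  Mode calls use thresholds ±0.5 (midway between the anchors;
configurable).  Activity segmentation thresholds the summed centred rolling
variance of the two normalized channels at 5% of the whole-trace variance
and absorbs quiet runs shorter than 2 s; boundary error is at most about
one window because the rolling window straddles transitions.  Abrupt
restorations — a full-range intensity swing within ≤ 3 frames, the
signature of sudden recovery of rotational freedom at vesicle scission —
are flagged by frame index.  Per-particle, per-stage summaries report the
whole-trace r per particle with a histogram over [−1, 1] and the median as
the distribution centre; significance testing between stages is left to
the user.

Twister motion (cargo corkscrewing along a linear track) is quantified by
the 5th–95th percentile envelope of the linearly detrended z trace
(peak-to-peak amplitude), the dominant period from the first local maximum
of the autocorrelation after its first zero crossing (parabolically
refined; the first local maximum is used because the global tail maximum
can alias onto a period multiple when the true period is a half-integer
number of frames), and the lateral path linearity as the principal-axis
variance fraction.  Traces without an autocorrelation peak above 0.2 are
flagged aperiodic.

## Synthetic motion scenarios

Trajectories are phase lists combining translational models (reflected
Brownian motion in a square corral; stop; directed runs; helical transport)
with rotational models (isotropic rotational diffusion via composed small
Rodrigues rotations with per-axis rotation-vector variance 2·D_rot·dt,
giving axis MSAD 4·D_rot·dt; azimuth- or elevation-biased diffusion;
deterministic elevation swings; frozen; slow directed drift).  Identical
spec and seed reproduce trajectories bit for bit, and every frame carries
exactly one phase label.

The `endocytosis` preset encodes the characteristic cargo signature at
desk scale: 15 s of active confined diffusion with fast isotropic rotation
(D_rot = 5 rad²/s — strong frame-to-frame intensity flicker at 30 fps),
10 s of restrained motion with an in-plane-biased component, a 20 s quiet
phase (translation stopped; slow directed elevation drift of 1°/s at
near-fixed azimuth, so one channel stays nearly constant while the other
changes slowly), and 15 s of restored active rotation.  The rotational
diffusion coefficients of membrane-bound probes are not established
quantities; these values were chosen once so that active phases flicker
strongly and the quiet phase does not, and all quantitative tests compare
against the configured ground truth, never against real recordings.  The
`transport` preset strings together track search, a ±300 nm vertical run,
a pause/turn, and a 2 s lateral run of > 5 µm with a helical twist (65 nm
radius, 0.35 s period, giving a 100–160 nm peak-to-peak z oscillation —
the span of an 80 nm rod tumbling about a ~25 nm microtubule).  The
two-stage cohort generator gives early-stage particles
out-of-plane-biased kinematics (elevation diffuses at 2 rad²/s, azimuth
nearly frozen at 0.05 rad²/s) and late-stage particles the reverse, so the
late-stage correlation centre exceeds the early one — the qualitative
ordering seen when receptor-bound cargo shifts toward in-plane rotation.

What the generator does **not** emulate: cell-background texture and
contrast gradients, neighbouring particles and crossing tracks, focal
drift other than what the feedback loop is asked to correct, EMCCD
multiplication noise (noise is Poisson + Gaussian), rod-length
polydispersity, and any mechanistic membrane or motor model.  Passing
tests therefore demonstrate correctness of the algorithms under the stated
image model, not performance on real recordings.

## Problem sizes and determinism

The shipped analyses use desk-scale sizes chosen to characterize each
property well: 51-plane calibration scans (20 nm steps), 240-frame
rotational anchors, 100-frame precision assays at three amplitudes,
20-seed segmentation sweeps of the 60 s endocytosis preset, and a
50-particle-per-stage cohort replicated 20 times.  All randomness flows
through explicit seeds; noiseless pipelines are bit-reproducible.

## Known limitations

- The mirror localizer's unmirrored pair correlation is exactly matched
  only when the half-plane PSF is symmetric about the split axis (default
  geometry); strongly sheared-along-split configurations would bias d by a
  fraction of the shear's split-axis component.
- The linear d(z) law is extrapolated outside ±500 nm with only a flag;
  real parallax optics deviate from linearity there.
- Single-target tracking only: one probe per region of interest, no
  multi-particle linking or fiducial-based drift correction.
- The score threshold is metric-dependent: the printed 0.4–0.6 range is
  meaningful for ZNCC, and other correlation normalizations would need a
  re-calibrated threshold.
- The mirror template defaults to the same frame (both options exposed);
  a reference-frame template trades noise correlation for staleness.
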