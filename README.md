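# paradic

Five-dimensional single-particle tracking in parallax differential
interference contrast (DIC) microscopy, as a fully simulated, testable
software instrument.

Rod-shaped plasmonic probes (gold nanorods) imaged in DIC appear as a pair
of apposed bright and dark diffraction-limited lobes on a gray background.
The lobe intensities measure the projections of the rod's long axis onto the
two orthogonal polarization directions,

    I_B = (sin ψ cos φ)⁴        I_D = (sin ψ sin φ)⁴,

where φ is the azimuth (from the bright polarization axis) and ψ the
elevation from the optical axis — so each frame encodes the probe's 3D
orientation.  Splitting the collection aperture with a wedge prism (parallax
mode) forms two half-plane images of every object, mirror images of one
another, whose mutual separation varies linearly with axial position:

    d = d₀ + g·z        (valid within ±0.5 µm of focus).

Together these give all five spatial coordinates per frame: x, y, z, φ, ψ.
The package is aimed at microscopists and methods developers who want to
prototype, stress-test and benchmark this tracking scheme without a
microscope: every stage of the real pipeline runs against a forward model
with known ground truth.

What is included:

- **Forward model** (`paradic.optics`): full-plane DIC and parallax-DIC
  rendering of a rod at any pose, with defocus broadening, half-plane PSF
  stretch, shot and read noise.
- **Localization** (`paradic.localize`): mirror-template correlation mapping
  of the half-plane pair (the measured separation gives z) and model-based
  correlation mapping for the anti-symmetric DIC PSF, both with subpixel
  score-weighted-centroid peaks and a configurable score threshold
  (0.4–0.6 conventional, 0.5 default).
- **Axial calibration** (`paradic.calibrate`): z-scan in fixed 20 nm steps,
  least-squares line fit of d(z), orientation-robustness sweep (36 azimuths
  per plane) and Monte-Carlo localization-precision assay.
- **Autofocus loop** (`paradic.focusloop`): a virtual objective scanner with
  proportional feedback that keeps the probe in focus; z is recorded as
  scanner positions plus the measured residual defocus.
- **Orientation** (`paradic.orientation`): normalized intensity traces and
  the closed-form inversion to (φ, ψ) with explicit degeneracy handling.
- **Rotational analytics** (`paradic.rotation`): sliding-window Pearson
  correlation of the bright/dark traces (in-plane rotation → r near +1,
  out-of-plane → r = −1), active/quiet segmentation of endocytic traces, and
  twister-motion analysis of transported cargo.
- **Scenario generator** (`paradic.scenarios`): ground-truthed motion
  presets — membrane binding with rotational diffusion, the full
  endocytosis signature (active → quiet → active), 3D intracellular
  transport with a vertical run and twister motion, plus the calibration
  and slow-sweep fixtures.
- **CLI** (`paradic` command): `simulate`, `calibrate`, `track`,
  `analyze-rotation`, `evaluate`.

## Worked example

Render a parallax frame of a rod at a known pose, localize it, and convert
the pair separation to an axial position:

```python
from paradic import (InstrumentModel, NanorodPose, render_parallax,
                     mirror_correlation_localize)

inst = InstrumentModel()                      # 160 nm/px, g = 0.626, d0 = 20 px
pose = NanorodPose(x=25.0, y=-40.0, z=150.0, phi=30.0, psi=75.0)
frame = render_parallax(pose, inst)
loc = mirror_correlation_localize(frame, inst)
print(f"d = {loc.d:.3f} px   score = {loc.score:.3f}")
print(f"x = {loc.x:.1f} nm   y = {loc.y:.1f} nm   "
      f"z = {(loc.d - inst.d0) / inst.gain_px_per_nm:.1f} nm")
```

```
d = 20.587 px   score = 0.985
x = 25.3 nm   y = -40.0 nm   z = 150.0 nm
```

The measured separation of 20.587 px exceeds the in-focus d₀ = 20 px by
g·z = 0.587 px, recovering the commanded 150 nm height; the lateral pose is
recovered to well under a nanometre of the 25/−40 nm ground truth.  Fitting
the full calibration scan (±500 nm in 20 nm steps) through the same
localizer:

```python
from paradic import calibrate_axial
from paradic.scenarios import _calibration_scan, render_movie

poses, meta = _calibration_scan(sweep=False)
stack = render_movie(poses, inst, mode="parallax", noise=False, extra_meta=meta)
cal = calibrate_axial(stack, inst)
print(f"slope = {cal.slope_dimensionless:.4f} d/dz   "
      f"d0 = {cal.d0:.3f} px   R^2 = {cal.r_squared:.6f}")
```

```
slope = 0.6267 d/dz   d0 = 20.000 px   R^2 = 0.999999
```

i.e. the pipeline recovers the configured dimensionless parallax gain of
0.626 to a tenth of a percent, with an essentially perfect linear fit.

The same pipeline is available from the shell:

```sh
paradic simulate --scenario calibration --seed 1 --no-noise --out scan.tif
paradic calibrate --in scan.tif --out cal.json
paradic simulate --scenario endocytosis --seed 1 --out movie.tif
paradic track --mode parallax --in movie.tif --out track.csv
```

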