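# Methods

## The reconstruction problem

Photoacoustic computed tomography (PACT) illuminates tissue with a
nanosecond laser pulse; absorbed optical energy launches a pressure wave
p(r, t) whose initial amplitude p0(r) maps optical absorption.  An array of
ultrasound detectors records time-resolved pressure, and reconstruction
inverts those records for p0 on a voxel grid.  `pactrecon` implements the
two standard time-domain back-projection estimators over arbitrary detector
geometries:

- **Delay-and-sum (DAS).** Each voxel j accumulates every detector i's
  sample at the time-of-flight delay t = l_ij / c, weighted by the solid
  angle ΔΩ_ij the detector subtends from the voxel:

      p0(j) = Σ_i w_ij · p_i(l_ij / c),     w_ij = cosθ_ij / l_ij²,

  where l_ij is the detector-to-voxel distance and θ_ij the angle between
  the detector normal and the voxel direction.  For a planar array at z = 0
  with normals (0, 0, 1) the weight reduces to z_j / l_ij³ — the cosine
  correction that matters when the voxel is far off a detector's axis.

- **Filtered back-projection (FBP).** Identical geometry, but the signal is
  replaced by the ramp-filtered integrand q(t) = p(t) − t·∂p/∂t, which
  sharpens boundaries.  Overall constant factors (the 2 of the continuous
  formula, acoustic constants) are absorbed into the image scale.

The Σ_i ΔΩ_ij denominator of the continuous formulas is dropped by default
(the constant-factor convention of the discrete forms) and restored exactly
by `normalize_solid_angle: true`.

### Numerical choices

- **Delay lookup.** Nearest-sample rounding (half away from zero) of
  l_ij/c·fs by default; linear interpolation between the two bracketing
  samples behind `interpolation: linear`.  Indices are clamped to
  [0, T−1]; because preprocessing forces the first and last sample of every
  row to exactly zero, a voxel whose time of flight falls outside the record
  receives an exact zero contribution — the clamp is the out-of-bounds
  contract, not an approximation.
- **Weights behind the detector plane.** cosθ < 0 (voxel in the detector's
  back half-space) gets weight 0; such voxels are invisible to that element.
- **Accumulation.** Per-voxel sums accumulate in float64 over detectors in
  a fixed order (vectorised blocks of 64 detectors, which does not change
  the per-voxel operation sequence); the stored volume is float32.  This
  makes the depth-slab partition bit-reproducible: a voxel's arithmetic is
  independent of which slab computes it, so any worker count yields a
  bit-identical volume.
- **FBP derivative.** ∂p/∂t by central differences (one-sided at the record
  ends), then boundary-zeroed like the raw rows.  Central differences keep
  the integrand local; the test suite cross-checks against spectral
  differentiation, excluding 32 samples around the N-wave support edges
  where the spectral oracle's Gibbs ringing (decaying roughly as 1/n from a
  discontinuity) exceeds the 2 % comparison band.

## Geometry conventions

The synthetic planar array (a linear array scanned mechanically) lies in
the z = 0 plane centred on the origin, normals (0, 0, 1), imaging z > 0;
element (step s, channel c) maps to signal-matrix row s·num_channels + c.
The hemispherical array occupies z ≤ 0 with normals pointing at the centre;
detectors are placed on a golden-angle (Fibonacci) lattice —
z_i = −R(i + ½)/N, φ_i = i·π(3 − √5) — the standard near-uniform
construction that avoids rotationally symmetric sampling artifacts.

The grid is axis-aligned with isotropic spacing `res`; `dims =
round(extent/res)` per axis and voxel centres are symmetric about the
requested centre (the origin field is itself a voxel centre, index offset
0).  Flat voxel indices are z-major (z slowest, x fastest), so depth slabs
are contiguous — the partition axis of the parallel scheme and the layout
of the saved volume file.

## Raw data model and preprocessing

Acquisitions are one headerless little-endian binary file per scan step,
channel-major within the file (all T samples of channel 0, then channel 1,
…).  The per-file layout is a package convention, documented here and
mirrored by the fixture writer, since vendor formats vary.  Files are
ordered by natural sort on the digit runs in their names; the fixture
writer zero-pads step numbers so lexicographic and natural order agree.
Samples convert to float32 on import (int16 is the common DAQ output).

Preprocessing applies, in order: an optional zero-phase forward–backward
Butterworth bandpass (order 3 per pass; "bandpass" is underspecified in
the field, and zero-phase filtering is chosen to preserve arrival times),
optional polyphase rational resampling (off by default; the studies here
use the native 40 MHz), and unconditional boundary-zeroing of the first and
last sample of every row (the out-of-record contract above).  Boundary-
zeroing is idempotent.

## The forward simulator

The synthetic-data generator produces the closed-form response of a
uniformly absorbing sphere under impulsive heating recorded by an ideal
point detector of unlimited bandwidth — the classic bipolar N-wave:

    p(t) = p0 · (d − c·t)/(2d)   for |d − c·t| ≤ Rs,  else 0,

for a detector at distance d from a sphere of radius Rs; physical constants
are absorbed into the phantom amplitude p0.  Samples are instantaneous
values at t = k/fs.  Multiple spheres superpose linearly; optional additive
i.i.d. Gaussian noise (off by default) requires an explicit seed and is
bit-reproducible.

The default study conditions reproduce the hemispherical simulation setup:
1024 detectors on a Fibonacci lattice of radius 100 mm, a 1 mm sphere at
the centre, a 5 mm × 5 mm × 5 mm field of view at 0.2 mm spacing (25³
voxels), c = 1500 m/s, fs = 40 MHz.  The record length is T = 3000 samples
so that every voxel's time of flight (≈ 2700–2800 samples) lies inside the
record.

What the generator deliberately does **not** model: finite detector
aperture and directivity, finite bandwidth, acoustic attenuation and
heterogeneity, laser pulse duration, and electronic noise coloration.
Passing tests therefore validate the geometry, weighting, delay and
partition logic of the pipeline — not its robustness to real-transducer
band-limiting or in vivo acoustic conditions.

### The flat-plateau property of the sphere phantom

A fact that shapes several tests: inside the N-wave support the FBP
integrand is constant, q(t) = p0/2 (the ramp term exactly cancels the
linear pressure ramp).  Every voxel strictly inside the sphere therefore
receives identical contributions from every detector, and the ideal
reconstruction of a uniform sphere is an exactly flat plateau over the
interior.  Consequences:

- The integer argmax over the volume is a tie among ~500 interior voxels,
  broken only by sub-percent discretisation ripple (the 1/l² weight's
  spatial variation, delay rounding).  Recovery is therefore asserted as
  "the centre voxel attains the maximum within 1 % and the argmax lies
  inside the phantom", plus the full-width-at-half-maximum of the central
  profile equalling the 2 mm diameter within ± 2·res.
- Localization-style checks (translation by one voxel, DAS/FBP peak
  colocation, MIP peak position) use a sub-resolution sphere
  (Rs = 0.15 mm < res), whose image is genuinely peaked, making
  single-voxel assertions strict.
- Raw DAS has a null at the exact source centre — the N-wave is
  antisymmetric about the arrival time, p(d/c) = 0 — so its peak sits one
  voxel off the FBP peak; in practice DAS images are viewed after
  rectification, which the postprocessing stage provides.

## Depth-slab parallelism

The grid's nz depth planes are split into contiguous slabs differing by at
most one plane (remainder to the earliest slabs), one per configured
worker ("device").  Each worker receives the full signal matrix and array —
partitioning detectors instead would not bound per-worker memory for large
grids — and computes only its slab; results are gathered by slab index and
concatenated, so output is deterministic irrespective of completion order.
Workers are OS processes (a process pool); with one worker the dispatch is
bypassed entirely.  The contract verified by the tests is exact: any
worker count from 1 to nz produces a bit-identical volume.

## Postprocessing

Reconstruction of bipolar signals leaves negative values; the package
provides absolute value, squaring, and the Hilbert-transform envelope
(magnitude of the analytic signal) taken along depth (z) lines, the
time-of-flight direction for the planar geometry.  Volumes are linearly
normalised to [0, 1] (rejecting constant volumes) and rendered as
maximum-intensity projections along a chosen axis, exported as 8-bit
grayscale PNG.  Volumes are saved as raw float32 in z-major order with a
YAML sidecar carrying dims, spacing and origin.

## Parameters at a glance

| key | meaning | unit | default |
|---|---|---|---|
| `vs` | speed of sound | m/s | required (1500 in the studies) |
| `fs` | sampling frequency | Hz | required (40 MHz) |
| `num_channels` / `num_steps` | elements per step × scan steps | — | required |
| `num_times` | samples per channel | — | required |
| `res` | grid spacing | m | required (0.2 mm) |
| `data_type` | raw sample type | — | `int16` |
| `algorithm` | `das` or `fbp` | — | `das` |
| `filter` | bandpass (low, high) | Hz | off |
| `normalize_solid_angle` | restore ΣΔΩ denominator | — | false |
| `interpolation` | delay lookup | — | `nearest` |
| `delay_offset` | constant acoustic delay | s | 0 |
| `num_devices` | slab workers | — | 1 |

## Problem sizes

The shipped studies run the full 1024-element hemisphere against the 25³
field of view (≈ 16 M detector–voxel pairs, seconds per reconstruction on
one core); oracle comparisons use ≤ 32 detectors on ≤ 8³ grids where the
scalar triple loop is tractable.  The same code paths scale to the
256 × 1380-element planar acquisitions by increasing the counts in the
configuration; the kernel streams detector blocks, so memory grows with
the voxel count, not the detector count.

## Known limitations

- No iterative/model-based or frequency-domain reconstruction.
- No detector directivity, bandwidth or aperture modelling in either the
  simulator or the weights.
- GPU execution is represented by the device/worker abstraction only; the
  partition contract, not hardware scheduling, is what this package
  verifies.
- The Hilbert envelope axis is fixed to z; for strongly curved arrays an
  along-ray envelope would differ.
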