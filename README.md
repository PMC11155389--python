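# pactrecon

3-D image reconstruction for photoacoustic computed tomography (PACT):
configuration-driven import of scanned-array raw data, solid-angle-weighted
delay-and-sum (DAS) and filtered back-projection (FBP) over arbitrary
detector geometries, depth-slab parallel execution, postprocessing
(rectification, envelope detection, maximum-intensity projection), and an
analytical forward simulator so the whole pipeline runs on synthetic
phantoms without any external data.

It is written for people building or evaluating PACT systems — planar
synthetic apertures formed by scanning a linear array, and hemispherical
matrix arrays — who need a reference CPU implementation of the standard
time-domain back-projection estimators with explicit, testable conventions.

## The estimators

A pulsed laser deposits energy in tissue; the resulting pressure transient
is recorded by N detectors and inverted for the initial pressure p0.  With
l_ij the distance from detector i to voxel j, c the speed of sound, and
θ_ij the angle between the detector normal and the voxel direction:

    DAS:  p0(j) = Σ_i  (cosθ_ij / l_ij²) · p_i(t)|_{t = l_ij/c}
    FBP:  p0(j) = Σ_i  (cosθ_ij / l_ij²) · [p_i(t) − t·∂p_i/∂t]|_{t = l_ij/c}

The weight cosθ_ij / l_ij² is proportional to the solid angle the element
subtends from the voxel; for a planar array at z = 0 it reduces to
z_j / l_ij³.  Dividing by Σ_i ΔΩ_ij is available behind a flag
(`normalize_solid_angle`); by default constants are absorbed into the image
scale.  Delays use nearest-sample lookup (linear interpolation optional),
and out-of-record delays clamp onto boundary samples that preprocessing
forces to zero.  See `docs/methods.md` for conventions, assumptions and
numerical choices.

## Worked example

Reconstruct the hemispherical simulation study — 1024 detectors on a
Fibonacci lattice of radius 100 mm, a 1 mm sphere at the centre, a
5 mm × 5 mm × 5 mm field of view at 0.2 mm spacing, 40 MHz sampling:

```python
import numpy as np
from pactrecon import (
    Config, SpherePhantom, backproject, build_fibonacci_hemisphere,
    build_grid, simulate_sphere_signals,
)
from pactrecon.io import zero_boundaries

cfg = Config(vs=1500.0, fs=40.0e6, num_channels=1, num_steps=1024,
             num_times=3000, res=0.20e-3, data_path="unused",
             algorithm="fbp")
array = build_fibonacci_hemisphere(1024, radius=0.1)
grid = build_grid(center=[0, 0, 0], extent=[5e-3] * 3, res=cfg.res)
phantom = SpherePhantom(center=[0, 0, 0], radius=1e-3)

S = zero_boundaries(simulate_sphere_signals(phantom, array, cfg))
vol = backproject(S, array, grid, cfg)

v = vol.values
peak = np.unravel_index(np.argmax(v), v.shape)
print("grid dims:", grid.dims)
print("peak voxel:", peak, "| centre fraction:", round(float(v[12, 12, 12] / v.max()), 3))
profile = v[:, 12, 12]
above = np.nonzero(profile >= profile.max() / 2)[0]
print("half-max profile span:", (above[-1] - above[0] + 1) * 0.2, "mm (sphere diameter 2.0 mm)")
```

prints

```
grid dims: (25, 25, 25)
peak voxel: (np.int64(14), np.int64(13), np.int64(8)) | centre fraction: 0.992
half-max profile span: 1.8 mm (sphere diameter 2.0 mm)
```

The reconstructed sphere interior is an (analytically exact) flat plateau —
the FBP integrand is p0/2 across the whole N-wave support — so the centre
voxel reaches 99.2 % of the maximum and the literal argmax falls elsewhere
inside the sphere; the voxel-quantised half-maximum span of the central
profile recovers the 2 mm diameter to within one voxel (sub-voxel
interpolation gives 1.94 mm).  `docs/methods.md` discusses this plateau and
its consequences.

The same pipeline runs from a shell against raw binary acquisitions
described by a `config.yaml`:

```sh
pactrecon simulate    -c config.yaml          # write synthetic raw files
pactrecon reconstruct -c config.yaml --num-devices 2 --algorithm fbp
pactrecon postprocess -c config.yaml --mode hilbert
```

`reconstruct` imports the per-step files, preprocesses (optional bandpass
and resampling, boundary-zeroing), back-projects with the configured number
of depth-slab workers — any worker count gives a bit-identical volume — and
writes the float32 volume, a MIP PNG, and a JSON run manifest with input
checksums and per-stage timings.

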