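"""Analytical forward simulator for spherical absorbers.

Under impulsive (delta-pulse) heating, a uniformly absorbing sphere of
radius Rs radiates the classic bipolar N-wave.  For an ideal point detector
of infinite bandwidth at distance d from the sphere centre, the pressure is

    p(t) = p0 * (d - vs*t) / (2*d)   for |d - vs*t| <= Rs,  else 0,

with constant physical prefactors absorbed into the phantom amplitude p0.
The wave is antisymmetric about the arrival time t = d/vs, its nonzero
support spans 2*Rs/vs, its leading edge is p0*Rs/(2*d), and its peak decays
as 1/d — the properties the reconstruction tests exploit.  Detectors sample
the instantaneous value at t = k/fs (no aperture or bandwidth integration).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .config import Config
from .geometry import DetectorArray


@dataclass
class SpherePhantom:
    """Uniform spherical absorber: centre (m), radius Rs (m), amplitude p0."""

    center: np.ndarray
    radius: float
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64).reshape(3)
        if self.radius <= 0:
            raise ValueError(f"phantom radius must be positive, got {self.radius}")


def phantoms_from_config(cfg: Config) -> list[SpherePhantom]:
    """Build phantom objects from the config ``phantom`` block (list of spheres)."""
    return [
        SpherePhantom(
            center=np.asarray(p["center"], dtype=np.float64),
            radius=float(p["radius"]),
            amplitude=float(p.get("amplitude", 1.0)),
        )
        for p in cfg.phantom
    ]


def nwave(t, distance: float, radius: float, amplitude: float, vs: float):
    """Closed-form N-wave of a uniform sphere at one detector.

    ``p(t) = p0 (d - vs t) / (2 d)`` for ``|d - vs t| <= Rs``, else 0.
    Accepts scalar or array ``t`` (seconds).
    """
    t = np.asarray(t, dtype=np.float64)
    distance = np.asarray(distance, dtype=np.float64)
    arg = distance - vs * t
    return np.where(np.abs(arg) <= radius, amplitude * arg, 0.0) / (2.0 * distance)


def simulate_sphere_signals(
    phantoms: SpherePhantom | Sequence[SpherePhantom],
    array: DetectorArray,
    cfg: Config,
    noise_std: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Closed-form N-wave recordings of spherical phantoms at every detector.

    Multiple phantoms superpose linearly.  Optional additive i.i.d. Gaussian
    noise of standard deviation ``noise_std`` requires a seed and is
    bit-reproducible for a fixed seed.

    Returns
    -------
    ndarray, shape (N detectors, num_times), float32.

    Raises
    ------
    ValueError
        If any detector lies inside (or on) a phantom sphere.
    """
    if isinstance(phantoms, SpherePhantom):
        phantoms = [phantoms]
    if noise_std is None:
        noise_std = cfg.noise_std
        seed = cfg.noise_seed if seed is None else seed

    t = np.arange(cfg.num_times, dtype=np.float64) / cfg.fs
    S = np.zeros((array.n_elements, cfg.num_times), dtype=np.float64)
    for ph in phantoms:
        d = np.linalg.norm(array.positions - ph.center, axis=1)
        inside = d <= ph.radius
        if np.any(inside):
            raise ValueError(
                f"detector(s) {np.nonzero(inside)[0].tolist()} lie inside the "
                f"phantom sphere at {ph.center.tolist()} (Rs = {ph.radius} m)"
            )
        S += nwave(t[None, :], d[:, None], ph.radius, ph.amplitude, cfg.vs)
    if noise_std:
        if seed is None:
            raise ValueError("a seed is mandatory when noise is enabled")
        rng = np.random.default_rng(seed)
        S = S + rng.normal(0.0, noise_std, size=S.shape)
    return S.astype(np.float32)


def write_raw_fixture(S: np.ndarray, cfg: Config, out_dir: str | Path) -> list[Path]:
    """Write a signal matrix as per-step raw binary files in the import dialect.

    Emits ``num_steps`` headerless little-endian files (channel-major within
    each file) named with a zero-padded step number, so natural and
    lexicographic sort agree and ``import_raw_data`` round-trips the matrix.
    Float sources are rounded to the nearest representable sample for
    integer ``data_type`` (documented lossy); values outside the type's
    range raise.
    """
    S = np.asarray(S)
    if S.shape != (cfg.num_detectors, cfg.num_times):
        raise ValueError(
            f"signal matrix shape {S.shape} does not match config "
            f"({cfg.num_detectors}, {cfg.num_times})"
        )
    dtype = cfg.dtype
    if np.issubdtype(dtype, np.integer):
        info = np.iinfo(dtype)
        rounded = np.rint(S)
        if rounded.min() < info.min or rounded.max() > info.max:
            raise ValueError(
                f"sample range [{S.min()}, {S.max()}] exceeds {cfg.data_type} "
                f"range [{info.min}, {info.max}]: quantization would clip"
            )
        quantized = rounded.astype(dtype)
    else:
        quantized = S.astype(dtype)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    width = max(5, len(str(cfg.num_steps - 1)))
    paths = []
    for step in range(cfg.num_steps):
        block = quantized[step * cfg.num_channels : (step + 1) * cfg.num_channels]
        path = out_dir / f"step_{step:0{width}d}.bin"
        block.tofile(path)
        paths.append(path)
    return paths
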