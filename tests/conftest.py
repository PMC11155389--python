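"""Shared fixtures: configs, detector arrays, simulated signals, and a naive
scalar back-projection oracle that is independent of the vectorised kernel."""

from __future__ import annotations

import math

import numpy as np
import pytest

from pactrecon import (
    Config,
    DetectorArray,
    SpherePhantom,
    build_fibonacci_hemisphere,
    build_grid,
    simulate_sphere_signals,
)
from pactrecon.io import zero_boundaries


def make_config(**overrides) -> Config:
    """A small valid baseline config; override any field."""
    base = dict(
        vs=1500.0,
        fs=40.0e6,
        num_channels=2,
        num_steps=3,
        num_times=64,
        res=0.20e-3,
        data_path="unused",
        data_type="int16",
    )
    base.update(overrides)
    return Config(**base)


@pytest.fixture
def small_cfg() -> Config:
    return make_config()


# --- hemisphere study: 1024-element Fibonacci array, R = 100 mm, 1 mm sphere
# at the centre, 5 mm cube FOV at 0.2 mm spacing, 40 MHz sampling.  The
# record length (3000 samples) covers every voxel's time of flight.

HEMI = dict(
    vs=1500.0,
    fs=40.0e6,
    num_channels=1,
    num_steps=1024,
    num_times=3000,
    res=0.20e-3,
    data_path="unused",
)


def hemi_config(**overrides) -> Config:
    return Config(**{**HEMI, **overrides})


@pytest.fixture(scope="session")
def hemisphere_array() -> DetectorArray:
    return build_fibonacci_hemisphere(1024, 0.1)


@pytest.fixture(scope="session")
def fov_grid():
    return build_grid([0.0, 0.0, 0.0], [5e-3, 5e-3, 5e-3], 0.20e-3)


@pytest.fixture(scope="session")
def sphere_signals(hemisphere_array):
    """Boundary-zeroed recordings of the centred 1 mm sphere phantom."""
    cfg = hemi_config()
    phantom = SpherePhantom(center=[0.0, 0.0, 0.0], radius=1e-3, amplitude=1.0)
    S = simulate_sphere_signals(phantom, hemisphere_array, cfg)
    return zero_boundaries(S)


@pytest.fixture(scope="session")
def sphere_volume_fbp(sphere_signals, hemisphere_array, fov_grid):
    from pactrecon import backproject

    cfg = hemi_config(algorithm="fbp")
    return backproject(sphere_signals, hemisphere_array, fov_grid, cfg)


def tiny_scene(num_devices: int = 1, seed: int = 17):
    """Deterministic small scene (8 detectors, 5x5x5 grid) for partition
    checks; identical data for every worker count."""
    rng = np.random.default_rng(seed)
    cfg = make_config(
        num_channels=1, num_steps=8, num_times=128, num_devices=num_devices
    )
    pos = rng.uniform(-1e-3, 1e-3, (8, 3))
    pos[:, 2] = -rng.uniform(0.5e-3, 1.5e-3, 8)
    nrm = np.tile([0.0, 0.0, 1.0], (8, 1))
    arr = DetectorArray(pos, nrm)
    S = zero_boundaries(rng.normal(size=(8, 128)).astype(np.float32))
    grid = build_grid([0.0, 0.0, 0.8e-3], [1e-3] * 3, 0.2e-3)
    return S, arr, grid, cfg


# --- independent oracle -----------------------------------------------------


def naive_backproject(S, array, grid, cfg) -> np.ndarray:
    """Scalar triple-loop back-projection, written from the definitions.

    Kept deliberately independent of the vectorised kernel: plain Python
    loops, ``math`` scalar ops, and its own finite-difference integrand.
    """
    S = np.asarray(S, dtype=np.float64)
    T = S.shape[1]
    if cfg.algorithm == "fbp":
        q = np.empty_like(S)
        dt = 1.0 / cfg.fs
        for i in range(S.shape[0]):
            for k in range(T):
                if k == 0:
                    d = (S[i, 1] - S[i, 0]) / dt
                elif k == T - 1:
                    d = (S[i, T - 1] - S[i, T - 2]) / dt
                else:
                    d = (S[i, k + 1] - S[i, k - 1]) / (2.0 * dt)
                q[i, k] = S[i, k] - (k * dt) * d
            q[i, 0] = 0.0
            q[i, T - 1] = 0.0
        sig = q
    else:
        sig = S

    nx, ny, nz = grid.dims
    out = np.zeros((nx, ny, nz), dtype=np.float64)
    xs = grid.axis_centers(0)
    ys = grid.axis_centers(1)
    zs = grid.axis_centers(2)
    for jx in range(nx):
        for jy in range(ny):
            for jz in range(nz):
                acc = 0.0
                wsum = 0.0
                for i in range(array.n_elements):
                    dx = xs[jx] - array.positions[i, 0]
                    dy = ys[jy] - array.positions[i, 1]
                    dz = zs[jz] - array.positions[i, 2]
                    l = math.sqrt(dx * dx + dy * dy + dz * dz)
                    if l == 0.0:
                        continue
                    cos = (
                        array.normals[i, 0] * dx
                        + array.normals[i, 1] * dy
                        + array.normals[i, 2] * dz
                    ) / l
                    if cos <= 0.0:
                        continue
                    w = cos / (l * l)
                    u = (l / cfg.vs + cfg.delay_offset) * cfg.fs
                    if cfg.interpolation == "linear":
                        u = min(max(u, 0.0), T - 1.0)
                        i0 = int(math.floor(u))
                        i1 = min(i0 + 1, T - 1)
                        val = (1.0 - (u - i0)) * sig[i, i0] + (u - i0) * sig[i, i1]
                    else:
                        k = int(math.floor(u + 0.5))
                        k = min(max(k, 0), T - 1)
                        val = sig[i, k]
                    acc += w * val
                    wsum += w
                if cfg.normalize_solid_angle and wsum > 0.0:
                    acc /= wsum
                out[jx, jy, jz] = acc
    return out
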