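"""Solid-angle-weighted back-projection (DAS and FBP).

Delay-and-sum estimates the initial pressure at voxel j as

    p0(j) = sum_i w_ij * p_i(t = l_ij / vs),

where l_ij is the detector-to-voxel distance and w_ij is proportional to
the solid angle the detector subtends from the voxel: w_ij = cos(theta_ij)
/ l_ij**2, with theta_ij the angle between the detector normal and the
voxel direction.  For a planar array at z = 0 with normals (0, 0, 1) this
reduces to w_ij = z_j / l_ij**3.  Filtered back-projection uses the same
weights on the modified signal q(t) = p(t) - t * dp/dt, which sharpens
boundaries.  The sum-of-weights denominator of the continuous formulas is
dropped by default (constant-factor convention) and restored by the
``normalize_solid_angle`` flag.

Out-of-record delays are handled by clamping the sample index to the record
ends, whose samples preprocessing forces to exactly zero — so a voxel whose
time of flight exceeds the record receives zero contribution.

Accumulation is float64 (order-robust for large sums); the stored volume
is float32.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .config import Config
from .geometry import DetectorArray, ReconGrid
from .io import zero_boundaries

#: Detectors processed per vectorised block (bounds peak memory; the
#: per-voxel accumulation order over detectors is block-independent).
_DET_BLOCK = 64


@dataclass
class WeightTerm:
    """Solid-angle weighting of one detector-voxel pair."""

    lij: float        # detector-to-voxel distance, m
    cos_theta: float  # normal . direction cosine
    weight: float     # cos_theta / lij**2 (0 behind the detector plane)


@dataclass
class ReconVolume:
    """Reconstructed initial-pressure volume on a grid.

    ``values`` has shape ``grid.dims`` = (nx, ny, nz), float32.
    """

    values: np.ndarray
    grid: ReconGrid

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != tuple(self.grid.dims):
            raise ValueError(
                f"volume shape {self.values.shape} != grid dims {self.grid.dims}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite values")

    def save(self, path: str | Path) -> Path:
        """Write raw float32 samples in jz-major (slowest) order plus a YAML
        sidecar describing dims, spacing and origin."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.values.transpose(2, 1, 0).astype("<f4").tofile(path)
        sidecar = {
            "dims": list(self.grid.dims),
            "spacing_m": self.grid.spacing.tolist(),
            "origin_m": self.grid.origin.tolist(),
            "dtype": "float32",
            "order": "z-major (z slowest, x fastest)",
        }
        with open(path.with_suffix(path.suffix + ".yaml"), "w") as fh:
            yaml.safe_dump(sidecar, fh)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ReconVolume":
        path = Path(path)
        with open(path.with_suffix(path.suffix + ".yaml")) as fh:
            meta = yaml.safe_load(fh)
        dims = tuple(meta["dims"])
        values = np.fromfile(path, dtype="<f4").reshape(dims[2], dims[1], dims[0])
        grid = ReconGrid(
            origin=np.array(meta["origin_m"]),
            spacing=np.array(meta["spacing_m"]),
            dims=dims,
        )
        return cls(values.transpose(2, 1, 0), grid)


def delay_index(lij, cfg: Config):
    """Time-of-flight sample index for a detector-voxel distance.

    Nearest mode rounds ``(lij/vs + delay_offset) * fs`` half away from zero
    and clamps to ``[0, num_times - 1]``; out-of-range delays therefore land
    on the boundary samples that preprocessing zeroed.  Linear mode returns
    the real-valued index with the same clamping applied to both bracketing
    samples at lookup time.
    """
    u = (np.asarray(lij, dtype=np.float64) / cfg.vs + cfg.delay_offset) * cfg.fs
    if cfg.interpolation == "nearest":
        idx = np.floor(u + 0.5)
        return np.clip(idx, 0, cfg.num_times - 1).astype(np.int64)
    return np.clip(u, 0.0, float(cfg.num_times - 1))


def solid_angle_weight(
    detector_position, detector_normal, voxel_position
) -> WeightTerm:
    """Solid-angle weight of one detector as seen from one voxel.

    ``weight = cos_theta / lij**2`` where ``cos_theta`` is the cosine
    between the detector normal and the detector-to-voxel direction; voxels
    behind the detector plane (cos_theta < 0) get weight 0.  For a planar
    array element at z = 0 with normal (0, 0, 1) the weight equals
    ``z_j / l_ij**3`` exactly.
    """
    det = np.asarray(detector_position, dtype=np.float64)
    nrm = np.asarray(detector_normal, dtype=np.float64)
    vox = np.asarray(voxel_position, dtype=np.float64)
    diff = vox - det
    lij = float(np.linalg.norm(diff))
    if lij == 0.0:
        raise ValueError("voxel coincides with the detector position")
    cos_theta = float(nrm @ diff) / lij
    weight = cos_theta / lij**2 if cos_theta > 0.0 else 0.0
    return WeightTerm(lij=lij, cos_theta=cos_theta, weight=weight)


def temporal_derivative(S: np.ndarray, cfg: Config) -> np.ndarray:
    """FBP integrand q(k) = p(k) - t_k * dp/dt(k), t_k = k/fs.

    dp/dt uses central differences at interior samples and one-sided
    differences at the two ends; the result is boundary-zeroed like the
    preprocessing step, preserving the out-of-record contract.
    """
    S = np.asarray(S, dtype=np.float32)
    if S.shape[1] < 3:
        raise ValueError("temporal derivative needs at least 3 time samples")
    t = (np.arange(S.shape[1], dtype=np.float64) / cfg.fs).astype(np.float32)
    dpdt = np.gradient(S.astype(np.float64), 1.0 / cfg.fs, axis=1)
    q = (S.astype(np.float64) - t[None, :] * dpdt).astype(np.float32)
    return zero_boundaries(q)


def backproject(
    S: np.ndarray,
    array: DetectorArray,
    grid: ReconGrid,
    cfg: Config,
    z_range: tuple[int, int] | None = None,
) -> ReconVolume:
    """Back-project a preprocessed signal matrix onto the grid.

    ``cfg.algorithm`` selects DAS (signals used as recorded) or FBP (the
    temporal-derivative integrand).  ``z_range = (z0, z1)`` restricts the
    output to a depth slab, computing exactly the operations the monolithic
    call performs for those voxels — the slab result is bit-identical to the
    corresponding slice of the full volume.

    Returns a ``ReconVolume`` whose grid covers the requested slab.
    """
    S = np.asarray(S, dtype=np.float32)
    if S.shape[0] != array.n_elements:
        raise ValueError(
            f"signal matrix has {S.shape[0]} rows but the array has "
            f"{array.n_elements} elements"
        )
    if S.shape[1] != cfg.num_times:
        raise ValueError(
            f"signal matrix has {S.shape[1]} time samples, config says {cfg.num_times}"
        )
    sig = temporal_derivative(S, cfg) if cfg.algorithm == "fbp" else S

    centers = grid.voxel_centers(z_range)          # (nx, ny, nz_sel, 3)
    out_shape = centers.shape[:3]
    vox = centers.reshape(-1, 3)                   # (V, 3)
    acc = np.zeros(vox.shape[0], dtype=np.float64)
    wsum = np.zeros(vox.shape[0], dtype=np.float64) if cfg.normalize_solid_angle else None

    linear = cfg.interpolation == "linear"
    T = cfg.num_times
    for start in range(0, array.n_elements, _DET_BLOCK):
        pos = array.positions[start : start + _DET_BLOCK]     # (B, 3)
        nrm = array.normals[start : start + _DET_BLOCK]
        sig_blk = sig[start : start + _DET_BLOCK].astype(np.float64)
        diff = vox[None, :, :] - pos[:, None, :]              # (B, V, 3)
        lij = np.sqrt(np.einsum("bvk,bvk->bv", diff, diff))
        with np.errstate(divide="ignore", invalid="ignore"):
            cos_theta = np.einsum("bvk,bk->bv", diff, nrm) / lij
            w = np.where(cos_theta > 0.0, cos_theta / lij**2, 0.0)
        w[lij == 0.0] = 0.0

        u = (lij / cfg.vs + cfg.delay_offset) * cfg.fs
        if linear:
            u = np.clip(u, 0.0, float(T - 1))
            i0 = np.floor(u).astype(np.int64)
            i1 = np.minimum(i0 + 1, T - 1)
            frac = u - i0
            rows = np.arange(sig_blk.shape[0])[:, None]
            vals = (1.0 - frac) * sig_blk[rows, i0] + frac * sig_blk[rows, i1]
        else:
            idx = np.clip(np.floor(u + 0.5), 0, T - 1).astype(np.int64)
            vals = sig_blk[np.arange(sig_blk.shape[0])[:, None], idx]

        acc += np.einsum("bv,bv->v", w, vals)
        if wsum is not None:
            wsum += w.sum(axis=0)

    if wsum is not None:
        nonzero = wsum > 0.0
        acc[nonzero] /= wsum[nonzero]

    values = acc.reshape(out_shape).astype(np.float32)
    if z_range is None:
        out_grid = grid
    else:
        z0, z1 = z_range
        origin = grid.origin.copy()
        origin[2] = grid.axis_centers(2)[z0]
        out_grid = ReconGrid(
            origin=origin,
            spacing=grid.spacing,
            dims=(grid.dims[0], grid.dims[1], z1 - z0),
        )
    return ReconVolume(values, out_grid)
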