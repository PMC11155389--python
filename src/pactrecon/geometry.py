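"""Detector arrays and the reconstruction grid.

Coordinate conventions: the synthetic planar array lies in the z = 0 plane,
centred on the origin, with every element normal (0, 0, 1) and the imaged
region at z > 0, so a voxel's z-coordinate is its height above the array.
The hemispherical array occupies z <= 0 (opening upward) with element
normals pointing at the hemisphere centre, and the imaged region sits around
the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class DetectorArray:
    """Detector element positions (m) and unit normals, shape (N, 3) each."""

    positions: np.ndarray
    normals: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=np.float64))
        self.normals = np.atleast_2d(np.asarray(self.normals, dtype=np.float64))
        if self.positions.shape != self.normals.shape or self.positions.shape[1] != 3:
            raise ValueError(
                f"positions {self.positions.shape} and normals {self.normals.shape} "
                "must both have shape (N, 3)"
            )
        if self.positions.shape[0] < 1:
            raise ValueError("detector array must have at least one element")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("detector positions must be finite")
        lengths = np.linalg.norm(self.normals, axis=1)
        if not np.allclose(lengths, 1.0, atol=1e-9):
            raise ValueError("detector normals must have unit length (within 1e-9)")

    @property
    def n_elements(self) -> int:
        return self.positions.shape[0]

    def __len__(self) -> int:
        return self.n_elements


@dataclass
class ReconGrid:
    """Axis-aligned voxel grid: origin = first voxel centre, uniform spacing.

    Voxel centre ``(jx, jy, jz)`` sits at ``origin + (jx, jy, jz) * spacing``
    (index offset 0: the origin is itself a voxel centre).  Flat voxel index
    is jz-major (slowest) then jy then jx (fastest), so constant-z slabs are
    contiguous ranges of the flat index.
    """

    origin: np.ndarray   # (3,) m, centre of voxel (0, 0, 0)
    spacing: np.ndarray  # (3,) m, > 0
    dims: tuple[int, int, int]  # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=np.float64).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=np.float64).reshape(3)
        self.dims = tuple(int(d) for d in self.dims)
        if any(d < 1 for d in self.dims):
            raise ValueError(f"grid dims must all be >= 1, got {self.dims}")
        if not np.all(self.spacing > 0):
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.dims

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (0 = x, 1 = y, 2 = z)."""
        n = self.dims[axis]
        return self.origin[axis] + np.arange(n) * self.spacing[axis]

    def voxel_centers(self, z_range: tuple[int, int] | None = None) -> np.ndarray:
        """All voxel centres, shape (nx, ny, nz_sel, 3).

        ``z_range = (z0, z1)`` restricts to the depth slab ``z0 <= jz < z1``;
        the coordinates of a slab voxel are bit-identical to the same voxel
        of the full grid.
        """
        x = self.axis_centers(0)
        y = self.axis_centers(1)
        z = self.axis_centers(2)
        if z_range is not None:
            z0, z1 = z_range
            if not (0 <= z0 < z1 <= self.dims[2]):
                raise ValueError(f"z_range {z_range} outside [0, {self.dims[2]}]")
            z = z[z0:z1]
        xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")
        return np.stack([xx, yy, zz], axis=-1)

    def flatten_index(self, jx: int, jy: int, jz: int) -> int:
        """Flat voxel index, jz-major (slowest) -> jy -> jx (fastest)."""
        nx, ny, _ = self.dims
        return (jz * ny + jy) * nx + jx

    def unflatten_index(self, j: int) -> tuple[int, int, int]:
        nx, ny, _ = self.dims
        jz, rem = divmod(j, ny * nx)
        jy, jx = divmod(rem, nx)
        return jx, jy, jz


def build_planar_synthetic_array(
    num_channels: int,
    channel_pitch: float,
    num_steps: int,
    step_size: float,
) -> DetectorArray:
    """Synthetic planar array formed by scanning a linear array.

    Element ``(step s, channel c)`` sits at ``(c * channel_pitch,
    s * step_size, 0)`` minus the array centroid, so the array is centred on
    the origin in the z = 0 plane.  Element index ``s * num_channels + c``
    matches the row order of the imported signal matrix.  All normals are
    (0, 0, 1).
    """
    if num_channels < 1 or num_steps < 1:
        raise ValueError("num_channels and num_steps must be >= 1")
    if channel_pitch <= 0 or step_size <= 0:
        raise ValueError("channel_pitch and step_size must be positive")
    c = np.arange(num_channels, dtype=np.float64) * channel_pitch
    s = np.arange(num_steps, dtype=np.float64) * step_size
    ss, cc = np.meshgrid(s, c, indexing="ij")  # step-major
    positions = np.column_stack(
        [cc.ravel(), ss.ravel(), np.zeros(num_channels * num_steps)]
    )
    positions -= positions.mean(axis=0)
    normals = np.tile([0.0, 0.0, 1.0], (positions.shape[0], 1))
    return DetectorArray(positions, normals)


def build_fibonacci_hemisphere(N: int, radius: float) -> DetectorArray:
    """Fibonacci (golden-angle) lattice of N detectors on the z <= 0 hemisphere.

    Point i has ``z_i = -R (i + 0.5) / N`` and azimuth ``i * pi (3 - sqrt 5)``;
    normals point from each element toward the hemisphere centre.  The
    golden-angle spiral spreads points near-uniformly, avoiding the
    rotational symmetry of latitude-longitude layouts.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    i = np.arange(N, dtype=np.float64)
    z = -radius * (i + 0.5) / N
    phi = i * GOLDEN_ANGLE
    rho = np.sqrt(np.maximum(radius**2 - z**2, 0.0))
    positions = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    normals = -positions / radius
    return DetectorArray(positions, normals)


def build_grid(center, extent, res: float) -> ReconGrid:
    """Reconstruction grid of a given physical extent and isotropic spacing.

    ``dims = round(extent / res)`` per axis; voxel centres are symmetric
    about ``center``.
    """
    center = np.asarray(center, dtype=np.float64).reshape(3)
    extent = np.broadcast_to(np.asarray(extent, dtype=np.float64), (3,)).copy()
    if res <= 0:
        raise ValueError("res must be positive")
    if np.any(extent <= 0):
        raise ValueError("extent must be positive on every axis")
    dims = tuple(int(np.round(e / res)) for e in extent)
    if any(d < 1 for d in dims):
        raise ValueError(
            f"extent {extent} at res {res} yields a zero-voxel axis (dims {dims})"
        )
    spacing = np.full(3, float(res))
    origin = center - (np.array(dims, dtype=np.float64) - 1.0) / 2.0 * spacing
    return ReconGrid(origin=origin, spacing=spacing, dims=dims)


def load_array_table(path) -> DetectorArray:
    """Read an arbitrary array from a plain-text table of N rows x 6 columns
    (x y z nx ny nz, metres / unit vectors)."""
    table = np.loadtxt(path, dtype=np.float64, ndmin=2)
    if table.shape[1] != 6:
        raise ValueError(f"{path}: expected 6 columns (x y z nx ny nz)")
    return DetectorArray(table[:, :3], table[:, 3:])


def array_from_config(geometry: dict) -> DetectorArray:
    """Build a detector array from a config ``geometry`` block."""
    if not geometry or "type" not in geometry:
        raise ValueError("geometry block with a 'type' key is required")
    kind = geometry["type"]
    if kind == "planar":
        return build_planar_synthetic_array(
            num_channels=int(geometry["num_channels"]),
            channel_pitch=float(geometry["channel_pitch"]),
            num_steps=int(geometry["num_steps"]),
            step_size=float(geometry["step_size"]),
        )
    if kind == "hemisphere":
        return build_fibonacci_hemisphere(
            N=int(geometry["num_elements"]), radius=float(geometry["radius"])
        )
    if kind == "table":
        return load_array_table(geometry["path"])
    raise ValueError(f"unknown geometry type {kind!r}")


def grid_from_config(grid_block: dict, res: float) -> ReconGrid:
    """Build the reconstruction grid from a config ``grid`` block."""
    if not grid_block:
        raise ValueError("grid block with 'center' and 'extent' is required")
    return build_grid(grid_block["center"], grid_block["extent"], res)
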