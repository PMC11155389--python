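"""Postprocessing of reconstructed volumes.

Back-projection of band-limited bipolar signals leaves negative voxel
values; three standard remedies are provided (absolute value, squaring,
and the Hilbert-transform envelope along depth lines).  Volumes are then
linearly normalised to [0, 1] and rendered as maximum-intensity
projections (MIP).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import hilbert

from .recon import ReconVolume

_AXES = {"x": 0, "y": 1, "z": 2}

RECTIFY_MODES = ("abs", "square", "hilbert")


@dataclass
class ProjectionImage:
    """2-D projection of a volume; ``axis`` names the collapsed axis."""

    values: np.ndarray
    axis: str


def _axis_index(axis) -> int:
    if isinstance(axis, str):
        if axis not in _AXES:
            raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
        return _AXES[axis]
    if axis in (0, 1, 2):
        return int(axis)
    raise ValueError(f"invalid projection axis {axis!r}")


def rectify(V: ReconVolume, mode: str = "abs") -> ReconVolume:
    """Map a signed volume to a nonnegative one.

    ``abs`` and ``square`` act voxel-wise; ``hilbert`` takes the magnitude
    of the analytic signal along each depth (z) line — the acoustic
    time-of-flight direction — yielding the envelope.
    """
    if mode == "abs":
        values = np.abs(V.values)
    elif mode == "square":
        values = np.square(V.values)
    elif mode == "hilbert":
        values = np.abs(hilbert(V.values.astype(np.float64), axis=2)).astype(np.float32)
    else:
        raise ValueError(f"unknown rectify mode {mode!r}; choose from {RECTIFY_MODES}")
    return ReconVolume(values, V.grid)


def normalize(V: ReconVolume) -> ReconVolume:
    """Linearly rescale the volume to fill [0, 1] exactly."""
    vmin = float(V.values.min())
    vmax = float(V.values.max())
    if vmax == vmin:
        raise ValueError("cannot normalize a constant volume (zero range)")
    values = (V.values.astype(np.float64) - vmin) / (vmax - vmin)
    return ReconVolume(values.astype(np.float32), V.grid)


def mip(V: ReconVolume, axis="z") -> ProjectionImage:
    """Maximum-intensity projection along one axis."""
    ax = _axis_index(axis)
    name = "xyz"[ax]
    return ProjectionImage(values=V.values.max(axis=ax), axis=name)


def save_mip_png(image: ProjectionImage, path: str | Path) -> Path:
    """Export a projection as an 8-bit grayscale PNG (values clipped to [0, 1])."""
    from PIL import Image

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    scaled = np.clip(image.values, 0.0, 1.0) * 255.0
    # transpose so the first volume axis runs along image x
    Image.fromarray(np.rint(scaled).astype(np.uint8).T, mode="L").save(path)
    return path
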