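"""Configuration handling for the reconstruction pipeline.

All run parameters live in a single ``config.yaml`` whose top-level keys
mirror the acquisition parameters of a scanned-array PACT system: speed of
sound ``vs`` (m/s), sampling frequency ``fs`` (Hz), channel / scan-step /
time-sample counts, reconstruction grid spacing ``res`` (m), the raw-data
directory and its sample type, and device settings.  Extension blocks
(``algorithm``, ``geometry``, ``grid``, ``filter``, ``phantom``, ``output``)
configure the reconstruction and the synthetic-data generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import yaml


class ConfigError(ValueError):
    """Raised when a configuration file is missing keys or fails validation."""


#: Mapping of config ``data_type`` tags to little-endian numpy dtypes.
DATA_TYPES: dict[str, np.dtype] = {
    "int16": np.dtype("<i2"),
    "int32": np.dtype("<i4"),
    "uint16": np.dtype("<u2"),
    "float32": np.dtype("<f4"),
    "float64": np.dtype("<f8"),
}

_MANDATORY = ("vs", "fs", "num_channels", "num_steps", "num_times", "res", "data_path")


@dataclass
class Config:
    """Validated run parameters.

    Mandatory fields follow the acquisition-parameter table of the config
    file; the remaining fields carry documented defaults.
    """

    vs: float                      # speed of sound, m/s
    fs: float                      # sampling frequency, Hz
    num_channels: int              # detector elements per scan step
    num_steps: int                 # mechanical scan steps (1 for a fixed array)
    num_times: int                 # time samples per channel
    res: float                     # reconstruction grid spacing, m
    data_path: str                 # directory of raw binary files
    data_type: str = "int16"       # raw sample scalar type tag
    device: str = "cpu"            # "cpu" | "gpu" backend tag
    num_devices: int = 1           # worker count for the slab partition
    algorithm: str = "das"         # "das" | "fbp"
    geometry: dict[str, Any] | None = None   # detector-array block
    grid: dict[str, Any] | None = None       # reconstruction-grid block
    filter: tuple[float, float] | None = None  # bandpass (low, high), Hz
    resample_fs: float | None = None           # target rate for resampling, Hz
    normalize_solid_angle: bool = False  # restore the sum-of-weights denominator
    interpolation: str = "nearest"       # "nearest" | "linear" delay lookup
    delay_offset: float = 0.0            # constant acoustic delay, s
    phantom: list[dict[str, Any]] = field(default_factory=list)
    noise_std: float = 0.0               # additive Gaussian noise level (simulation)
    noise_seed: int | None = None        # mandatory when noise_std > 0
    output: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("vs", "fs", "res"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"'{name}' must be positive, got {getattr(self, name)}")
        for name in ("num_channels", "num_steps", "num_times", "num_devices"):
            value = getattr(self, name)
            if not (isinstance(value, (int, np.integer)) and value >= 1):
                raise ConfigError(f"'{name}' must be an integer >= 1, got {value!r}")
        if self.data_type not in DATA_TYPES:
            raise ConfigError(
                f"'data_type' must be one of {sorted(DATA_TYPES)}, got {self.data_type!r}"
            )
        if self.device not in ("cpu", "gpu"):
            raise ConfigError(f"'device' must be 'cpu' or 'gpu', got {self.device!r}")
        if self.algorithm not in ("das", "fbp"):
            raise ConfigError(f"'algorithm' must be 'das' or 'fbp', got {self.algorithm!r}")
        if self.interpolation not in ("nearest", "linear"):
            raise ConfigError(
                f"'interpolation' must be 'nearest' or 'linear', got {self.interpolation!r}"
            )
        if self.filter is not None:
            low, high = self.filter
            if not (0.0 < low < high < self.fs / 2.0):
                raise ConfigError(
                    f"filter band ({low}, {high}) Hz must satisfy 0 < low < high < fs/2"
                    f" = {self.fs / 2.0} Hz"
                )
            self.filter = (float(low), float(high))
        if self.resample_fs is not None and not self.resample_fs > 0:
            raise ConfigError(f"'resample_fs' must be positive, got {self.resample_fs}")
        if self.noise_std < 0:
            raise ConfigError(f"'noise_std' must be >= 0, got {self.noise_std}")
        if self.noise_std > 0 and self.noise_seed is None:
            raise ConfigError("'noise_seed' is mandatory when noise_std > 0")

    @property
    def num_detectors(self) -> int:
        """Total synthetic-array element count N = num_steps * num_channels."""
        return self.num_steps * self.num_channels

    @property
    def dtype(self) -> np.dtype:
        """Numpy dtype of the raw samples."""
        return DATA_TYPES[self.data_type]

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        if d["filter"] is not None:
            d["filter"] = list(d["filter"])
        return d


def load_config(path: str | Path) -> Config:
    """Parse and validate a YAML configuration file.

    Parameters
    ----------
    path
        Path to a ``config.yaml``.

    Raises
    ------
    ConfigError
        If a mandatory key is missing or any invariant fails; the message
        names the offending key.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level of the config must be a mapping")

    missing = [k for k in _MANDATORY if k not in raw]
    if missing:
        raise ConfigError(f"{path}: missing mandatory key(s): {', '.join(missing)}")

    known = set(Config.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown key(s): {', '.join(sorted(unknown))}")

    kwargs = dict(raw)
    for name in ("num_channels", "num_steps", "num_times", "num_devices"):
        if name in kwargs:
            kwargs[name] = _as_int(name, kwargs[name])
    for name in ("vs", "fs", "res"):
        kwargs[name] = float(kwargs[name])
    if kwargs.get("filter") is not None:
        band = kwargs["filter"]
        if not (isinstance(band, (list, tuple)) and len(band) == 2):
            raise ConfigError(f"{path}: 'filter' must be a [low, high] pair in Hz")
        kwargs["filter"] = (float(band[0]), float(band[1]))
    kwargs["data_path"] = str(kwargs["data_path"])
    return Config(**kwargs)


def _as_int(name: str, value: Any) -> int:
    if isinstance(value, bool) or not isinstance(value, (int, np.integer)):
        raise ConfigError(f"'{name}' must be an integer, got {value!r}")
    return int(value)
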