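"""Raw-signal import and preprocessing.

The raw acquisition is stored as one headerless binary file per scan step,
each holding ``num_channels x num_times`` little-endian samples in
channel-major order (all time samples of channel 0, then channel 1, ...).
``import_raw_data`` concatenates the per-step files into a single signal
matrix of shape ``(num_steps * num_channels, num_times)`` — row index
``step * num_channels + channel`` — converted to float32.

``preprocess`` applies an optional zero-phase bandpass, optional polyphase
resampling, and always zeroes the first and last sample of every row, so
that out-of-record delay indices clamped to the boundary read an exact zero.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
from scipy.signal import butter, sosfiltfilt, resample_poly

from .config import Config, ConfigError


class RawDataError(IOError):
    """Raised when raw binary files do not match the configuration."""


def _natural_key(name: str) -> tuple:
    """Sort key splitting digit runs so step_2 < step_10."""
    return tuple(int(tok) if tok.isdigit() else tok for tok in re.split(r"(\d+)", name))


def list_raw_files(cfg: Config) -> list[Path]:
    """Raw files under ``cfg.data_path`` in deterministic (natural-sort) order."""
    data_dir = Path(cfg.data_path)
    if not data_dir.is_dir():
        raise RawDataError(f"data_path does not exist or is not a directory: {data_dir}")
    files = sorted(
        (p for p in data_dir.iterdir() if p.is_file()),
        key=lambda p: _natural_key(p.name),
    )
    if len(files) != cfg.num_steps:
        raise RawDataError(
            f"expected {cfg.num_steps} raw files in {data_dir}, found {len(files)}"
        )
    return files


def import_raw_data(cfg: Config) -> np.ndarray:
    """Bulk-import all per-step raw files into one float32 signal matrix.

    Returns
    -------
    ndarray of shape ``(num_steps * num_channels, num_times)``, float32.
        Row ordering is step-major: row = step * num_channels + channel.

    Raises
    ------
    RawDataError
        On file-count mismatch (reporting expected vs found) or file-size
        mismatch (naming the file).
    """
    files = list_raw_files(cfg)
    expected = cfg.num_channels * cfg.num_times
    out = np.empty((cfg.num_steps * cfg.num_channels, cfg.num_times), dtype=np.float32)
    for step, path in enumerate(files):
        samples = np.fromfile(path, dtype=cfg.dtype)
        if samples.size != expected:
            raise RawDataError(
                f"{path}: expected {expected} samples of {cfg.data_type}, "
                f"found {samples.size}"
            )
        block = samples.reshape(cfg.num_channels, cfg.num_times)
        out[step * cfg.num_channels : (step + 1) * cfg.num_channels] = block
    return out


def zero_boundaries(S: np.ndarray) -> np.ndarray:
    """Set the first and last sample of every row to exactly zero (in place)."""
    S[:, 0] = 0.0
    S[:, -1] = 0.0
    return S


def preprocess(S: np.ndarray, cfg: Config) -> np.ndarray:
    """Bandpass-filter, optionally resample, and boundary-zero a signal matrix.

    The bandpass is a zero-phase forward-backward Butterworth (order 3)
    applied per row when ``cfg.filter`` is set.  Resampling to
    ``cfg.resample_fs`` uses polyphase rational resampling; the time-sample
    count changes accordingly.  Regardless of the other steps, the first and
    last sample of every row are forced to exactly zero.
    """
    if S.shape != (cfg.num_detectors, cfg.num_times):
        raise ValueError(
            f"signal matrix shape {S.shape} does not match config "
            f"({cfg.num_detectors}, {cfg.num_times})"
        )
    out = np.asarray(S, dtype=np.float32).copy()

    if cfg.filter is not None:
        low, high = cfg.filter
        nyq = cfg.fs / 2.0
        if not (0.0 < low < high < nyq):
            raise ConfigError(f"filter band ({low}, {high}) Hz outside (0, {nyq}) Hz")
        sos = butter(3, [low / nyq, high / nyq], btype="bandpass", output="sos")
        out = sosfiltfilt(sos, out, axis=1).astype(np.float32)

    if cfg.resample_fs is not None and cfg.resample_fs != cfg.fs:
        from fractions import Fraction

        frac = Fraction(cfg.resample_fs / cfg.fs).limit_denominator(1000)
        out = resample_poly(out, frac.numerator, frac.denominator, axis=1)
        out = np.ascontiguousarray(out, dtype=np.float32)

    return zero_boundaries(out)
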