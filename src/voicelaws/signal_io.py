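"""Reading acoustic signals and forming the instantaneous-energy series.

A mono waveform is represented as an :class:`AmplitudeSeries` with samples
normalized to [-1, 1] (integer PCM is divided by the full-scale magnitude of
its width, e.g. 32768 for 16-bit).  The quantity the rest of the pipeline
consumes is the instantaneous energy eps(t) = |A(t)|^2, a nonnegative series
with, up to constants, units of energy per unit time.

Supported inputs: PCM WAV (integer 8/16/24/32-bit and float, via scipy),
headerless raw integer files with a user-declared rate/width/endianness, and
plain one-column text/CSV files holding a precomputed energy series.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from scipy.io import wavfile

from .errors import InputError, ParameterError, UnsupportedFormatError

__all__ = [
    "AmplitudeSeries",
    "EnergySeries",
    "load_audio",
    "load_energy",
    "energy_series",
]

# full-scale divisor per integer sample width (bytes)
_FULL_SCALE = {1: 128.0, 2: 32768.0, 3: 8388608.0, 4: 2147483648.0}


@dataclass
class AmplitudeSeries:
    """A mono amplitude time series A(t), normalized to [-1, 1]."""

    samples: np.ndarray
    rate: float
    source_label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise InputError("amplitude series must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("amplitude series contains non-finite samples")
        if self.rate <= 0:
            raise ParameterError(f"sample rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.samples.size


@dataclass
class EnergySeries:
    """The instantaneous-energy series eps(t) = |A(t)|^2."""

    values: np.ndarray
    rate: float
    source_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size == 0:
            raise InputError("energy series must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.values)):
            raise InputError("energy series contains non-finite values")
        if np.any(self.values < 0):
            raise InputError("energy values must be nonnegative")
        if self.rate <= 0:
            raise ParameterError(f"sample rate must be positive, got {self.rate}")

    def __len__(self) -> int:
        return self.values.size


def _to_mono(data: np.ndarray, channel_policy: str) -> np.ndarray:
    if data.ndim == 1:
        return data
    if channel_policy == "first":
        return data[:, 0]
    if channel_policy == "mean":
        return data.mean(axis=1)
    raise ParameterError(f"unknown channel policy {channel_policy!r}")


def load_audio(
    path: str | os.PathLike,
    *,
    raw_rate: float | None = None,
    raw_width: int | None = None,
    raw_endian: str = "little",
    raw_signed: bool = True,
    channel_policy: str = "first",
    normalize: bool = True,
) -> AmplitudeSeries:
    """Read a PCM WAV or headerless raw integer file into an AmplitudeSeries.

    Files ending in ``.wav`` are parsed as WAV; anything else is treated as a
    headerless raw stream and requires ``raw_rate`` and ``raw_width`` (bytes
    per sample).  Integer samples are divided by the full-scale magnitude of
    their width so samples land in [-1, 1]; pass ``normalize=False`` to keep
    raw integer values (then bin widths are in raw-unit energies).
    Multichannel audio is reduced to mono by ``channel_policy`` ("first" or
    "mean").
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")

    if path.lower().endswith(".wav"):
        try:
            rate, data = wavfile.read(path)
        except ValueError as exc:
            raise UnsupportedFormatError(f"cannot decode WAV {path}: {exc}") from exc
        except Exception as exc:  # truncated/corrupt header
            raise InputError(f"unreadable WAV {path}: {exc}") from exc
        stored = data.dtype  # mono reduction promotes ints to float
        data = _to_mono(np.atleast_1d(data), channel_policy)
        if data.size == 0:
            raise InputError(f"WAV file {path} holds no samples (byte offset 44)")
        if stored.kind == "f":
            samples = data.astype(np.float64)
        elif stored == np.uint8:
            # WAV convention: 8-bit is unsigned, midpoint 128
            samples = (data.astype(np.float64) - 128.0)
            samples = samples / 128.0 if normalize else samples
            return AmplitudeSeries(samples, float(rate), source_label=path)
        else:
            scale = _FULL_SCALE.get(stored.itemsize)
            if scale is None:
                raise UnsupportedFormatError(
                    f"unsupported WAV sample width {stored.itemsize} bytes"
                )
            samples = data.astype(np.float64)
            if normalize:
                samples = samples / scale
        return AmplitudeSeries(samples, float(rate), source_label=path)

    # headerless raw stream
    if raw_rate is None or raw_width is None:
        raise ParameterError(
            "raw files need a declared rate and sample width (raw_rate=, raw_width=)"
        )
    if raw_width not in (1, 2, 4) and raw_width != 3:
        raise UnsupportedFormatError(f"unsupported raw sample width {raw_width}")
    nbytes = os.path.getsize(path)
    if nbytes % raw_width:
        raise InputError(
            f"truncated raw file {path}: {nbytes} bytes is not a multiple of "
            f"{raw_width} (trailing partial sample at byte offset "
            f"{nbytes - nbytes % raw_width})"
        )
    if raw_width == 3:  # 24-bit packed: widen by hand
        buf = np.fromfile(path, dtype=np.uint8).reshape(-1, 3)
        if raw_endian == "big":
            buf = buf[:, ::-1]
        data = (
            buf[:, 0].astype(np.int32)
            | (buf[:, 1].astype(np.int32) << 8)
            | (buf[:, 2].astype(np.int32) << 16)
        )
        data = np.where(data >= 1 << 23, data - (1 << 24), data)
    else:
        kind = "i" if raw_signed else "u"
        order = "<" if raw_endian == "little" else ">"
        dtype = np.dtype(f"{order}{kind}{raw_width}")
        data = np.fromfile(path, dtype=dtype)
    if data.size == 0:
        raise InputError(f"raw file {path} holds no samples (byte offset 0)")
    samples = data.astype(np.float64)
    if not raw_signed:
        samples -= _FULL_SCALE[raw_width]  # recentre unsigned at zero
    if normalize:
        samples /= _FULL_SCALE[raw_width]
    return AmplitudeSeries(samples, float(raw_rate), source_label=path)


def load_energy(path: str | os.PathLike, rate: float = 1.0) -> EnergySeries:
    """Load a precomputed one-column energy series from text/CSV."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise InputError(f"no such file: {path}")
    try:
        values = np.loadtxt(path, delimiter=None if not path.endswith(".csv") else ",")
    except Exception as exc:
        raise InputError(f"cannot parse energy file {path}: {exc}") from exc
    values = np.atleast_1d(values)
    if values.ndim > 1:
        values = values[:, 0]
    return EnergySeries(values, rate, source_label=path)


def energy_series(a: AmplitudeSeries) -> EnergySeries:
    """Square the amplitude: eps(t) = |A(t)|^2, one value per audio sample."""
    return EnergySeries(a.samples ** 2, a.rate, source_label=a.source_label)
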