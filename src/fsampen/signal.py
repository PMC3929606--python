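"""Uniformly sampled single-channel time series.

Every operation in this package consumes and produces :class:`Signal`
objects — a plain array of amplitude samples plus a sampling rate in Hz.
Amplitude units are arbitrary (accelerometer output, simulation units);
nothing downstream assumes a physical scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Signal"]


@dataclass(frozen=True, init=False)
class Signal:
    """A 1-D uniformly sampled time series.

    Parameters
    ----------
    samples
        Amplitude values, finite, length >= 1. Stored as float64.
    fs
        Sampling rate in Hz, > 0.
    """

    samples: np.ndarray
    fs: float

    def __init__(self, samples, fs: float):
        samples = np.asarray(samples, dtype=np.float64)
        if samples.ndim != 1:
            raise ValueError(f"samples must be 1-D, got shape {samples.shape}")
        if samples.size < 1:
            raise ValueError("signal must contain at least one sample")
        if not np.all(np.isfinite(samples)):
            raise ValueError("signal contains non-finite samples")
        fs = float(fs)
        if not (fs > 0):
            raise ValueError(f"sampling rate must be positive, got {fs}")
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "fs", fs)

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (sample count / rate)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.samples.size) / self.fs

    def sd(self, ddof: int = 1) -> float:
        """Standard deviation of the whole record (sample SD by default)."""
        return float(np.std(self.samples, ddof=ddof))
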