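"""Core container for a sampled single-channel signal."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidInputError


@dataclass(frozen=True)
class Signal:
    """A finite, uniformly sampled real-valued trace.

    Parameters
    ----------
    samples : array-like
        Amplitude values (arbitrary units, typically mV). Must be finite and
        contain at least two samples.
    fs : float
        Sampling rate in Hz, strictly positive.
    """

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 1 or arr.size < 2:
            raise InvalidInputError(
                f"signal must be a 1-D vector with at least 2 samples, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("signal contains non-finite samples")
        if not (self.fs > 0 and np.isfinite(self.fs)):
            raise InvalidInputError(f"sampling rate must be positive and finite, got {self.fs}")
        object.__setattr__(self, "samples", arr)
        object.__setattr__(self, "fs", float(self.fs))

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Duration in seconds (N / fs)."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample instants in seconds."""
        return np.arange(self.samples.size) / self.fs
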