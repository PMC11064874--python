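"""Discrete Stockwell transform (S-transform) and its inverses.

The S-transform maps a length-``N`` real signal onto a complex time-frequency
matrix with rows at frequencies ``f_k = k fs / N`` for ``k = 0 .. N//2`` and one
column per sample.  Row ``k`` is computed with the standard frequency-domain
formulation: the spectrum is shifted by ``k`` bins, multiplied by the sampled
Gaussian ``exp(-2 pi^2 alpha^2 / k^2)`` (the Fourier transform of the
frequency-scaled Gaussian window ``|f|/sqrt(2 pi) * exp(-t^2 f^2 / 2)``), and
inverse transformed.  This is exact for band-limited discrete signals and costs
O(N^2 log N).

Two exact inverses are provided:

``marginal``
    Summing each row over time yields the Fourier coefficient at that
    frequency (the S-transform marginal identity); the signal is recovered by
    inverse FFT.  This inverse depends on the matrix only through its row sums.

``local``
    Column-wise synthesis: each column is demodulated back to its absolute
    frequencies, summed over rows, and the resulting trace is renormalized in
    the Fourier domain by exact per-frequency weights (computed once per ``N``
    from the transform of a unit impulse).  For a consistent matrix this is
    also an exact inverse, but unlike the marginal form it is sensitive to
    *time-local* modifications of the matrix, which is what a time-frequency
    filter needs.  See the methods note for the discussion.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.fft import fft, ifft, irfft

from .core import Signal
from .errors import InvalidInputError

__all__ = [
    "TFR",
    "forward_st",
    "inverse_st",
    "split_mag_phase",
    "combine_mag_phase",
]


@dataclass(frozen=True)
class TFR:
    """Complex time-frequency representation of a real signal.

    ``values`` has shape ``(N//2 + 1, N)``: rows are frequency bins
    ``f_k = k fs / N`` (row 0 is DC), columns are time samples.
    """

    values: np.ndarray
    fs: float
    n_samples: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=complex)
        n = int(self.n_samples)
        if n < 2:
            raise InvalidInputError(f"n_samples must be >= 2, got {n}")
        if arr.shape != (n // 2 + 1, n):
            raise InvalidInputError(
                f"TFR shape {arr.shape} inconsistent with n_samples={n}; "
                f"expected {(n // 2 + 1, n)}"
            )
        if not np.all(np.isfinite(arr)):
            raise InvalidInputError("TFR contains non-finite entries")
        object.__setattr__(self, "values", arr)
        object.__setattr__(self, "fs", float(self.fs))
        object.__setattr__(self, "n_samples", n)

    @property
    def frequencies(self) -> np.ndarray:
        """Row centre frequencies in Hz."""
        return np.arange(self.n_samples // 2 + 1) * self.fs / self.n_samples


def _gaussian_row_windows(n: int) -> np.ndarray:
    # alpha enumerated in FFT (wrapped) order, in integer bins
    return np.fft.fftfreq(n, 1.0 / n)


def _forward_rows(spectrum: np.ndarray, n: int) -> np.ndarray:
    """Rows 1..N//2 of the S-transform from an (already DC-free) spectrum."""
    half = n // 2
    doubled = np.concatenate([spectrum, spectrum])
    alpha = _gaussian_row_windows(n)
    rows = np.empty((half, n), dtype=complex)
    for k in range(1, half + 1):
        gauss = np.exp(-2.0 * np.pi**2 * alpha**2 / k**2)
        rows[k - 1] = ifft(doubled[k : k + n] * gauss)
    return rows


def forward_st(signal: Signal) -> TFR:
    """Forward S-transform of a real signal.

    Row 0 holds the signal mean (the Gaussian window is undefined at f = 0);
    rows ``k >= 1`` follow the FFT formulation described in the module
    docstring, applied to the mean-free signal so the DC content lives only in
    row 0 (the sampled Gaussian has a small but nonzero tail at the shifted
    DC bin otherwise).
    """
    x = signal.samples
    n = x.size
    half = n // 2
    mean = x.mean()
    X = fft(x - mean)
    values = np.empty((half + 1, n), dtype=complex)
    values[0] = mean
    values[1:] = _forward_rows(X, n)
    return TFR(values=values, fs=signal.fs, n_samples=n)


def _diag_sum(values: np.ndarray, n: int) -> np.ndarray:
    """Column synthesis Re sum_k S[k, j] e^{2 pi i k j / N} over all rows.

    Negative-frequency rows are the conjugates of the positive ones (real
    input), so they are folded in with a factor 2; an even-N Nyquist row is
    counted once.
    """
    half = n // 2
    j = np.arange(n)
    phases = np.exp(2j * np.pi * np.outer(np.arange(1, half + 1), j) / n)
    d = 2.0 * np.real(np.sum(values[1:, :] * phases, axis=0))
    if n % 2 == 0:
        d -= np.real(values[half, :] * phases[half - 1, :])
    return d


@lru_cache(maxsize=8)
def _local_ist_weights(n: int) -> np.ndarray:
    """Exact spectral renormalization for the column-synthesis inverse.

    The column synthesis of a consistent S-transform matrix is, in the Fourier
    domain, a diagonal re-weighting ``X_hat[g] = c[g] X[g]``.  The weights are
    obtained exactly by pushing a unit impulse (whose spectrum is all ones)
    through forward transform and column synthesis.
    """
    half = n // 2
    impulse = np.zeros(n)
    impulse[0] = 1.0
    spectrum = fft(impulse - impulse.mean())  # DC-free, matching forward_st
    values = np.empty((half + 1, n), dtype=complex)
    values[0] = 1.0 / n  # mean of the unit impulse
    values[1:] = _forward_rows(spectrum, n)
    c = fft(_diag_sum(values, n)).real.copy()
    c[0] = 1.0  # DC is recovered from row 0 directly, never via c
    c.flags.writeable = False
    return c


def inverse_st(tfr: TFR, method: str = "marginal") -> Signal:
    """Invert a (possibly modified) S-transform matrix back to a signal.

    Parameters
    ----------
    tfr : TFR
    method : {"marginal", "local"}
        ``marginal`` recovers the spectrum from row sums (default); ``local``
        uses renormalized column synthesis.  Both reproduce
        ``inverse_st(forward_st(x)) == x`` to machine precision.
    """
    values = tfr.values
    n = tfr.n_samples
    half = n // 2
    if method == "marginal":
        spectrum = values.sum(axis=1)
        spectrum[0] = values[0, 0] * n
    elif method == "local":
        c = _local_ist_weights(n)
        dhat = fft(_diag_sum(values, n))
        spectrum = np.empty(half + 1, dtype=complex)
        spectrum[1:] = dhat[1 : half + 1] / c[1 : half + 1]
        spectrum[0] = values[0, 0] * n
        if n % 2 == 0:
            spectrum[half] = spectrum[half].real
    else:
        raise InvalidInputError(f"unknown inverse method {method!r}")
    x = irfft(spectrum[: half + 1], n=n)
    return Signal(samples=x, fs=tfr.fs)


def split_mag_phase(tfr: TFR) -> tuple[np.ndarray, np.ndarray]:
    """Split a TFR into its magnitude (>= 0) and phase (in (-pi, pi]) planes.

    Zero entries get phase 0 by convention (``np.angle(0) == 0``).
    """
    return np.abs(tfr.values), np.angle(tfr.values)


def combine_mag_phase(
    magnitude: np.ndarray,
    phase: np.ndarray,
    fs: float,
    n_samples: int,
    clip_negative: bool = True,
) -> TFR:
    """Recombine magnitude and phase planes into a complex TFR.

    Magnitudes must be non-negative; filtering BIMF planes independently and
    summing them can produce small negative magnitudes, which are clipped to
    zero when ``clip_negative`` is set (the minimal correction), otherwise an
    error is raised.
    """
    magnitude = np.asarray(magnitude, dtype=float)
    phase = np.asarray(phase, dtype=float)
    if magnitude.shape != phase.shape:
        raise InvalidInputError(
            f"magnitude shape {magnitude.shape} != phase shape {phase.shape}"
        )
    if np.any(magnitude < 0):
        if not clip_negative:
            raise InvalidInputError("negative magnitude entries and clipping disabled")
        magnitude = np.clip(magnitude, 0.0, None)
    return TFR(values=magnitude * np.exp(1j * phase), fs=fs, n_samples=n_samples)
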