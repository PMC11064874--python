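"""Comparison denoisers: wavelet thresholding and time-domain 1-D NLM.

These are the two standard methods the hybrid scheme is compared against.
They are deliberately conventional: a db4 / level-5 discrete wavelet
decomposition with a soft universal threshold, and the sample-domain
non-local means with the same exponential patch weights as the 2-D filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from ._kernels import nlm1d
from .core import Signal
from .errors import InvalidParameterError
from .nlm import NLMParams, _MAD_TO_STD

__all__ = ["WTConfig", "wt_denoise", "nlm1d_denoise", "estimate_sigma_1d"]


@dataclass(frozen=True)
class WTConfig:
    """Wavelet-threshold baseline settings.

    ``threshold`` overrides the universal rule when set (0 disables
    thresholding entirely, giving perfect reconstruction).
    """

    wavelet: str = "db4"
    level: int = 5
    mode: str = "soft"
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.level < 1:
            raise InvalidParameterError("level must be >= 1")
        if self.mode not in ("soft", "hard"):
            raise InvalidParameterError("mode must be 'soft' or 'hard'")
        if self.threshold is not None and self.threshold < 0:
            raise InvalidParameterError("threshold must be >= 0")


def estimate_sigma_1d(x: np.ndarray, wavelet: str = "db4") -> float:
    """Noise std from the MAD of the finest-scale wavelet detail."""
    _, detail = pywt.dwt(np.asarray(x, dtype=float), wavelet)
    return float(np.median(np.abs(detail - np.median(detail)))) * _MAD_TO_STD


def wt_denoise(signal: Signal, config: WTConfig | None = None) -> Signal:
    """Universal-threshold wavelet denoising (sigma sqrt(2 ln N) on details)."""
    config = config or WTConfig()
    x = signal.samples
    n = x.size
    max_level = pywt.dwt_max_level(n, config.wavelet)
    if config.level > max_level:
        raise InvalidParameterError(
            f"level {config.level} infeasible for length {n} "
            f"with {config.wavelet} (max {max_level})"
        )
    coeffs = pywt.wavedec(x, config.wavelet, level=config.level)
    if config.threshold is not None:
        thr = config.threshold
    else:
        sigma = float(np.median(np.abs(coeffs[-1] - np.median(coeffs[-1])))) * _MAD_TO_STD
        thr = sigma * np.sqrt(2.0 * np.log(n))
    def shrink(c: np.ndarray) -> np.ndarray:
        if config.mode == "soft":
            return np.sign(c) * np.maximum(np.abs(c) - thr, 0.0)
        return np.where(np.abs(c) > thr, c, 0.0)

    den = [coeffs[0]] + [shrink(c) for c in coeffs[1:]]
    out = pywt.waverec(den, config.wavelet)[:n]
    return Signal(samples=out, fs=signal.fs)


def nlm1d_denoise(signal: Signal, params: NLMParams | None = None) -> Signal:
    """Time-domain non-local means with scalar sample indices.

    Patch length is ``2P+1`` (mirror-padded at the edges) and the search
    window ``2Q+1`` samples, truncated at the signal ends.  When neither
    ``lam`` nor ``sigma`` is provided, sigma is estimated from the finest
    wavelet detail and ``lam = 0.5 sigma``.
    """
    x = signal.samples
    n = x.size
    if params is None:
        p = max(1, min(10, (n - 1) // 2))
        params = NLMParams(patch_half_width=p,
                           neighborhood_half_width=max(p, min(300, n - 1)))
    p = params.patch_half_width
    q = params.neighborhood_half_width
    if 2 * p + 1 > n or q > n - 1:
        raise InvalidParameterError(
            f"patch/search sizes (P={p}, Q={q}) too large for length {n}"
        )
    if params.lam is None and params.sigma <= 0:
        params = params.with_sigma(estimate_sigma_1d(x))
    out = nlm1d(np.ascontiguousarray(x), p, q, params.bandwidth)
    return Signal(samples=out, fs=signal.fs)
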