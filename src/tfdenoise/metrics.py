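"""Signal-quality metrics for (reference, estimate) pairs.

All four measures compare a clean reference ``y`` with a denoised estimate
``y_hat`` of equal length M:

* ``snr_db``  = 10 log10( sum y^2 / sum (y - y_hat)^2 )   [dB]
* ``rmse``    = sqrt( mean (y - y_hat)^2 )
* ``prd``     = 100 sqrt( sum (y - y_hat)^2 / sum y^2 )   [%]
* ``ssim``    = (2 mu_x mu_y + C1)(2 cov + C2) /
                ((mu_x^2 + mu_y^2 + C1)(var_x + var_y + C2))

SNR and PRD are linked algebraically: SNR = 40 - 20 log10(PRD).

SSIM is computed in its global single-window form by default, with population
(divide-by-N) moments and C1 = (K1 L)^2, C2 = (K2 L)^2, K1 = 0.01, K2 = 0.03,
L the reference value range.  A windowed mean-SSIM variant is available via
``window``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidInputError, UndefinedMetricError

__all__ = ["MetricsReport", "snr_db", "rmse", "prd", "ssim", "evaluate"]


@dataclass(frozen=True)
class MetricsReport:
    """SNR (dB), RMSE, PRD (%) and SSIM for one (reference, estimate) pair."""

    snr_db: float
    rmse: float
    prd: float
    ssim: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _pair(reference, estimate) -> tuple[np.ndarray, np.ndarray]:
    ref = np.asarray(reference, dtype=float)
    est = np.asarray(estimate, dtype=float)
    if ref.shape != est.shape:
        raise InvalidInputError(f"shape mismatch: {ref.shape} vs {est.shape}")
    if ref.size < 1:
        raise InvalidInputError("empty inputs")
    if not (np.all(np.isfinite(ref)) and np.all(np.isfinite(est))):
        raise InvalidInputError("non-finite values")
    return ref, est


def snr_db(reference, estimate) -> float:
    """Output signal-to-noise ratio in dB; +inf when the estimate is exact."""
    ref, est = _pair(reference, estimate)
    sig = float((ref**2).sum())
    if sig == 0.0:
        raise UndefinedMetricError("SNR undefined for an all-zero reference")
    err = float(((ref - est) ** 2).sum())
    if err == 0.0:
        return float("inf")
    return 10.0 * np.log10(sig / err)


def rmse(reference, estimate) -> float:
    ref, est = _pair(reference, estimate)
    return float(np.sqrt(((ref - est) ** 2).mean()))


def prd(reference, estimate) -> float:
    """Percent root-mean-square difference (distortion, %)."""
    ref, est = _pair(reference, estimate)
    sig = float((ref**2).sum())
    if sig == 0.0:
        raise UndefinedMetricError("PRD undefined for an all-zero reference")
    return 100.0 * float(np.sqrt(((ref - est) ** 2).sum() / sig))


def _global_ssim(x: np.ndarray, y: np.ndarray, c1: float, c2: float) -> float:
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()  # population convention
    cov = ((x - mx) * (y - my)).mean()
    return float(
        ((2 * mx * my + c1) * (2 * cov + c2))
        / ((mx * mx + my * my + c1) * (vx + vy + c2))
    )


def ssim(
    reference,
    estimate,
    k1: float = 0.01,
    k2: float = 0.03,
    L: float | None = None,
    window: int | None = None,
) -> float:
    """Structural similarity index of a vector or plane pair.

    ``L`` defaults to the reference value range; ``window`` switches to the
    mean of local SSIM values over uniform square (or 1-D) windows of that
    size instead of the global single-window statistic.
    """
    ref, est = _pair(reference, estimate)
    if ref.size < 2:
        raise UndefinedMetricError("SSIM needs at least 2 elements")
    if L is None:
        L = float(ref.max() - ref.min())
        if L == 0.0:
            raise UndefinedMetricError(
                "dynamic range of the reference is zero; pass L explicitly"
            )
    if not L > 0:
        raise InvalidInputError("L must be > 0")
    c1, c2 = (k1 * L) ** 2, (k2 * L) ** 2
    if window is None:
        return _global_ssim(ref, est, c1, c2)
    if window < 2:
        raise InvalidInputError("window must be >= 2")
    mean = lambda a: ndimage.uniform_filter(a, size=window, mode="reflect")
    mx, my = mean(ref), mean(est)
    vx = mean(ref**2) - mx**2
    vy = mean(est**2) - my**2
    cov = mean(ref * est) - mx * my
    smap = ((2 * mx * my + c1) * (2 * cov + c2)) / (
        (mx**2 + my**2 + c1) * (vx + vy + c2)
    )
    return float(smap.mean())


def evaluate(reference, estimate, **ssim_kwargs) -> MetricsReport:
    """All four metrics for one pair (SSIM computed on the signals directly)."""
    return MetricsReport(
        snr_db=snr_db(reference, estimate),
        rmse=rmse(reference, estimate),
        prd=prd(reference, estimate),
        ssim=ssim(reference, estimate, **ssim_kwargs),
    )
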