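"""Patch-based non-local means (NLM) filtering of 2-D planes.

The estimate at pixel ``m`` is a weighted average of the pixels ``n`` in a
(2Q+1)^2 search window, with weights

    w(m, n) = exp(-d2(m, n) / (2 L lambda^2)),

where ``d2`` is the sum of squared differences between the (2P+1)^2 patches
centred on ``m`` and ``n`` (``L = (2P+1)^2`` patch samples) and ``lambda`` is
the bandwidth.  When ``lambda`` is left unset it follows the 0.5 sigma rule,
with ``sigma`` the noise standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ._kernels import nlm2d
from .errors import InvalidInputError, InvalidParameterError

__all__ = ["NLMParams", "estimate_sigma", "nlm_denoise"]

#: Laplacian high-pass used by the noise estimator.
_LAPLACIAN = np.array([[0.0, -1.0, 0.0], [-1.0, 4.0, -1.0], [0.0, -1.0, 0.0]])
_LAPLACIAN_NORM = float(np.sqrt((_LAPLACIAN**2).sum()))
#: Gaussian consistency constant: MAD / 0.6745 estimates a normal std.
_MAD_TO_STD = 1.0 / 0.6745


@dataclass(frozen=True)
class NLMParams:
    """Bandwidth, patch and search-window geometry for NLM.

    ``lam`` is the smoothing bandwidth; when ``None`` it resolves to
    ``0.5 * sigma``.  ``patch_half_width`` (P) and ``neighborhood_half_width``
    (Q >= P) control the patch and search-window sizes.
    """

    lam: float | None = None
    patch_half_width: int = 1
    neighborhood_half_width: int = 10
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.patch_half_width < 1:
            raise InvalidParameterError("patch_half_width must be >= 1")
        if self.neighborhood_half_width < self.patch_half_width:
            raise InvalidParameterError(
                "neighborhood_half_width must be >= patch_half_width"
            )
        if self.sigma < 0:
            raise InvalidParameterError("sigma must be >= 0")
        if self.lam is not None and not self.lam > 0:
            raise InvalidParameterError("lam must be > 0 when given")

    @property
    def bandwidth(self) -> float:
        """The effective lambda: explicit value, or 0.5 sigma."""
        lam = self.lam if self.lam is not None else 0.5 * self.sigma
        if not lam > 0:
            raise InvalidParameterError(
                "bandwidth is not positive; set lam or a positive sigma"
            )
        return float(lam)

    def with_sigma(self, sigma: float) -> "NLMParams":
        return replace(self, sigma=float(sigma))


def estimate_sigma(plane: np.ndarray) -> float:
    """Robust pixel-level noise std via the MAD of a Laplacian high-pass.

    The 3x3 Laplacian suppresses smooth structure; for i.i.d. Gaussian noise
    its response has std ``sqrt(20) sigma``, so the median absolute deviation
    is rescaled by ``1/0.6745`` and the filter norm.  A constant plane gives 0.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise InvalidInputError("plane must be 2-D")
    if not np.all(np.isfinite(plane)):
        raise InvalidInputError("plane contains non-finite values")
    resp = ndimage.convolve(plane, _LAPLACIAN, mode="reflect")
    mad = float(np.median(np.abs(resp - np.median(resp))))
    return mad * _MAD_TO_STD / _LAPLACIAN_NORM


def nlm_denoise(plane: np.ndarray, params: NLMParams) -> np.ndarray:
    """NLM-filter a plane; output shape equals input shape.

    Patches are extracted from a mirror-padded plane; search windows are
    truncated at the borders.  The output is a convex combination of input
    values, hence bounded by the input range.
    """
    plane = np.asarray(plane, dtype=float)
    if plane.ndim != 2:
        raise InvalidInputError("plane must be 2-D")
    if not np.all(np.isfinite(plane)):
        raise InvalidInputError("plane contains non-finite values")
    p = params.patch_half_width
    q = params.neighborhood_half_width
    if 2 * p + 1 > min(plane.shape) or q > max(plane.shape) - 1:
        raise InvalidParameterError(
            f"patch/search sizes (P={p}, Q={q}) too large for plane {plane.shape}"
        )
    return nlm2d(np.ascontiguousarray(plane), p, q, params.bandwidth)
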