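import numpy as np
import pytest

from tfdenoise import ECGSpec, NoiseSpec, Signal, add_noise_at_snr, gen_ecg, gen_noise


@pytest.fixture
def rng():
    return np.random.default_rng(20240404)


@pytest.fixture
def small_ecg():
    """A short, cheap ECG fixture (3 s at 120 Hz) for pipeline-level tests."""
    return gen_ecg(ECGSpec(fs=120.0, duration=3.0, seed=7))


@pytest.fixture
def noisy_small_ecg(small_ecg):
    spec = NoiseSpec(kind="gaussian", target_snr_db=5.0, seed=11)
    noise = gen_noise(spec, small_ecg.n_samples, small_ecg.fs)
    noisy, _ = add_noise_at_snr(small_ecg, noise, 5.0)
    return noisy


def brute_force_nlm2d(plane, P, Q, lam):
    """Literal quadruple-loop transcription of the NLM weighted average.

    Mirror-padded patches, border-truncated search windows; the oracle the
    fast kernel must reproduce exactly.
    """
    plane = np.asarray(plane, float)
    rows, cols = plane.shape
    L = (2 * P + 1) ** 2
    pad = np.pad(plane, P, mode="reflect")
    out = np.empty_like(plane)
    for r in range(rows):
        for c in range(cols):
            num = den = 0.0
            for a in range(max(0, r - Q), min(rows, r + Q + 1)):
                for b in range(max(0, c - Q), min(cols, c + Q + 1)):
                    d2 = 0.0
                    for dr in range(-P, P + 1):
                        for dc in range(-P, P + 1):
                            d = pad[r + P + dr, c + P + dc] - pad[a + P + dr, b + P + dc]
                            d2 += d * d
                    w = np.exp(-d2 / (2.0 * L * lam * lam))
                    num += w * plane[a, b]
                    den += w
            out[r, c] = num / den
    return out


def brute_force_nlm1d(x, P, Q, lam):
    """Double-loop transcription of the 1-D sample-domain NLM."""
    x = np.asarray(x, float)
    n = x.size
    L = 2 * P + 1
    pad = np.pad(x, P, mode="reflect")
    out = np.empty_like(x)
    for m in range(n):
        num = den = 0.0
        for a in range(max(0, m - Q), min(n, m + Q + 1)):
            d2 = 0.0
            for d in range(-P, P + 1):
                diff = pad[m + P + d] - pad[a + P + d]
                d2 += diff * diff
            w = np.exp(-d2 / (2.0 * L * lam * lam))
            num += w * x[a]
            den += w
        out[m] = num / den
    return out
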