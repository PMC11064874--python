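"""S-transform: forward correctness against direct quadrature, exact inverses."""

import numpy as np
import pytest
from scipy.fft import fft

from tfdenoise import (
    InvalidInputError,
    Signal,
    TFR,
    combine_mag_phase,
    forward_st,
    inverse_st,
    split_mag_phase,
)


def direct_st_oracle(x, k):
    """Row k of the S-transform by direct time-domain quadrature.

    Independent of the FFT formulation: the frequency-scaled Gaussian window
    g(t, f) = |f|/sqrt(2 pi) exp(-t^2 f^2 / 2) is sampled, periodized over
    many replicas, and the windowed Fourier sum is evaluated literally per
    output column.
    """
    x = np.asarray(x, float)
    n = x.size
    fb = k / n  # cycles per sample
    d = np.arange(-10 * n, 10 * n + 1)
    g = fb / np.sqrt(2 * np.pi) * np.exp(-0.5 * (d * fb) ** 2)
    w_per = np.zeros(n)
    for i, dd in enumerate(d):
        w_per[dd % n] += g[i]
    m = np.arange(n)
    out = np.empty(n, complex)
    for j in range(n):
        out[j] = np.sum(x * np.exp(-2j * np.pi * k * m / n) * w_per[(m - j) % n])
    return out


class TestForward:
    def test_constant_signal_energy_only_at_dc(self):
        sig = Signal(np.full(64, 3.7), fs=64.0)
        tfr = forward_st(sig)
        assert np.all(np.abs(tfr.values[1:]) < 1e-10)
        assert np.allclose(tfr.values[0], 3.7)

    def test_pure_tone_peaks_at_its_bin(self):
        fs, n, f0 = 256.0, 256, 32.0
        t = np.arange(n) / fs
        tfr = forward_st(Signal(np.cos(2 * np.pi * f0 * t), fs))
        k0 = int(f0 * n / fs)
        assert np.all(np.abs(tfr.values).argmax(axis=0) == k0)

    @pytest.mark.parametrize("k", [3, 8, 16, 31])
    def test_agrees_with_direct_quadrature(self, k, rng):
        n = 64
        x = np.cos(2 * np.pi * 5 * np.arange(n) / n) + 0.3 * rng.standard_normal(n)
        tfr = forward_st(Signal(x, float(n)))
        oracle = direct_st_oracle(x, k)
        rel = np.abs(tfr.values[k] - oracle).max() / np.abs(oracle).max()
        assert rel < 1e-6

    def test_linearity(self, rng):
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        a, b = 2.5, -1.25
        lhs = forward_st(Signal(a * x + b * y, 100.0)).values
        rhs = a * forward_st(Signal(x, 100.0)).values + b * forward_st(Signal(y, 100.0)).values
        assert np.abs(lhs - rhs).max() < 1e-10

    def test_marginal_identity_rows_average_to_spectrum(self, rng):
        x = rng.standard_normal(128)
        tfr = forward_st(Signal(x, 128.0))
        spectrum = fft(x)[:65]
        assert np.abs(tfr.values.mean(axis=1) - spectrum / 128).max() < 1e-10

    def test_rejects_bad_inputs(self):
        with pytest.raises(InvalidInputError):
            Signal(np.array([1.0, np.nan, 2.0]), 10.0)
        with pytest.raises(InvalidInputError):
            Signal(np.array([1.0]), 10.0)


class TestInverse:
    @pytest.mark.parametrize("method", ["marginal", "local"])
    @pytest.mark.parametrize("n", [64, 128, 131, 360])
    def test_roundtrip(self, method, n, rng):
        x = rng.standard_normal(n)
        rec = inverse_st(forward_st(Signal(x, float(n))), method=method)
        tol = 1e-8 * max(1.0, np.abs(x).max())
        assert np.abs(rec.samples - x).max() < tol
        assert rec.fs == n

    @pytest.mark.parametrize("method", ["marginal", "local"])
    def test_impulse_roundtrip(self, method):
        x = np.zeros(64)
        x[10] = 1.0
        rec = inverse_st(forward_st(Signal(x, 64.0)), method=method)
        assert np.abs(rec.samples - x).max() < 1e-8

    def test_zero_tfr_gives_zero_signal(self):
        tfr = TFR(np.zeros((33, 64), complex), fs=64.0, n_samples=64)
        assert np.abs(inverse_st(tfr).samples).max() == 0.0

    def test_analytic_single_tone_tfr(self):
        # a matrix carrying only one frequency row, with the row sum equal to
        # the tone's Fourier coefficient, must invert to that tone
        n, k0 = 64, 7
        values = np.zeros((33, 64), complex)
        values[k0] = 0.5  # sum over columns = N/2 = X[k0] of cos
        x = inverse_st(TFR(values, fs=64.0, n_samples=n), method="marginal").samples
        expected = np.cos(2 * np.pi * k0 * np.arange(n) / n)
        assert np.abs(x - expected).max() < 1e-6

    def test_rejects_bad_shape(self):
        with pytest.raises(InvalidInputError):
            TFR(np.zeros((30, 64), complex), fs=64.0, n_samples=64)
        with pytest.raises(InvalidInputError):
            inverse_st(forward_st(Signal(np.zeros(8) + 1, 8.0)), method="bogus")


class TestMagPhase:
    def test_polar_form(self):
        tfr = TFR(np.full((5, 8), 3 + 4j), fs=8.0, n_samples=8)
        mag, phase = split_mag_phase(tfr)
        assert np.allclose(mag, 5.0)
        assert np.allclose(phase, np.arctan2(4, 3))

    def test_zero_entry_convention(self):
        values = np.zeros((5, 8), complex)
        mag, phase = split_mag_phase(TFR(values, fs=8.0, n_samples=8))
        assert mag.sum() == 0.0 and phase.sum() == 0.0

    def test_split_combine_is_identity(self, rng):
        values = rng.standard_normal((17, 32)) + 1j * rng.standard_normal((17, 32))
        tfr = TFR(values, fs=32.0, n_samples=32)
        mag, phase = split_mag_phase(tfr)
        rec = combine_mag_phase(mag, phase, fs=32.0, n_samples=32)
        assert np.abs(rec.values - values).max() < 1e-12

    def test_unit_magnitude_zero_phase(self):
        tfr = combine_mag_phase(np.ones((5, 8)), np.zeros((5, 8)), fs=8.0, n_samples=8)
        assert np.allclose(tfr.values, 1.0)

    def test_negative_magnitude_clipped(self):
        mag = np.ones((5, 8))
        mag[2, 3] = -0.3
        tfr = combine_mag_phase(mag, np.zeros((5, 8)), fs=8.0, n_samples=8)
        assert tfr.values[2, 3] == 0.0
        with pytest.raises(InvalidInputError):
            combine_mag_phase(mag, np.zeros((5, 8)), fs=8.0, n_samples=8, clip_negative=False)

    def test_shape_mismatch(self):
        with pytest.raises(InvalidInputError):
            combine_mag_phase(np.ones((5, 8)), np.zeros((5, 7)), fs=8.0, n_samples=8)
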