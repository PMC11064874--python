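"""Seeded synthetic ECG fixtures and the five additive noise models.

The clean trace is a quasi-periodic sum-of-Gaussians P-QRS-T morphology at a
configurable heart rate (default 60 bpm, 360 Hz, 10 s).  Noise generators
cover power-line interference (60 Hz sinusoid), white Gaussian noise,
low-frequency baseline wander (0.15-0.3 Hz), and band-limited stochastic
surrogates for muscle artifact (20-100 Hz) and electrode-motion transients
(< 5 Hz).  Noise vectors are emitted unscaled; ``add_noise_at_snr`` rescales
them so that the segment-wide input SNR hits the requested level exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import Signal
from .errors import InvalidInputError, InvalidParameterError

__all__ = [
    "ECGSpec",
    "NoiseSpec",
    "NOISE_KINDS",
    "gen_ecg",
    "gen_noise",
    "add_noise_at_snr",
    "add_noise_at_amplitude",
]

NOISE_KINDS = ("pli", "gaussian", "baseline_wander", "muscle_artifact", "electrode_motion")

#: (amplitude mV, centre offset from the R peak in s, Gaussian width in s)
_DEFAULT_MORPHOLOGY: tuple[tuple[float, float, float], ...] = (
    (0.12, -0.200, 0.025),  # P
    (-0.10, -0.035, 0.010),  # Q
    (1.00, 0.000, 0.012),  # R
    (-0.15, 0.035, 0.012),  # S
    (0.30, 0.250, 0.045),  # T
)


@dataclass(frozen=True)
class ECGSpec:
    """Parameters of the synthetic ECG generator."""

    fs: float = 360.0
    duration: float = 10.0
    heart_rate: float = 60.0
    morphology: tuple[tuple[float, float, float], ...] = _DEFAULT_MORPHOLOGY
    jitter_frac: float = 0.03
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fs > 0 and self.duration > 0 and self.heart_rate > 0):
            raise InvalidParameterError("fs, duration and heart_rate must be > 0")
        n = self.fs * self.duration
        if abs(n - round(n)) > 1e-9:
            raise InvalidParameterError(
                f"fs * duration must be an integer number of samples, got {n}"
            )
        if self.jitter_frac < 0:
            raise InvalidParameterError("jitter_frac must be >= 0")
        amps = [m[0] for m in self.morphology]
        if max(amps) != amps[2]:
            raise InvalidParameterError("the R component must have the largest amplitude")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


@dataclass(frozen=True)
class NoiseSpec:
    """One noise realization: kind, target input SNR and seed."""

    kind: str
    target_snr_db: float
    seed: int = 0
    pli_freq: float = 60.0
    bw_freq: float = 0.2
    bw_mode: str = "sinusoid"  # or "random_walk"
    ma_band: tuple[float, float] = (20.0, 100.0)
    em_cutoff: float = 5.0
    em_rate_hz: float = 1.5

    def __post_init__(self) -> None:
        if self.kind not in NOISE_KINDS:
            raise InvalidParameterError(
                f"unknown noise kind {self.kind!r}; expected one of {NOISE_KINDS}"
            )
        if not np.isfinite(self.target_snr_db):
            raise InvalidParameterError("target_snr_db must be finite")
        if not 0.15 <= self.bw_freq <= 0.3:
            raise InvalidParameterError("bw_freq must lie in [0.15, 0.3] Hz")
        if self.bw_mode not in ("sinusoid", "random_walk"):
            raise InvalidParameterError("bw_mode must be 'sinusoid' or 'random_walk'")
        if not 0 < self.ma_band[0] < self.ma_band[1]:
            raise InvalidParameterError("ma_band must be an increasing positive pair")


def gen_ecg(spec: ECGSpec | None = None) -> Signal:
    """Deterministic synthetic ECG: jittered sum-of-Gaussians beats.

    With zero jitter the R peaks are exactly ``fs * 60 / heart_rate`` samples
    apart; the beat-to-beat interval is perturbed by a Gaussian factor of
    relative width ``jitter_frac`` otherwise.
    """
    spec = spec or ECGSpec()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    period = 60.0 / spec.heart_rate
    n_beats = int(np.ceil(spec.duration / period)) + 1
    x = np.zeros(n)
    for i in range(n_beats):
        centre = (i + 0.35) * period
        if spec.jitter_frac > 0:
            centre += period * spec.jitter_frac * rng.standard_normal()
        for amp, offset, width in spec.morphology:
            x += amp * np.exp(-0.5 * ((t - centre - offset) / width) ** 2)
    return Signal(samples=x, fs=spec.fs)


def gen_noise(spec: NoiseSpec, n_samples: int, fs: float) -> np.ndarray:
    """One unscaled noise vector of length ``n_samples`` (see ``add_noise_at_snr``)."""
    if n_samples < 2 or fs <= 0:
        raise InvalidParameterError("need n_samples >= 2 and fs > 0")
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n_samples) / fs
    if spec.kind == "pli":
        phase = rng.uniform(0, 2 * np.pi)
        return np.sin(2 * np.pi * spec.pli_freq * t + phase)
    if spec.kind == "gaussian":
        return rng.standard_normal(n_samples)
    if spec.kind == "baseline_wander":
        if spec.bw_mode == "sinusoid":
            phase = rng.uniform(0, 2 * np.pi)
            return np.sin(2 * np.pi * spec.bw_freq * t + phase)
        walk = np.cumsum(rng.standard_normal(n_samples))
        sos = sps.butter(2, spec.bw_freq * 2, btype="lowpass", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos, walk)
        return out - out.mean()
    if spec.kind == "muscle_artifact":
        white = rng.standard_normal(n_samples)
        sos = sps.butter(4, spec.ma_band, btype="bandpass", fs=fs, output="sos")
        return sps.sosfiltfilt(sos, white)
    if spec.kind == "electrode_motion":
        # sparse signed impulses smoothed into low-frequency steps/ramps
        events = rng.random(n_samples) < spec.em_rate_hz / fs
        impulses = np.where(events, rng.standard_normal(n_samples), 0.0)
        if not impulses.any():  # force at least one transient
            impulses[n_samples // 2] = 1.0
        sos = sps.butter(2, spec.em_cutoff, btype="lowpass", fs=fs, output="sos")
        out = sps.sosfiltfilt(sos, impulses)
        return out - out.mean()
    raise InvalidParameterError(f"unknown noise kind {spec.kind!r}")  # pragma: no cover


def add_noise_at_snr(
    clean: Signal, noise: np.ndarray, target_snr_db: float
) -> tuple[Signal, np.ndarray]:
    """Scale ``noise`` so the mixture hits ``target_snr_db`` exactly.

    The scale is ``alpha = sqrt(P_clean / (P_noise 10^(target/10)))`` so that
    ``10 log10(P_clean / P_scaled) == target_snr_db`` identically.
    Returns the noisy signal and the scaled noise vector.
    """
    noise = np.asarray(noise, dtype=float)
    if noise.shape != clean.samples.shape:
        raise InvalidInputError(
            f"noise length {noise.shape} != signal length {clean.samples.shape}"
        )
    p_clean = float((clean.samples**2).sum())
    p_noise = float((noise**2).sum())
    if p_clean == 0.0:
        raise InvalidInputError("clean signal is all-zero")
    if p_noise == 0.0:
        raise InvalidInputError("noise vector is all-zero")
    alpha = np.sqrt(p_clean / (p_noise * 10.0 ** (target_snr_db / 10.0)))
    scaled = alpha * noise
    return Signal(samples=clean.samples + scaled, fs=clean.fs), scaled


def add_noise_at_amplitude(
    clean: Signal, noise: np.ndarray, peak_frac: float = 0.5
) -> tuple[Signal, np.ndarray]:
    """Amplitude-mode mixing: scale the noise by peak-to-peak ratio.

    The alternative to SNR calibration for interference that is usually
    described by amplitude (power-line interference reaches up to ~50% of the
    ECG peak-to-peak amplitude): the scaled noise's peak-to-peak span equals
    ``peak_frac`` times the clean signal's.
    """
    noise = np.asarray(noise, dtype=float)
    if noise.shape != clean.samples.shape:
        raise InvalidInputError(
            f"noise length {noise.shape} != signal length {clean.samples.shape}"
        )
    if not peak_frac > 0:
        raise InvalidParameterError("peak_frac must be > 0")
    span = float(np.ptp(noise))
    if span == 0.0:
        raise InvalidInputError("noise vector is constant")
    scaled = noise * (peak_frac * float(np.ptp(clean.samples)) / span)
    return Signal(samples=clean.samples + scaled, fs=clean.fs), scaled
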