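# tfdenoise

Hybrid time-frequency denoising of single-channel ECG traces, with the
evaluation metrics, noise-injection protocol and baseline denoisers needed to
study it.

ECG recordings are contaminated by power-line interference (PLI), broadband
Gaussian noise, baseline wander (BW), muscle artifact (MA) and electrode
motion (EM). The scheme implemented here attacks them in the time-frequency
domain:

1. **S-transform (ST)** — the signal `x(t)` is mapped to a complex matrix
   `ST(t, f)` using a frequency-scaled Gaussian window
   `g(t, f) = |f|/√(2π) · exp(−t²f²/2)`, giving progressive (wavelet-like)
   resolution with absolutely referenced phase.
2. **Magnitude/phase split** — only the magnitude `|ST|` is filtered; the
   phase is kept untouched.
3. **BEMD** — bi-dimensional empirical mode decomposition sifts the magnitude
   plane into multi-scale BIMFs plus a residue by subtracting the mean of
   upper/lower envelope surfaces built through the local extrema
   (thin-plate-spline interpolation, or order-statistics envelopes for large
   planes). The decomposition sums back to the input exactly.
4. **NLM** — each BIMF (and the residue) is filtered with patch-based
   non-local means: `ŝ(m) = Σ w(m,n) y(n) / Z(m)` with
   `w(m,n) = exp(−d²(m,n) / (2 L λ²))`, patch half-width `P`, search
   half-width `Q`, and bandwidth `λ = 0.5 σ` by default.
5. The filtered planes are superimposed, clipped at zero, recombined with the
   original phase, and inverted back to the time domain.

Quality is scored with SNR (dB), RMSE, PRD (%) and SSIM.

**A result worth knowing before you use it:** on additive noise this pipeline
is close to a no-op. The dominant corruption of the ST magnitude is a
Rayleigh noise *floor*, and non-local means — a convex combination of plane
values — can reduce speckle variance but cannot remove a floor. The package
implements the scheme faithfully and measures this honestly; see
`docs/methods.md` for the analysis and the oracle experiments that bound what
any convex magnitude filter can achieve here.

## Worked example

```python
import numpy as np
from tfdenoise import (ECGSpec, NoiseSpec, add_noise_at_snr, denoise,
                       evaluate, gen_ecg, gen_noise, nlm1d_denoise)

clean = gen_ecg(ECGSpec(seed=0))                      # 10 s at 360 Hz
noise = gen_noise(NoiseSpec(kind="gaussian", target_snr_db=5.0, seed=1000),
                  clean.n_samples, clean.fs)
noisy, _ = add_noise_at_snr(clean, noise, 5.0)        # input SNR = 5 dB exactly

den, diags = denoise(noisy)
print(evaluate(clean.samples, den.samples).as_dict())
print(evaluate(clean.samples, nlm1d_denoise(noisy).samples).as_dict())
```

prints (seed 0):

```
{'snr_db': 4.79, 'rmse': 0.0976, 'prd': 57.64, 'ssim': 0.839}
{'snr_db': 11.13, 'rmse': 0.0470, 'prd': 27.75, 'ssim': 0.956}
```

The first line is the hybrid scheme: output SNR 4.79 dB against a 5 dB input —
the time-frequency pipeline neither gains nor loses much, for the structural
reason explained in the methods note. The second line is the plain
time-domain 1-D NLM baseline, which does denoise (11.1 dB out). The wavelet
baseline lands in between (~9.7 dB).

## Command line

```sh
tfdenoise generate --out fixtures --noise pli --snr 5 --seed 3
tfdenoise denoise --input fixtures/noisy.csv --fs 360 --out den.csv \
    --reference fixtures/clean.csv
tfdenoise compare --input fixtures/noisy.csv --reference fixtures/clean.csv \
    --fs 360 --out table.csv
tfdenoise experiment --out results --noises gaussian pli --snrs 0 5 10 \
    --n-seeds 5 --seed 1
```

`experiment` writes per-cell metrics (`cells.csv`), mean ± sd aggregates
(`summary.csv`) and a reproducibility log (`experiment.json`).

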