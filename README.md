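# manifolddim

Estimating the intrinsic dimensionality of multi-channel neural population
recordings.

Cortical population activity is highly redundant: the firing of N recorded
channels is largely confined to a manifold of much lower dimension d, the
number of latent degrees of freedom needed to describe the population
state. Knowing d matters for interpreting population codes and for sizing
decoders and latent-variable models — but estimating it from real
recordings is hard, because the latent-to-channel embedding may be
nonlinear and the channels carry independent noise, both of which bias
standard estimators.

`manifolddim` is a toolkit for studying and doing this estimation:

- a **simulator** of multi-channel datasets with known d, controllable
  embedding nonlinearity `f(x) = (e^{αx} − 1)/(e^{α} − 1)`, per-channel
  SNR, and channel-variance heterogeneity;
- **linear estimators** built on the covariance eigenspectrum {λᵢ}:
  PCA with a 90% variance cutoff, the Participation Ratio
  `PR = (Σλᵢ)²/Σλᵢ²`, and Parallel Analysis (eigenvalues against a
  channel-shuffled null, 200 shuffles, 95th percentile);
- **nonlinear estimators** built on local geometry: Correlation Dimension,
  Levina–Bickel maximum likelihood (LBMLE), Two Nearest Neighbors (TNN),
  and Fisher Separability Analysis (FSA);
- **denoisers**: PCA reconstruction and the Joint Autoencoder (JAE) — two
  ReLU autoencoders over a random channel partition trained with the cost
  `C = MSE(X₁, X̂₁) + MSE(X₂, X̂₂) + MSE(Z₁, Z₂)`, whose bottleneck
  agreement term keeps shared signal and rejects channel-independent
  noise;
- the **recommended pipeline**: Parallel-Analysis upper bound → dual
  denoising → reconstruction-VAF comparison (a practical nonlinearity
  detector) → branch-appropriate final estimate;
- a **benchmark harness** with Monte Carlo replication, percentile
  bootstrap CIs, and presets for the noise-free, unequal-variance,
  dimensionality, nonlinearity, data-amount, noise, and denoising
  experiments.

The audience is systems/computational neuroscientists analysing
multi-electrode array data, and anyone benchmarking intrinsic-dimension
estimators on realistic rate-like signals.

## Worked example

```python
from manifolddim import (
    SimulationConfig, simulate_dataset, run_pipeline, PipelineConfig,
)

ds = simulate_dataset(
    SimulationConfig(d=6, M=6000, N=96, alpha=16.0, snr_db=10.0, seed=7)
)
report = run_pipeline(ds.observed, PipelineConfig(seed=1, jae_max_epochs=800))
print(report.branch, report.D_upper, round(report.final_estimate, 2))
```

Running `python examples/04_run_pipeline.py` (the same computation with
commentary) prints:

```
upper bound D:        11
reconstruction VAF:   PCA 0.689   JAE 0.793
branch:               nonlinear
PA / LBMLE / TNN:     5 / 10.85 / 10.53
final estimate:       10.85  (true d = 6)
```

Reading: noise at 10 dB inflates the linear upper bound to 11; the JAE
reconstructs the noisy input clearly better than PCA at the same
bottleneck (0.793 vs 0.689 VAF), flagging a nonlinear manifold; the final
LBMLE estimate on the JAE-denoised signals is 10.9 — still above the true
6 (noise is never removed perfectly) but far below the raw-data estimate
of about 21. The other scripts in `examples/` walk through simulation,
individual estimators, denoiser comparison, and benchmark sweeps.

A thin CLI mirrors the library:

```bash
manifolddim simulate --d 6 --m 6000 --n 96 --alpha 16 --snr-db 10 --seed 1 --out data/
manifolddim estimate --method lbmle --input data/observed.csv
manifolddim pipeline --input data/observed.csv --seed 1 --out report.json
manifolddim sweep --preset noise --n 10 --seed 1 --out results/
```

User-supplied recordings enter as delimited text matrices (samples ×
channels, non-negative binned rates); an empirical firing-rate file can
replace the built-in latent surrogate via `latent_source=`.

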