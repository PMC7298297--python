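# ouosc

Oscillation detection and noise quantification for single-cell
protein-expression time series, plus a stochastic network-motif simulator
linking noise timescale to downstream cell-state switching.

Developmental transcription factors of the Hes/Her family can express
either as ultradian oscillations (periods of 1–2 h) or as aperiodic
fluctuations, and the *dynamic quality* of that noise — how fast it
decorrelates — can itself carry regulatory meaning. This package is for
quantitative biologists analysing live-imaging reporter traces who need
to answer, per cell: is this trace periodic or just noisy, at a stated
false discovery rate? And per condition: how does the noise differ in
timescale, spectral content and variability, and what would those
differences do to a downstream bistable target gene?

## The statistical core

Each detrended, z-scored trace is modelled as a zero-mean Gaussian process
observed with fixed technical noise, under two competing stationary
covariance functions

    K_OU(τ)    = σ² e^(−α_OU |τ|)              (aperiodic)
    K_OUosc(τ) = σ² e^(−α_OUosc |τ|) cos(βτ)   (quasi-periodic, period P = 2π/β)

The per-cell statistic is the log-likelihood ratio
`LLR = 2(LML_OUosc − LML_OU)` of the maximized marginal likelihoods (the
periodic lengthscale carries a SmoothBox1 prior during optimization).
Technical-noise variance is calibrated from background traces recorded
where the fluorophore is absent and held fixed during fitting. A synthetic
aperiodic null — OU traces resampled from the experiment's own fitted
lengthscales, refitted through the identical path — converts LLRs into
q-values, and cells with q ≤ 0.03 are called oscillatory.

Around that core: photobleaching correction, nuclear normalization and GP
detrending (timescales above 3 h); periodogram-based coherence and
high-frequency (> 1.5 cycles/h) noise content; local coefficient of
variation in 1.5 h windows; and a Hill-function repressor→target motif
(forward Euler / Euler–Maruyama) whose switching probability falls as the
repressor's aperiodic lengthscale α_OU grows — inverse stochastic
resonance. A synthetic-data module generates full mock experiments with
known ground truth, so the entire stack is testable without imaging data.

## Worked example

```python
from ouosc import (ExperimentConfig, SyntheticDatasetConfig,
                   make_embryo_dataset, run_pipeline)

dataset = make_embryo_dataset(
    SyntheticDatasetConfig(n_cells=20, frac_oscillatory=0.8, seed=7))
result = run_pipeline(ExperimentConfig(n_sims=200, seed=1), dataset=dataset)
print(result.fits_table[["cell_id", "llr", "q_value", "label", "period_h"]].tail(3))
print("fraction oscillatory:", result.classification.proportion_oscillatory)
```

prints

```
    cell_id        llr  q_value            label  period_h
17  cell017  -7.957584    0.842  non_oscillatory  0.866974
18  cell018   0.190867    0.382  non_oscillatory  1.905303
19  cell019 -16.800703    0.970  non_oscillatory  1.287829
fraction oscillatory: 0.8
```

Cells with large positive LLR (the quasi-periodic model wins by many nats)
get q ≈ 0 and are called oscillatory; cells with negative LLR sit in the
bulk of the aperiodic null. Here the classifier recovers the true 80%
oscillatory fraction, with fitted periods near the generating 1.5 h. The
`examples/` directory has one narrative script per capability
(classification, noise spectra, motif switching, preprocessing/QC).

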