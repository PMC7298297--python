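# Methods

This note documents the models and procedures `ouosc` implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real imaging data.

## The two covariance models

A detrended, z-scored single-cell trace `y(t)` is modelled as a zero-mean
Gaussian process observed through additive technical noise of known
variance `sigma_n^2`:

    y ~ N(0, K + sigma_n^2 I)

with one of two stationary covariance functions:

    K_OU(tau)    = sigma^2 * exp(-alpha_OU * |tau|)                 (aperiodic)
    K_OUosc(tau) = sigma^2 * exp(-alpha_OUosc * |tau|) * cos(beta*tau)  (quasi-periodic)

`alpha` (1/h) is the rate at which temporal autocorrelation decays;
`beta` (rad/h) sets the ultradian period `P = 2*pi/beta`. Because traces
are z-scored before fitting, the prefactor is held at `sigma^2 = 1`; we
interpret it as the signal *variance* so that `K(0)` equals the variance
of the z-scored signal (at `sigma = 1` the variance and standard-deviation
readings of the prefactor coincide).

The oscillation statistic is `LLR = 2*(LML_OUosc - LML_OU)` where `LML`
is the maximized log marginal likelihood. The LLR is not normalized by
trace length; a length-normalized variant would change only the scale of
the statistic, and since both the observed and null statistics share one
trace length, classification is unaffected.

### Fitting

- Multi-start quasi-Newton (L-BFGS-B) on log-parameters with analytic
  gradients; 5 restarts by default, initial points from a Halton sequence
  seeded from a checksum of the trace values, so fitting is bit-reproducible
  without global state.
- Bounds: `alpha` in [1e-2, 1e3] 1/h, period in [0.25, 10] h.
- The quasi-periodic lengthscale carries a SmoothBox1 prior
  `SB1(a) = S(eta*(a-l)) * (1 - S(eta*(a-L)))` with logistic `S`, knees
  `l = 1`, `L = 2` (1/h) and steepness `eta = 5`. The prior is used during
  optimization (MAP) but excluded from the reported LLR, which therefore
  compares data likelihoods only. No prior is placed on `beta` or on the
  aperiodic lengthscale. The knees are read as being on the periodic-
  lengthscale axis in 1/h.
- `sigma_n^2` is calibrated externally (below) and held fixed during
  optimization, never co-estimated: this is what prevents either model
  from explaining fluctuations below the detection limit.
- When the likelihood is flat from the optimum to the upper `alpha` bound
  (white-noise-like data), the estimate is pinned at the bound and a
  warning is raised; the fit is still returned.
- Covariance factorizations add escalating diagonal jitter, starting at
  `1e-6 * sigma^2` and growing tenfold to at most `1e-2 * sigma^2` before
  raising a numerical error. The same policy applies everywhere a kernel
  matrix is factorized (sampling, likelihood, trend estimation).

## Technical-noise calibration

Background traces recorded where the fluorophore is absent measure
autofluorescence plus detector noise. Their detrended pooled variance, on
raw intensity scale, is propagated to the scale of each analysed signal by
dividing by the squared nuclear-channel mean (the ratio step) and the
squared per-cell z-scoring scale; the experiment-level noise variance
handed to the GP models is the median of the per-cell values. A fully
per-cell noise model would be possible but would make the synthetic null
(one refit path per draw) ambiguous; the median is a deliberate,
conservative middle ground.

## FDR classification

The null distribution of the LLR is built from the experiment itself:
each of `n_sims = 1000` draws resamples (with replacement) one cell's
fitted aperiodic parameters, simulates an OU trace on the experiment's
grid, adds calibrated noise, z-scores, and refits both models through the
identical path (including the SmoothBox1 prior). Then

    FDR(t) = Pr_null(LLR >= t) / Pr_obs(LLR >= t)

with the null proportion `pi0` fixed conservatively at 1, monotonized by
a prefix minimum ascending in `t` (the q-value of a cell is the smallest
estimated FDR over thresholds that would still reject it) and capped at 1.
Cells with `q <= 0.03` are called oscillatory. Classification is strictly
per experiment: nothing is pooled across experiments.

## Preprocessing

Order of operations, fixed: bleach correction per channel, reporter/nuclear
ratio, detrending, z-scoring.

- **Bleaching** is modelled multiplicatively (fluorescence loss scales
  with signal): the population-mean intensity is fitted by OLS against
  time and the slope, expressed as a fraction of the fitted t=0 intercept
  per hour, is divided out as `1 - slope*t`. Correction is per channel per
  dataset by default, with explicit per-cell override.
- **Detrending** removes timescales above 3 h with a GP regression using a
  squared-exponential kernel of lengthscale 3 h. The observation-noise
  variance is the trace's high-frequency variance estimate (half the mean
  squared first difference). The kernel variance is 10x a low-frequency
  variance estimate (variance of 3 h-window means, minus the expected
  white-noise leakage `noise_var / n_per_window`): generous enough that
  genuine slow trends are followed essentially fully even at low
  signal-to-noise, while the lengthscale alone decides what counts as
  "slow". If the leakage-corrected slow variance is indistinguishable from
  zero the trend is just the mean — this makes detrending idempotent in
  practice. A cubic-polynomial fallback is available (`method="poly"`).
- **Z-scoring** records its offset and scale so the ratio is exactly
  reconstructable; zero-variance traces raise a degenerate-input error
  rather than silently returning zeros.
- **Z-position** is reported as a Pearson correlation with intensity and
  never used to alter data.

## Spectral statistics

The periodogram is computed on the native DFT grid (no zero padding) as
`S(f_k) = |DFT(x*w)|^2 / (N*Fs)`, window `w` rectangular or Hamming
multiplied in the time domain, reported one-sided. With this normalization
the Riemann sum of the two-sided spectrum over frequency equals the
windowed signal's mean square. The `psd` mode rescales so the one-sided
spectrum trapezoid-integrates to 1, making spectral shape comparable
across cells.

- **Coherence**: a polynomial (order 6, linear power vs linear frequency)
  smooths the aggregate spectrum; the peak is the argmax of the fitted
  curve on the grid; coherence integrates the *true* power over a band of
  total width 10% of the peak frequency, centred on it (full-width
  reading; a +-10% half-width variant is available via `band_fraction`),
  divided by total power. The zero-frequency bin is excluded everywhere.
- **High-frequency contribution**: percentage of the psd-normalized
  spectral area above 1.5 cycles/h (periods shorter than 40 min).

Both statistics are invariant to positive rescaling of the spectrum, so
the power/psd choice is immaterial for them.

## Local COV and kurtosis

LCOV cuts the positive ratio trace into contiguous non-overlapping 1.5 h
windows (trailing partial window dropped; stride-1 overlapping windows
available by flag), takes sd/mean per window and averages the window
values — the mean was chosen as the per-cell reducer. The group statistic
is `median(group A) / median(group B)`. Excess kurtosis uses the plain
bias-uncorrected moment estimator `m4/m2^2 - 3`.

## Synthetic data

The generator emulates paired reporter/nuclear traces sampled every 6 min
(`dt = 0.1 h`) over 12 h: single-cell dynamics drawn from OU
(control-like `alpha_OU = 2` 1/h; mutant-like 15 1/h) or OUosc (period
1.5 h, periodic lengthscale 0.5 1/h) kernels, composed as

    intensity = baseline * (1 - bleach_slope*t) * (1 + trend + signal)

with a sinusoidal slow trend (timescale 8 h, amplitude 0.1, random phase),
relative signal amplitude 0.2, additive white technical noise (sd 6 on a
baseline of 100, i.e. noise variance roughly 10% of reporter signal
variance), and at least two pure-noise background traces per channel.
The nuclear channel carries no ultradian signal, so it doubles as a
negative control. OU traces use the exact discrete-time recursion
`y[k+1] = y[k]*exp(-alpha*dt) + N(0, sigma2*(1-exp(-2*alpha*dt)))`;
OUosc traces use dense-covariance Cholesky sampling (no simple recursion
exists), with the jitter policy above. Kernel parameters are fixed per
condition by default, with an optional log-normal per-cell jitter switch
(`param_jitter_sd`), since the population distribution of single-cell
parameters is not identifiable from the data the generator emulates.

What passing tests on these data show: the estimators recover the
parameters of their own generating models at realistic noise, length and
sampling; the FDR machinery controls false positives against the null it
claims to control. What they do not show: robustness to segmentation and
tracking artefacts, non-Gaussian or multiplicative measurement noise,
cell-cycle-coupled trends, or model misspecification beyond OU/OUosc —
none of which the generator emulates.

## Network-motif model

The downstream target obeys

    dX/dt = G1(Y) + G2(X) - mu*X
    G1(Y) = k1 / (1 + (Y/Y0)^n)       (repression by Y)
    G2(X) = k2 / (1 + (X/X0_X)^-n)    (auto-activation)

with the repressor Y either an exogenous OU sample around a constant
baseline (open loop; exact OU update on the Euler grid) or coupled through

    dY/dt = alpha_OU*Y_in*G3(X) - alpha_OU*Y + sqrt(2*alpha_OU*sigma2)*xi
    G3(X) = 1 / (1 + (X/X0_Y)^n)

integrated by Euler–Maruyama. Defaults: `k1=0.5, k2=10, Y0=7.9, X0_X=0.5,
X0_Y=2.0, n=4, mu=3, sigma2=1.7, Y_in=6.0, dt=0.0015, duration=30` (time
units arbitrary), which place the clamped system at `Y = Y_in` in a
bistable regime (stable states X ≈ 0.158 and 3.457, verified against a
bracketing+bisection fixed-point oracle to 1e-9).

Choices the equations do not fix:

- **Switching criterion**: first crossing of the midpoint of the low and
  high stable fixed points at `Y = Y_in`; no dwell requirement. When
  de-repression removes the low state entirely, the midpoint between the
  auto-activation-free level `G1(Y_in)/mu` and the high state is used, so
  a certain switch still registers.
- **Negative Y** is clipped to 0 inside `G1` (with even Hill coefficient a
  negative excursion would otherwise increase repression spuriously).
- **Initial conditions**: `X(0) = 0` (off state); `Y(0)` is a stationary
  draw around `Y_in` in both variants.
- Replicates are vectorized across one RNG stream; probabilities carry a
  Jeffreys binomial confidence interval.

## Problem sizes and determinism

Default analysis sizes: 120-point traces, 1000 null refits and 200
observed cells for false-positive-rate checks, 50 replicates per condition
for recovery medians, 100 replicates per lengthscale for switching curves.
These sizes put every Monte-Carlo standard error comfortably inside the
tolerances asserted in the test suite. Every stochastic routine takes an
explicit seed; the pipeline splits one master seed per stage, and repeated
runs are byte-identical.

## Known limitations

- The GP machinery is dense (O(n^3) per likelihood evaluation); adequate
  for hundreds of points, not for thousands. A state-space OU
  representation would scale linearly but is not implemented.
- The experiment-level (median) noise scale understates per-cell noise for
  dim cells and overstates it for bright ones.
- Coherence depends on the polynomial order and band convention near flat
  spectra; it is a population-level, qualitative measure and is treated as
  such.
- The z-scoring/fixed-variance convention means the model marginal
  variance (`1 + sigma_n^2`) slightly exceeds the data variance (1); this
  inflates fitted lengthscales mildly at short trace lengths (the bias
  shrinks with length, as the tests verify), and affects both observed and
  null statistics identically.
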