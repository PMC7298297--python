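"""Synthetic single-cell imaging datasets with known ground truth.

Emulates paired reporter ("venus") and nuclear-marker ("h2b") intensity
traces as acquired in ultradian live-imaging experiments: samples every
6 min over 10-12 h, linear photobleaching per channel, slow long-term
trends, additive technical white noise calibrated from background regions,
and single-cell dynamics drawn from either the aperiodic OU or the
quasi-periodic OUosc covariance model.

The generator is the ground-truth side of every downstream test: the
oscillatory fraction, the per-cell kernel parameters and the injected
noise level are all recorded in the returned :class:`SyntheticDataset`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from .kernels import OUParams, OUoscParams, cov_matrix, jittered_cholesky
from .trace import TimeGrid, Trace

__all__ = [
    "SyntheticDatasetConfig",
    "SyntheticDataset",
    "sample_ou_trace",
    "sample_ouosc_trace",
    "sample_ouosc_trace_dense",
    "add_technical_noise",
    "add_trend_and_bleach",
    "make_embryo_dataset",
]


def sample_ou_trace(params: OUParams, grid: TimeGrid, seed: int) -> Trace:
    """Draw a stationary zero-mean OU trace on a uniform grid.

    Uses the exact discrete-time update
    ``y[k+1] = y[k] * exp(-alpha*dt) + N(0, sigma2 * (1 - exp(-2*alpha*dt)))``
    started from the stationary marginal ``N(0, sigma2)``, so the sample path
    has exactly the OU autocovariance at every lag regardless of ``dt``.
    """
    rng = np.random.default_rng(seed)
    rho = np.exp(-params.alpha_ou * grid.dt)
    innov_sd = np.sqrt(params.sigma2 * (1.0 - rho**2))
    y = np.empty(grid.n)
    y[0] = rng.normal(0.0, np.sqrt(params.sigma2))
    shocks = rng.normal(0.0, innov_sd, size=grid.n - 1)
    for k in range(grid.n - 1):
        y[k + 1] = rho * y[k] + shocks[k]
    return Trace(cell_id="ou", channel="signal", times=grid.times, values=y)


def sample_ouosc_trace_dense(params, grid: TimeGrid, seed: int) -> Trace:
    """Draw a zero-mean Gaussian trace from a dense covariance matrix.

    Works for both OU and OUosc parameters; the OUosc kernel has no simple
    Markov recursion, so the covariance matrix is built on the grid and
    factorized with escalating diagonal jitter.
    """
    rng = np.random.default_rng(seed)
    K = cov_matrix(grid.times, params)
    L = jittered_cholesky(K, scale=params.sigma2)
    y = L @ rng.standard_normal(grid.n)
    return Trace(cell_id="ouosc", channel="signal", times=grid.times, values=y)


def sample_ouosc_trace(params: OUoscParams, grid: TimeGrid, seed: int) -> Trace:
    """Draw a stationary zero-mean quasi-periodic (OUosc) trace."""
    return sample_ouosc_trace_dense(params, grid, seed)


def add_technical_noise(trace: Trace, noise_sd: float, seed: int) -> Trace:
    """Add i.i.d. Gaussian measurement noise of standard deviation ``noise_sd``.

    Emulates technical noise (autofluorescence + detector noise) whose
    variance is what the calibration-from-background step later recovers.
    ``noise_sd = 0`` returns the input unchanged.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    if noise_sd == 0:
        return trace
    rng = np.random.default_rng(seed)
    return trace.with_values(trace.values + rng.normal(0.0, noise_sd, size=len(trace)))


def add_trend_and_bleach(
    trace: Trace,
    trend_amplitude: float,
    trend_timescale: float,
    bleach_slope: float,
    baseline: float,
    seed: int = 0,
    trend_phase: Optional[float] = None,
) -> Trace:
    """Wrap a dimensionless signal in baseline, slow trend and photobleaching.

    The composition order is fixed:

        ``out(t) = baseline * (1 - bleach_slope * t) * (1 + trend(t) + signal(t))``

    with ``trend(t) = trend_amplitude * sin(2*pi*t/trend_timescale + phase)``.
    Bleaching is multiplicative on the baseline (fluorescence loss scales
    with signal); the trend sits above the 3 h detrending cutoff so the
    preprocessing stage can remove it.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if trend_timescale <= 3.0:
        raise ValueError("trend_timescale must exceed the 3 h detrending cutoff")
    t = trace.times - trace.times[0]
    decay = 1.0 - bleach_slope * t
    if np.any(decay <= 0):
        raise ValueError("bleach_slope too strong: decay factor reaches zero in the window")
    if trend_phase is None:
        trend_phase = float(np.random.default_rng(seed).uniform(0, 2 * np.pi))
    trend = trend_amplitude * np.sin(2 * np.pi * t / trend_timescale + trend_phase)
    out = baseline * decay * (1.0 + trend + trace.values)
    if np.any(out < 0):
        raise ValueError("composition produced negative intensities")
    return trace.with_values(out)


@dataclass
class SyntheticDatasetConfig:
    """Study conditions for one mock "embryo" experiment.

    Defaults emulate a control-like condition: 6-min sampling over 12 h,
    oscillators with a 1.5 h ultradian period, aperiodic cells with
    lengthscale 2 /h, baseline intensities around 100 a.u. with a relative
    signal amplitude of 0.2 and background noise at sd 6 a.u. (noise
    variance roughly 10% of the signal variance in the reporter channel).
    """

    n_cells: int = 50
    frac_oscillatory: float = 0.8
    ou: OUParams = field(default_factory=lambda: OUParams(alpha_ou=2.0, sigma2=1.0))
    ouosc: OUoscParams = field(
        default_factory=lambda: OUoscParams(alpha_ouosc=0.5, beta=2 * np.pi / 1.5, sigma2=1.0)
    )
    grid: TimeGrid = field(default_factory=lambda: TimeGrid(t0=0.0, dt=0.1, n=121))
    noise_sd: float = 6.0
    h2b_noise_sd: float = 3.0
    venus_baseline: float = 100.0
    h2b_baseline: float = 100.0
    signal_amplitude: float = 0.2
    venus_bleach_slope: float = 0.002
    h2b_bleach_slope: float = 0.02
    trend_amplitude: float = 0.1
    trend_timescale: float = 8.0
    n_background: int = 2
    param_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_oscillatory <= 1.0:
            raise ValueError("frac_oscillatory must lie in [0, 1]")
        if self.noise_sd < 0 or self.h2b_noise_sd < 0:
            raise ValueError("noise sd must be non-negative")
        if self.n_background < 2:
            raise ValueError("need at least 2 background traces per channel")
        if self.n_cells < 1:
            raise ValueError("n_cells must be positive")


@dataclass
class SyntheticDataset:
    """Mock experiment: paired traces, backgrounds and ground truth."""

    config: SyntheticDatasetConfig
    venus: List[Trace]
    h2b: List[Trace]
    backgrounds: dict  # channel -> list of Trace
    labels: List[str]  # per cell: "oscillatory" | "aperiodic"
    true_params: List[object]  # per cell: OUParams | OUoscParams

    @property
    def n_cells(self) -> int:
        return len(self.venus)

    def all_traces(self) -> List[Trace]:
        out = list(self.venus) + list(self.h2b)
        for traces in self.backgrounds.values():
            out.extend(traces)
        return out


def _jittered(params, factor: float):
    """Per-cell log-normal jitter of the lengthscale (optional population spread)."""
    if isinstance(params, OUParams):
        return OUParams(alpha_ou=params.alpha_ou * factor, sigma2=params.sigma2)
    return OUoscParams(
        alpha_ouosc=params.alpha_ouosc * factor, beta=params.beta, sigma2=params.sigma2
    )


def make_embryo_dataset(config: SyntheticDatasetConfig) -> SyntheticDataset:
    """Generate one full mock experiment with ground-truth labels.

    The configured fraction of cells carries OUosc reporter dynamics and the
    rest OU dynamics; the nuclear channel carries only baseline, trend,
    bleach and noise (no ultradian signal) and therefore doubles as the
    negative-control channel.  Background traces are pure Gaussian white
    noise at the per-channel noise sd.  Fully deterministic under
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    n_osc = int(round(config.frac_oscillatory * config.n_cells))
    labels = ["oscillatory"] * n_osc + ["aperiodic"] * (config.n_cells - n_osc)

    venus, h2b, true_params = [], [], []
    for i, label in enumerate(labels):
        cell = f"cell{i:03d}"
        base = config.ouosc if label == "oscillatory" else config.ou
        factor = (
            float(np.exp(rng.normal(0.0, config.param_jitter_sd)))
            if config.param_jitter_sd > 0
            else 1.0
        )
        params = _jittered(base, factor)
        true_params.append(params)

        seed_sig, seed_vn, seed_hn, seed_vt, seed_ht = rng.integers(0, 2**31 - 1, size=5)
        if label == "oscillatory":
            sig = sample_ouosc_trace(params, grid, int(seed_sig))
        else:
            sig = sample_ou_trace(params, grid, int(seed_sig))
        sig = sig.with_values(config.signal_amplitude * sig.values)

        v = add_trend_and_bleach(
            sig,
            config.trend_amplitude,
            config.trend_timescale,
            config.venus_bleach_slope,
            config.venus_baseline,
            seed=int(seed_vt),
        )
        v = add_technical_noise(v, config.noise_sd, int(seed_vn))
        v.cell_id, v.channel = cell, "venus"

        flat = Trace(cell_id=cell, channel="h2b", times=grid.times, values=np.zeros(grid.n))
        h = add_trend_and_bleach(
            flat,
            config.trend_amplitude,
            config.trend_timescale,
            config.h2b_bleach_slope,
            config.h2b_baseline,
            seed=int(seed_ht),
        )
        h = add_technical_noise(h, config.h2b_noise_sd, int(seed_hn))
        h.cell_id, h.channel = cell, "h2b"

        venus.append(v)
        h2b.append(h)

    backgrounds = {"venus_background": [], "h2b_background": []}
    for j in range(config.n_background):
        for channel, sd in (
            ("venus_background", config.noise_sd),
            ("h2b_background", config.h2b_noise_sd),
        ):
            vals = rng.normal(0.0, sd, size=grid.n) if sd > 0 else np.zeros(grid.n)
            backgrounds[channel].append(
                Trace(cell_id=f"bg{j:02d}", channel=channel, times=grid.times, values=vals)
            )

    return SyntheticDataset(
        config=config,
        venus=venus,
        h2b=h2b,
        backgrounds=backgrounds,
        labels=labels,
        true_params=true_params,
    )
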