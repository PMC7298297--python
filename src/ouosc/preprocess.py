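"""Raw two-channel traces -> detrended, z-scored signals.

The preprocessing chain mirrors standard practice for quantitative
live-imaging intensity traces:

1. estimate per-channel linear photobleaching from the population mean and
   divide it out,
2. normalize the reporter to the nuclear marker (removes global
   concentration fluctuations shared by both channels),
3. remove slow trends (timescales above 3 h) with a squared-exponential
   Gaussian-process regression, and
4. z-score the residual so the covariance-model variance is 1.

Z-position is only ever reported as a QC correlation; it is never used to
alter the data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
from scipy.linalg import cho_factor, cho_solve

from .trace import Trace

__all__ = [
    "DegenerateTraceError",
    "PreprocessedTrace",
    "estimate_bleach_slope",
    "correct_bleaching",
    "normalize_to_nuclear",
    "detrend",
    "qc_z_correlation",
    "preprocess_pair",
    "preprocess_dataset",
]

#: detrending cutoff (h): fluctuations slower than this go into the trend
DEFAULT_CUTOFF = 3.0


class DegenerateTraceError(ValueError):
    """Raised when a trace has no variance left to analyse (z-scoring impossible)."""


@dataclass
class PreprocessedTrace:
    """Detrended, z-scored ratio signal with full affine bookkeeping.

    The original ratio is reconstructed exactly as
    ``ratio = trend + mean_offset + scale * detrended``.
    """

    cell_id: str
    ratio: Trace
    trend: np.ndarray
    detrended: Trace
    mean_offset: float
    scale: float
    bleach_slopes: dict

    def reconstruct_ratio(self) -> np.ndarray:
        return self.trend + self.mean_offset + self.scale * self.detrended.values


def estimate_bleach_slope(traces: List[Trace]) -> float:
    """Linear photobleaching rate of one channel (fraction of t=0 intensity per h).

    Ordinary least squares through the population-mean intensity versus
    time; the slope is divided by the fitted t=0 intercept so the result is
    a fractional decay rate, positive when intensity is falling.
    """
    if not traces:
        raise ValueError("need at least one trace to estimate bleaching")
    t0 = traces[0].times
    for tr in traces[1:]:
        if len(tr) != len(t0) or not np.allclose(tr.times, t0):
            raise ValueError("all traces must share one time grid")
    mean_intensity = np.mean([tr.values for tr in traces], axis=0)
    t = t0 - t0[0]
    b, a = np.polyfit(t, mean_intensity, 1)
    if abs(a) < 1e-12:
        raise ValueError("fitted t=0 intercept is zero; cannot express fractional decay")
    return float(-b / a)


def correct_bleaching(trace: Trace, slope: float) -> Trace:
    """Divide out the normalized linear decay ``1 - slope * t``.

    Exact algebraic inverse of multiplicative linear bleaching; ``slope=0``
    is the identity.
    """
    if slope == 0:
        return trace
    t = trace.times - trace.times[0]
    decay = 1.0 - slope * t
    if np.any(decay <= 0):
        raise ValueError(
            f"decay factor reaches {decay.min():.3g} <= 0 within the trace; "
            "bleach slope too strong for this duration"
        )
    return trace.with_values(trace.values / decay)


def normalize_to_nuclear(venus: Trace, h2b: Trace) -> Trace:
    """Pointwise reporter/nuclear ratio, cancelling shared global fluctuations."""
    if len(venus) != len(h2b) or not np.allclose(venus.times, h2b.times):
        raise ValueError("venus and h2b traces must share one time grid")
    bad = np.nonzero(h2b.values <= 0)[0]
    if bad.size:
        raise ValueError(
            f"non-positive nuclear intensity at t={h2b.times[bad[0]]:.3f} h "
            f"(cell {h2b.cell_id}); cannot form ratio"
        )
    out = venus.with_values(venus.values / h2b.values, channel="ratio")
    return out


def _se_trend(times: np.ndarray, values: np.ndarray, lengthscale: float) -> np.ndarray:
    """GP-regression posterior mean with a squared-exponential kernel.

    The observation-noise variance is the trace's high-frequency variance
    estimate (half the mean squared first difference), which keeps fast
    fluctuations out of the trend.  The kernel variance is a low-frequency
    variance estimate (variance of cutoff-length window means), so a trace
    with no slow content gets an almost-zero trend and detrending is
    nearly idempotent.
    """
    y = values - values.mean()
    var = float(np.var(y))
    if var == 0.0:
        return np.full_like(values, values.mean())
    noise_var = 0.5 * float(np.mean(np.diff(y) ** 2))
    # floor keeps the smoother from interpolating noiseless smooth inputs
    noise_var = max(noise_var, 1e-8 * var)
    span = times[-1] - times[0]
    n_win = max(int(span // lengthscale), 2)
    edges = np.linspace(times[0], times[-1] + 1e-12, n_win + 1)
    means, counts = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (times >= lo) & (times < hi)
        if np.any(sel):
            means.append(y[sel].mean())
            counts.append(int(sel.sum()))
    # window means of pure fast noise have variance ~ noise_var / n_per_window;
    # subtract that leakage so an already-detrended trace gets ~zero trend
    leak = noise_var / float(np.mean(counts))
    slow_var = float(np.var(means)) - leak
    if slow_var < 0.5 * leak:
        # no detectable slow content: the trend is just the mean
        return np.full_like(values, values.mean())
    # generous prior amplitude: capture is governed by the lengthscale, and a
    # kernel variance well above the slow-content estimate makes the smoother
    # follow genuine trends fully even at low signal-to-noise
    kern_var = max(10.0 * slow_var, 1e-6 * var)
    d2 = (times[:, None] - times[None, :]) ** 2
    K = kern_var * np.exp(-0.5 * d2 / lengthscale**2)
    C = K + noise_var * np.eye(len(times))
    alpha = cho_solve(cho_factor(C, lower=True), y)
    return values.mean() + K @ alpha


def _poly_trend(times: np.ndarray, values: np.ndarray, order: int = 3) -> np.ndarray:
    t = times - times[0]
    return np.polyval(np.polyfit(t, values, order), t)


def detrend(
    trace: Trace, cutoff: float = DEFAULT_CUTOFF, method: str = "gp"
) -> Tuple[Trace, Trace, float, float]:
    """Split a trace into slow trend and z-scored fast residual.

    Returns ``(detrended, trend, mean_offset, scale)`` where the residual
    satisfies mean 0, sd 1 and ``trace = trend + mean_offset + scale * detrended``.

    Parameters
    ----------
    cutoff:
        Trend timescale boundary in hours (squared-exponential lengthscale).
    method:
        ``"gp"`` (default) or ``"poly"`` for a cubic-polynomial fallback.
    """
    if trace.duration <= cutoff:
        raise ValueError(
            f"trace duration {trace.duration:.2f} h must exceed the {cutoff:g} h cutoff"
        )
    if method == "gp":
        trend_vals = _se_trend(trace.times, trace.values, cutoff)
    elif method == "poly":
        trend_vals = _poly_trend(trace.times, trace.values)
    else:
        raise ValueError(f"unknown detrending method {method!r}")
    resid = trace.values - trend_vals
    mu = float(resid.mean())
    sd = float(resid.std())
    if sd < 1e-12:
        raise DegenerateTraceError(
            f"trace {trace.cell_id} has no residual variance after detrending"
        )
    z = (resid - mu) / sd
    detrended = trace.with_values(z, channel="detrended")
    trend = trace.with_values(trend_vals, channel="trend")
    return detrended, trend, mu, sd


def qc_z_correlation(trace: Trace) -> float:
    """Pearson correlation between intensity and imaging depth.

    Purely diagnostic (no z-correction is ever applied).  Returns NaN with
    a warning for constant intensity or constant depth.
    """
    if trace.z_position is None:
        raise ValueError(f"trace {trace.cell_id} has no z_position record")
    x, z = trace.values, trace.z_position
    if np.std(x) == 0 or np.std(z) == 0:
        warnings.warn(
            f"z-correlation undefined for trace {trace.cell_id} (zero variance)",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, z)[0, 1])


def preprocess_pair(
    venus: Trace,
    h2b: Trace,
    venus_slope: float,
    h2b_slope: float,
    cutoff: float = DEFAULT_CUTOFF,
    method: str = "gp",
) -> PreprocessedTrace:
    """Full chain for one cell: bleach-correct both channels, ratio, detrend, z-score."""
    v = correct_bleaching(venus, venus_slope)
    h = correct_bleaching(h2b, h2b_slope)
    ratio = normalize_to_nuclear(v, h)
    detrended, trend, mu, sd = detrend(ratio, cutoff=cutoff, method=method)
    return PreprocessedTrace(
        cell_id=venus.cell_id,
        ratio=ratio,
        trend=trend.values,
        detrended=detrended,
        mean_offset=mu,
        scale=sd,
        bleach_slopes={"venus": venus_slope, "h2b": h2b_slope},
    )


def preprocess_dataset(
    venus: List[Trace],
    h2b: List[Trace],
    cutoff: float = DEFAULT_CUTOFF,
    method: str = "gp",
    venus_slope: Optional[float] = None,
    h2b_slope: Optional[float] = None,
) -> Tuple[List[PreprocessedTrace], dict]:
    """Preprocess one experiment: shared per-channel bleach slopes, then per-cell chain.

    Bleach slopes are estimated once per channel from the population mean
    (override by passing them explicitly, e.g. for per-cell correction).
    """
    if len(venus) != len(h2b):
        raise ValueError("need one h2b trace per venus trace")
    if venus_slope is None:
        venus_slope = estimate_bleach_slope(venus)
    if h2b_slope is None:
        h2b_slope = estimate_bleach_slope(h2b)
    out = [
        preprocess_pair(v, h, venus_slope, h2b_slope, cutoff=cutoff, method=method)
        for v, h in zip(venus, h2b)
    ]
    return out, {"venus": venus_slope, "h2b": h2b_slope}
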