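"""Snapshot-style expression-noise statistics.

Local coefficient of variation (LCOV) measures variability around the mean
in short windows (1.5 h by default), so slow drifts in level do not inflate
the estimate; the per-condition comparison statistic is the ratio of group
median LCOVs.  Excess kurtosis of level distributions quantifies
heterogeneity: zero for a normal distribution, positive for heavy-tailed
(e.g. bimodal-high) snapshot distributions.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .trace import Trace

__all__ = ["local_cov", "lcov_ratio", "excess_kurtosis", "DEFAULT_LCOV_WINDOW"]

DEFAULT_LCOV_WINDOW = 1.5  # hours


def local_cov(trace: Trace, window: float = DEFAULT_LCOV_WINDOW, overlapping: bool = False) -> float:
    """Local coefficient of variation of a (positive-mean) ratio trace.

    The trace is cut into windows of the stated duration (contiguous and
    non-overlapping by default; ``overlapping=True`` slides by one sample);
    each window contributes sd/mean, and the per-cell LCOV is the mean of
    the window values.  A trailing partial window is dropped.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    if trace.duration < window:
        raise ValueError(
            f"trace duration {trace.duration:.2f} h shorter than window {window:g} h"
        )
    w = int(round(window / trace.dt))
    w = max(w, 2)
    starts = range(0, len(trace) - w + 1, 1 if overlapping else w)
    covs = []
    for s in starts:
        chunk = trace.values[s : s + w]
        m = chunk.mean()
        if m <= 0:
            raise ValueError(
                f"non-positive window mean at t={trace.times[s]:.2f} h in trace {trace.cell_id}"
            )
        covs.append(chunk.std(ddof=1) / m)
    return float(np.mean(covs))


def lcov_ratio(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """median(group_a) / median(group_b), e.g. mutant over control LCOVs."""
    a, b = np.asarray(group_a, dtype=float), np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    mb = float(np.median(b))
    if mb == 0:
        raise ValueError("denominator group has zero median LCOV")
    return float(np.median(a)) / mb


def excess_kurtosis(values: Sequence[float]) -> float:
    """Sample excess kurtosis (fourth standardized moment minus 3).

    Bias-uncorrected moment estimator: 0 for a normal distribution,
    negative for light tails (uniform: -1.2; symmetric two-point: -2).
    """
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for kurtosis")
    m2 = float(np.mean((x - x.mean()) ** 2))
    if m2 == 0:
        raise ValueError("zero variance: kurtosis undefined")
    m4 = float(np.mean((x - x.mean()) ** 4))
    return m4 / m2**2 - 3.0
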