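"""Core time-series containers.

A :class:`Trace` is one uniformly sampled single-cell intensity time
series.  Times are in hours everywhere in this package; rates and
lengthscales are per hour and angular frequencies are rad/h.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["TimeGrid", "Trace"]

#: maximum relative deviation from uniform spacing tolerated in a Trace
_UNIFORMITY_RTOL = 1e-6


@dataclass(frozen=True)
class TimeGrid:
    """Uniform sampling grid: ``n`` samples starting at ``t0`` spaced ``dt`` (h)."""

    t0: float = 0.0
    dt: float = 0.1
    n: int = 121

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.n < 2:
            raise ValueError(f"need at least 2 samples, got n={self.n}")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.n)

    @property
    def duration(self) -> float:
        """Span from first to last sample (h)."""
        return self.dt * (self.n - 1)

    @property
    def fs(self) -> float:
        """Sampling frequency (1/h)."""
        return 1.0 / self.dt


def _check_uniform(times: np.ndarray) -> float:
    """Return the grid step, raising if spacing is not uniform."""
    diffs = np.diff(times)
    if np.any(diffs <= 0):
        raise ValueError("times must be strictly increasing")
    dt = float(np.mean(diffs))
    if np.max(np.abs(diffs - dt)) > _UNIFORMITY_RTOL * dt:
        raise ValueError("times must be uniformly spaced")
    return dt


@dataclass
class Trace:
    """One single-cell intensity time series.

    Parameters
    ----------
    cell_id:
        Identifier of the tracked cell (or background region).
    channel:
        One of ``venus``, ``h2b``, ``venus_background``, ``h2b_background``
        (other labels are accepted for derived signals, e.g. ``ratio``).
    times:
        Uniformly spaced time points in hours.
    values:
        Intensity values (arbitrary units), finite.
    z_position:
        Optional imaging depth (um) per time point, used only for QC.
    """

    cell_id: str
    channel: str
    times: np.ndarray
    values: np.ndarray
    z_position: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise ValueError("a trace needs at least 2 samples")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite values in trace {self.cell_id}/{self.channel}")
        _check_uniform(self.times)
        if self.z_position is not None:
            self.z_position = np.asarray(self.z_position, dtype=float)
            if self.z_position.shape != self.times.shape:
                raise ValueError("z_position must match times in length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    @property
    def grid(self) -> TimeGrid:
        return TimeGrid(t0=float(self.times[0]), dt=self.dt, n=len(self.times))

    def with_values(self, values: np.ndarray, channel: Optional[str] = None) -> "Trace":
        """Copy of this trace carrying new values (and optionally a new channel)."""
        return replace(
            self,
            values=np.asarray(values, dtype=float),
            channel=self.channel if channel is None else channel,
        )
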