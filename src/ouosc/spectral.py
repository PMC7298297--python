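"""Periodogram reconstruction, coherence and high-frequency noise content.

The single-cell periodogram is computed on the native DFT grid
``f_k = k * Fs / N`` as

    ``S(f_k) = (1 / (N * Fs)) * |sum_n x(n) w(n) exp(-2*pi*i*f_k*n/Fs)|^2``

with the window ``w`` multiplied onto the detrended signal in the time
domain (rectangular or Hamming).  With this normalization the Riemann sum
of the two-sided spectrum over frequency equals the windowed signal's mean
square (discrete Parseval identity).  Spectra are reported one-sided.

Two derived statistics summarize spectral shape:

* coherence — the percentage of total power inside a narrow band centred
  on the dominant frequency of a polynomial-smoothed aggregate spectrum;
  high for coherent oscillator populations.
* high-frequency contribution — the percentage of a variance-normalized
  single-cell spectrum lying above 1.5 cycles/h (periods shorter than
  40 min), a measure of high-frequency noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .trace import Trace

__all__ = [
    "Spectrum",
    "periodogram",
    "aggregate_spectrum",
    "coherence",
    "high_freq_contribution",
    "DEFAULT_HF_CUTOFF",
]

#: boundary between ultradian and high-frequency ranges (cycles/h; 40 min period)
DEFAULT_HF_CUTOFF = 1.5


@dataclass
class Spectrum:
    """One-sided periodogram on the native DFT grid."""

    freqs: np.ndarray  # cycles/h, ascending, <= fs/2
    power: np.ndarray
    normalization: str  # "power" | "psd"
    window: str  # "rectangular" | "hamming"
    fs: float  # sampling frequency (1/h)
    n: int  # original trace length

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.freqs.shape != self.power.shape:
            raise ValueError("freqs and power must have equal length")
        if np.any(self.freqs < 0) or np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be non-negative and ascending")
        if self.freqs[-1] > self.fs / 2 * (1 + 1e-12):
            raise ValueError("freqs must not exceed the Nyquist frequency")
        if np.any(self.power < -1e-15):
            raise ValueError("power must be non-negative")

    @property
    def nyquist(self) -> float:
        return self.fs / 2.0


def _window(name: str, n: int) -> np.ndarray:
    if name == "rectangular":
        return np.ones(n)
    if name == "hamming":
        return np.hamming(n)
    raise ValueError(f"unknown window {name!r} (use 'rectangular' or 'hamming')")


def periodogram(
    trace: Trace, window: str = "rectangular", normalization: str = "power"
) -> Spectrum:
    """One-sided periodogram of a detrended trace.

    ``normalization="power"`` keeps the raw periodogram units;
    ``"psd"`` rescales so the one-sided spectrum trapezoid-integrates to 1,
    making spectral *shape* comparable across cells irrespective of
    amplitude.  No zero padding: the native DFT grid is used.
    """
    n = len(trace)
    if n < 8:
        raise ValueError("need at least 8 samples for a periodogram")
    fs = 1.0 / trace.dt
    w = _window(window, n)
    xw = trace.values * w
    X = np.fft.rfft(xw)
    two_sided = np.abs(X) ** 2 / (n * fs)
    # fold negative frequencies onto positive bins (one-sided convention)
    power = two_sided.copy()
    if n % 2 == 0:
        power[1:-1] *= 2.0
    else:
        power[1:] *= 2.0
    freqs = np.fft.rfftfreq(n, d=trace.dt)
    if normalization == "psd":
        total = np.trapezoid(power, freqs)
        if total <= 0:
            raise ValueError("zero total power; cannot normalize to psd")
        power = power / total
    elif normalization != "power":
        raise ValueError(f"unknown normalization {normalization!r}")
    return Spectrum(
        freqs=freqs, power=power, normalization=normalization, window=window, fs=fs, n=n
    )


def aggregate_spectrum(spectra: Sequence[Spectrum]) -> Spectrum:
    """Per-bin arithmetic mean of spectra over all cells of one condition."""
    spectra = list(spectra)
    if not spectra:
        raise ValueError("no spectra to aggregate")
    ref = spectra[0]
    for s in spectra[1:]:
        if s.freqs.shape != ref.freqs.shape or not np.allclose(s.freqs, ref.freqs):
            raise ValueError("all spectra must share one frequency grid")
    mean_power = np.mean([s.power for s in spectra], axis=0)
    return replace(ref, power=mean_power)


def coherence(
    aggregate: Spectrum, poly_order: int = 6, band_fraction: float = 0.10
) -> float:
    """Concentration of power (percent of total) around the dominant frequency.

    A polynomial of the stated order is fitted to the aggregate power
    versus frequency to smooth multi-peaked shapes; the peak frequency is
    the argmax of the fitted curve on the grid.  Coherence integrates the
    TRUE (unfitted) power over a band of total width ``band_fraction *
    f_peak`` centred at ``f_peak`` and divides by the total power integral.
    The zero-frequency bin is excluded throughout (data are detrended).
    """
    mask = aggregate.freqs > 0
    f, p = aggregate.freqs[mask], aggregate.power[mask]
    if f.size < poly_order + 2:
        raise ValueError("too few frequency bins for the polynomial fit")
    coeffs = np.polyfit(f, p, poly_order)
    fitted = np.polyval(coeffs, f)
    if not np.all(np.isfinite(fitted)):
        raise ValueError("degenerate polynomial fit")
    f_peak = float(f[np.argmax(fitted)])
    half = 0.5 * band_fraction * f_peak
    lo, hi = f_peak - half, f_peak + half
    band = _band_integral(f, p, lo, hi)
    total = np.trapezoid(p, f)
    if total <= 0:
        raise ValueError("zero total power")
    return 100.0 * band / total


def _band_integral(f: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid integral of (f, p) restricted to [lo, hi], interpolating the edges."""
    lo = max(lo, f[0])
    hi = min(hi, f[-1])
    if hi <= lo:
        return 0.0
    inner = (f > lo) & (f < hi)
    fs = np.concatenate(([lo], f[inner], [hi]))
    ps = np.concatenate(([np.interp(lo, f, p)], p[inner], [np.interp(hi, f, p)]))
    return float(np.trapezoid(ps, fs))


def high_freq_contribution(
    psd_spectrum: Spectrum, cutoff: float = DEFAULT_HF_CUTOFF
) -> float:
    """Percent of spectral area above the ultradian/high-frequency cutoff.

    Requires a variance-normalized (psd) spectrum; the zero-frequency bin
    is excluded.  Errors if the cutoff is at or beyond Nyquist.
    """
    if psd_spectrum.normalization != "psd":
        raise ValueError("high-frequency contribution requires psd normalization")
    if cutoff >= psd_spectrum.nyquist:
        raise ValueError(
            f"cutoff {cutoff:g}/h must be below the Nyquist frequency "
            f"{psd_spectrum.nyquist:g}/h"
        )
    mask = psd_spectrum.freqs > 0
    f, p = psd_spectrum.freqs[mask], psd_spectrum.power[mask]
    total = np.trapezoid(p, f)
    if total <= 0:
        raise ValueError("zero total power")
    high = _band_integral(f, p, cutoff, f[-1])
    return 100.0 * high / total
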