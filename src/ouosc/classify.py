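"""Oscillatory / non-oscillatory classification at a controlled false discovery rate.

The decision statistic is the per-cell LLR from :mod:`ouosc.gp`.  Because
the LLR null distribution depends on the experiment's own noise level and
lengthscale spectrum, the null is built synthetically: aperiodic OU traces
are drawn from the per-cell fitted OU parameters, given the calibrated
technical noise, processed like the observations and refitted through the
identical two-model path.  q-values follow the empirical-FDR construction

    ``FDR(t) = Pr_null(LLR >= t) / Pr_obs(LLR >= t)``            (pi0 = 1)

monotonized so each cell's q is the smallest estimated FDR over rejection
thresholds that still include it.  A cell is called oscillatory when
``q <= fdr_threshold`` (3% default).
Classification is performed independently per experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .gp import LLRResult, NoiseModel, SmoothBoxPrior, llr as compute_llr
from .kernels import OUParams
from .preprocess import DegenerateTraceError
from .synthetic import add_technical_noise, sample_ou_trace
from .trace import TimeGrid, Trace

__all__ = [
    "ClassificationResult",
    "calibrate_technical_noise",
    "null_llr_distribution",
    "q_values",
    "classify",
]

DEFAULT_FDR = 0.03
DEFAULT_N_SIMS = 1000
_RETRY_CAP = 3


@dataclass
class ClassificationResult:
    """Per-cell calls plus full provenance for one experiment."""

    cell_ids: List[str]
    llrs: np.ndarray
    q_value: np.ndarray
    labels: List[str]  # "oscillatory" | "non_oscillatory"
    llr_null: np.ndarray
    fdr_threshold: float
    fits: List[LLRResult] = field(default_factory=list)
    experiment_id: str = "experiment"

    @property
    def proportion_oscillatory(self) -> float:
        return float(np.mean([lab == "oscillatory" for lab in self.labels]))

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


def calibrate_technical_noise(
    background_traces: Sequence[Trace],
    detrend_cutoff: float = 3.0,
) -> NoiseModel:
    """Pooled variance of detrended background traces.

    Background traces are recorded where the fluorophore is absent, so
    their detrended fluctuations are pure technical noise (autofluorescence
    plus detector noise).  At least two backgrounds per experiment per
    channel are required.  The returned variance is on the raw intensity
    scale of the inputs; rescale it through the same ratio / z-score
    bookkeeping applied to the signal traces before fitting (see
    :func:`ouosc.pipeline.run_pipeline`).
    """
    if len(background_traces) < 2:
        raise ValueError(
            f"need at least 2 background traces, got {len(background_traces)}"
        )
    pooled_ss, pooled_n = 0.0, 0
    for tr in background_traces:
        resid = tr.values - _background_trend(tr, detrend_cutoff)
        pooled_ss += float(np.sum((resid - resid.mean()) ** 2))
        pooled_n += len(resid) - 1
    return NoiseModel(technical_variance=pooled_ss / pooled_n)


def _background_trend(tr: Trace, cutoff: float) -> np.ndarray:
    """Slow trend of a background trace (zeros when the trace is too short)."""
    if tr.duration <= cutoff:
        return np.full(len(tr), tr.values.mean())
    from .preprocess import _se_trend

    return _se_trend(tr.times, tr.values, cutoff)


def null_llr_distribution(
    fitted_ou: Sequence[OUParams],
    grid: TimeGrid,
    noise: NoiseModel,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    prior: Optional[SmoothBoxPrior] = None,
    n_restarts: int = 5,
    detrend_cutoff: Optional[float] = None,
) -> np.ndarray:
    """LLR statistics under the aperiodic null hypothesis.

    Each draw samples OU parameters with replacement from the experiment's
    fitted per-cell set, simulates an OU trace on the experiment's grid,
    adds calibrated technical noise, processes it exactly as the observed
    data were processed, and refits both models through the identical path.
    When the observed traces were detrended, pass the same
    ``detrend_cutoff`` here: detrending band-passes aperiodic noise and
    shifts its LLR distribution upward, so a null that skips it is not
    exchangeable with the observations and under-controls the FDR.
    Deterministic under ``seed``; a failed refit is re-drawn up to a small
    retry cap.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100 for a usable null")
    if not fitted_ou:
        raise ValueError("need at least one fitted OU parameter set")
    rng = np.random.default_rng(seed)
    noise_sd = float(np.sqrt(noise.technical_variance))
    out = np.empty(n_sims)
    for i in range(n_sims):
        for attempt in range(_RETRY_CAP + 1):
            params = fitted_ou[int(rng.integers(len(fitted_ou)))]
            s1, s2 = rng.integers(0, 2**31 - 1, size=2)
            try:
                tr = sample_ou_trace(params, grid, int(s1))
                tr = add_technical_noise(tr, noise_sd, int(s2))
                if detrend_cutoff is not None:
                    from .preprocess import detrend as _detrend

                    ztr, _, _, _ = _detrend(tr, cutoff=detrend_cutoff)
                else:
                    vals = tr.values
                    sd = vals.std()
                    if sd < 1e-12:
                        raise DegenerateTraceError("degenerate null draw")
                    ztr = tr.with_values((vals - vals.mean()) / sd)
                out[i] = compute_llr(ztr, noise, prior=prior, n_restarts=n_restarts).llr
                break
            except (np.linalg.LinAlgError, DegenerateTraceError):
                if attempt == _RETRY_CAP:
                    raise
    return out


def q_values(observed_llr: np.ndarray, null_llr: np.ndarray) -> np.ndarray:
    """Empirical q-values of observed LLRs against a synthetic null.

    ``FDR(t) = [fraction of null >= t] / [fraction of observed >= t]`` with
    pi0 conservatively fixed at 1, then monotonized (prefix minimum
    ascending in t, so q is non-increasing in the statistic) and capped at 1.
    """
    obs = np.asarray(observed_llr, dtype=float)
    null = np.asarray(null_llr, dtype=float)
    if obs.size == 0 or null.size == 0:
        raise ValueError("observed and null LLR vectors must be non-empty")
    sorted_obs = np.sort(obs)
    sorted_null = np.sort(null)
    frac_null = (null.size - np.searchsorted(sorted_null, obs, side="left")) / null.size
    frac_obs = (obs.size - np.searchsorted(sorted_obs, obs, side="left")) / obs.size
    fdr = frac_null / frac_obs
    # monotonize: the q-value at statistic t is the smallest estimated FDR
    # over rejection thresholds t' <= t, so run a prefix minimum ascending in t
    order = np.argsort(obs)
    q = np.empty_like(obs)
    q[order] = np.minimum.accumulate(fdr[order])
    return np.minimum(q, 1.0)


def classify(
    preprocessed: Sequence[Trace],
    noise: NoiseModel,
    fdr_threshold: float = DEFAULT_FDR,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
    prior: Optional[SmoothBoxPrior] = None,
    n_restarts: int = 5,
    experiment_id: str = "experiment",
    null_detrend_cutoff: Optional[float] = None,
) -> ClassificationResult:
    """Classify detrended, z-scored traces of one experiment at a stated FDR.

    ``noise`` must already be expressed on the z-scored signal scale.
    Returns per-cell LLRs, q-values, labels and the sampled null, so the
    decision is fully reproducible.
    """
    if not 0.0 <= fdr_threshold <= 1.0:
        raise ValueError("fdr_threshold must lie in [0, 1]")
    preprocessed = list(preprocessed)
    if not preprocessed:
        raise ValueError("no traces to classify")
    fits = [compute_llr(tr, noise, prior=prior, n_restarts=n_restarts) for tr in preprocessed]
    obs = np.array([f.llr for f in fits])
    fitted_ou = [f.fit_ou.params for f in fits]
    null = null_llr_distribution(
        fitted_ou,
        preprocessed[0].grid,
        noise,
        n_sims=n_sims,
        seed=seed,
        prior=prior,
        n_restarts=n_restarts,
        detrend_cutoff=null_detrend_cutoff,
    )
    q = q_values(obs, null)
    labels = ["oscillatory" if qi <= fdr_threshold else "non_oscillatory" for qi in q]
    if fdr_threshold == 0.0:
        labels = ["non_oscillatory"] * len(q)
    return ClassificationResult(
        cell_ids=[tr.cell_id for tr in preprocessed],
        llrs=obs,
        q_value=q,
        labels=labels,
        llr_null=null,
        fdr_threshold=fdr_threshold,
        fits=fits,
        experiment_id=experiment_id,
    )
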