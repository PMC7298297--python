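"""Ornstein-Uhlenbeck covariance kernels for aperiodic and quasi-periodic dynamics.

Two competing stationary covariance functions describe z-scored single-cell
fluctuations:

* aperiodic:      ``K_OU(tau)    = sigma2 * exp(-alpha * |tau|)``
* quasi-periodic: ``K_OUosc(tau) = sigma2 * exp(-alpha * |tau|) * cos(beta * tau)``

``alpha`` (1/h) is the lengthscale parameter: the rate at which temporal
autocorrelation decays, so larger alpha means faster-decorrelating noise.
``beta`` (rad/h) sets the ultradian period ``P = 2*pi/beta``.  The prefactor
is interpreted as the signal variance so that ``K(0)`` equals the variance
of the (z-scored) signal; with z-scored data it is held at 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OUParams",
    "OUoscParams",
    "k_ou",
    "k_ouosc",
    "cov_matrix",
    "jittered_cholesky",
]


@dataclass(frozen=True)
class OUParams:
    """Aperiodic model: lengthscale ``alpha_ou`` (1/h) and variance ``sigma2``."""

    alpha_ou: float
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_ou <= 0:
            raise ValueError(f"alpha_ou must be positive, got {self.alpha_ou}")
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")


@dataclass(frozen=True)
class OUoscParams:
    """Quasi-periodic model: lengthscale ``alpha_ouosc`` (1/h), angular
    frequency ``beta`` (rad/h) and variance ``sigma2``."""

    alpha_ouosc: float
    beta: float
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha_ouosc <= 0:
            raise ValueError(f"alpha_ouosc must be positive, got {self.alpha_ouosc}")
        if self.beta <= 0:
            raise ValueError(f"beta must be positive, got {self.beta}")
        if self.sigma2 <= 0:
            raise ValueError(f"sigma2 must be positive, got {self.sigma2}")

    @property
    def period(self) -> float:
        """Ultradian period P = 2*pi/beta (h)."""
        return 2.0 * np.pi / self.beta


def k_ou(tau, params: OUParams):
    """Aperiodic covariance ``sigma2 * exp(-alpha * |tau|)``.

    Stationary kernel: negative lags are folded to ``|tau|``.
    """
    tau = np.abs(np.asarray(tau, dtype=float))
    return params.sigma2 * np.exp(-params.alpha_ou * tau)


def k_ouosc(tau, params: OUoscParams):
    """Quasi-periodic covariance ``sigma2 * exp(-alpha * |tau|) * cos(beta * tau)``."""
    tau = np.abs(np.asarray(tau, dtype=float))
    return params.sigma2 * np.exp(-params.alpha_ouosc * tau) * np.cos(params.beta * tau)


def cov_matrix(times: np.ndarray, params) -> np.ndarray:
    """Dense covariance matrix of the kernel on a set of time points."""
    lags = np.abs(times[:, None] - times[None, :])
    if isinstance(params, OUParams):
        return k_ou(lags, params)
    if isinstance(params, OUoscParams):
        return k_ouosc(lags, params)
    raise TypeError(f"unsupported parameter type {type(params)!r}")


# Jitter escalation used everywhere a covariance matrix is factorized:
# start at 1e-6 * sigma2 on the diagonal and multiply by 10 up to 1e-2 * sigma2.
_JITTER_START = 1e-6
_JITTER_MAX = 1e-2


def jittered_cholesky(K: np.ndarray, scale: float = 1.0) -> np.ndarray:
    """Lower Cholesky factor of ``K`` with escalating diagonal jitter.

    ``scale`` sets the unit of jitter (normally the signal variance).  Raises
    ``np.linalg.LinAlgError`` if the matrix cannot be factorized even at the
    jitter ceiling.
    """
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        pass
    jitter = _JITTER_START * scale
    eye = np.eye(K.shape[0])
    while jitter <= _JITTER_MAX * scale * (1 + 1e-12):
        try:
            return np.linalg.cholesky(K + jitter * eye)
        except np.linalg.LinAlgError:
            jitter *= 10.0
    raise np.linalg.LinAlgError(
        f"covariance matrix not positive definite even with jitter {_JITTER_MAX * scale:g}"
    )
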