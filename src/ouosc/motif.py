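"""Stochastic repressor -> self-activating-target network motif.

A fluctuating repressor Y (modelling noisy Her6-like expression with
tunable aperiodic lengthscale ``alpha_ou``) gates a bistable downstream
target X:

    dX/dt = G1(Y(t)) + G2(X) - mu * X

with Hill repression ``G1(Y) = k1 / (1 + (Y/Y0)^n)``, Hill auto-activation
``G2(X) = k2 / (1 + (X/X0_X)^-n)`` and linear degradation.  In the
open-loop variant Y is an exogenous OU sample around a constant baseline;
in the feedback variant X represses Y production through
``G3(X) = 1 / (1 + (X/X0_Y)^n)``:

    dY/dt = alpha_ou * Y_in * G3(X) - alpha_ou * Y + sqrt(2*alpha_ou*sigma2) * xi

The system exhibits inverse stochastic resonance: slow (small alpha_ou)
repressor fluctuations dwell long enough below the repression threshold to
let X escape to the high state, while fast fluctuations average out and X
stays off.  Switching probability therefore falls as alpha_ou grows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

__all__ = [
    "MotifParams",
    "MotifTrajectory",
    "g1",
    "g2",
    "g3",
    "steady_states",
    "switching_threshold",
    "simulate_open_loop",
    "simulate_feedback",
    "switching_probability",
]


@dataclass(frozen=True)
class MotifParams:
    """Motif parameters; defaults place the target in a bistable, timescale-
    sensitive regime (arbitrary molecule/time units)."""

    k1: float = 0.5        # max X production under de-repression
    k2: float = 10.0       # max auto-activation production
    Y0: float = 7.9        # repression threshold of X by Y
    X0_X: float = 0.5      # auto-activation threshold
    X0_Y: float = 2.0      # threshold for repression of Y by X (feedback)
    n: int = 4             # Hill coefficient
    mu: float = 3.0        # X degradation rate
    sigma2: float = 1.7    # OU variance of Y fluctuations
    Y_in: float = 6.0      # Y baseline / initial expression level
    alpha_ou: float = 2.0  # aperiodic lengthscale of Y
    dt: float = 0.0015     # forward-Euler step
    duration: float = 30.0 # simulation length (time units)

    def __post_init__(self) -> None:
        for name in ("k1", "k2", "Y0", "X0_X", "X0_Y", "mu", "Y_in", "alpha_ou"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be non-negative")
        if self.n < 1 or int(self.n) != self.n:
            raise ValueError("Hill coefficient n must be a positive integer")
        if self.dt <= 0 or self.duration <= self.dt:
            raise ValueError("need dt > 0 and duration > dt")


@dataclass
class MotifTrajectory:
    """One simulated (Y, X) path with its switching outcome."""

    times: np.ndarray
    Y_path: np.ndarray
    X_path: np.ndarray
    switched: bool
    switch_time: Optional[float]
    threshold: float


def g1(Y, params: MotifParams):
    """Hill repression of X production by Y; negative Y is clipped to 0."""
    Y = np.maximum(np.asarray(Y, dtype=float), 0.0)
    return params.k1 / (1.0 + (Y / params.Y0) ** params.n)


def g2(X, params: MotifParams):
    """Hill auto-activation of X; G2(0) = 0 by the limit convention."""
    X = np.asarray(X, dtype=float)
    scalar = X.ndim == 0
    Xa = np.atleast_1d(X)
    out = np.zeros_like(Xa)
    pos = Xa > 0
    out[pos] = params.k2 / (1.0 + (Xa[pos] / params.X0_X) ** (-params.n))
    return float(out[0]) if scalar else out


def g3(X, params: MotifParams):
    """Hill repression of Y production by X, in [0, 1]."""
    X = np.maximum(np.asarray(X, dtype=float), 0.0)
    return 1.0 / (1.0 + (X / params.X0_Y) ** params.n)


def steady_states(params: MotifParams, Y_fixed: float) -> Tuple[np.ndarray, np.ndarray]:
    """Fixed points of dX/dt at clamped Y, with stability classification.

    Scans ``X in [0, 2*k2/mu]`` for sign changes of
    ``G1(Y_fixed) + G2(X) - mu*X`` and polishes each bracket by bisection
    to 1e-9.  Returns ``(roots, stable)`` with ``stable[i]`` true when the
    derivative of the flow is negative at the root.
    """
    f = lambda X: float(g1(Y_fixed, params) + g2(np.array([X]), params)[0] - params.mu * X)
    # production is bounded by k1 + k2, so every fixed point lies below (k1+k2)/mu
    hi = 2.0 * (params.k1 + params.k2) / params.mu
    xs = np.linspace(0.0, hi, 2001)
    vals = np.array([f(x) for x in xs])
    roots = []
    for i in range(len(xs) - 1):
        if vals[i] == 0.0:
            roots.append(xs[i])
        elif vals[i] * vals[i + 1] < 0:
            roots.append(brentq(f, xs[i], xs[i + 1], xtol=1e-9))
    if vals[-1] == 0.0:
        roots.append(xs[-1])
    if not roots:
        raise ValueError("no fixed point found in the scanned X range")
    roots = np.array(sorted(set(np.round(roots, 12))))
    eps = 1e-6
    stable = np.array([(f(r + eps) - f(r - eps)) < 0 for r in roots])
    return roots, stable


def switching_threshold(params: MotifParams) -> float:
    """Midpoint of the low and high stable fixed points at Y = Y_in.

    When strong de-repression leaves only the high state (the off branch has
    vanished), the threshold is the midpoint between the auto-activation-free
    level ``G1(Y_in)/mu`` and that high state, so a de-repressed system still
    registers its (certain) switch.  Errors when no high state exists at all,
    since switching is then undefined.
    """
    roots, stable = steady_states(params, params.Y_in)
    stable_roots = roots[stable]
    if len(stable_roots) >= 2:
        return float(0.5 * (stable_roots[0] + stable_roots[-1]))
    x_off = float(g1(params.Y_in, params)) / params.mu
    if len(stable_roots) == 1 and stable_roots[0] > 5.0 * x_off:
        return float(0.5 * (x_off + stable_roots[0]))
    raise ValueError(
        f"system is not bistable at Y={params.Y_in:g} "
        f"(stable fixed points: {stable_roots}); switching undefined"
    )


def _euler_x_step(X, Y, params, dt):
    return X + dt * (g1(Y, params) + g2(X, params) - params.mu * X)


def _simulate(params: MotifParams, seed: int, feedback: bool, n_reps: int = 1):
    """Vectorized Euler(-Maruyama) integration of n_reps independent paths."""
    rng = np.random.default_rng(seed)
    n_steps = int(round(params.duration / params.dt))
    times = params.dt * np.arange(n_steps + 1)
    a, s2, dt = params.alpha_ou, params.sigma2, params.dt

    Y = np.full(n_reps, params.Y_in) + (
        rng.normal(0.0, np.sqrt(s2), size=n_reps) if s2 > 0 else 0.0
    )
    X = np.zeros(n_reps)
    Y_paths = np.empty((n_reps, n_steps + 1))
    X_paths = np.empty((n_reps, n_steps + 1))
    Y_paths[:, 0], X_paths[:, 0] = Y, X

    if feedback:
        noise_amp = np.sqrt(2.0 * a * s2 * dt)
        for k in range(n_steps):
            xi = rng.standard_normal(n_reps) if s2 > 0 else 0.0
            Y_new = Y + dt * (a * params.Y_in * g3(X, params) - a * Y) + noise_amp * xi
            X = _euler_x_step(X, Y, params, dt)
            Y = Y_new
            Y_paths[:, k + 1], X_paths[:, k + 1] = Y, X
    else:
        # exact OU update for the exogenous fluctuation around Y_in
        rho = np.exp(-a * dt)
        innov_sd = np.sqrt(s2 * (1.0 - rho**2)) if s2 > 0 else 0.0
        dev = Y - params.Y_in
        for k in range(n_steps):
            X = _euler_x_step(X, Y, params, dt)
            dev = rho * dev + (
                rng.normal(0.0, innov_sd, size=n_reps) if s2 > 0 else 0.0
            )
            Y = params.Y_in + dev
            Y_paths[:, k + 1], X_paths[:, k + 1] = Y, X

    if not np.all(np.isfinite(X_paths)):
        raise FloatingPointError("X diverged during Euler integration")
    return times, Y_paths, X_paths


def _package_trajectory(times, Y, X, threshold) -> MotifTrajectory:
    above = np.nonzero(X >= threshold)[0]
    switched = above.size > 0
    return MotifTrajectory(
        times=times,
        Y_path=Y,
        X_path=X,
        switched=switched,
        switch_time=float(times[above[0]]) if switched else None,
        threshold=threshold,
    )


def simulate_open_loop(params: MotifParams, seed: int = 0) -> MotifTrajectory:
    """One open-loop trajectory: exogenous OU repressor driving the target."""
    threshold = switching_threshold(params)
    times, Y, X = _simulate(params, seed, feedback=False)
    return _package_trajectory(times, Y[0], X[0], threshold)


def simulate_feedback(params: MotifParams, seed: int = 0) -> MotifTrajectory:
    """One closed-loop trajectory: the target represses its repressor."""
    threshold = switching_threshold(params)
    times, Y, X = _simulate(params, seed, feedback=True)
    return _package_trajectory(times, Y[0], X[0], threshold)


def switching_probability(
    params: MotifParams,
    variant: str = "open_loop",
    n_reps: int = 100,
    seed: int = 0,
    ci_level: float = 0.95,
) -> dict:
    """Fraction of replicates whose target crosses to the high state.

    Replicates are simulated in one vectorized pass; a path counts as
    switched on first crossing of the midpoint between the low and high
    stable fixed points at Y = Y_in.  Returns the point estimate with a
    Jeffreys binomial confidence interval.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    if variant not in ("open_loop", "feedback"):
        raise ValueError(f"unknown variant {variant!r}")
    threshold = switching_threshold(params)
    times, Y, X = _simulate(params, seed, feedback=(variant == "feedback"), n_reps=n_reps)
    switched = np.any(X >= threshold, axis=1)
    k = int(switched.sum())
    p = k / n_reps
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    ci_lo = 0.0 if k == 0 else float(beta_dist.ppf(lo_q, k + 0.5, n_reps - k + 0.5))
    ci_hi = 1.0 if k == n_reps else float(beta_dist.ppf(hi_q, k + 0.5, n_reps - k + 0.5))
    return {
        "p_switch": p,
        "ci_lo": ci_lo,
        "ci_hi": ci_hi,
        "n_reps": n_reps,
        "n_switched": k,
        "variant": variant,
        "alpha_ou": params.alpha_ou,
        "threshold": threshold,
    }
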