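import numpy as np
import pytest

from ouosc import (
    NoiseModel,
    OUParams,
    OUoscParams,
    TimeGrid,
    Trace,
)

PERIOD = 1.5  # default ultradian period used across fixtures (h)


@pytest.fixture(scope="session")
def grid():
    """Default imaging grid: 6-min sampling over 12 h."""
    return TimeGrid(t0=0.0, dt=0.1, n=121)


@pytest.fixture(scope="session")
def ctrl_ou():
    """Control-like aperiodic dynamics: slowly decorrelating noise."""
    return OUParams(alpha_ou=2.0, sigma2=1.0)


@pytest.fixture(scope="session")
def mutant_ou():
    """Mutant-like aperiodic dynamics: fast, high-frequency noise."""
    return OUParams(alpha_ou=15.0, sigma2=1.0)


@pytest.fixture(scope="session")
def osc_params():
    """Quasi-periodic dynamics with a 1.5 h ultradian period."""
    return OUoscParams(alpha_ouosc=0.5, beta=2 * np.pi / PERIOD, sigma2=1.0)


@pytest.fixture(scope="session")
def noise():
    """Technical-noise model on the z-scored signal scale."""
    return NoiseModel(technical_variance=0.05)


def zscore_trace(trace: Trace) -> Trace:
    v = trace.values
    return trace.with_values((v - v.mean()) / v.std())
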