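"""Kernels, marginal likelihood, SmoothBox1 prior, fitting and the LLR."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ouosc import (
    NoiseModel,
    OUParams,
    OUoscParams,
    SmoothBoxPrior,
    TimeGrid,
    Trace,
    add_technical_noise,
    fit_ou,
    fit_ouosc,
    k_ou,
    k_ouosc,
    llr,
    log_marginal_likelihood,
    sample_ou_trace,
    sample_ouosc_trace,
    smoothbox1,
)
from conftest import zscore_trace


def dense_lml_oracle(y, times, kernel, params, noise_var):
    """Independent brute-force LML: explicit inverse and slogdet."""
    lags = np.abs(times[:, None] - times[None, :])
    C = kernel(lags, params) + noise_var * np.eye(len(y))
    sign, logdet = np.linalg.slogdet(C)
    assert sign > 0
    return -0.5 * y @ np.linalg.inv(C) @ y - 0.5 * logdet - 0.5 * len(y) * np.log(2 * np.pi)


class TestKernels:
    @pytest.mark.parametrize(
        "tau,expected",
        [(0.0, 1.0), (0.5, np.exp(-1.0)), (100.0, pytest.approx(0.0, abs=1e-12))],
    )
    def test_ou_closed_form(self, tau, expected):
        assert k_ou(tau, OUParams(alpha_ou=2.0, sigma2=1.0)) == pytest.approx(expected)

    def test_ouosc_values(self):
        p = OUoscParams(alpha_ouosc=1.0, beta=2 * np.pi, sigma2=1.3)
        assert k_ouosc(0.0, p) == pytest.approx(1.3)
        tau = np.pi / p.beta
        assert k_ouosc(tau, p) == pytest.approx(-1.3 * np.exp(-tau))

    def test_ouosc_reduces_to_ou_at_small_beta(self):
        """As beta -> 0 the periodic kernel degenerates to the aperiodic one."""
        taus = np.linspace(0, 10, 101)
        ou = k_ou(taus, OUParams(alpha_ou=0.7, sigma2=2.0))
        osc = k_ouosc(taus, OUoscParams(alpha_ouosc=0.7, beta=1e-9, sigma2=2.0))
        assert np.allclose(ou, osc, rtol=1e-12, atol=1e-12)

    def test_stationarity_negative_lag(self):
        p = OUParams(alpha_ou=2.0, sigma2=1.0)
        assert k_ou(-0.3, p) == k_ou(0.3, p)


class TestLogMarginalLikelihood:
    def test_single_point_closed_form(self):
        """n=1, y=0, K(0)=1, no noise: LML = -log(2*pi)/2."""
        val = log_marginal_likelihood(
            np.array([0.0]), np.array([0.0]), k_ou, OUParams(1.0, 1.0), NoiseModel(0.0)
        )
        assert val == pytest.approx(-0.5 * np.log(2 * np.pi), abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(2, 50),
        alpha=st.floats(0.1, 50.0),
        noise_var=st.floats(0.0, 1.0),
        periodic=st.booleans(),
    )
    def test_agrees_with_dense_oracle(self, seed, n, alpha, noise_var, periodic):
        """Cholesky LML equals the explicit inverse/determinant oracle to 1e-8."""
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 10, size=n))
        y = rng.standard_normal(n)
        if periodic:
            params, kernel = OUoscParams(alpha, beta=rng.uniform(0.7, 25.0)), k_ouosc
        else:
            params, kernel = OUParams(alpha), k_ou
        nv = noise_var + 1e-6  # keep the oracle's plain inverse well posed
        ours = log_marginal_likelihood(y, times, kernel, params, NoiseModel(nv))
        oracle = dense_lml_oracle(y, times, kernel, params, nv)
        assert ours == pytest.approx(oracle, abs=1e-8)

    def test_diagonal_noise_limit(self):
        """With y=0 and huge alpha (diagonal K), LML is the closed diagonal form."""
        n = 10
        times = np.arange(n, dtype=float)
        y = np.zeros(n)
        nv = 0.3
        val = log_marginal_likelihood(y, times, k_ou, OUParams(1e6, 1.0), NoiseModel(nv))
        expected = -0.5 * n * np.log(1.0 + nv) - 0.5 * n * np.log(2 * np.pi)
        assert val == pytest.approx(expected, abs=1e-8)


class TestSmoothBox:
    def test_reference_value(self):
        """SB1(1.5) at defaults = S(2.5)*(1-S(-2.5)) = 0.92414...^2."""
        s = 1.0 / (1.0 + np.exp(-2.5))
        assert smoothbox1(1.5, SmoothBoxPrior()) == pytest.approx(s * s, abs=1e-10)
        assert smoothbox1(1.5, SmoothBoxPrior()) == pytest.approx(0.85404, abs=1e-4)

    def test_vanishes_far_below_lower_knee(self):
        assert smoothbox1(-5.0, SmoothBoxPrior()) < 1e-10

    @pytest.mark.parametrize("d", [0.1, 0.4, 1.0])
    def test_symmetric_about_band_centre(self, d):
        p = SmoothBoxPrior()
        assert smoothbox1(1.5 + d, p) == pytest.approx(smoothbox1(1.5 - d, p), rel=1e-12)

    def test_invalid_prior_rejected(self):
        with pytest.raises(ValueError):
            SmoothBoxPrior(l=2.0, L=1.0)


class TestFitting:
    def test_white_noise_pins_alpha_at_upper_bound(self, grid, noise):
        """With nothing but uncorrelated noise the lengthscale runs to the bound.

        Uses a draw whose sample lag-1 autocorrelation is negative, i.e. the
        OU kernel has no correlation to fit and the likelihood is flat in
        the large-alpha direction.
        """
        rng = np.random.default_rng(1)
        tr = Trace("c", "detrended", grid.times, rng.standard_normal(grid.n))
        with pytest.warns(RuntimeWarning, match="upper bound"):
            fit = fit_ou(zscore_trace(tr), noise)
        assert fit.params.alpha_ou == pytest.approx(1e3)

    def test_fit_determinism(self, grid, noise, ctrl_ou):
        tr = zscore_trace(sample_ou_trace(ctrl_ou, grid, seed=3))
        a = fit_ou(tr, noise)
        b = fit_ou(tr, noise)
        assert a.params == b.params and a.log_marginal_likelihood == b.log_marginal_likelihood

    def test_time_translation_invariance(self, noise, ctrl_ou):
        g0 = TimeGrid(0.0, 0.1, 121)
        tr = zscore_trace(sample_ou_trace(ctrl_ou, g0, seed=4))
        shifted = Trace("c", "detrended", tr.times + 5.0, tr.values)
        f0, f1 = fit_ou(tr, noise), fit_ou(shifted, noise)
        assert f0.params.alpha_ou == pytest.approx(f1.params.alpha_ou, rel=1e-6)
        o0, o1 = fit_ouosc(tr, noise), fit_ouosc(shifted, noise)
        assert o0.params.beta == pytest.approx(o1.params.beta, rel=1e-6)

    def test_lengthscale_contrast_recovered(self, grid, noise, ctrl_ou, mutant_ou):
        """Fast-decorrelating populations fit systematically larger alpha."""
        slow, fast = [], []
        for i in range(15):
            t1 = zscore_trace(sample_ou_trace(ctrl_ou, grid, seed=i))
            t2 = zscore_trace(sample_ou_trace(mutant_ou, grid, seed=100 + i))
            slow.append(fit_ou(t1, noise).params.alpha_ou)
            fast.append(fit_ou(t2, noise).params.alpha_ou)
        assert np.median(fast) > 2 * np.median(slow)

    def test_prior_suppresses_large_periodic_lengthscale(self, grid, noise, ctrl_ou):
        """Null refits keep alpha_ouosc below L + 3/eta in >=95% of cases."""
        prior = SmoothBoxPrior()
        alphas = []
        for i in range(20):
            tr = zscore_trace(sample_ou_trace(ctrl_ou, grid, seed=500 + i))
            alphas.append(fit_ouosc(tr, noise, prior=prior).params.alpha_ouosc)
        frac = np.mean([a <= prior.L + 3 / prior.eta for a in alphas])
        assert frac >= 0.95

    def test_bias_shrinks_with_trace_length(self, ctrl_ou):
        """Median |alpha error| decreases monotonically over 60/120/240 points."""
        nv = 0.05
        nm = NoiseModel(nv / (1 + nv))  # z-scored scale
        errs = []
        for n in (60, 120, 240):
            grid = TimeGrid(0, 0.1, n)
            ahats = []
            for i in range(50):
                tr = sample_ou_trace(ctrl_ou, grid, seed=i)
                tr = add_technical_noise(tr, np.sqrt(nv), seed=10_000 + i)
                ahats.append(fit_ou(zscore_trace(tr), nm).params.alpha_ou)
            errs.append(abs(np.median(ahats) - ctrl_ou.alpha_ou))
        assert errs[0] > errs[1] > errs[2]


class TestLLR:
    def test_strong_oscillator_scores_high(self, grid, noise, osc_params):
        tr = sample_ouosc_trace(osc_params, grid, seed=8)
        tr = add_technical_noise(tr, 0.1, seed=9)
        res = llr(zscore_trace(tr), noise)
        assert res.llr > 10

    def test_period_from_beta(self, grid, noise, osc_params):
        tr = zscore_trace(sample_ouosc_trace(osc_params, grid, seed=10))
        res = llr(tr, noise)
        assert res.period == pytest.approx(2 * np.pi / res.fit_ouosc.params.beta)
        assert res.llr == pytest.approx(
            2 * (res.fit_ouosc.log_marginal_likelihood - res.fit_ou.log_marginal_likelihood)
        )
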