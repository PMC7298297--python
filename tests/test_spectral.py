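"""Periodogram identities, coherence and high-frequency contribution."""

import numpy as np
import pytest

from ouosc import (
    OUParams,
    OUoscParams,
    Spectrum,
    TimeGrid,
    Trace,
    aggregate_spectrum,
    coherence,
    high_freq_contribution,
    periodogram,
    sample_ou_trace,
    sample_ouosc_trace,
)


def make_trace(grid, values):
    return Trace("c", "detrended", grid.times, values)


@pytest.fixture(scope="module")
def grid120():
    return TimeGrid(0, 0.1, 120)


class TestPeriodogram:
    def test_single_bin_for_grid_cosine(self, grid120):
        """DFT orthogonality: a cosine at an exact grid frequency fills one bin."""
        k = 9
        f0 = k / (grid120.n * grid120.dt)
        x = np.cos(2 * np.pi * f0 * grid120.times)
        spec = periodogram(make_trace(grid120, x), window="rectangular")
        peak_idx = np.argmax(spec.power)
        assert spec.freqs[peak_idx] == pytest.approx(f0)
        others = np.delete(spec.power, peak_idx)
        assert np.max(others) <= 1e-10 * spec.power[peak_idx]

    @pytest.mark.parametrize("window", ["rectangular", "hamming"])
    def test_parseval_riemann_sum(self, grid120, window):
        """Riemann sum of the spectrum over frequency = windowed mean square."""
        rng = np.random.default_rng(4)
        x = rng.standard_normal(grid120.n)
        spec = periodogram(make_trace(grid120, x), window=window)
        w = np.ones(grid120.n) if window == "rectangular" else np.hamming(grid120.n)
        df = spec.fs / grid120.n
        assert np.sum(spec.power) * df == pytest.approx(np.mean((x * w) ** 2), abs=1e-8)

    def test_white_noise_spectrum_flat(self, grid120):
        """Mean periodogram of white noise is uniform across bins within 3 SEs."""
        n_rep = 500
        acc = None
        for i in range(n_rep):
            x = np.random.default_rng(i).standard_normal(grid120.n)
            p = periodogram(make_trace(grid120, x)).power
            acc = p if acc is None else acc + p
        mean_p = acc[1:-1] / n_rep  # interior bins share one doubling convention
        grand = mean_p.mean()
        se = mean_p.std(ddof=1) / np.sqrt(len(mean_p))
        assert np.all(np.abs(mean_p - grand) < 3 * np.sqrt(len(mean_p)) * se)

    def test_psd_normalization_integrates_to_one(self, grid120):
        rng = np.random.default_rng(5)
        spec = periodogram(make_trace(grid120, rng.standard_normal(grid120.n)),
                           normalization="psd")
        assert np.trapezoid(spec.power, spec.freqs) == pytest.approx(1.0, abs=1e-6)

    def test_nonuniform_grid_rejected(self):
        times = np.array([0.0, 0.1, 0.2, 0.35, 0.4, 0.5, 0.6, 0.7])
        with pytest.raises(ValueError):
            Trace("c", "d", times, np.zeros(8))


class TestAggregate:
    def test_single_and_identical_spectra_identity(self, grid120):
        rng = np.random.default_rng(6)
        s = periodogram(make_trace(grid120, rng.standard_normal(grid120.n)))
        assert np.allclose(aggregate_spectrum([s]).power, s.power)
        assert np.allclose(aggregate_spectrum([s, s]).power, s.power)

    def test_linearity_with_delta_spectra(self, grid120):
        spectra = []
        for k in (5, 15, 25):
            f0 = k / (grid120.n * grid120.dt)
            x = np.cos(2 * np.pi * f0 * grid120.times)
            spectra.append(periodogram(make_trace(grid120, x)))
        agg = aggregate_spectrum(spectra)
        top3 = np.sort(agg.power)[-3:]
        assert top3 == pytest.approx(np.full(3, top3[0]), rel=1e-10)

    def test_grid_mismatch_rejected(self, grid120):
        s1 = periodogram(make_trace(grid120, np.sin(grid120.times)))
        g2 = TimeGrid(0, 0.1, 64)
        s2 = periodogram(Trace("c", "d", g2.times, np.sin(g2.times)))
        with pytest.raises(ValueError):
            aggregate_spectrum([s1, s2])


class TestCoherence:
    def test_concentrated_spectrum_near_total(self, grid120):
        f0 = 30 / (grid120.n * grid120.dt)  # 2.5 cycles/h
        x = np.cos(2 * np.pi * f0 * grid120.times)
        spec = periodogram(make_trace(grid120, x))
        assert coherence(spec) > 95.0

    def test_flat_spectrum_matches_trapezoid_oracle(self):
        """For constant power the coherence equals band width / total bandwidth."""
        freqs = np.linspace(0, 5, 301)
        flat = Spectrum(freqs=freqs, power=np.ones_like(freqs),
                        normalization="power", window="rectangular", fs=10.0, n=600)
        got = coherence(flat, poly_order=6, band_fraction=0.10)
        # oracle: fitted curve is ~flat; argmax lands on some grid peak f*;
        # band integral = 0.10*f*, total = f_max - f_min on the positive grid
        f = freqs[freqs > 0]
        coeffs = np.polyfit(f, np.ones_like(f), 6)
        f_peak = f[np.argmax(np.polyval(coeffs, f))]
        lo = max(f_peak * 0.95, f[0])  # band is clipped to the grid support
        hi = min(f_peak * 1.05, f[-1])
        expected = 100.0 * (hi - lo) / (f[-1] - f[0])
        assert got == pytest.approx(expected, rel=1e-6)

    def test_scale_invariance(self, grid120):
        rng = np.random.default_rng(8)
        spec = periodogram(make_trace(grid120, rng.standard_normal(grid120.n)))
        import dataclasses

        scaled = dataclasses.replace(spec, power=37.0 * spec.power)
        assert coherence(spec) == pytest.approx(coherence(scaled), rel=1e-12)

    def test_oscillator_population_more_coherent_than_aperiodic(self, grid120):
        osc = OUoscParams(alpha_ouosc=0.5, beta=2 * np.pi / 1.5, sigma2=1.0)
        ou = OUParams(alpha_ou=2.0, sigma2=1.0)
        osc_spectra, ou_spectra = [], []
        for i in range(40):
            osc_spectra.append(periodogram(sample_ouosc_trace(osc, grid120, seed=i)))
            ou_spectra.append(periodogram(sample_ou_trace(ou, grid120, seed=500 + i)))
        c_osc = coherence(aggregate_spectrum(osc_spectra))
        c_ou = coherence(aggregate_spectrum(ou_spectra))
        assert c_osc > c_ou

    def test_coherence_decreases_with_periodic_lengthscale(self, grid120):
        """Faster phase diffusion (larger alpha at fixed beta) lowers coherence."""
        cohs = []
        for alpha in (1.0, 2.0, 4.0):
            params = OUoscParams(alpha_ouosc=alpha, beta=2 * np.pi / 1.5, sigma2=1.0)
            spectra = [
                periodogram(sample_ouosc_trace(params, grid120, seed=1000 * int(alpha) + i))
                for i in range(200)
            ]
            cohs.append(coherence(aggregate_spectrum(spectra)))
        assert cohs[0] > cohs[1] > cohs[2]


class TestHighFrequency:
    def test_all_power_below_cutoff(self):
        freqs = np.linspace(0, 5, 101)
        power = np.where(freqs < 1.0, 1.0, 0.0)
        spec = Spectrum(freqs=freqs, power=power / np.trapezoid(power, freqs),
                        normalization="psd", window="rectangular", fs=10.0, n=200)
        assert high_freq_contribution(spec) == pytest.approx(0.0, abs=1e-9)

    def test_all_power_above_cutoff(self):
        freqs = np.linspace(0, 5, 101)
        power = np.where(freqs > 2.0, 1.0, 0.0)
        spec = Spectrum(freqs=freqs, power=power / np.trapezoid(power, freqs),
                        normalization="psd", window="rectangular", fs=10.0, n=200)
        assert high_freq_contribution(spec) == pytest.approx(100.0, abs=1e-9)

    def test_white_noise_flat_spectrum_value(self, grid120):
        """At fs=10/h and 1.5/h cutoff, white noise gives ~(5-1.5)/5 = 70%."""
        vals = []
        for i in range(300):
            x = np.random.default_rng(i).standard_normal(grid120.n)
            spec = periodogram(make_trace(grid120, x), normalization="psd")
            vals.append(high_freq_contribution(spec))
        assert np.mean(vals) == pytest.approx(70.0, abs=3.0)

    def test_requires_psd_and_valid_cutoff(self, grid120):
        spec_power = periodogram(make_trace(grid120, np.sin(grid120.times)))
        with pytest.raises(ValueError):
            high_freq_contribution(spec_power)
        spec_psd = periodogram(make_trace(grid120, np.sin(grid120.times)),
                               normalization="psd")
        with pytest.raises(ValueError):
            high_freq_contribution(spec_psd, cutoff=6.0)

    def test_high_frequency_rises_with_aperiodic_lengthscale(self, grid120):
        """Faster-decorrelating noise shifts spectral mass above the cutoff."""
        means = []
        for alpha in (2.0, 15.0, 100.0):
            vals = []
            for i in range(100):
                tr = sample_ou_trace(OUParams(alpha_ou=alpha), grid120, seed=7000 + i)
                vals.append(high_freq_contribution(periodogram(tr, normalization="psd")))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
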