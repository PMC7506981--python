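"""Shaping filter, moving-average envelope, SS1/SS2 simulators, IG-EM fit."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import invgamma, kstest

from emgaug import (
    IDENTITY_FILTER,
    MultichannelSignal,
    ParameterError,
    SS1Params,
    SS2Params,
    ShapingFilter,
    envelope_ma,
    fit_inverse_gamma_em,
    shaping_filter_response,
    shaping_psd,
    simulate_ss1,
    simulate_ss2,
)
from emgaug.augment_sim import ss1_carrier


class TestShapingFilter:
    def test_psd_vanishes_at_dc(self):
        assert shaping_psd(0.0, 2.0, 20.0) == 0.0

    def test_corner_validation(self):
        with pytest.raises(ParameterError):
            ShapingFilter(fl=20.0, fh=2.0)
        with pytest.raises(ParameterError):
            ShapingFilter(fl=2.0, fh=60.0, fs=100.0)  # fh >= nyquist

    def test_magnitude_tracks_analytic_psd(self):
        filt = ShapingFilter()
        g = shaping_filter_response(filt)
        w, H = sps.freqz(g, worN=8192, fs=filt.fs)
        mag2 = np.abs(H) ** 2
        psd = shaping_psd(w, filt.fl, filt.fh)
        mag2 /= mag2.max()
        psd /= psd.max()
        band = (w >= filt.fl / 2) & (w <= min(2 * filt.fh, 0.45 * filt.fs))
        rel = np.abs(mag2[band] - psd[band]) / psd[band]
        assert rel.max() < 0.05

    def test_empirical_peak_matches_analytic_maximizer(self):
        filt = ShapingFilter()
        g = shaping_filter_response(filt)
        w, H = sps.freqz(g, worN=8192, fs=filt.fs)
        grid = np.linspace(0, filt.fs / 2, 200_001)
        analytic_peak = grid[np.argmax(shaping_psd(grid, filt.fl, filt.fh))]
        empirical_peak = w[np.argmax(np.abs(H))]
        # one frequency bin at the realized filter's resolution (fs/n_taps)
        assert abs(empirical_peak - analytic_peak) <= filt.fs / filt.n_taps

    def test_doubling_fh_shifts_peak_as_predicted(self):
        # long filters localize the (broad) spectral peak well enough to
        # compare the shift factor against the analytic maximizers
        f1 = ShapingFilter(fl=2.0, fh=10.0, fs=200.0, n_taps=1025)
        f2 = ShapingFilter(fl=2.0, fh=20.0, fs=200.0, n_taps=1025)

        def peak(filt):
            w, H = sps.freqz(shaping_filter_response(filt), worN=65536, fs=filt.fs)
            return w[np.argmax(np.abs(H))]

        grid = np.linspace(0, 100, 200_001)
        pred1 = grid[np.argmax(shaping_psd(grid, f1.fl, f1.fh))]
        pred2 = grid[np.argmax(shaping_psd(grid, f2.fl, f2.fh))]
        assert np.isclose(peak(f2) / peak(f1), pred2 / pred1, rtol=0.05)

    def test_linear_phase(self):
        g = shaping_filter_response(ShapingFilter())
        np.testing.assert_allclose(g, g[::-1], atol=1e-12)  # even symmetry


class TestEnvelopeMa:
    def test_constant(self):
        x = MultichannelSignal(np.full((30, 2), 4.0), 100.0)
        np.testing.assert_allclose(envelope_ma(x, 50.0).samples, 4.0)

    def test_impulse_plateau(self):
        samples = np.zeros((21, 1))
        samples[10] = 1.0
        x = MultichannelSignal(samples, 1000.0)
        env = envelope_ma(x, 3.0).samples[:, 0]  # 3-sample window
        np.testing.assert_allclose(env[9:12], 1 / 3)
        assert env[7] == 0.0 and env[13] == 0.0

    def test_matches_boxcar_convolution(self, rng):
        x = MultichannelSignal(rng.standard_normal((200, 1)), 1000.0)
        w = 15
        env = envelope_ma(x, 15.0).samples[:, 0]
        oracle = np.convolve(x.samples[:, 0], np.ones(w) / w, mode="same")
        # interior agrees exactly; edges differ by the truncation convention
        np.testing.assert_allclose(env[w:-w], oracle[w:-w], atol=1e-12)


class TestSS1:
    def test_zero_signal_gives_pure_sensor_noise(self):
        x = MultichannelSignal(np.zeros((100_000, 2)), 100.0)
        y = simulate_ss1(x, SS1Params(rng_seed=0))
        std = y.samples.std()
        assert abs(std - 0.1) < 0.005  # within 5% of sigma=0.1

    def test_carrier_reproduces_channel_correlation(self, rng):
        rho = 0.8
        chol = np.linalg.cholesky(np.array([[1.0, rho], [rho, 1.0]]))
        base = rng.standard_normal((100_000, 2)) @ chol.T
        x = MultichannelSignal(base, 100.0)
        carrier = ss1_carrier(x, SS1Params(noise_sigma=0.0, rng_seed=3))
        r = np.corrcoef(carrier.T)[0, 1]
        assert abs(r - rho) < 0.05

    def test_bit_reproducible(self, noise_signal):
        a = simulate_ss1(noise_signal, SS1Params(rng_seed=21))
        b = simulate_ss1(noise_signal, SS1Params(rng_seed=21))
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_carrier_decorrelates_past_filter_support(self, rng):
        # the carrier is FIR-filtered white noise: its autocorrelation must
        # vanish (to sampling error) at lags beyond the filter length
        taps = 31
        x = MultichannelSignal(rng.standard_normal((20_000, 1)), 100.0)
        p = SS1Params(
            filter=ShapingFilter(n_taps=taps), noise_sigma=0.0, rng_seed=5
        )
        y = ss1_carrier(x, p)[:, 0]
        y = y - y.mean()
        n = len(y)
        ac = np.correlate(y, y, "full")[n - 1 :] / np.dot(y, y)
        # Bartlett band: for a series with short-range correlation rho_k the
        # sample autocorrelation at dead lags has variance
        # (1 + 2 sum rho_k^2)/n; rho_k is the filter's own autocorrelation.
        # 4 sigma allows for the max over ~200 lags (family error ~1%).
        g = shaping_filter_response(ShapingFilter(n_taps=taps))
        rho = np.correlate(g, g, "full")[taps - 1 :] / np.dot(g, g)
        band = 4 * np.sqrt((1 + 2 * np.sum(rho[1:] ** 2)) / n)
        assert np.max(np.abs(ac[taps + 1 : taps + 200])) < band


class TestIGFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(2024)
        a0, b0 = 3.0, 2.0
        s2 = invgamma.rvs(a0, scale=b0, size=20_000, random_state=rng)
        x = rng.standard_normal(20_000) * np.sqrt(s2)
        fit = fit_inverse_gamma_em(x)
        assert abs(fit.alpha - a0) / a0 < 0.15
        assert abs(fit.beta - b0) / b0 < 0.15

    def test_loglik_monotone(self, rng):
        for data in [
            rng.standard_normal(2_000),
            rng.standard_t(df=5, size=2_000),
            np.concatenate([rng.standard_normal(1_000), 5 * rng.standard_normal(1_000)]),
        ]:
            fit = fit_inverse_gamma_em(data, max_iter=100)
            steps = np.diff(fit.loglik_trace)
            assert np.all(steps > -1e-8)

    def test_scale_equivariance(self, rng):
        x = rng.standard_t(df=6, size=5_000)
        k2 = 7.3
        f1 = fit_inverse_gamma_em(x, max_iter=300)
        f2 = fit_inverse_gamma_em(np.sqrt(k2) * x, max_iter=300)
        assert np.isclose(f2.alpha, f1.alpha, rtol=1e-6)
        assert np.isclose(f2.beta, k2 * f1.beta, rtol=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ParameterError):
            fit_inverse_gamma_em(np.zeros(100))
        with pytest.raises(ParameterError):
            fit_inverse_gamma_em(np.full(100, 2.0))
        with pytest.raises(ParameterError):
            fit_inverse_gamma_em(np.arange(5))  # too few samples


class TestSS2:
    def test_construction_oracle_identity_filter(self):
        """output / sqrt(variance envelope) is standard normal (KS)."""
        rng = np.random.default_rng(77)
        s2 = invgamma.rvs(3.0, scale=2.0, size=100_000, random_state=rng)
        x = MultichannelSignal(
            rng.standard_normal(100_000) * np.sqrt(s2), 100.0
        )
        p = SS2Params(filter=IDENTITY_FILTER, noise_sigma=0.0, rng_seed=11)
        y, details = simulate_ss2(x, p, return_details=True)
        z = y.samples[:, 0] / np.sqrt(details["variance_envelopes"][:, 0])
        stat = kstest(z, "norm").statistic
        assert stat < 0.01

    def test_constant_input_propagates_fit_error(self):
        x = MultichannelSignal(np.full((100, 1), 3.0), 100.0)
        with pytest.raises(ParameterError):
            simulate_ss2(x, SS2Params(rng_seed=0))

    def test_shape_and_determinism(self, noise_signal):
        a = simulate_ss2(noise_signal, SS2Params(rng_seed=13))
        b = simulate_ss2(noise_signal, SS2Params(rng_seed=13))
        assert a.samples.shape == noise_signal.samples.shape
        np.testing.assert_array_equal(a.samples, b.samples)
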