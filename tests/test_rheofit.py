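"""Relaxation-model fitting: closed forms, oracles, recovery studies."""

import numpy as np
import pytest
from scipy.special import erfi

from viscnet import (ForceCurve, chi_stat, convolve_relaxation,
                     fit_exponential, fit_power_law, generate_synthetic_curve,
                     hertz_exponent)
from viscnet.rheofit import exponential_dwell


class TestChiStat:
    def test_identical_vectors(self):
        x = np.linspace(0, 1, 20)
        assert chi_stat(x, x) == 0.0

    def test_constant_offset(self):
        x = np.zeros(13)
        assert chi_stat(x, x + 0.7) == pytest.approx(0.49)

    def test_matches_explicit_loop(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(size=7), rng.normal(size=7)
        acc = 0.0
        for i in range(7):
            acc += (a[i] - b[i]) ** 2
        assert chi_stat(a, b) == pytest.approx(acc / 7, abs=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            chi_stat(np.zeros(3), np.zeros(4))


class TestClosedForms:
    def test_exponential_dwell_amplitude_limits(self):
        # tau >> tau_l: the dwell amplitude at t = tau_l approaches dE
        t = np.array([1.0])
        f = exponential_dwell(t, E_inf=0.0, dE=2.0, tau=1e6, tau_l=1.0)
        assert f[0] == pytest.approx(2.0, rel=1e-4)
        # tau << tau_l: almost fully relaxed during loading
        f = exponential_dwell(t, E_inf=1.0, dE=2.0, tau=1e-3, tau_l=1.0)
        assert f[0] == pytest.approx(1.0, abs=1e-2)

    def test_dawson_form_equals_erfi_form(self):
        # direct evaluation of b e^(-(t-tau_l)/tau) - c e^(-t/tau)
        tau_l, tau, dE, E = 2.0, 3.5, 0.8, 0.4
        t = np.linspace(2.1, 40, 50)
        b = 1.5 * tau / tau_l * dE
        c = 0.75 * np.sqrt(np.pi) * (tau / tau_l) ** 1.5 * dE * erfi(
            np.sqrt(tau_l / tau))
        direct = E + b * np.exp(-(t - tau_l) / tau) - c * np.exp(-t / tau)
        assert exponential_dwell(t, E, dE, tau, tau_l) == pytest.approx(
            direct, rel=1e-12)


class TestSelfFits:
    def test_power_law_noiseless_recovery(self):
        curve = generate_synthetic_curve(
            "PL", {"E_inf": 0.2, "a": 1.0, "beta": 1.2}, tau_l=1.0,
            dwell_time=49.0)
        fit = fit_power_law(curve)
        assert fit.E_inf == pytest.approx(0.2, abs=1e-4)
        assert fit.a == pytest.approx(1.0, abs=1e-4)
        assert fit.beta == pytest.approx(1.2, abs=1e-4)
        assert fit.chi < 1e-12

    def test_exponential_noiseless_recovery(self):
        curve = generate_synthetic_curve(
            "EXP", {"E_inf": 0.3, "dE": 0.5, "tau": 2.0}, tau_l=1.0,
            dwell_time=30.0)
        fit = fit_exponential(curve)
        assert fit.E_inf == pytest.approx(0.3, abs=1e-4)
        assert fit.dE == pytest.approx(0.5, abs=1e-4)
        assert fit.tau == pytest.approx(2.0, abs=1e-4)
        # b and c follow the closed forms
        assert fit.b == pytest.approx(1.5 * fit.tau / 1.0 * fit.dE, rel=1e-9)

    @pytest.mark.parametrize("model", ["PL", "EXP"])
    def test_random_parameter_draws_recover(self, model):
        rng = np.random.default_rng(11)
        for _ in range(20):
            E, amp = rng.uniform(0.05, 2.0), rng.uniform(0.1, 3.0)
            if model == "PL":
                params = {"E_inf": E, "a": amp,
                          "beta": rng.uniform(0.3, 2.5)}
                truth = [params["E_inf"], params["a"], params["beta"]]
            else:
                params = {"E_inf": E, "dE": amp,
                          "tau": rng.uniform(0.2, 10.0)}
                truth = [params["E_inf"], params["dE"], params["tau"]]
            curve = generate_synthetic_curve(model, params, tau_l=1.0,
                                             dwell_time=60.0, n_samples=3000)
            fit = (fit_power_law if model == "PL" else fit_exponential)(curve)
            got = ([fit.E_inf, fit.a, fit.beta] if model == "PL"
                   else [fit.E_inf, fit.dE, fit.tau])
            assert got == pytest.approx(truth, rel=1e-4, abs=1e-4)

    def test_cross_model_misfit_exponential_truth(self):
        # exponential truth with SNR 100: the wrong (power-law) model
        # misfits by far more than the right one
        params = {"E_inf": 0.3, "dE": 1.0, "tau": 3.0}
        curve = generate_synthetic_curve("EXP", params, tau_l=1.0,
                                         dwell_time=30.0, noise_sd=0.01,
                                         seed=123)
        chi_E = fit_exponential(curve).chi
        chi_P = fit_power_law(curve).chi
        assert chi_P >= 2.0 * chi_E

    def test_flat_curve_gives_zero_amplitude(self):
        t = 1.0 + np.linspace(0.01, 30.0, 500)
        curve = ForceCurve(t=t, delta=np.full_like(t, 0.8),
                           f_raw=np.full_like(t, 0.42),
                           f_norm=np.full_like(t, 0.42), tau_l=1.0,
                           meta={"sigma_s": 11.0, "delta_max": 0.8})
        fit = fit_exponential(curve)
        assert fit.dE * np.exp(-0.0) == pytest.approx(0.0, abs=1e-6)
        assert fit.E_inf == pytest.approx(0.42, abs=1e-9)

    def test_insufficient_dwell_samples(self):
        t = np.linspace(0.1, 0.9, 20)  # all during loading
        curve = ForceCurve(t=t, delta=t, f_raw=t, f_norm=t, tau_l=1.0,
                           meta={})
        with pytest.raises(ValueError):
            fit_power_law(curve)


class TestHertzExponent:
    @staticmethod
    def loading_curve(lam, delta_max=1.0, prefactor=2.0):
        t = np.linspace(0.001, 1.0, 400)
        delta = delta_max * t
        f = prefactor * delta ** lam
        return ForceCurve(t=t, delta=delta, f_raw=f, f_norm=f, tau_l=1.0,
                          meta={"delta_max": delta_max})

    def test_exact_power_law_recovered(self):
        fit = hertz_exponent(self.loading_curve(1.5))
        assert fit.lam == pytest.approx(1.5, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_conical_like_exponent(self):
        assert hertz_exponent(self.loading_curve(2.0)).lam == pytest.approx(
            2.0, abs=1e-12)

    def test_rejects_nonpositive_force(self):
        curve = self.loading_curve(1.5)
        curve.f_norm[-10] = -1.0
        with pytest.raises(ValueError):
            hertz_exponent(curve)


class TestConvolutionOracle:
    @staticmethod
    def ramp_hold(tau_l, T, n):
        t = np.linspace(T / n, T, n)
        delta = np.minimum(t / tau_l, 1.0)
        return t, delta

    def test_elastic_limit_exact(self):
        t, delta = self.ramp_hold(1.0, 5.0, 2000)
        R = np.full_like(t, 0.7)
        F = convolve_relaxation(t, R, delta, delta_max=1.0)
        # skip the earliest samples, where the quadrature has almost no
        # support and the force itself is ~0
        m = t > 0.1
        assert F[m] == pytest.approx(0.7 * delta[m] ** 1.5, rel=5e-3)

    def test_quadrature_matches_exponential_closed_form(self):
        tau_l, T, n = 1.0, 20.0, 10_000
        E, dE, tau = 0.4, 1.0, 2.5
        t, delta = self.ramp_hold(tau_l, T, n)
        R = E + dE * np.exp(-t / tau)
        # R(t) sampled from lag 0: shift so R[0] corresponds to lag ~0
        lag = t - t[0]
        Rlag = E + dE * np.exp(-lag / tau)
        F = convolve_relaxation(t, Rlag, delta, delta_max=1.0)
        dwell = t > 2 * tau_l
        expected = exponential_dwell(t[dwell], E, dE, tau, tau_l)
        assert np.max(np.abs(F[dwell] - expected) / expected) < 0.01

    def test_quadrature_power_law_tail_slope(self):
        # R ~ t^-beta with beta = 0.5: the dwell force decays with
        # log-log slope -beta once t >> tau_l
        tau_l, T, n = 1.0, 400.0, 40_000
        beta = 0.5
        t, delta = self.ramp_hold(tau_l, T, n)
        lag = t - t[0]
        Rlag = (lag + 1e-9) ** -beta
        F = convolve_relaxation(t, Rlag, delta, delta_max=1.0)
        tail = t > 50 * tau_l
        slope = np.polyfit(np.log(t[tail]), np.log(F[tail]), 1)[0]
        assert slope == pytest.approx(-beta, rel=0.02)

    def test_rejects_non_monotone_time(self):
        t = np.array([0.0, 1.0, 0.5])
        with pytest.raises(ValueError):
            convolve_relaxation(t, t, t)


class TestSyntheticGenerator:
    def test_same_seed_identical(self):
        kw = dict(model="PL", params={"E_inf": 0.2, "a": 1.0, "beta": 0.8},
                  tau_l=1.0, dwell_time=10.0, noise_sd=0.05, seed=7)
        a = generate_synthetic_curve(**kw)
        b = generate_synthetic_curve(**kw)
        assert np.array_equal(a.f_norm, b.f_norm)

    def test_noise_increases_chi_of_true_model(self):
        params = {"E_inf": 0.3, "dE": 1.0, "tau": 2.0}
        chis = []
        for sd in (0.0, 0.01, 0.05, 0.2):
            curve = generate_synthetic_curve("EXP", params, tau_l=1.0,
                                             dwell_time=20.0, noise_sd=sd,
                                             seed=42)
            chis.append(fit_exponential(curve).chi)
        assert np.all(np.diff(chis) > 0)

    def test_beta_recovery_bias_at_one_percent_noise(self):
        # Monte-Carlo recovery: 1% (of dE-scale) Gaussian noise, many
        # seeds; the fitted beta is unbiased to within 0.02
        params = {"E_inf": 0.2, "a": 1.0, "beta": 1.2}
        betas = []
        for seed in range(100):
            curve = generate_synthetic_curve("PL", params, tau_l=1.0,
                                             dwell_time=49.0, n_samples=500,
                                             noise_sd=0.01, seed=seed)
            betas.append(fit_power_law(curve).beta)
        assert abs(np.mean(betas) - 1.2) < 0.02

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_synthetic_curve("XX", {}, 1.0, 1.0)
        with pytest.raises(ValueError):
            generate_synthetic_curve("PL", {"E_inf": 0, "a": 1, "beta": 1},
                                     1.0, 1.0, noise_sd=-0.1)
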