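import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from patchykin.meanfield import (KamalParams, MeanFieldRateParams,
                                 diffusion_model, effective_barrier,
                                 expected_attempts, integrate_kinetics,
                                 kamal_rate, rate_constants_auto,
                                 rate_constants_fixed)


def _params(**kw):
    base = dict(k_c=4.56e-3, k_d=1.015, n0=2.01, n_inf=1.830, b=0.31,
                D0=0.05, p0=0.902, gamma=2.69)
    base.update(kw)
    return MeanFieldRateParams(**base)


class TestEffectiveBarrier:
    def test_initial_value(self):
        assert effective_barrier(0.0, 4.0, 50.0) == 4.0

    def test_boltzmann_factor_linear_growth(self):
        # e^(-dU) = e^(-dU0) (1 + xi p) exactly while unfloored
        p = np.linspace(0, 0.4, 9)
        dU = effective_barrier(p, 4.0, 50.0)
        lhs = np.exp(-dU)
        rhs = np.exp(-4.0) * (1 + 50.0 * p)
        assert np.allclose(lhs, rhs, rtol=1e-14)

    @given(st.floats(0, 1), st.floats(0, 6), st.floats(0, 100))
    @settings(deadline=None, max_examples=50)
    def test_monotone_nonincreasing_in_p(self, p, dU0, xi):
        v1 = effective_barrier(p, dU0, xi)
        v2 = effective_barrier(min(1.0, p + 0.05), dU0, xi)
        assert v2 <= v1 + 1e-12


class TestExpectedAttempts:
    def test_values(self):
        assert expected_attempts(0.0) == 1.0
        assert expected_attempts(4.0) == pytest.approx(54.598, abs=1e-3)

    def test_matches_truncated_series(self):
        # Eq: N = sum n q^n / sum q^n with q = 1 - e^(-bdU)
        for bdU in (0.5, 1.0, 2.0, 3.0):
            q = 1 - np.exp(-bdU)
            n = np.arange(1, 4000)
            series = np.sum(n * q**n) / np.sum(q**n)
            assert expected_attempts(bdU) == pytest.approx(series, rel=1e-10)

    def test_log_linear(self):
        x = np.linspace(0, 5, 11)
        assert np.allclose(np.diff(np.log(expected_attempts(x))),
                           np.diff(x), rtol=1e-12)


class TestRateConstants:
    def test_no_barrier_case(self):
        par = _params()
        k_chem, k_diff, k_all = rate_constants_fixed(
            0.3, 0.02, par, 0.0, n=2.0, k0=1.0)
        assert k_chem == pytest.approx(par.k_c)
        assert k_diff == pytest.approx(par.k_d * 0.02)
        assert k_all == pytest.approx(1 / (1 / k_chem + 1 / k_diff))

    def test_harmonic_limits(self):
        par = _params()
        _, k_diff, k_all = rate_constants_fixed(0.1, 1e12, par, 0.0)
        # k_diff huge -> k_overall ~ k_chem
        k_chem = rate_constants_fixed(0.1, 1e12, par, 0.0)[0]
        assert k_all == pytest.approx(k_chem, rel=1e-6)
        # equal channels halve
        kc, kd, ka = rate_constants_fixed(0.0, par.k_c / par.k_d, par, 0.0,
                                          n=2.0, k0=1.0)
        assert ka == pytest.approx(kc / 2)

    def test_diffusion_arrest_is_not_an_error(self):
        par = _params()
        _, _, k_all = rate_constants_fixed(0.2, 0.0, par, 1.0)
        assert k_all == 0.0

    def test_xi_zero_reduces_to_fixed(self):
        par = _params(dU0=2.0, xi=0.0)
        p = np.linspace(0, 0.8, 17)
        D = par.D(p)
        assert np.allclose(rate_constants_auto(p, D, par),
                           rate_constants_fixed(p, D, par, 2.0), rtol=1e-12)

    def test_substitution_identity(self):
        """Plugging the decreasing barrier into the fixed-barrier rates
        reproduces the autocatalytic forms to 1e-12 (while unfloored)."""
        rng = np.random.default_rng(3)
        for _ in range(30):
            dU0 = rng.uniform(0.2, 5.0)
            xi = rng.uniform(0.0, 80.0)
            p = rng.uniform(0.0, 0.95)
            dU = effective_barrier(p, dU0, xi)
            if dU <= 0.0:
                continue
            par = _params(dU0=dU0, xi=xi)
            D = float(par.D(p))
            n_p = par.n_inf + (par.n0 - par.n_inf) * (1 + xi * p) \
                * np.exp(-dU0)
            k0_p = (1 + xi * p) ** (-par.b) * np.exp(par.b * dU0)
            fixed = rate_constants_fixed(p, D, par, float(dU), n=n_p,
                                         k0=k0_p)
            auto = rate_constants_auto(p, D, par)
            assert np.allclose(fixed, auto, rtol=1e-12)

    @given(st.floats(0.0, 0.9), st.floats(1e-4, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_harmonic_mean_bound(self, p, D):
        par = _params()
        k_chem, k_diff, k_all = rate_constants_fixed(p, D, par, 1.0)
        assert k_all <= min(k_chem, k_diff) + 1e-15


class TestDiffusionModel:
    def test_endpoints(self):
        assert diffusion_model(0.0, 0.05, 0.902, 2.69) == 0.05
        assert diffusion_model(0.902, 0.05, 0.902, 2.69) == 0.0

    def test_half_arrest_value(self):
        # p = p0/2: D/D0 = 0.5^gamma
        val = diffusion_model(0.451, 1.0, 0.902, 2.69)
        assert val == pytest.approx(0.5 ** 2.69, rel=1e-12)
        assert val == pytest.approx(0.1549, abs=5e-4)

    def test_beyond_arrest_warns_and_zeroes(self):
        with pytest.warns(UserWarning):
            assert diffusion_model(0.95, 1.0, 0.902, 2.69) == 0.0


class TestKamal:
    def test_constant_limit(self):
        kp = KamalParams(k1=0.3, k2=0.0, M=1.0, N=2.0)
        p = np.linspace(0, 0.9, 10)
        assert np.allclose(kamal_rate(p, kp), 0.3)

    def test_contains_linear_autocatalytic_form(self):
        # M=1, N=n reproduces k_c (1 + xi p)(1-p)^(n-2) with k1 = k_c
        kp = KamalParams(k1=2.0, k2=6.0, M=1.0, N=1.9)
        p = np.linspace(0, 0.9, 20)
        expect = 2.0 * (1 + 3.0 * p) * (1 - p) ** (1.9 - 2.0)
        assert np.allclose(kamal_rate(p, kp), expect, rtol=1e-12)
        assert kp.xi_hat == pytest.approx(3.0)


class TestIntegrateKinetics:
    def test_constant_rate_closed_form(self):
        """dp/dt = k (1-p)^2 has the exact solution p = kt/(1+kt)."""
        par = _params(p0=1.0)
        t = np.linspace(0, 10, 101)
        curve = integrate_kinetics(par, t, k_overall=lambda p: 1.0)
        assert np.abs(curve.p - t / (1 + t)).max() < 1e-8

    def test_zero_rate(self):
        par = _params()
        curve = integrate_kinetics(par, np.linspace(0, 5, 11),
                                   k_overall=lambda p: 0.0)
        assert np.all(curve.p == 0.0)

    def test_sigmoidal_rate_maximum_with_autocatalysis(self):
        par = _params(dU0=4.0, xi=50.0)
        t = np.linspace(0, 3000, 600)
        curve = integrate_kinetics(par, t, mode="auto")
        rate = np.gradient(curve.p, t)
        k = int(np.argmax(rate))
        assert 0 < k < len(t) - 1
        assert curve.p[k] > 0.01

    def test_monotone_and_bounded(self):
        par = _params(dU0=1.0, xi=10.0)
        t = np.linspace(0, 5e4, 400)
        curve = integrate_kinetics(par, t, mode="auto")
        assert np.all(np.diff(curve.p) >= -1e-15)
        assert curve.p[-1] <= par.p0

    def test_time_rescaling_collapse(self):
        """Pure chemical regime with n, k0 frozen at their dU values:
        curves at different barriers collapse when t is scaled by
        exp(beta dU)."""
        par = _params()
        t = np.linspace(0, 400, 201)
        base = integrate_kinetics(
            par, t, k_overall=lambda p: par.k_c * (1 - p) ** 0.0)
        for bdU in (1.0, 2.0):
            fac = np.exp(-bdU)
            scaled = integrate_kinetics(
                par, t / fac,
                k_overall=lambda p: par.k_c * fac * (1 - p) ** 0.0)
            assert np.allclose(scaled.p, base.p, atol=1e-9)

    def test_bad_grid_rejected(self):
        par = _params()
        with pytest.raises(ValueError):
            integrate_kinetics(par, [0.0, 0.0, 1.0])
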