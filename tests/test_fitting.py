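import numpy as np
import pytest
from scipy import stats as sps

from patchykin.fitting import (ExperimentalIsotherm, arrhenius,
                               fit_epoxy_multi_isotherm, fit_fixed_barrier,
                               fit_kamal, fit_no_barrier)
from patchykin.meanfield import (KamalParams, MeanFieldRateParams,
                                 integrate_kinetics, kamal_rate,
                                 rate_constants_fixed)
from patchykin.observables import KineticCurve
from patchykin.synth import SyntheticIsothermSpec, generate_synthetic_isotherms

TRUTH = MeanFieldRateParams(k_c=4.56e-3, k_d=1.015, n0=2.01, n_inf=1.830,
                            b=0.31, D0=0.05, p0=0.902, gamma=2.69)


def _noisy_curve(params, t_max, rng, sigma=0.002, n=80, mode="auto"):
    t = np.linspace(0.0, t_max, n)
    clean = integrate_kinetics(params, t, mode=mode)
    p = np.clip(clean.p + rng.normal(scale=sigma, size=n), 0, 0.999)
    p = np.maximum.accumulate(p)
    return KineticCurve(times=t, p=p, sem=np.full(n, sigma))


def _mahalanobis2(theta_hat, theta_true, cov):
    d = np.asarray(theta_hat) - np.asarray(theta_true)
    return float(d @ np.linalg.solve(cov, d))


class TestNoBarrierFit:
    def test_parameter_recovery(self):
        rng = np.random.default_rng(0)
        curve = _noisy_curve(TRUTH, 600.0, rng, sigma=0.0015, mode="fixed")
        res = fit_no_barrier(curve, TRUTH.D)
        # joint 2-sigma ellipse for 2 parameters
        m2 = _mahalanobis2(res.values, [TRUTH.k_c, TRUTH.k_d], res.cov)
        assert m2 < sps.chi2.ppf(0.954, 2) * 2.5

    def test_unidentifiable_diffusive_channel(self):
        rng = np.random.default_rng(1)
        par = MeanFieldRateParams(k_c=4.56e-3, k_d=1e4, D0=1.0, p0=1.0,
                                  gamma=1.0)
        curve = _noisy_curve(par, 150.0, rng, sigma=0.001, mode="fixed")
        res = fit_no_barrier(curve, lambda p: np.ones_like(p))
        assert res.flags.get("k_d_unidentifiable", False)
        assert res["k_c"] == pytest.approx(par.k_c, rel=0.05)


class TestFixedBarrierFit:
    def _curves(self, rng, bdUs=(1.0, 2.0, 4.0), sigma=0.001):
        curves = {}
        import dataclasses

        for bdU in bdUs:
            par = dataclasses.replace(TRUTH, dU0=bdU, xi=0.0)
            t_max = 500.0 * np.exp(bdU)
            curves[bdU] = _noisy_curve(par, t_max, rng, sigma=sigma,
                                       mode="fixed")
        return curves

    def test_per_barrier_recovery_and_laws(self):
        rng = np.random.default_rng(2)
        curves = self._curves(rng)
        res = fit_fixed_barrier(curves, TRUTH.k_c, TRUTH.k_d, TRUTH.D)
        for bdU, fr in res.per_barrier.items():
            n_true = TRUTH.n_inf + (TRUTH.n0 - TRUTH.n_inf) * np.exp(-bdU)
            k0_true = np.exp(TRUTH.b * bdU)
            assert abs(fr["n"] - n_true) < max(3 * fr.sigma("n"), 0.02)
            assert abs(fr["k0"] - k0_true) < max(3 * fr.sigma("k0"),
                                                 0.05 * k0_true)
        assert res.b == pytest.approx(TRUTH.b, abs=max(3 * res.b_sigma, 0.05))
        assert res.n_inf == pytest.approx(
            TRUTH.n_inf, abs=max(3 * res.n_inf_sigma, 0.03))

    def test_zero_barrier_limit(self):
        rng = np.random.default_rng(3)
        curves = self._curves(rng, bdUs=(0.0,), sigma=0.001)
        res = fit_fixed_barrier(curves, TRUTH.k_c, TRUTH.k_d, TRUTH.D,
                                fit_laws=False)
        fr = res.per_barrier[0.0]
        assert fr["n"] == pytest.approx(2.01, abs=0.05)
        assert fr["k0"] == pytest.approx(1.0, abs=0.1)

    def test_law_fit_needs_three_barriers(self):
        rng = np.random.default_rng(4)
        curves = self._curves(rng, bdUs=(1.0, 2.0))
        with pytest.raises(ValueError):
            fit_fixed_barrier(curves, TRUTH.k_c, TRUTH.k_d, TRUTH.D)


class TestKamalFit:
    def test_self_recovery(self):
        rng = np.random.default_rng(5)
        kp_true = KamalParams(k1=2e-3, k2=8e-3, M=1.2, N=1.8)
        par = MeanFieldRateParams(k_c=1.0, k_d=1e6, D0=1.0, p0=1.0,
                                  gamma=1.0)
        t = np.linspace(0, 900.0, 90)
        clean = integrate_kinetics(par, t, mode="kamal", kamal=kp_true)
        p = np.clip(clean.p + rng.normal(scale=5e-4, size=len(t)), 0, 0.999)
        curve = KineticCurve(times=t, p=np.maximum.accumulate(p),
                             sem=np.full(len(t), 5e-4))
        kp, res = fit_kamal(curve)
        assert kp.k1 == pytest.approx(kp_true.k1, rel=0.2)
        assert kp.xi_hat == pytest.approx(kp_true.xi_hat, rel=0.2)
        assert kp.N == pytest.approx(kp_true.N, abs=0.15)

    def test_k2_zero_on_non_autocatalytic_data(self):
        rng = np.random.default_rng(6)
        import dataclasses

        par = dataclasses.replace(TRUTH, dU0=0.0, xi=0.0)
        curve = _noisy_curve(par, 400.0, rng, sigma=0.001, mode="fixed")
        kp_free, res_free = fit_kamal(curve, D_of_p=TRUTH.D, k_d=TRUTH.k_d)
        kp_zero, res_zero = fit_kamal(curve, D_of_p=TRUTH.D, k_d=TRUTH.k_d,
                                      fix_k2_zero=True)
        # constraining k2 = 0 does not degrade the description
        assert res_zero.rmse <= 1.3 * res_free.rmse + 1e-12

    def test_xi_bias_against_barrier_effect_data(self):
        """Kamal fits describe barrier-effect kinetics well yet may
        misestimate the autocatalytic strength k2/k1."""
        rng = np.random.default_rng(7)
        import dataclasses

        xi_true = 20.0
        par = dataclasses.replace(TRUTH, dU0=2.0, xi=xi_true)
        curve = _noisy_curve(par, 2500.0, rng, sigma=0.001, mode="auto")
        kp, res = fit_kamal(curve)
        assert kp.k2 > 0
        # good description despite the wrong functional form
        assert res.rmse < 10.0
        # the estimate lands near xi but is not guaranteed to match it
        assert 0.3 * xi_true < kp.xi_hat < 3.0 * xi_true


class TestEpoxyFit:
    def test_recovery_from_synthetic_isotherms(self):
        spec = SyntheticIsothermSpec(noise=0.0015)
        isos, truth = generate_synthetic_isotherms(
            spec, rng=np.random.default_rng(8))
        fit = fit_epoxy_multi_isotherm(isos, n_starts=4, seed=0)
        assert fit.dU_c == pytest.approx(truth.dU_c, rel=0.10)
        assert fit.dU_a == pytest.approx(truth.dU_a, rel=0.10)
        assert fit.n_inf == pytest.approx(truth.n_inf, abs=0.15)
        assert fit.lam == pytest.approx(truth.lam, abs=0.15)

    def test_equal_enthalpies_recovered_as_equal(self):
        from patchykin.fitting import EpoxyFitParams

        truth = EpoxyFitParams(dU_c=9.6e-20, dU_a=9.6e-20, A=5e6, B=2e7,
                               n_inf=1.4, k_d=6e-3, lam=0.45)
        spec = SyntheticIsothermSpec(truth=truth, noise=0.001,
                                     T_list=(335.0, 350.0, 365.0))
        isos, _ = generate_synthetic_isotherms(
            spec, rng=np.random.default_rng(9))
        fit = fit_epoxy_multi_isotherm(isos, n_starts=4, seed=1)
        assert abs(fit.dU_c - fit.dU_a) < 0.08 * truth.dU_c

    def test_needs_two_isotherms(self):
        spec = SyntheticIsothermSpec(T_list=(340.0,))
        isos, _ = generate_synthetic_isotherms(
            spec, rng=np.random.default_rng(10))
        with pytest.raises(ValueError):
            fit_epoxy_multi_isotherm(isos)


class TestArrhenius:
    def test_single_temperature_no_slope(self):
        from patchykin.synth import default_truth

        k1, k2, s1, s2 = arrhenius(default_truth(), [350.0])
        assert s1 is None and s2 is None
        assert k1.shape == (1,)

    def test_two_point_slope_exact(self):
        from patchykin.fitting import K_B
        from patchykin.synth import default_truth

        truth = default_truth()
        _, _, s1, s2 = arrhenius(truth, [330.0, 360.0])
        assert s1 == pytest.approx(-truth.dU_c / K_B, rel=1e-12)
        assert s2 == pytest.approx(-truth.dU_a / K_B, rel=1e-12)

    def test_noisy_regression_recovery(self):
        from patchykin.fitting import K_B
        from patchykin.synth import default_truth

        rng = np.random.default_rng(11)
        truth = default_truth()
        T = np.linspace(320.0, 380.0, 5)
        lnk = np.log(truth.k1(T)) + rng.normal(scale=0.02, size=5)
        slope, _ = np.polyfit(1.0 / T, lnk, 1)
        # 2-sigma of the regression slope
        resid = lnk - np.polyval(np.polyfit(1.0 / T, lnk, 1), 1.0 / T)
        x = 1.0 / T
        s_slope = np.sqrt(np.sum(resid**2) / 3 / np.sum((x - x.mean()) ** 2))
        assert abs(slope - (-truth.dU_c / K_B)) < 2 * s_slope + 0.05 * abs(
            truth.dU_c / K_B)
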