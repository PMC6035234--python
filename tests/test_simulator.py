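import numpy as np
import pytest
from scipy import stats as sps
from scipy.integrate import solve_ivp

import patchykin._kernels as K
from patchykin.simulate import (EventStats, advance,
                                autocatalytic_barrier_update,
                                crossing_statistics, site_barrier_event,
                                thermostat_rescale)
from patchykin.state import InteractionParams


class TestFreeFlight:
    def test_single_particle_ballistic(self, two_body_factory):
        st = two_body_factory([1], [[50.0, 50.0, 50.0]], [[0.3, -0.2, 0.1]])
        advance(st, InteractionParams(), 7.0, thermostat_interval=None)
        t_nat = 7.0 * np.sqrt(10.0)
        expect = np.array([50.0, 50.0, 50.0]) + t_nat * np.array([0.3, -0.2, 0.1])
        assert np.allclose(st.pos[0], expect, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_symmetric_top_flight_matches_ode(self, seed):
        """Closed-form torque-free rotation equals an ODE integration."""
        rng = np.random.default_rng(seed)
        I1, I3 = 70.72, 5.44
        q0 = rng.normal(size=4)
        q0 /= np.linalg.norm(q0)
        L = rng.normal(size=3) * 4.0

        def rhs(t, y):
            q = y / np.linalg.norm(y)
            w = K.omega_world(q, L, I1, I3)
            return 0.5 * K.q_mul(np.array([0.0, *w]), q)

        T = 1.5
        sol = solve_ivp(rhs, (0, T), q0, rtol=1e-12, atol=1e-12)
        qn = sol.y[:, -1] / np.linalg.norm(sol.y[:, -1])
        qc = K.flight_quat(q0, L, I1, I3, T)
        assert np.abs(K.q_to_mat(qc) - K.q_to_mat(qn)).max() < 1e-9


class TestCollisions:
    def test_head_on_equal_mass_velocity_exchange(self, two_body_factory):
        st = two_body_factory([1, 1],
                              [[50, 50, 40.0], [50, 50, 60.0]],
                              [[0, 0, 1.0], [0, 0, -1.0]])
        stats = EventStats()
        advance(st, InteractionParams(dU0=100.0), 3.0,
                thermostat_interval=None, stats=stats)
        assert stats.core_collisions == 1
        assert np.allclose(st.vel[:, 2], [-1.0, 1.0], atol=1e-10)

    def test_nve_conservation(self, packed_state):
        st = packed_state.copy()
        E0 = sum(st.kinetic_energy())
        mom0 = (st.masses[:, None] * st.vel).sum(axis=0)
        stats = EventStats()
        advance(st, InteractionParams(), 2.0, thermostat_interval=None,
                frozen=True, stats=stats)
        E1 = sum(st.kinetic_energy())
        mom1 = (st.masses[:, None] * st.vel).sum(axis=0)
        assert stats.core_collisions > 0
        assert abs(E1 - E0) / E0 < 1e-6 * 2.0  # < 1e-6 per unit time
        assert np.abs(mom1 - mom0).max() < 1e-10


class TestBarrierEvents:
    def _aligned_pair(self, two_body_factory, v_rel, gap=0.6):
        """A tip site approaching B's equatorial site head-on along z.

        B lies along x (rotated 90 deg about y) with its equatorial site
        pointing down, so the two sites meet before the hard cores touch.
        """
        s2 = np.sqrt(0.5)
        st = two_body_factory(
            [0, 1],
            [[50, 50, 40.0], [50.0, 50.0, 51.0 + gap]],
            [[0, 0, v_rel], [0, 0, 0.0]],
            quat=[[1, 0, 0, 0], [s2, 0, s2, 0]])
        return st

    def test_zero_barrier_always_crosses(self, two_body_factory):
        st = self._aligned_pair(two_body_factory, 1.0)
        params = InteractionParams(dU0=0.0)
        stats = EventStats()
        advance(st, params, 2.0, thermostat_interval=None, stats=stats)
        assert stats.attempts >= 1
        assert stats.crossings == stats.attempts
        assert len(st.registry) == 1

    def test_huge_barrier_reflects(self, two_body_factory):
        st = self._aligned_pair(two_body_factory, 1.0)
        params = InteractionParams(dU0=500.0)
        stats = EventStats()
        advance(st, params, 2.0, thermostat_interval=None, stats=stats)
        assert stats.attempts >= 1
        assert stats.crossings == 0
        assert len(st.registry) == 0

    def test_bonded_pair_confined_forever(self, two_body_factory):
        st = self._aligned_pair(two_body_factory, 1.0)
        params = InteractionParams(dU0=0.0, u0=0.1)
        stats = EventStats()
        advance(st, params, 30.0, thermostat_interval=None, stats=stats)
        assert len(st.registry) == 1
        # the bonded site pair never separates beyond delta
        (sa, sb), = st.registry.pairs
        i, j = st.site_owner[sa], st.site_owner[sb]
        xa = st.pos[i] + K.q_to_mat(st.quat[i]) @ st.site_local[sa]
        xb = st.pos[j] + K.q_to_mat(st.quat[j]) @ st.site_local[sb]
        assert np.linalg.norm(xb - xa) <= 0.2 + 1e-7
        assert stats.wall_reflections > 0

    def test_site_barrier_event_energetics(self, two_body_factory):
        st = self._aligned_pair(two_body_factory, 1.0)
        st.dU = 100.0  # far above the pair's radial kinetic energy
        out = site_barrier_event(st, (0, 6), InteractionParams(dU0=100.0))
        assert out == "reflected"
        st2 = self._aligned_pair(two_body_factory, 1.0)
        st2.dU = 0.0
        out2 = site_barrier_event(st2, (0, 6), InteractionParams(dU0=0.0))
        assert out2 == "crossed"
        assert len(st2.registry) == 1

    def test_site_barrier_event_rejects_same_type(self, two_body_factory):
        st = self._aligned_pair(two_body_factory, 1.0)
        with pytest.raises(ValueError):
            site_barrier_event(st, (0, 1), InteractionParams())


class TestAutocatalyticBarrier:
    def test_initial_value_at_p_zero(self, two_body_factory):
        st = two_body_factory([0, 1], [[10, 10, 10], [90, 90, 90]],
                              np.zeros((2, 3)))
        params = InteractionParams(dU0=4.0, xi=50.0)
        assert autocatalytic_barrier_update(st, params) == 4.0

    def test_formula_value(self):
        # dU0=4, xi=50, p=0.5 -> 4 - ln 26
        from patchykin.meanfield import effective_barrier

        val = effective_barrier(0.5, 4.0, 50.0)
        assert val == pytest.approx(4.0 - np.log(26.0), abs=1e-12)
        assert val == pytest.approx(0.7420, abs=1e-4)  # printed precision

    def test_floor_at_zero(self):
        from patchykin.meanfield import effective_barrier

        assert effective_barrier(0.9, 1.0, 50.0) == 0.0

    def test_xi_zero_constant(self):
        from patchykin.meanfield import effective_barrier

        ps = np.linspace(0, 1, 11)
        assert np.all(effective_barrier(ps, 3.0, 0.0) == 3.0)

    def test_negative_xi_rejected(self):
        with pytest.raises(ValueError):
            InteractionParams(xi=-1.0)


class TestThermostat:
    def test_identity_at_target(self, packed_state):
        st = packed_state.copy()
        thermostat_rescale(st, 1.0)
        tr, ro = st.kinetic_energy()
        before = st.vel.copy()
        thermostat_rescale(st, 1.0)
        assert np.allclose(st.vel, before, rtol=1e-12)

    def test_doubling_restored(self, packed_state):
        st = packed_state.copy()
        thermostat_rescale(st, 1.0)
        e_ref = sum(st.kinetic_energy())
        st.vel *= 2.0
        st.angmom *= 2.0
        thermostat_rescale(st, 1.0)
        assert sum(st.kinetic_energy()) == pytest.approx(e_ref, rel=1e-12)

    def test_zero_velocities_error(self, two_body_factory):
        st = two_body_factory([1, 1], [[10, 10, 10], [90, 90, 90]],
                              np.zeros((2, 3)))
        with pytest.raises(ValueError):
            thermostat_rescale(st, 1.0)

    def test_long_run_kinetic_temperature(self, packed_state):
        """Time-averaged kinetic temperature equals the target within 1%."""
        st = packed_state.copy()
        temps = []

        def probe(s):
            tr, _ = s.kinetic_energy()
            temps.append(tr / (1.5 * s.n_particles))

        advance(st, InteractionParams(), 2.0, frozen=True, on_block=probe)
        assert np.mean(temps) == pytest.approx(1.0, abs=0.01)


class TestCrossingStatistics:
    def test_zero_barrier_first_attempt(self):
        rng = np.random.default_rng(0)
        fails = crossing_statistics(InteractionParams(dU0=0.0), 1000, rng)
        assert np.all(fails == 0)

    @pytest.mark.parametrize("mode", ["energetic", "stochastic"])
    def test_mean_attempts_boltzmann(self, mode):
        """Mean attempts per bond = exp(beta dU) (thermalized flux)."""
        rng = np.random.default_rng(11)
        params = InteractionParams(dU0=2.0, crossing_mode=mode)
        fails = crossing_statistics(params, 100_000, rng)
        attempts = fails + 1.0
        sem = attempts.std(ddof=1) / np.sqrt(len(attempts))
        assert abs(attempts.mean() - np.exp(2.0)) < 3 * sem

    def test_high_barrier_mean(self):
        rng = np.random.default_rng(13)
        fails = crossing_statistics(InteractionParams(dU0=4.0), 100_000, rng)
        attempts = fails + 1.0
        sem = attempts.std(ddof=1) / np.sqrt(len(attempts))
        assert abs(attempts.mean() - np.exp(4.0)) < 3 * sem

    def test_geometric_distribution_gof(self):
        """Failure counts pass a chi-square test against the geometric law."""
        rng = np.random.default_rng(17)
        bdU = 1.5
        fails = crossing_statistics(InteractionParams(dU0=bdU), 50_000, rng)
        q = 1.0 - np.exp(-bdU)
        kmax = 12
        obs = np.bincount(np.minimum(fails, kmax), minlength=kmax + 1)
        probs = (1 - q) * q ** np.arange(kmax)
        probs = np.append(probs, q ** kmax)  # tail lumped
        chi2 = np.sum((obs - len(fails) * probs) ** 2 / (len(fails) * probs))
        pval = sps.chi2.sf(chi2, df=kmax)
        assert pval > 0.01
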