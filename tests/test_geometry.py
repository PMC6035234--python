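import numpy as np
import pytest

from patchykin.geometry import (BoxSpec, Pose, box_for_packing, build_species,
                                pw_contact, random_packing, world_sites)


def _sphere(radius):
    """A synthetic spherical 'species' for contact-function checks."""
    from patchykin.geometry import EllipsoidSpecies

    return EllipsoidSpecies(label="A", semiaxes=np.full(3, radius), mass=1.0,
                            principal_moments=np.full(3, 0.4 * radius**2),
                            site_local_positions=np.zeros((0, 3)))


class TestSpecies:
    @pytest.mark.parametrize("label,semiaxes,mass,valence", [
        ("A", (2, 2, 10), 3.4, 2),
        ("B", (1, 1, 5), 1.0, 5),
    ])
    def test_constructor_geometry(self, label, semiaxes, mass, valence):
        sp = build_species(label)
        assert np.allclose(sp.semiaxes, semiaxes)
        assert sp.mass == mass
        assert sp.valence == valence

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            build_species("C")

    @pytest.mark.parametrize("label", ["A", "B"])
    def test_sites_on_surface(self, label):
        sp = build_species(label)
        for site in sp.site_local_positions:
            assert abs(np.sum((site / sp.semiaxes) ** 2) - 1.0) < 1e-9

    @pytest.mark.parametrize("label", ["A", "B"])
    def test_uniform_density_moments(self, label):
        sp = build_species(label)
        a, b, c = sp.semiaxes
        expect = sp.mass / 5.0 * np.array(
            [b * b + c * c, a * a + c * c, a * a + b * b])
        assert np.allclose(sp.principal_moments, expect)

    def test_a_sites_at_major_axis_tips(self):
        sp = build_species("A")
        got = {tuple(s) for s in sp.site_local_positions}
        assert got == {(0.0, 0.0, 10.0), (0.0, 0.0, -10.0)}

    def test_b_sites_mutually_separated_beyond_delta(self):
        sp = build_species("B")
        s = sp.site_local_positions
        d = np.linalg.norm(s[:, None] - s[None, :], axis=-1)
        off = d[np.triu_indices(5, 1)]
        assert np.all(off > 0.2)


class TestContactFunction:
    def test_equal_spheres_tangency(self):
        sph = _sphere(1.5)
        F = pw_contact(Pose([0, 0, 0]), sph, Pose([3.0, 0, 0]), sph)
        assert abs(F - 1.0) < 1e-10

    def test_equal_spheres_separated_and_overlapping(self):
        sph = _sphere(1.0)
        assert pw_contact(Pose([0, 0, 0]), sph, Pose([3.0, 0, 0]), sph) \
            == pytest.approx(2.25, abs=1e-9)
        assert pw_contact(Pose([0, 0, 0]), sph, Pose([1.0, 0, 0]), sph) \
            == pytest.approx(0.25, abs=1e-9)

    def test_sphere_contact_monotone_in_distance(self):
        sph = _sphere(1.0)
        dists = np.linspace(0.5, 5.0, 20)
        Fs = [pw_contact(Pose([0, 0, 0]), sph, Pose([d, 0, 0]), sph)
              for d in dists]
        assert np.all(np.diff(Fs) > 0)
        # sphere-sphere reduces to (distance / radius sum)^2
        assert np.allclose(Fs, (dists / 2.0) ** 2, atol=1e-8)

    def test_symmetry_under_swap(self):
        rng = np.random.default_rng(7)
        spA, spB = build_species("A"), build_species("B")
        for _ in range(10):
            pa = Pose(rng.uniform(-5, 5, 3), rng.normal(size=4))
            pb = Pose(rng.uniform(-5, 5, 3), rng.normal(size=4))
            F1 = pw_contact(pa, spA, pb, spB)
            F2 = pw_contact(pb, spB, pa, spA)
            assert F1 == pytest.approx(F2, rel=1e-9)

    def test_degenerate_semiaxis_rejected(self):
        from patchykin.geometry import EllipsoidSpecies

        bad = EllipsoidSpecies("A", np.array([1.0, 1.0, 0.0]), 1.0,
                               np.ones(3), np.zeros((0, 3)))
        with pytest.raises(ValueError):
            pw_contact(Pose([0, 0, 0]), bad, Pose([3, 0, 0]), bad)

    def test_against_surface_sampling_oracle(self):
        """Overlap verdicts agree with a dense surface-point oracle.

        A point of one ellipsoid lying inside the other proves overlap;
        the oracle's verdict must match pw_contact's sign on random pairs
        (excluding near-tangent cases below the oracle's resolution).
        """
        rng = np.random.default_rng(42)
        spA, spB = build_species("A"), build_species("B")
        u = rng.normal(size=(400, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        checked = 0
        for _ in range(200):
            pa = Pose(np.zeros(3), rng.normal(size=4))
            pb = Pose(rng.uniform(-8, 8, 3), rng.normal(size=4))
            F = pw_contact(pa, spA, pb, spB)
            if abs(F - 1.0) < 0.05:
                continue  # tangent region: sampling oracle unreliable
            # sample both surfaces, test containment in the other body
            Ra, Rb = pa.rotation_matrix(), pb.rotation_matrix()
            ptsA = (u * spA.semiaxes) @ Ra.T + pa.center
            ptsB = (u * spB.semiaxes) @ Rb.T + pb.center
            inB = np.sum(((ptsA - pb.center) @ Rb / spB.semiaxes) ** 2,
                         axis=1) < 1.0
            inA = np.sum(((ptsB - pa.center) @ Ra / spA.semiaxes) ** 2,
                         axis=1) < 1.0
            oracle_overlap = bool(np.any(inB) or np.any(inA))
            if oracle_overlap:
                assert F < 1.0
            checked += 1
        assert checked > 100


class TestWorldSites:
    def test_identity_orientation(self):
        sp = build_species("A")
        sites = world_sites(Pose(np.zeros(3)), sp)
        assert np.allclose(sorted(sites[:, 2]), [-10.0, 10.0])
        assert np.allclose(sites[:, :2], 0.0)

    def test_rigid_translation(self):
        sp = build_species("B")
        v = np.array([1.0, -2.0, 3.0])
        s0 = world_sites(Pose(np.zeros(3)), sp)
        s1 = world_sites(Pose(v), sp)
        assert np.allclose(s1 - s0, v)

    def test_quarter_turn_about_x(self):
        sp = build_species("A")
        q = np.array([np.cos(np.pi / 4), np.sin(np.pi / 4), 0.0, 0.0])
        sites = world_sites(Pose(np.zeros(3), q), sp)
        # (0,0,10) -> (0,-10,0) under +90 deg about x
        assert np.min(np.linalg.norm(sites - np.array([0, -10.0, 0]),
                                     axis=1)) < 1e-9


class TestPacking:
    def test_box_volume_formula(self):
        box = box_for_packing((1200, 480), 0.30)
        expect = (4 * np.pi / 3) * (1200 * 40 + 480 * 5) / 0.30
        assert box.volume == pytest.approx(expect, rel=1e-12)

    def test_achieved_phi_exact(self):
        box = box_for_packing((120, 48), 0.30)
        spA, spB = build_species("A"), build_species("B")
        phi = (120 * spA.volume + 48 * spB.volume) / box.volume
        assert phi == pytest.approx(0.30, abs=1e-6)

    def test_packed_state_overlap_free(self, packed_state):
        st = packed_state
        spA, spB = build_species("A"), build_species("B")
        sp = [spA, spB]
        rng = np.random.default_rng(0)
        idx = rng.choice(st.n_particles, size=40, replace=False)
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                F = pw_contact(Pose(st.pos[i], st.quat[i]),
                               sp[st.species_id[i]],
                               Pose(st.pos[j], st.quat[j]),
                               sp[st.species_id[j]], st.box)
                assert F >= 1.0 - 1e-9

    def test_packing_deterministic(self):
        s1 = random_packing((110, 44), 0.25, np.random.default_rng(5))
        s2 = random_packing((110, 44), 0.25, np.random.default_rng(5))
        assert np.array_equal(s1.pos, s2.pos)
        assert np.array_equal(s1.vel, s2.vel)

    def test_velocities_maxwellian(self, packed_state):
        trans, rot = packed_state.kinetic_energy()
        n = packed_state.n_particles
        # (3/2) kT per particle, within 3 standard errors of the chi^2 sum
        sem = np.sqrt(1.5 / n)
        assert abs(trans / n - 1.5) < 3 * sem + 3.0 / (2 * n)
        assert abs(rot / n - 1.5) < 3 * sem

    def test_minimum_image_guard(self):
        with pytest.raises(ValueError, match="minimum-image"):
            random_packing((20, 8), 0.30, np.random.default_rng(0))

    def test_excessive_phi_rejected(self):
        with pytest.raises(ValueError):
            random_packing((120, 48), 0.50, np.random.default_rng(0))


class TestBox:
    def test_minimum_image_within_half_edge(self):
        box = BoxSpec([10.0, 20.0, 30.0])
        rng = np.random.default_rng(3)
        dr = rng.uniform(-100, 100, size=(200, 3))
        mi = np.array([box.minimum_image(v) for v in dr])
        assert np.all(np.abs(mi) <= box.edges / 2 + 1e-12)

    def test_bad_edges(self):
        with pytest.raises(ValueError):
            BoxSpec([1.0, -1.0, 1.0])
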