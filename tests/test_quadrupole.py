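"""Rank-2 tensor algebra: conversions, rotation, translation, angular factor."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from q2arom.multipole import MultipoleSite
from q2arom.quadrupole import (
    CartesianQuadrupole,
    SphericalQuadrupole,
    angular_factor,
    cartesian_to_spherical,
    magnitude,
    rotate_site,
    solid_harmonic_moments,
    spherical_to_cartesian,
    translate_quadrupole,
)

from oracles import charge_sum_quadrupole, spherical_from_cartesian_matrix


class TestAngularFactor:
    @pytest.mark.parametrize(
        "theta,expected",
        [(0.0, 1.0), (np.pi / 2, -0.5), (np.pi, 1.0), (np.arccos(1 / np.sqrt(3)), 0.0)],
    )
    def test_known_values(self, theta, expected):
        assert angular_factor(theta) == pytest.approx(expected, abs=1e-12)

    @given(st.floats(-10, 10))
    def test_range_and_mirror_symmetry(self, theta):
        v = angular_factor(theta)
        assert -0.5 - 1e-12 <= v <= 1.0 + 1e-12
        assert v == pytest.approx(angular_factor(np.pi - theta), abs=1e-9)


class TestSphericalCartesian:
    def test_axial_tensor(self):
        c = spherical_to_cartesian(SphericalQuadrupole(1.0, 0, 0, 0, 0))
        assert c.zz == 1.0
        assert c.xx == c.yy == -0.5
        assert c.xy == c.xz == c.yz == 0.0

    def test_round_trip_random(self, rng):
        for _ in range(100):
            q = SphericalQuadrupole.from_array(rng.normal(size=5))
            back = cartesian_to_spherical(spherical_to_cartesian(q))
            np.testing.assert_allclose(back.as_array(), q.as_array(), atol=1e-12)

    def test_output_traceless(self, rng):
        q = SphericalQuadrupole.from_array(rng.normal(size=5))
        m = spherical_to_cartesian(q).as_matrix()
        assert abs(np.trace(m)) < 1e-12 * max(1.0, np.abs(m).max())

    def test_dual_formula_point_charges(self, rng):
        """Spherical moments via solid harmonics vs direct Cartesian charge sum."""
        pos = rng.uniform(-2, 2, size=(10, 3))
        q = rng.uniform(-1, 1, size=10)
        spherical = sum(qi * solid_harmonic_moments(ri)[4:9] for qi, ri in zip(q, pos))
        cart = charge_sum_quadrupole(q, pos, np.zeros(3))
        converted = spherical_to_cartesian(SphericalQuadrupole.from_array(spherical)).as_matrix()
        np.testing.assert_allclose(converted, cart, atol=1e-12)

    def test_from_matrix_rejects_traceful(self):
        with pytest.raises(ValueError, match="traceless"):
            CartesianQuadrupole.from_matrix(np.eye(3))


class TestMagnitude:
    @pytest.mark.parametrize(
        "comps,expected", [((1, 0, 0, 0, 0), 1.0), ((3, 4, 0, 0, 0), 5.0)]
    )
    def test_pythagorean(self, comps, expected):
        assert magnitude(SphericalQuadrupole(*comps)) == expected

    def test_rotation_invariance(self, rng):
        q = SphericalQuadrupole.from_array(rng.normal(size=5))
        for seed in range(10):
            r = Rotation.random(random_state=seed).as_matrix()
            m = spherical_to_cartesian(q).as_matrix()
            rotated = cartesian_to_spherical(
                CartesianQuadrupole.from_matrix(r @ m @ r.T)
            )
            assert rotated.magnitude == pytest.approx(q.magnitude, abs=1e-10)


class TestRotateSite:
    def _site(self, rng, rank=2):
        return MultipoleSite("C1", rng.normal(size=3), rank, rng.normal(size=(rank + 1) ** 2))

    def test_identity(self, rng):
        s = self._site(rng)
        out = rotate_site(s, np.eye(3))
        np.testing.assert_allclose(out.position, s.position)
        np.testing.assert_allclose(out.components, s.components)

    def test_quarter_turn_maps_x_dipole_to_y(self):
        s = MultipoleSite("N", [0, 0, 0], 1, [0.0, 0.0, 1.0, 0.0])  # pure Q11c
        r = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
        out = rotate_site(s, r)
        np.testing.assert_allclose(out.components, [0.0, 0.0, 0.0, 1.0], atol=1e-15)

    def test_rank2_norm_preserved(self, rng):
        s = self._site(rng)
        for seed in range(5):
            r = Rotation.random(random_state=seed).as_matrix()
            out = rotate_site(s, r)
            assert np.linalg.norm(out.components[4:9]) == pytest.approx(
                np.linalg.norm(s.components[4:9]), abs=1e-10
            )

    def test_higher_ranks_carried_unrotated(self, rng):
        s = self._site(rng, rank=3)
        r = Rotation.random(random_state=0).as_matrix()
        np.testing.assert_array_equal(rotate_site(s, r).components[9:], s.components[9:])

    def test_rejects_nonorthogonal(self, rng):
        with pytest.raises(ValueError, match="orthogonal"):
            rotate_site(self._site(rng), np.eye(3) * 2.0)


def _charge_sites(charges, positions):
    return [
        MultipoleSite(f"X{i}", p, 0, [q]) for i, (q, p) in enumerate(zip(charges, positions))
    ]


class TestTranslateQuadrupole:
    def test_unit_charge_on_axis(self):
        sites = _charge_sites([1.0], [[0.0, 0.0, 1.0]])
        q = translate_quadrupole(sites, np.zeros(3), "bohr")
        assert q.q20 == pytest.approx(1.0, abs=1e-14)

    def test_own_position_returns_site_tensor(self, rng):
        comps = np.zeros(9)
        comps[0] = rng.normal()
        comps[1:4] = rng.normal(size=3)
        comps[4:9] = rng.normal(size=5)
        pos = rng.normal(size=3)
        site = MultipoleSite("O", pos, 2, comps)
        q = translate_quadrupole([site], pos, "bohr")
        np.testing.assert_allclose(q.as_array(), comps[4:9], atol=1e-14)

    def test_matches_direct_charge_sum(self, rng):
        for _ in range(20):
            pos = rng.uniform(-3, 3, size=(20, 3))
            charges = rng.uniform(-1, 1, size=20)
            point = rng.uniform(-2, 2, size=3)
            q = translate_quadrupole(_charge_sites(charges, pos), point, "bohr")
            expected = spherical_from_cartesian_matrix(
                charge_sum_quadrupole(charges, pos, point)
            )
            np.testing.assert_allclose(q.as_array(), expected, atol=1e-10)

    @pytest.mark.parametrize("delta", [0.3, 1.0, 2.5])
    def test_dipole_pair_exact_any_separation(self, rng, delta):
        """A ± charge pair has zero monopole/quadrupole about its center, so the
        point-dipole translation term reproduces it exactly, not asymptotically."""
        center = rng.normal(size=3)
        m = 0.7
        pair = _charge_sites(
            [m, -m], [center + [0, 0, delta], center - [0, 0, delta]]
        )
        comps = np.zeros(4)
        comps[1] = 2 * m * delta  # Q10 = mu_z
        dipole_site = [MultipoleSite("D", center, 1, comps)]
        point = rng.normal(size=3)
        q_pair = translate_quadrupole(pair, point, "bohr")
        q_dip = translate_quadrupole(dipole_site, point, "bohr")
        np.testing.assert_allclose(q_pair.as_array(), q_dip.as_array(), atol=1e-12)

    def test_quadrupole_triple_exact(self, rng):
        """q at ±δẑ plus −2q at the center is a pure axial site quadrupole."""
        center = rng.normal(size=3)
        q, delta = 0.4, 0.8
        triple = _charge_sites(
            [q, q, -2 * q],
            [center + [0, 0, delta], center - [0, 0, delta], center],
        )
        comps = np.zeros(9)
        comps[4] = 2 * q * delta**2  # Q20 of the triple about its center
        site = [MultipoleSite("Q", center, 2, comps)]
        point = rng.normal(size=3)
        np.testing.assert_allclose(
            translate_quadrupole(triple, point, "bohr").as_array(),
            translate_quadrupole(site, point, "bohr").as_array(),
            atol=1e-12,
        )

    def test_linearity_over_site_sets(self, rng):
        pos = rng.uniform(-2, 2, size=(8, 3))
        charges = rng.uniform(-1, 1, size=8)
        point = rng.normal(size=3)
        sites = _charge_sites(charges, pos)
        whole = translate_quadrupole(sites, point, "bohr").as_array()
        parts = (
            translate_quadrupole(sites[:3], point, "bohr").as_array()
            + translate_quadrupole(sites[3:], point, "bohr").as_array()
        )
        np.testing.assert_allclose(whole, parts, atol=1e-12)

    def test_origin_independence_neutral_dipole_free(self, rng):
        # +q, +q, -q, -q arranged with zero net charge and zero net dipole
        pos = np.array([[1.0, 0, 0], [-1.0, 0, 0], [0, 1.0, 0], [0, -1.0, 0]])
        charges = np.array([0.5, 0.5, -0.5, -0.5])
        sites = _charge_sites(charges, pos)
        p1 = translate_quadrupole(sites, rng.normal(size=3), "bohr").as_array()
        p2 = translate_quadrupole(sites, rng.normal(size=3), "bohr").as_array()
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_sign_structure_axis_vs_plane(self):
        """A positive charge on the z-axis adds to Q20; in the xy-plane it
        subtracts exactly ½ q r² (the charged-substituent artifact)."""
        on_axis = translate_quadrupole(_charge_sites([0.8], [[0, 0, 2.0]]), np.zeros(3), "bohr")
        assert on_axis.q20 == pytest.approx(0.8 * 4.0, abs=1e-12)
        in_plane = translate_quadrupole(_charge_sites([0.8], [[1.5, 0, 0]]), np.zeros(3), "bohr")
        assert in_plane.q20 == pytest.approx(-0.5 * 0.8 * 1.5**2, abs=1e-12)

    def test_angstrom_positions_converted(self):
        from q2arom.constants import BOHR_PER_ANGSTROM

        sites = [MultipoleSite("X", [0.0, 0.0, 1.0], 0, [1.0])]
        q = translate_quadrupole(sites, np.zeros(3), "angstrom")
        assert q.q20 == pytest.approx(BOHR_PER_ANGSTROM**2, rel=1e-14)

    def test_requires_unit_metadata(self):
        with pytest.raises(ValueError, match="length_unit"):
            translate_quadrupole(_charge_sites([1.0], [[0, 0, 1]]), np.zeros(3), None)
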