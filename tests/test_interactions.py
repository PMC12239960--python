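"""Force/torque terms: gradients of their potentials, conservation laws,
cutoff continuity and the Coulomb friction cone."""

import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from magjanus import interactions as ia

EPS_FD = 1e-6  # central-difference step, units of sigma


def central_diff_force(u_func, r_vec):
    """-grad U by central differences."""
    f = np.zeros(3)
    for k in range(3):
        dr = np.zeros(3)
        dr[k] = EPS_FD
        f[k] = -(u_func(r_vec + dr) - u_func(r_vec - dr)) / (2.0 * EPS_FD)
    return f


unit_vec = st.builds(
    lambda th, ph: np.array(
        [math.sin(th) * math.cos(ph), math.sin(th) * math.sin(ph), math.cos(th)]
    ),
    st.floats(0.05, math.pi - 0.05),
    st.floats(0.0, 2.0 * math.pi),
)


class TestWca:
    def test_zero_at_cutoff(self):
        r = ia.RCUT
        assert ia.u_wca(r) == 0.0
        load = ia.wca_pair_force([0, 0, 0], [r, 0, 0])
        assert np.allclose(load.force_i, 0.0)

    def test_potential_continuous_at_cutoff(self):
        below = ia.u_wca(ia.RCUT - 1e-9)
        assert abs(below) < 1e-7

    def test_contact_force_magnitude(self):
        # at r = sigma the repulsion is 24 eps/sigma
        load = ia.wca_pair_force([0, 0, 0], [1.0, 0, 0])
        assert np.linalg.norm(load.force_i) == pytest.approx(24.0, rel=1e-12)

    @given(st.floats(0.85, 1.25), unit_vec)
    @settings(max_examples=50, deadline=None)
    def test_force_is_potential_gradient(self, r, n):
        r_vec = r * n
        load = ia.wca_pair_force(r_vec, np.zeros(3))
        fd = central_diff_force(lambda v: ia.u_wca(float(np.linalg.norm(v))), r_vec)
        assert np.allclose(load.force_i, fd, rtol=1e-5, atol=1e-5)

    @given(st.floats(0.9, 1.3), unit_vec)
    @settings(max_examples=30, deadline=None)
    def test_newtons_third_law(self, r, n):
        load = ia.wca_pair_force(r * n, np.zeros(3))
        assert np.allclose(load.force_i + load.force_j, 0.0, atol=1e-14)

    def test_coincident_centres_rejected(self):
        with pytest.raises(ValueError):
            ia.wca_pair_force([0.0, 0.0, 0.0], [0.0, 0.0, 0.0])


class TestDipolePair:
    def test_head_to_tail_energy(self):
        mu = np.array([1.0, 0.0, 0.0])
        assert ia.u_dipole(np.array([1.0, 0, 0]), mu, mu) == pytest.approx(-2.0)

    def test_side_by_side_energy(self):
        mu = np.array([0.0, 0.0, 1.0])
        assert ia.u_dipole(np.array([1.0, 0, 0]), mu, mu) == pytest.approx(1.0)

    def test_head_to_tail_attraction_magnitude(self):
        mu = np.array([1.0, 0.0, 0.0])
        f_i, _, _ = ia.dipole_pair_interaction(
            np.array([1.0, 0, 0]), np.zeros(3), mu, mu
        )
        # attractive (toward j) with magnitude 6 eps/sigma
        assert f_i[0] == pytest.approx(-6.0, rel=1e-12)

    @given(st.floats(0.85, 2.0), unit_vec, unit_vec, unit_vec)
    @settings(max_examples=60, deadline=None)
    def test_force_is_potential_gradient(self, r, n, m1, m2):
        r_vec = r * n
        f_i, _, _ = ia.dipole_pair_interaction(r_vec, np.zeros(3), m1, m2)
        fd = central_diff_force(lambda v: ia.u_dipole(v, m1, m2), r_vec)
        scale = max(1.0, float(np.linalg.norm(f_i)))
        assert np.allclose(f_i, fd, rtol=1e-5, atol=1e-5 * scale)

    @given(st.floats(0.85, 2.0), unit_vec, unit_vec, unit_vec)
    @settings(max_examples=60, deadline=None)
    def test_internal_loads_conserve_momentum_and_angular_momentum(
        self, r, n, m1, m2
    ):
        r_ci = 0.6 * r * n + np.array([0.2, -0.1, 0.9])
        r_cj = -0.4 * r * n + np.array([0.2, -0.1, 0.9])
        u_i = np.cross(m1, n)
        u_j = np.cross(m2, n)
        for u in (u_i, u_j):
            if np.linalg.norm(u) < 1e-3:
                return
        u_i /= np.linalg.norm(u_i)
        u_j /= np.linalg.norm(u_j)
        s = 0.2878
        r_m_gap = np.linalg.norm((r_ci - s * u_i) - (r_cj - s * u_j))
        assume(r_m_gap > ia.DIPOLE_RMIN + 0.02)
        load = ia.dipole_pair_loads(r_ci, r_cj, u_i, u_j, m1, m2, s, s)
        # linear momentum
        assert np.allclose(load.force_i + load.force_j, 0.0, atol=1e-12)
        # angular momentum about the origin: torques about centres plus
        # r_c x F sum to zero
        total = (
            load.torque_i
            + load.torque_j
            + np.cross(r_ci, load.force_i)
            + np.cross(r_cj, load.force_j)
        )
        assert np.allclose(total, 0.0, atol=1e-10)

    def test_orientation_torque_matches_energy_gradient(self):
        # rotate mu_i by small angle; dU/dtheta == -(tau . axis)
        rng = np.random.default_rng(7)
        for _ in range(10):
            r_vec = rng.normal(size=3)
            r_vec *= (1.0 + rng.random()) / np.linalg.norm(r_vec)
            m1 = rng.normal(size=3)
            m1 /= np.linalg.norm(m1)
            m2 = rng.normal(size=3)
            m2 /= np.linalg.norm(m2)
            axis = np.cross(m1, rng.normal(size=3))
            axis /= np.linalg.norm(axis)
            _, tau_i, _ = ia.dipole_pair_interaction(r_vec, np.zeros(3), m1, m2)
            d = 1e-6

            def rot(v, a, ang):
                return (
                    v * math.cos(ang)
                    + np.cross(a, v) * math.sin(ang)
                    + a * np.dot(a, v) * (1 - math.cos(ang))
                )

            du = (
                ia.u_dipole(r_vec, rot(m1, axis, d), m2)
                - ia.u_dipole(r_vec, rot(m1, axis, -d), m2)
            ) / (2 * d)
            assert np.dot(tau_i, axis) == pytest.approx(-du, rel=1e-4, abs=1e-8)


class TestFieldTorque:
    def test_aligned_dipole_feels_no_torque(self):
        assert np.allclose(
            ia.external_field_torque([0, 0, 2.0], [0, 0, 5.0]), 0.0
        )

    def test_cross_product_direction(self):
        tau = ia.external_field_torque([1.0, 0, 0], [0, 0, 3.0])
        assert np.allclose(tau, [0.0, -3.0, 0.0])

    def test_torque_rotates_toward_alignment(self):
        # small rotation along tau must lower -mu.B
        mu = np.array([1.0, 0.0, 0.0])
        B = np.array([0.0, 0.0, 2.0])
        tau = ia.external_field_torque(mu, B)
        axis = tau / np.linalg.norm(tau)
        d = 1e-4
        mu_rot = (
            mu * math.cos(d) + np.cross(axis, mu) * math.sin(d)
        )
        assert -np.dot(mu_rot, B) < -np.dot(mu, B)


class TestGravityBuoyancy:
    def test_cap_down_has_no_torque(self, default_particle):
        _, tau = ia.gravity_buoyancy_loads(np.array([0.0, 0.0, 1.0]), default_particle)
        assert np.allclose(tau, 0.0)

    def test_total_force_is_net_weight(self, default_particle):
        f, _ = ia.gravity_buoyancy_loads(np.array([0.3, 0.1, 0.9]), default_particle)
        assert f[0] == f[1] == 0.0
        assert -f[2] == pytest.approx(default_particle.net_weight)

    def test_hydrogel_load_magnitude(self, default_units, default_particle):
        # (1120-1000) * V_sphere * g ~ 0.133 uN
        g_c = default_units.to_physical_force(default_particle.weight_center)
        assert g_c * 1e6 == pytest.approx(0.133, abs=2e-3)

    def test_righting_torque_restores_upright(self, default_particle):
        th = math.radians(30.0)
        u = np.array([math.sin(th), 0.0, math.cos(th)])
        _, tau = ia.gravity_buoyancy_loads(u, default_particle)
        # torque about -y rotates u back toward +z
        assert tau[1] < 0.0
        assert abs(tau[1]) == pytest.approx(
            default_particle.s_offset * default_particle.weight_cap * math.sin(th),
            rel=1e-12,
        )


class TestWall:
    def test_zero_beyond_cutoff(self):
        assert ia.wall_wca_force(ia.WALL_RCUT * 1.01) == 0.0

    def test_matches_numerical_gradient(self):
        for d in (0.45, 0.5, 0.55):
            fd = -(ia.u_wall(d + EPS_FD) - ia.u_wall(d - EPS_FD)) / (2 * EPS_FD)
            assert ia.wall_wca_force(d) == pytest.approx(fd, rel=1e-5)

    def test_continuous_at_cutoff(self):
        assert ia.u_wall(ia.WALL_RCUT - 1e-9) == pytest.approx(0.0, abs=1e-7)

    def test_penetration_rejected(self):
        with pytest.raises(ValueError):
            ia.wall_wca_force(-0.1)


class TestCoulombFriction:
    def test_free_particles_feel_no_friction(self):
        f, t = ia.coulomb_friction([5.0, 0, 0], 3.0, 10.0, in_chain=False)
        assert np.allclose(f, 0.0) and t == 0.0

    def test_static_cancellation_below_cone(self):
        ft = np.array([0.2, 0.0, 0.0])  # 0.4 * lambda_s * N with N=1
        f, _ = ia.coulomb_friction(ft, 0.0, 1.0, in_chain=True)
        assert np.allclose(f, -ft)

    def test_kinetic_magnitude(self):
        ft = np.array([3.0, 4.0, 0.0])  # |ft| = 5 > lambda_s * N = 0.5
        f, _ = ia.coulomb_friction(ft, 0.0, 1.0, in_chain=True)
        assert np.linalg.norm(f) == pytest.approx(0.4)
        assert np.dot(f, ft) < 0.0

    @given(
        st.floats(0.0, 10.0),
        st.floats(0.0, 20.0),
        st.floats(0.0, 2 * math.pi),
    )
    @settings(max_examples=60, deadline=None)
    def test_friction_never_exceeds_static_cone(self, n_force, f_mag, ang):
        ft = f_mag * np.array([math.cos(ang), math.sin(ang), 0.0])
        f, t = ia.coulomb_friction(ft, 0.3, n_force, in_chain=True)
        cone = 0.5 * n_force + 1e-9
        assert np.linalg.norm(f) <= cone + 1e-12 or np.allclose(f, -ft)
        assert abs(t) <= 0.5 * n_force * 0.5 + 1e-12

    def test_yaw_torque_stick_and_slip(self):
        _, t_stick = ia.coulomb_friction([0, 0, 0], 0.1, 1.0, in_chain=True)
        assert t_stick == pytest.approx(-0.1)
        _, t_slip = ia.coulomb_friction([0, 0, 0], 5.0, 1.0, in_chain=True)
        assert t_slip == pytest.approx(-0.4 * 0.5)

    def test_negative_normal_force_rejected(self):
        with pytest.raises(ValueError):
            ia.coulomb_friction([1, 0, 0], 0.0, -1.0, in_chain=True)
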