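"""Integrator contracts: fixed points, analytic relaxation, drift,
orientation integrity, convergence, and single-particle settling."""

import math

import numpy as np
import pytest

from magjanus.arena import build_arena
from magjanus.dynamics import (
    SimulationConfig,
    SimulationError,
    integrate_step,
    run_simulation,
)
from magjanus.fields import RotatingField, StaticField
from magjanus.scenarios import REST_Z, build_scenario
from magjanus.units import default_reduced_particle


@pytest.fixture(scope="module")
def particle_units():
    return default_reduced_particle()


def _single_state(u=(0.0, 0.0, 1.0), mu=(1.0, 0.0, 0.0), z=REST_Z):
    r = np.array([[0.0, 0.0, z]])
    return r, np.array([u], dtype=float), np.array([mu], dtype=float)


class TestIntegrateStep:
    def test_equilibrium_is_a_fixed_point(self, particle_units):
        particle, units = particle_units
        # resting upright at the height where wall force balances weight:
        # solve for it by relaxing first
        cfg = SimulationConfig(
            positions=np.array([[0.0, 0.0, REST_Z]]),
            axes=np.array([[0.0, 0.0, 1.0]]),
            dipole_dirs=np.array([[1.0, 0.0, 0.0]]),
            particles=[particle],
            field_program=StaticField(0.0, (0, 0, 1)),
            arena=build_arena("flat"),
            units=units,
            duration=20.0,
        )
        traj = run_simulation(cfg)
        r = traj.positions[-1]
        u = traj.axes[-1]
        muh = traj.dipole_dirs[-1]
        r2, u2, _ = integrate_step(r, u, muh, [particle], np.zeros(3),
                                   cfg.arena, units)
        assert np.allclose(r2, r, atol=1e-6)
        assert np.allclose(u2, u, atol=1e-9)

    def test_constant_force_linear_drift(self, particle_units):
        """A free particle under constant force F moves n dt F / gamma."""
        particle, units = particle_units
        # no walls nearby, no field: the only force is the net weight
        r, u, mu = _single_state(z=50.0)
        dt = 1e-3
        r_new, _, _ = integrate_step(r, u, mu, [particle], np.zeros(3),
                                     build_arena("flat"), units, dt=dt)
        expected_dz = -dt * particle.net_weight / units.gamma
        assert r_new[0, 2] - r[0, 2] == pytest.approx(expected_dz, rel=1e-12)

    def test_field_alignment_matches_analytic_relaxation(self, particle_units):
        """Torque-only dynamics: dtheta/dt = -(m B / gamma_r) sin(theta),
        whose solution is tan(theta/2) = tan(theta0/2) exp(-m B t/gamma_r).
        Run at a refined step so the first-order integrator reaches the
        1e-4 agreement the analytic check demands."""
        particle, units = particle_units
        b0 = 0.25  # reduced field along +x
        theta0 = 2.0
        # dipole in the xy plane at angle theta0 from +x; axis +z (no gravity
        # torque about z, particle floats far from walls)
        r = np.array([[0.0, 0.0, 50.0]])
        u = np.array([[0.0, 0.0, 1.0]])
        mu = np.array([[math.cos(theta0), math.sin(theta0), 0.0]])
        cfg = SimulationConfig(
            positions=r, axes=u, dipole_dirs=mu, particles=[particle],
            field_program=StaticField(
                b0 * units.field_unit * 1e3, (1, 0, 0)
            ),
            arena=build_arena("flat"), units=units, duration=1.0, stride=500,
            dt=1e-4,
        )
        traj = run_simulation(cfg)
        rate = particle.m_star * b0 / units.gamma_r
        for k in range(traj.n_frames):
            t = traj.times[k]
            mu_k = traj.dipole_dirs[k, 0]
            theta = math.atan2(mu_k[1], mu_k[0])
            expected = 2.0 * math.atan(math.tan(theta0 / 2.0) * math.exp(-rate * t))
            assert theta == pytest.approx(expected, abs=1e-4)

    def test_gravity_ignores_horizontal(self, particle_units):
        particle, units = particle_units
        r, u, mu = _single_state(z=50.0)
        r_new, _, _ = integrate_step(r, u, mu, [particle], np.zeros(3),
                                     build_arena("flat"), units)
        assert r_new[0, 0] == r[0, 0] and r_new[0, 1] == r[0, 1]


class TestRunSimulation:
    def test_frame_count_contract(self, particle_units):
        particle, units = particle_units
        r, u, mu = _single_state()
        cfg = SimulationConfig(
            positions=r, axes=u, dipole_dirs=mu, particles=[particle],
            field_program=StaticField(0.0, (0, 0, 1)),
            arena=build_arena("flat"), units=units,
            duration=2.0, stride=100,
        )
        traj = run_simulation(cfg)
        assert traj.n_frames == cfg.n_steps // 100 + 1
        assert np.all(np.diff(traj.times) > 0.0)

    def test_orientations_stay_orthonormal_over_long_run(self, particle_units):
        particle, units = particle_units
        r, u, mu = _single_state(u=(0.6, 0.0, 0.8), mu=(0.0, 1.0, 0.0), z=REST_Z)
        cfg = SimulationConfig(
            positions=r, axes=u, dipole_dirs=mu, particles=[particle],
            field_program=RotatingField(4.0, 1.0, "yz"),
            arena=build_arena("flat"), units=units,
            duration=600.0, stride=10_000,
        )
        traj = run_simulation(cfg)
        norms_u = np.linalg.norm(traj.axes, axis=2)
        norms_m = np.linalg.norm(traj.dipole_dirs, axis=2)
        dots = np.sum(traj.axes * traj.dipole_dirs, axis=2)
        assert np.max(np.abs(norms_u - 1.0)) < 1e-8
        assert np.max(np.abs(norms_m - 1.0)) < 1e-8
        assert np.max(np.abs(dots)) < 1e-8

    def test_com_drift_equals_external_force_over_drag(self, particle_units):
        """With no walls in range and no field, internal pair forces do not
        move the centre of mass: it sinks at W_total/(N gamma)."""
        particle, units = particle_units
        r = np.array([[0.0, 0.0, 30.0], [1.05, 0.0, 30.0]])
        u = np.tile([0.0, 0.0, 1.0], (2, 1))
        mu = np.tile([1.0, 0.0, 0.0], (2, 1))
        duration = 1.0
        cfg = SimulationConfig(
            positions=r, axes=u, dipole_dirs=mu, particles=[particle] * 2,
            field_program=StaticField(0.0, (0, 0, 1)),
            arena=build_arena("flat"), units=units,
            duration=duration, stride=100,
        )
        traj = run_simulation(cfg)
        com = traj.centroid()
        expected = -particle.net_weight / units.gamma * duration
        assert com[-1, 2] - com[0, 2] == pytest.approx(expected, rel=1e-6)
        assert np.allclose(com[:, :2], com[0, :2], atol=1e-9)

    def test_halving_timestep_converges(self):
        cfg1 = build_scenario("dimer_assembly", seed=1, duration=20.0)
        cfg2 = build_scenario("dimer_assembly", seed=1, duration=20.0)
        cfg2.dt = 5e-4
        tr1, tr2 = run_simulation(cfg1), run_simulation(cfg2)
        diff = np.abs(tr1.positions[-1] - tr2.positions[-1]).max()
        assert diff < 1e-3

    def test_coincident_particles_raise(self, particle_units):
        particle, units = particle_units
        r = np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 5.0]])
        u = np.tile([0.0, 0.0, 1.0], (2, 1))
        mu = np.tile([1.0, 0.0, 0.0], (2, 1))
        cfg = SimulationConfig(
            positions=r, axes=u, dipole_dirs=mu, particles=[particle] * 2,
            field_program=StaticField(0.0, (0, 0, 1)),
            arena=build_arena("flat"), units=units, duration=1.0,
        )
        with pytest.raises(SimulationError):
            run_simulation(cfg)


class TestSettling:
    def test_tilted_particle_settles_cap_down(self, particle_units):
        """A single robot released tilted in zero field rights itself:
        the heavy cap swings to the bottom (u -> +z) within 100 tau."""
        particle, units = particle_units
        th = math.radians(70.0)
        cfg = SimulationConfig(
            positions=np.array([[0.0, 0.0, 1.0]]),
            axes=np.array([[math.sin(th), 0.0, math.cos(th)]]),
            dipole_dirs=np.array([[math.cos(th), 0.0, -math.sin(th)]]),
            particles=[particle],
            field_program=StaticField(0.0, (0, 0, 1)),
            arena=build_arena("flat"),
            units=units,
            duration=100.0,
            stride=1000,
        )
        traj = run_simulation(cfg)
        u_final = traj.axes[-1, 0]
        angle = math.degrees(math.acos(np.clip(u_final[2], -1.0, 1.0)))
        assert angle < 1.0
        assert traj.positions[-1, 0, 2] == pytest.approx(0.55, abs=0.02)
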