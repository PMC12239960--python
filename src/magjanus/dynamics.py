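"""Overdamped simulation driver.

The equations of motion are first order (non-thermal Brownian dynamics):
velocity is force over the translational damping ``gamma``, angular
velocity is torque over the rotational damping ``gamma_r``; there is no
inertia and no thermal noise, so a run is fully deterministic given its
initial state and field program.  Randomness enters only through seeded
initial placements (see :mod:`magjanus.scenarios`).

Time is integrated with explicit Euler steps of ``dt`` (default 1e-3 tau);
orientations advance by the exponential map of the angular-velocity vector
and the body frame (u, mu_hat) is re-orthonormalised each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .arena import Arena, build_arena
from .fields import FieldProgram
from .units import DEFAULT_DT, ReducedParticle, UnitSystem

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "SimulationError",
    "run_simulation",
    "compute_loads",
    "integrate_step",
]

BOND_CUTOFF = 1.1  # contact-shell bond criterion, units of sigma


class SimulationError(RuntimeError):
    """Integration failure with step context."""


@dataclass
class SimulationConfig:
    """Complete, reproducible description of one run.

    Positions/orientations are reduced (units of sigma); ``duration`` and
    ``dt`` are in units of tau.  ``stride`` is the recording interval in
    steps.
    """

    positions: np.ndarray                 # (N, 3)
    axes: np.ndarray                      # (N, 3) unit u, cap -> hydrogel pole
    dipole_dirs: np.ndarray               # (N, 3) unit mu_hat, perpendicular to u
    particles: Sequence[ReducedParticle]
    field_program: FieldProgram
    arena: Arena = field(default_factory=lambda: build_arena("flat"))
    units: UnitSystem = field(default_factory=UnitSystem)
    dt: float = DEFAULT_DT
    duration: float = 600.0
    stride: int = 100
    seed: int | None = None
    bond_cutoff: float = BOND_CUTOFF

    def __post_init__(self) -> None:
        self.positions = np.array(self.positions, dtype=float)
        self.axes = np.array(self.axes, dtype=float)
        self.dipole_dirs = np.array(self.dipole_dirs, dtype=float)
        n = self.positions.shape[0]
        if self.axes.shape != (n, 3) or self.dipole_dirs.shape != (n, 3):
            raise ValueError("positions, axes and dipole_dirs must be (N, 3)")
        if len(self.particles) != n:
            raise ValueError("need one ReducedParticle per particle")
        if self.dt <= 0.0:
            raise ValueError("dt must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one timestep")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        # normalise the body frames defensively
        self.axes /= np.linalg.norm(self.axes, axis=1, keepdims=True)
        self.dipole_dirs -= (
            np.sum(self.dipole_dirs * self.axes, axis=1, keepdims=True) * self.axes
        )
        norms = np.linalg.norm(self.dipole_dirs, axis=1, keepdims=True)
        if np.any(norms < 1e-9):
            raise ValueError("dipole directions must not be parallel to axes")
        self.dipole_dirs /= norms

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass
class Trajectory:
    """Recorded frames of one run (reduced units unless noted)."""

    times: np.ndarray        # (F,), units of tau
    positions: np.ndarray    # (F, N, 3)
    axes: np.ndarray         # (F, N, 3)
    dipole_dirs: np.ndarray  # (F, N, 3)
    field_mT: np.ndarray     # (F, 3)
    units: UnitSystem
    config: SimulationConfig
    n_extra_substeps: int = 0

    @property
    def n_frames(self) -> int:
        return self.times.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def times_s(self) -> np.ndarray:
        return self.times * self.units.tau

    def magnetic_points(self) -> np.ndarray:
        """r_m = r_c - s*u per frame/particle."""
        s = np.array([p.s_offset for p in self.config.particles])
        return self.positions - s[None, :, None] * self.axes

    def centroid(self) -> np.ndarray:
        return self.positions.mean(axis=1)


def _particle_arrays(particles: Sequence[ReducedParticle]):
    m = np.array([p.m_star for p in particles])
    s = np.array([p.s_offset for p in particles])
    wc = np.array([p.weight_center for p in particles])
    wm = np.array([p.weight_cap for p in particles])
    return m, s, wc, wm


def run_simulation(config: SimulationConfig) -> Trajectory:
    """Integrate the configured system and return its trajectory."""
    n_steps = config.n_steps
    stride = config.stride
    units = config.units

    times_s = np.arange(n_steps) * config.dt * units.tau
    b_mT = config.field_program.sample(times_s)
    b_red = np.ascontiguousarray(b_mT * 1e-3 / units.field_unit)

    wall_c, wall_e1, wall_e2, wall_a, wall_lam = config.arena.to_arrays()
    m, s, wc, wm = _particle_arrays(config.particles)

    r = config.positions.copy()
    u = config.axes.copy()
    muh = config.dipole_dirs.copy()

    n_frames = n_steps // stride + 1
    out_r = np.empty((n_frames, config.n_particles, 3))
    out_u = np.empty_like(out_r)
    out_muh = np.empty_like(out_r)

    status, at_step, n_extra = _kernels.run(
        r, u, muh, m, s, wc, wm, b_red,
        wall_c, wall_e1, wall_e2, wall_a, wall_lam,
        config.dt, units.gamma, units.gamma_r,
        config.bond_cutoff, 1e-3, stride,
        out_r, out_u, out_muh,
    )
    if status == _kernels.STATUS_COINCIDENT:
        raise SimulationError(
            f"coincident particles at step {at_step} (t = {at_step * config.dt:.3f} tau)"
        )
    if status == _kernels.STATUS_BLOWUP:
        raise SimulationError(
            f"timestep too large: step {at_step} "
            f"(t = {at_step * config.dt:.3f} tau) needed more than "
            f"{_kernels.MAX_SUBSTEPS} sub-steps"
        )

    frame_steps = np.minimum(
        np.arange(n_frames) * stride, n_steps
    )
    frame_steps[-1] = n_steps
    times = frame_steps * config.dt
    field_idx = np.minimum(frame_steps, n_steps - 1)
    return Trajectory(
        times=times,
        positions=out_r,
        axes=out_u,
        dipole_dirs=out_muh,
        field_mT=b_mT[field_idx],
        units=units,
        config=config,
        n_extra_substeps=int(n_extra),
    )


# ---------------------------------------------------------------------------
# single-step API (useful for tests and custom integration loops)

def compute_loads(
    r: np.ndarray,
    u: np.ndarray,
    muh: np.ndarray,
    particles: Sequence[ReducedParticle],
    b_red: np.ndarray,
    arena: Arena,
    units: UnitSystem | None = None,
    bond_cutoff: float = BOND_CUTOFF,
):
    """Total reduced forces and torques (friction included) for one state."""
    units = units or UnitSystem()
    wall_c, wall_e1, wall_e2, wall_a, wall_lam = arena.to_arrays()
    m, s, wc, wm = _particle_arrays(particles)
    n = r.shape[0]
    F = np.empty((n, 3))
    T = np.empty((n, 3))
    status = _kernels._compute_loads(
        np.ascontiguousarray(r, dtype=float),
        np.ascontiguousarray(u, dtype=float),
        np.ascontiguousarray(muh, dtype=float),
        m, s, wc, wm, np.asarray(b_red, dtype=float),
        wall_c, wall_e1, wall_e2, wall_a, wall_lam,
        bond_cutoff, units.gamma, 1e-3, F, T,
    )
    if status != _kernels.STATUS_OK:
        raise SimulationError("coincident particles in compute_loads")
    return F, T


def integrate_step(
    r: np.ndarray,
    u: np.ndarray,
    muh: np.ndarray,
    particles: Sequence[ReducedParticle],
    b_red: np.ndarray,
    arena: Arena,
    units: UnitSystem | None = None,
    dt: float = DEFAULT_DT,
    bond_cutoff: float = BOND_CUTOFF,
):
    """One explicit Euler step; returns new (r, u, muh) without mutating."""
    units = units or UnitSystem()
    F, T = compute_loads(r, u, muh, particles, b_red, arena, units, bond_cutoff)
    r_new = r + dt / units.gamma * F
    u_new = u.copy()
    muh_new = muh.copy()
    w = T / units.gamma_r
    for i in range(r.shape[0]):
        angle = float(np.linalg.norm(w[i])) * dt
        if angle > 1e-14:
            axis = w[i] / np.linalg.norm(w[i])
            _kernels._rotate(u_new[i], axis[0], axis[1], axis[2], angle)
            _kernels._rotate(muh_new[i], axis[0], axis[1], axis[2], angle)
        u_new[i] /= np.linalg.norm(u_new[i])
        muh_new[i] -= np.dot(muh_new[i], u_new[i]) * u_new[i]
        muh_new[i] /= np.linalg.norm(muh_new[i])
    return r_new, u_new, muh_new
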