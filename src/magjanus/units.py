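"""Reduced <-> physical unit mapping.

The simulation works in Lennard-Jones-style reduced units: the energy unit
``epsilon``, the length unit ``sigma`` (one particle diameter) and the time
unit ``tau``.  Derived units follow: force = epsilon/sigma, torque =
epsilon, drag coefficient = epsilon*tau/sigma^2.

Magnetic quantities are mapped through the dipole-dipole energy: a reduced
dipole of magnitude m* at reduced separation r stores the energy

    U = epsilon * [mi.mj - 3 (mi.n)(mj.n)] / r^3,

which matches the physical point-dipole energy with the mu0/(4 pi)
prefactor when

    m* = mu * sqrt( mu0 / (4 pi epsilon sigma^3) ).

The consistent magnetic-field unit is then B_unit =
sqrt(mu0 * epsilon / (4 pi sigma^3)), so that m* B* epsilon = mu B.

Reference values: epsilon = 4.0694e-10 J, sigma = 600 um, tau = 1/60 s,
reduced translational damping gamma = 0.3 (physical drag 5.65e-6 kg/s) and
reduced rotational damping gamma_r = gamma/3 * sigma^2 = 0.1 for sigma = 1.
For particle sizes other than the 600 um reference, epsilon is rescaled
with the particle volume so that the reduced dipole strength — and with it
the whole reduced interaction hierarchy — is size-invariant, while the
physical drag coefficient scales linearly with size as in Stokes flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .geometry import (
    DEFAULT_CAP_FRACTION,
    DEFAULT_RADIUS,
    JanusGeometry,
    MaterialParams,
    ParticleSpec,
    make_particle,
)

__all__ = ["MU0", "UnitSystem", "ReducedParticle"]

MU0 = 1.25663706e-6  # vacuum permeability, kg m / (s^2 A^2)

REFERENCE_EPSILON = 4.0694e-10  # J, for the 600 um reference particle
REFERENCE_SIGMA = 600e-6        # m
DEFAULT_TAU = 1.0 / 60.0        # s
DEFAULT_GAMMA = 0.3             # reduced translational damping
DEFAULT_GAMMA_R = 0.1           # reduced rotational damping (gamma/3)
DEFAULT_DT = 1e-3               # integration step, units of tau


@dataclass(frozen=True)
class UnitSystem:
    """Reduced-unit system with converters in both directions."""

    epsilon: float = REFERENCE_EPSILON  # J
    sigma: float = REFERENCE_SIGMA      # m
    tau: float = DEFAULT_TAU            # s
    gamma: float = DEFAULT_GAMMA        # reduced
    gamma_r: float = DEFAULT_GAMMA_R    # reduced

    def __post_init__(self) -> None:
        for name in ("epsilon", "sigma", "tau", "gamma", "gamma_r"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_diameter(cls, sigma: float, **kwargs) -> "UnitSystem":
        """Unit system for a particle of diameter ``sigma`` (m).

        ``epsilon`` scales with the particle volume relative to the
        reference robot, which keeps the reduced dipole magnitude
        independent of size (dipole moment itself scales with cap volume).
        """
        eps = REFERENCE_EPSILON * (sigma / REFERENCE_SIGMA) ** 3
        return cls(epsilon=eps, sigma=sigma, **kwargs)

    # -- derived units -------------------------------------------------
    @property
    def force_unit(self) -> float:
        """epsilon/sigma (N)."""
        return self.epsilon / self.sigma

    @property
    def torque_unit(self) -> float:
        """epsilon (N m)."""
        return self.epsilon

    @property
    def drag_unit(self) -> float:
        """epsilon*tau/sigma^2 (kg/s)."""
        return self.epsilon * self.tau / self.sigma**2

    @property
    def velocity_unit(self) -> float:
        """sigma/tau (m/s)."""
        return self.sigma / self.tau

    @property
    def field_unit(self) -> float:
        """Magnetic field unit (T)."""
        return math.sqrt(MU0 * self.epsilon / (4.0 * math.pi * self.sigma**3))

    @property
    def dipole_unit(self) -> float:
        """Magnetic moment unit (A m^2); m* = mu / dipole_unit."""
        return math.sqrt(4.0 * math.pi * self.epsilon * self.sigma**3 / MU0)

    @property
    def physical_drag(self) -> float:
        """Physical translational drag coefficient implied by gamma (kg/s)."""
        return self.gamma * self.drag_unit

    # -- converters ----------------------------------------------------
    def to_reduced_length(self, x: float) -> float:
        return x / self.sigma

    def to_physical_length(self, x: float) -> float:
        return x * self.sigma

    def to_reduced_time(self, t: float) -> float:
        return t / self.tau

    def to_physical_time(self, t: float) -> float:
        return t * self.tau

    def to_reduced_energy(self, e: float) -> float:
        return e / self.epsilon

    def to_physical_energy(self, e: float) -> float:
        return e * self.epsilon

    def to_reduced_force(self, f: float) -> float:
        return f / self.force_unit

    def to_physical_force(self, f: float) -> float:
        return f * self.force_unit

    def to_reduced_torque(self, t: float) -> float:
        return t / self.torque_unit

    def to_physical_torque(self, t: float) -> float:
        return t * self.torque_unit

    def to_reduced_drag(self, g: float) -> float:
        return g / self.drag_unit

    def to_physical_drag(self, g: float) -> float:
        return g * self.drag_unit

    def to_reduced_dipole(self, mu: float) -> float:
        return mu / self.dipole_unit

    def to_physical_dipole(self, m: float) -> float:
        return m * self.dipole_unit

    def to_reduced_field(self, b_tesla: float) -> float:
        return b_tesla / self.field_unit

    def to_physical_field(self, b: float) -> float:
        return b * self.field_unit

    def to_reduced_velocity(self, v: float) -> float:
        return v / self.velocity_unit

    def to_physical_velocity(self, v: float) -> float:
        return v * self.velocity_unit


@dataclass(frozen=True)
class ReducedParticle:
    """Per-particle reduced parameters entering the equations of motion."""

    m_star: float         # reduced dipole magnitude
    s_offset: float       # centre -> cap-centroid distance, units of sigma
    weight_center: float  # |G_c|, units of epsilon/sigma
    weight_cap: float     # |G_m|, units of epsilon/sigma

    @property
    def net_weight(self) -> float:
        return self.weight_center + self.weight_cap

    @classmethod
    def from_spec(cls, spec: ParticleSpec, units: UnitSystem) -> "ReducedParticle":
        return cls(
            m_star=units.to_reduced_dipole(spec.dipole_moment),
            s_offset=units.to_reduced_length(spec.geometry.centroid_offset),
            weight_center=units.to_reduced_force(spec.weight_center),
            weight_cap=units.to_reduced_force(spec.weight_cap),
        )


def default_reduced_particle(
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    radius: float = DEFAULT_RADIUS,
    materials: MaterialParams | None = None,
) -> tuple[ReducedParticle, UnitSystem]:
    """Convenience: reduced parameters for a particle of the given
    geometry, with the unit system scaled to its diameter."""
    geom = JanusGeometry(radius=radius, cap_fraction=cap_fraction)
    units = UnitSystem.for_diameter(geom.sigma)
    spec = make_particle(geom, materials)
    return ReducedParticle.from_spec(spec, units), units
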