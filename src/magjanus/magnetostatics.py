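"""Closed-form point-dipole estimates and the physical force budget.

These analytic numbers motivate the simulation's force hierarchy: at
contact-scale separations the dipolar attraction between two robots is
roughly an order of magnitude larger than a robot's net buoyant weight,
which in turn dwarfs the hydrodynamic drag at the highest observed speeds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

from .geometry import JanusGeometry, MaterialParams, make_particle
from .units import MU0, UnitSystem

__all__ = ["peak_dipole_force", "axial_field", "ForceBudget", "force_scale_report"]

import math


def peak_dipole_force(mu: float, d: float, convention: str = "budget") -> float:
    """Peak attractive force (N) between two coaxial dipoles ``mu`` (A m^2)
    at separation ``d`` (m).

    convention='budget' (default) uses F = 3 mu0 mu^2 / (pi d^4), the form
    used for the order-of-magnitude force budget; convention='coaxial'
    uses the textbook coaxial-dipole gradient force 3 mu0 mu^2/(2 pi d^4),
    a factor of two smaller.
    """
    if d <= 0.0:
        raise ValueError("separation d must be positive")
    if convention == "budget":
        return 3.0 * MU0 * mu * mu / (math.pi * d**4)
    if convention == "coaxial":
        return 3.0 * MU0 * mu * mu / (2.0 * math.pi * d**4)
    raise ValueError(f"unknown convention {convention!r}")


def axial_field(mu: float, d: float) -> float:
    """On-axis field (T) of a point dipole: B = mu0 mu / (2 pi d^3).

    Decays as the inverse cube of the distance to the dipole centre.
    """
    if d <= 0.0:
        raise ValueError("distance d must be positive")
    return MU0 * mu / (2.0 * math.pi * d**3)


@dataclass(frozen=True)
class ForceBudget:
    """Headline physical force magnitudes for one robot design (SI)."""

    f_magnetic: float         # peak dipole-dipole force, N
    f_gravity_buoyancy: float  # net buoyant weight, N
    f_drag: float             # drag at the reference speed, N
    mass: float               # robot mass, kg
    mass_water: float         # displaced water mass, kg
    drag_coefficient: float   # kg/s
    velocity: float           # reference speed, m/s
    separation: float         # dipole separation used for f_magnetic, m
    dipole_moment: float      # A m^2

    def as_dict(self) -> dict:
        return {
            "F_mag_uN": self.f_magnetic * 1e6,
            "F_gravity_buoyancy_uN": self.f_gravity_buoyancy * 1e6,
            "F_drag_uN": self.f_drag * 1e6,
            "mass_mg": self.mass * 1e6,
            "mass_water_mg": self.mass_water * 1e6,
            "drag_coefficient_kg_per_s": self.drag_coefficient,
            "velocity_mm_per_s": self.velocity * 1e3,
            "separation_um": self.separation * 1e6,
            "dipole_moment_Am2": self.dipole_moment,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2)

    def table(self) -> str:
        rows = [
            ("peak dipole force F_mag", f"{self.f_magnetic * 1e6:8.2f} uN"),
            ("net buoyant weight F_g", f"{self.f_gravity_buoyancy * 1e6:8.2f} uN"),
            ("drag force F_d", f"{self.f_drag * 1e6:8.3f} uN"),
            ("robot mass", f"{self.mass * 1e6:8.4f} mg"),
            ("displaced water mass", f"{self.mass_water * 1e6:8.4f} mg"),
            ("drag coefficient", f"{self.drag_coefficient:8.3e} kg/s"),
            ("reference speed", f"{self.velocity * 1e3:8.1f} mm/s"),
        ]
        width = max(len(r[0]) for r in rows)
        return "\n".join(f"{name:<{width}}  {val}" for name, val in rows)


def force_scale_report(
    geometry: JanusGeometry | None = None,
    materials: MaterialParams | None = None,
    units: UnitSystem | None = None,
    separation: float = 4.8e-4,
    velocity: float = 20e-3,
) -> ForceBudget:
    """Assemble the analytic force budget for a robot design.

    ``separation`` is the dipole-dipole distance (m) for the peak magnetic
    force (default: the contact-scale magnetic gap of a zigzag pair);
    ``velocity`` the reference speed (m/s) for the drag term.  The drag
    coefficient is the physical value implied by the reduced damping.
    """
    geometry = geometry or JanusGeometry()
    materials = materials or MaterialParams()
    units = units or UnitSystem.for_diameter(geometry.sigma)
    spec = make_particle(geometry, materials)
    return ForceBudget(
        f_magnetic=peak_dipole_force(materials.dipole_moment, separation),
        f_gravity_buoyancy=spec.net_weight,
        f_drag=units.physical_drag * velocity,
        mass=spec.mass,
        mass_water=spec.mass_water,
        drag_coefficient=units.physical_drag,
        velocity=velocity,
        separation=separation,
        dipole_moment=materials.dipole_moment,
    )
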