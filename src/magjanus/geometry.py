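"""Janus particle geometry and material parameters.

A magnetic Janus microrobot is modelled as a sphere of diameter ``sigma``
made of hydrogel, with a spherical cap of dense, permanently magnetised
NdFeB-loaded composite at one pole.  The cap height is expressed as a
fraction ``h`` of the diameter ("sedimentation height"): the cap occupies
the region within ``h*sigma`` of the magnetic pole.

Two reference points matter for the dynamics:

* the geometric centre ``r_c`` where buoyancy-corrected hydrogel weight acts,
* the cap centroid ``r_m = r_c - s*u`` where the excess cap weight and the
  magnetic point dipole sit.  ``u`` is the unit symmetry axis pointing from
  the cap toward the hydrogel pole, and ``s`` the centre-to-cap-centroid
  distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "JanusGeometry",
    "MaterialParams",
    "ParticleSpec",
    "cap_volume",
    "cap_centroid_offset",
    "make_particle",
]

#: Default cap fraction.  Chosen so that, with the default radius and
#: densities below, the particle mass evaluates to ~0.314 mg and the net
#: buoyant weight to ~1.97 uN, the design point of the reference robot.
DEFAULT_CAP_FRACTION = 0.33

#: Default particle radius (m); the reference robot has a 600 um diameter.
DEFAULT_RADIUS = 300e-6

#: Measured permanent dipole moment of the reference robot (A m^2).
DEFAULT_DIPOLE = 1.08e-6

#: Remanent-moment value from magnetometry of a single robot (A m^2);
#: available as an alternative preset for the dipole strength.
REMANENT_DIPOLE = 0.87e-6

#: Measured characterisation values of the fabricated robots.  These are
#: experimental inputs (fabrication and magnetometry), not quantities the
#: simulator predicts; they parameterise presets and sanity checks only.
MEASURED = {
    "diameters_m": (325e-6, 575e-6, 1082e-6),  # mean fabricated diameters
    "remanent_moment_Am2": REMANENT_DIPOLE,
    "coercivity_mT": 300.0,
    "min_actuation_field_mT": 0.4,   # weakest field that tilts a chain
    "plateau_tilt_deg": 84.0,        # tilt saturation at ~1 mT
    "release_time_s": 360.0,         # near-complete soft-matrix release
}


def cap_volume(h: float, sigma: float) -> float:
    """Volume of a spherical cap of height ``h*sigma`` cut from a sphere
    of diameter ``sigma``.

    V_cap = (1/6) pi h^2 (3 - 2h) sigma^3, the classical cap formula
    (pi/3) a^2 (3R - a) with a = h*sigma and R = sigma/2.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"cap fraction h must lie in [0, 1], got {h}")
    if sigma <= 0.0:
        raise ValueError(f"diameter sigma must be positive, got {sigma}")
    return math.pi / 6.0 * h * h * (3.0 - 2.0 * h) * sigma**3


def cap_centroid_offset(h: float, R: float) -> float:
    """Distance from the sphere centre to the centroid of a spherical cap
    of height ``2*R*h``.

    s = 3 R (1 - h)^2 / (3 - 2h).  Limits: a hemisphere (h = 1/2) has its
    centroid at 3R/8; the full sphere (h = 1) at the centre (s = 0); an
    infinitesimal cap (h -> 0) sits on the surface (s -> R).
    """
    if not 0.0 < h <= 1.0:
        raise ValueError(f"cap fraction h must lie in (0, 1], got {h}")
    if R <= 0.0:
        raise ValueError(f"radius R must be positive, got {R}")
    return 3.0 * R * (1.0 - h) ** 2 / (3.0 - 2.0 * h)


@dataclass(frozen=True)
class JanusGeometry:
    """Geometry of a single Janus particle (SI lengths)."""

    radius: float = DEFAULT_RADIUS
    cap_fraction: float = DEFAULT_CAP_FRACTION

    def __post_init__(self) -> None:
        if self.radius <= 0.0:
            raise ValueError(f"radius must be positive, got {self.radius}")
        if not 0.0 < self.cap_fraction < 1.0:
            raise ValueError(
                f"cap_fraction must lie in (0, 1), got {self.cap_fraction}"
            )

    @property
    def sigma(self) -> float:
        """Particle diameter (m)."""
        return 2.0 * self.radius

    @property
    def sphere_volume(self) -> float:
        """V_sphere = (1/6) pi sigma^3 (m^3)."""
        return math.pi / 6.0 * self.sigma**3

    @property
    def cap_volume(self) -> float:
        """Cap volume (m^3)."""
        return cap_volume(self.cap_fraction, self.sigma)

    @property
    def centroid_offset(self) -> float:
        """Distance s between sphere centre and cap centroid (m)."""
        return cap_centroid_offset(self.cap_fraction, self.radius)


@dataclass(frozen=True)
class MaterialParams:
    """Densities, gravity and dipole strength (SI).

    ``dipole_moment`` is the permanent moment of the *reference* geometry
    (radius 300 um, default cap fraction); :func:`make_particle` rescales
    it with the cap volume for other sizes or cap fractions, holding the
    magnetisation density of the cap material fixed.
    """

    rho_water: float = 1000.0
    rho_hydrogel: float = 1120.0
    rho_ndfeb: float = 7600.0
    g: float = 9.81
    dipole_moment: float = DEFAULT_DIPOLE
    reference_geometry: JanusGeometry = field(default_factory=JanusGeometry)

    def __post_init__(self) -> None:
        if not self.rho_ndfeb > self.rho_hydrogel > self.rho_water > 0.0:
            raise ValueError(
                "densities must satisfy rho_ndfeb > rho_hydrogel > rho_water > 0"
            )
        if self.dipole_moment < 0.0:
            raise ValueError("dipole_moment must be nonnegative")


@dataclass(frozen=True)
class ParticleSpec:
    """Derived per-particle quantities (SI) used to build a simulation.

    ``weight_center`` is the buoyancy-corrected weight of the hydrogel
    sphere, acting at the geometric centre; ``weight_cap`` the *excess*
    weight of the cap over hydrogel, acting at the cap centroid.  Their sum
    is the net buoyant weight of the particle.
    """

    geometry: JanusGeometry
    materials: MaterialParams
    mass: float            # kg
    mass_water: float      # displaced water mass, kg
    weight_center: float   # |G_c|, N
    weight_cap: float      # |G_m|, N
    dipole_moment: float   # A m^2, scaled with cap volume

    @property
    def net_weight(self) -> float:
        """Net buoyant weight g*(m - m_water) (N)."""
        return self.weight_center + self.weight_cap


def make_particle(
    geom: JanusGeometry, mat: MaterialParams | None = None
) -> ParticleSpec:
    """Derive masses, weight split and dipole moment for one particle.

    The gravity/buoyancy load is split into two point loads:

    * G_c = (rho_hydrogel - rho_water) V_sphere g at the centre,
    * G_m = (rho_ndfeb - rho_hydrogel) V_cap g at the cap centroid,

    whose sum equals the net buoyant weight exactly.  The dipole moment is
    the reference moment scaled by the ratio of cap volumes, i.e. the cap
    magnetisation density is treated as a material constant.
    """
    mat = mat or MaterialParams()
    v_sphere = geom.sphere_volume
    v_cap = geom.cap_volume
    mass = mat.rho_hydrogel * v_sphere + (mat.rho_ndfeb - mat.rho_hydrogel) * v_cap
    mass_water = mat.rho_water * v_sphere
    g_c = (mat.rho_hydrogel - mat.rho_water) * v_sphere * mat.g
    g_m = (mat.rho_ndfeb - mat.rho_hydrogel) * v_cap * mat.g
    mu = mat.dipole_moment * v_cap / mat.reference_geometry.cap_volume
    return ParticleSpec(
        geometry=geom,
        materials=mat,
        mass=mass,
        mass_water=mass_water,
        weight_center=g_c,
        weight_cap=g_m,
        dipole_moment=mu,
    )
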