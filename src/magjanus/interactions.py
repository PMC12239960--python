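"""Pairwise, body, field and wall force/torque terms (reduced units).

These are the reference implementations of every term entering the
overdamped equations of motion

    gamma   dr_c/dt = sum_j (F_WCA + F_dip) + G_c + G_m + F_wall - F_fric
    gamma_r omega   = sum_j T_dip + T_grav + T_B - T_fric

All quantities are reduced: lengths in particle diameters sigma, energies
in epsilon, forces in epsilon/sigma.  The compiled integration kernel in
``_kernels`` reimplements the same terms for speed; the test suite checks
the two against each other and every force against the numerical gradient
of its potential.

Sign conventions
----------------
* The WCA potential is truncated and shifted *up* by epsilon so both the
  potential and the force vanish continuously at the cutoff 2^(1/6) sigma.
* The external-field energy is taken as U_B = -mu.B, so the torque
  mu x B rotates a dipole toward alignment with the field.
* Dipole-dipole forces act at the magnetic reference points r_m; mapping
  them to loads about the particle centres adds the lever-arm torque
  (r_m - r_c) x F.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .units import ReducedParticle

__all__ = [
    "RCUT",
    "PairLoad",
    "u_wca",
    "wca_pair_force",
    "u_dipole",
    "dipole_pair_interaction",
    "dipole_pair_loads",
    "external_field_torque",
    "gravity_buoyancy_loads",
    "u_wall",
    "wall_wca_force",
    "coulomb_friction",
]

RCUT = 2.0 ** (1.0 / 6.0)          # WCA cutoff, units of sigma
WALL_SIGMA = 0.5                   # effective sigma of the particle-wall WCA
WALL_RCUT = RCUT * WALL_SIGMA
V_STICK = 1e-3                     # stick/slip crossover speed, sigma/tau
#: short-range saturation of the point-dipole interaction (see module
#: docstring of ``_kernels``): below this magnetic-point separation the
#: 1/r powers are evaluated at DIPOLE_RMIN while directions follow the
#: true separation vector.  The point-dipole picture of an extended cap
#: is not meaningful below the cap's own size.
DIPOLE_RMIN = 0.8


@dataclass(frozen=True)
class PairLoad:
    """Forces and torques (about the particle centres) of one pair term."""

    force_i: np.ndarray
    force_j: np.ndarray
    torque_i: np.ndarray
    torque_j: np.ndarray


# ---------------------------------------------------------------------------
# excluded volume

def u_wca(r: float, eps: float = 1.0, sigma: float = 1.0) -> float:
    """Truncated-shifted Lennard-Jones (WCA) potential."""
    if r <= 0.0:
        raise ValueError("pair distance must be positive")
    if r >= RCUT * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 4.0 * eps * (sr6 * sr6 - sr6) + eps


def _wca_force_mag(r: float, eps: float, sigma: float) -> float:
    """Magnitude of the repulsive WCA force, -dU/dr (>= 0 inside cutoff)."""
    if r >= RCUT * sigma:
        return 0.0
    sr6 = (sigma / r) ** 6
    return 24.0 * eps * (2.0 * sr6 * sr6 - sr6) / r


def wca_pair_force(
    r_ci: np.ndarray, r_cj: np.ndarray, eps: float = 1.0, sigma: float = 1.0
) -> PairLoad:
    """Central repulsive WCA force between two particle centres."""
    rij = np.asarray(r_ci, float) - np.asarray(r_cj, float)
    r = float(np.linalg.norm(rij))
    if r < 1e-12:
        raise ValueError(
            f"coincident particle centres at {np.asarray(r_ci)}: WCA force diverges"
        )
    f = _wca_force_mag(r, eps, sigma) * rij / r
    zero = np.zeros(3)
    return PairLoad(f, -f, zero, zero)


# ---------------------------------------------------------------------------
# dipole-dipole

def u_dipole(r_vec: np.ndarray, mu_i: np.ndarray, mu_j: np.ndarray,
             eps: float = 1.0) -> float:
    """Reduced point-dipole pair energy.

    U = eps * [mu_i.mu_j - 3 (mu_i.n)(mu_j.n)] / r^3 with r_vec from j to i.
    """
    r_vec = np.asarray(r_vec, float)
    r = float(np.linalg.norm(r_vec))
    if r < 1e-12:
        raise ValueError("coincident magnetic reference points")
    n = r_vec / r
    r = max(r, DIPOLE_RMIN)
    return eps * (
        float(np.dot(mu_i, mu_j)) - 3.0 * float(np.dot(mu_i, n)) * float(np.dot(mu_j, n))
    ) / r**3


def dipole_pair_interaction(
    r_mi: np.ndarray,
    r_mj: np.ndarray,
    mu_i: np.ndarray,
    mu_j: np.ndarray,
    eps: float = 1.0,
):
    """Force on i (at its magnetic point) and the orientation torques.

    Returns ``(f_i, tau_i, tau_j)``; the force on j is ``-f_i``.  The
    torques are the mu x B form, B being the reduced dipole field of the
    partner evaluated at the magnetic point.
    """
    mu_i = np.asarray(mu_i, float)
    mu_j = np.asarray(mu_j, float)
    rij = np.asarray(r_mi, float) - np.asarray(r_mj, float)
    r = float(np.linalg.norm(rij))
    if r < 1e-12:
        raise ValueError("coincident magnetic reference points")
    n = rij / r
    r = max(r, DIPOLE_RMIN)
    mi_n = float(np.dot(mu_i, n))
    mj_n = float(np.dot(mu_j, n))
    mi_mj = float(np.dot(mu_i, mu_j))
    f_i = (3.0 * eps / r**4) * (
        mi_n * mu_j + mj_n * mu_i + mi_mj * n - 5.0 * mi_n * mj_n * n
    )
    # dipole field B(d) = (3 (m.dhat) dhat - m)/|d|^3; from j to i dhat = +n,
    # from i to j dhat = -n, and the two sign flips cancel in the first term
    b_at_i = eps * (3.0 * mj_n * n - mu_j) / r**3
    b_at_j = eps * (3.0 * mi_n * n - mu_i) / r**3
    tau_i = np.cross(mu_i, b_at_i)
    tau_j = np.cross(mu_j, b_at_j)
    return f_i, tau_i, tau_j


def dipole_pair_loads(
    r_ci: np.ndarray,
    r_cj: np.ndarray,
    u_i: np.ndarray,
    u_j: np.ndarray,
    mu_i: np.ndarray,
    mu_j: np.ndarray,
    s_i: float,
    s_j: float,
    eps: float = 1.0,
) -> PairLoad:
    """Dipole pair loads referred to the particle centres.

    The magnetic points are r_m = r_c - s*u; the torque about each centre
    is the orientation torque plus the lever arm (r_m - r_c) x F.
    """
    r_ci = np.asarray(r_ci, float)
    r_cj = np.asarray(r_cj, float)
    u_i = np.asarray(u_i, float)
    u_j = np.asarray(u_j, float)
    r_mi = r_ci - s_i * u_i
    r_mj = r_cj - s_j * u_j
    f_i, tau_i, tau_j = dipole_pair_interaction(r_mi, r_mj, mu_i, mu_j, eps)
    tau_i = tau_i + np.cross(r_mi - r_ci, f_i)
    tau_j = tau_j + np.cross(r_mj - r_cj, -f_i)
    return PairLoad(f_i, -f_i, tau_i, tau_j)


# ---------------------------------------------------------------------------
# external field and body loads

def external_field_torque(mu: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Torque mu x B of a uniform field (no net force)."""
    return np.cross(np.asarray(mu, float), np.asarray(B, float))


def gravity_buoyancy_loads(
    u: np.ndarray, particle: ReducedParticle
) -> tuple[np.ndarray, np.ndarray]:
    """Total gravity/buoyancy force and its torque about the centre.

    The hydrogel load G_c acts at the centre (no torque); the excess cap
    load G_m acts at r_m = r_c - s*u, giving the torque (-s*u) x G_m that
    rights the particle cap-down.
    """
    u = np.asarray(u, float)
    g_c = np.array([0.0, 0.0, -particle.weight_center])
    g_m = np.array([0.0, 0.0, -particle.weight_cap])
    torque = np.cross(-particle.s_offset * u, g_m)
    return g_c + g_m, torque


# ---------------------------------------------------------------------------
# walls

def u_wall(dist: float, eps: float = 1.0) -> float:
    """Particle-wall WCA potential as a function of the centre-to-plane
    distance, with effective sigma = one particle radius."""
    return u_wca(dist, eps, WALL_SIGMA)


def wall_wca_force(dist: float, eps: float = 1.0) -> float:
    """Magnitude N of the repulsive wall normal force (zero beyond cutoff)."""
    if dist <= 0.0:
        raise ValueError("particle centre has penetrated the wall plane")
    return _wca_force_mag(dist, eps, WALL_SIGMA)


# ---------------------------------------------------------------------------
# Coulomb friction

def coulomb_friction(
    f_tangential: np.ndarray,
    yaw_torque: float,
    normal_force: float,
    in_chain: bool,
    lambda_static: float = 0.5,
    lambda_dynamic: float = 0.4,
    gamma: float = 0.3,
    v_stick: float = V_STICK,
    contact_radius: float = 0.5,
) -> tuple[np.ndarray, float]:
    """Stick/slip wall friction for a chain-arranged particle.

    Single particles roll rather than slide and get no friction at all.
    For particles in a chain: if the applied tangential force would drive a
    speed below ``v_stick`` or lies inside the static cone lambda_s * N,
    friction cancels it exactly (stick); otherwise kinetic friction of
    magnitude lambda_d * N opposes the sliding direction.  The yaw torque
    about the contact normal is resisted analogously with effective
    contact radius ``contact_radius``.

    Returns ``(friction_force, friction_torque_about_normal)`` to be
    *subtracted* handled as: net = applied + returned (returned opposes).
    """
    if normal_force < 0.0:
        raise ValueError("normal force must be nonnegative")
    f_t = np.asarray(f_tangential, float)
    if not in_chain or normal_force == 0.0:
        return np.zeros(3), 0.0
    mag = float(np.linalg.norm(f_t))
    threshold = max(lambda_static * normal_force, gamma * v_stick)
    if mag <= threshold:
        f_fric = -f_t
    else:
        f_fric = -lambda_dynamic * normal_force * f_t / mag
    cap_static = lambda_static * normal_force * contact_radius
    if abs(yaw_torque) <= cap_static:
        t_fric = -yaw_torque
    else:
        t_fric = -math.copysign(
            lambda_dynamic * normal_force * contact_radius, yaw_torque
        )
    return f_fric, t_fric
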