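"""Trajectory post-processing.

Chains are connected components of the contact graph (centre-to-centre
distance below a bond cutoff, default 1.1 sigma — the contact shell of the
WCA minimum).  On top of that the module provides the assembly-efficiency
statistic, dimer offset angles, centroid kinematics for gait speeds,
fragmentation timing, and the cumulative cargo-release percentage computed
from fluorescence-area series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .dynamics import BOND_CUTOFF, Trajectory

__all__ = [
    "ChainPartition",
    "detect_chains",
    "assembly_efficiency",
    "offset_angle",
    "centroid_kinematics",
    "mean_speed",
    "fragmentation_time",
    "chain_sizes_over_time",
    "release_percent",
    "ReleaseRecord",
    "zigzag_signature",
]


@dataclass(frozen=True)
class ChainPartition:
    """Partition of the particle population into chains at one instant.

    Each chain is ordered along its principal axis; ties broken by
    particle id so outputs are deterministic.
    """

    chains: tuple[tuple[int, ...], ...]
    time: float = 0.0

    @property
    def n_particles(self) -> int:
        return sum(len(c) for c in self.chains)

    @property
    def sizes(self) -> tuple[int, ...]:
        return tuple(len(c) for c in self.chains)

    @property
    def largest(self) -> tuple[int, ...]:
        return max(self.chains, key=len)


def detect_chains(
    positions: np.ndarray, bond_cutoff: float = BOND_CUTOFF, time: float = 0.0
) -> ChainPartition:
    """Connected components of the contact graph of one frame."""
    if bond_cutoff <= 1.0:
        raise ValueError("bond_cutoff should exceed one particle diameter")
    pos = np.asarray(positions, dtype=float)
    n = pos.shape[0]
    if n == 0:
        return ChainPartition((), time)
    adj = squareform(pdist(pos) < bond_cutoff).astype(np.int8)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    chains = []
    for c in range(n_comp):
        ids = np.flatnonzero(labels == c)
        if len(ids) > 2:
            coords = pos[ids] - pos[ids].mean(axis=0)
            # principal axis from the largest singular vector
            _, _, vt = np.linalg.svd(coords, full_matrices=False)
            proj = coords @ vt[0]
            order = np.lexsort((ids, proj))
            ids = ids[order]
        elif len(ids) == 2:
            ids = np.sort(ids)
        chains.append(tuple(int(i) for i in ids))
    chains.sort(key=lambda c: (-len(c), c[0]))
    return ChainPartition(tuple(chains), time)


def assembly_efficiency(partition: ChainPartition) -> float:
    """Fraction of the population incorporated into the largest chain."""
    if not partition.chains:
        raise ValueError("empty partition")
    return len(partition.largest) / partition.n_particles


def offset_angle(
    positions: np.ndarray,
    dipole_dirs: np.ndarray,
    bond_cutoff: float = BOND_CUTOFF,
) -> float:
    """Offset angle of a bonded dimer, degrees.

    Angle between the centre-to-centre vector and the common dipole
    direction; 0 deg is a perfectly head-to-tail pair, 90 deg a
    side-by-side pair.  Folded to [0, 90].
    """
    pos = np.asarray(positions, dtype=float)
    if pos.shape != (2, 3):
        raise ValueError("offset_angle expects exactly two particles")
    sep = pos[1] - pos[0]
    dist = float(np.linalg.norm(sep))
    if dist >= bond_cutoff:
        raise ValueError(f"pair is not bonded (distance {dist:.3f} sigma)")
    mu = np.asarray(dipole_dirs, dtype=float).mean(axis=0)
    mu /= np.linalg.norm(mu)
    cosang = abs(float(np.dot(sep / dist, mu)))
    return math.degrees(math.acos(min(1.0, cosang)))


def centroid_kinematics(traj: Trajectory):
    """Centroid displacement and central-difference velocity series.

    Returns ``(times_tau, displacement, velocity)`` in reduced units; the
    displacement is relative to the first frame.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least two frames")
    c = traj.centroid()
    disp = c - c[0]
    vel = np.gradient(c, traj.times, axis=0)
    return traj.times, disp, vel


def mean_speed(
    traj: Trajectory,
    frequency_hz: float,
    transient_periods: float = 2.0,
    axis: int | None = None,
) -> float:
    """Mean centroid speed in mm/s over an integer number of field periods.

    Discards ``transient_periods`` of the actuation period at the start,
    keeps the largest integer number of whole periods that fits, and
    divides the net centroid displacement (component ``axis``, or the
    Euclidean norm) by the elapsed time.
    """
    period_tau = 1.0 / (frequency_hz * traj.units.tau)
    t0 = transient_periods * period_tau
    t_end = traj.times[-1]
    n_periods = math.floor((t_end - t0) / period_tau)
    if n_periods < 1:
        raise ValueError("averaging window longer than trajectory")
    t1 = t0 + n_periods * period_tau
    c = traj.centroid()
    i0 = int(np.searchsorted(traj.times, t0 - 1e-9))
    i1 = int(np.searchsorted(traj.times, t1 - 1e-9))
    i1 = min(i1, traj.n_frames - 1)
    dt = traj.times[i1] - traj.times[i0]
    delta = c[i1] - c[i0]
    dist = abs(float(delta[axis])) if axis is not None else float(np.linalg.norm(delta))
    speed_red = dist / dt
    return speed_red * traj.units.velocity_unit * 1e3  # m/s -> mm/s


def chain_sizes_over_time(
    traj: Trajectory, bond_cutoff: float = BOND_CUTOFF
) -> list[ChainPartition]:
    return [
        detect_chains(traj.positions[k], bond_cutoff, time=float(traj.times[k]))
        for k in range(traj.n_frames)
    ]


def fragmentation_time(
    traj: Trajectory,
    bond_cutoff: float = BOND_CUTOFF,
    mode: str = "first_split",
    t_from: float = 0.0,
) -> float:
    """Seconds from ``t_from`` (tau) until the chain first fragments.

    mode='first_split': first frame with >= 2 connected components.
    mode='dispersal':   first frame where the largest component is at
                        most half the starting size.
    Returns ``inf`` if the event never occurs within the trajectory.
    """
    start = int(np.searchsorted(traj.times, t_from - 1e-9))
    first = detect_chains(traj.positions[start], bond_cutoff)
    if len(first.chains) != 1:
        raise ValueError("trajectory does not start as a single chain")
    n0 = len(first.largest)
    for k in range(start, traj.n_frames):
        part = detect_chains(traj.positions[k], bond_cutoff)
        if mode == "first_split":
            hit = len(part.chains) >= 2
        elif mode == "dispersal":
            hit = len(part.largest) <= n0 // 2
        else:
            raise ValueError(f"unknown mode {mode!r}")
        if hit:
            return float((traj.times[k] - t_from) * traj.units.tau)
    return math.inf


# ---------------------------------------------------------------------------
# cargo release

@dataclass(frozen=True)
class ReleaseRecord:
    """Fluorescence-area series of a degrading carrier."""

    area_initial: float
    areas: np.ndarray
    times_s: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.area_initial <= 0.0:
            raise ValueError("initial area must be positive")

    def release_series(self) -> np.ndarray:
        return release_percent(self.area_initial, np.asarray(self.areas, float))


def release_percent(a0: float, a_t):
    """Cumulative release percentage 100 * (A0 - A_t) / A0.

    Values outside [0, 100] (area growth or negative areas) are passed
    through unclipped so anomalies stay visible to the caller.
    """
    if a0 <= 0.0:
        raise ValueError("initial fluorescence area A0 must be positive")
    return 100.0 * (a0 - np.asarray(a_t, dtype=float)) / a0


# ---------------------------------------------------------------------------
# chain shape

def zigzag_signature(positions: np.ndarray, chain: tuple[int, ...]) -> np.ndarray:
    """Perpendicular offsets of chain members from the chain's principal
    axis, in chain order.  A zigzag chain alternates the sign of the
    dominant transverse component along the chain."""
    pos = np.asarray(positions, dtype=float)[list(chain)]
    centred = pos - pos.mean(axis=0)
    _, _, vt = np.linalg.svd(centred, full_matrices=False)
    axis, trans = vt[0], vt[1]
    return centred @ trans
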