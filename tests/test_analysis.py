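"""Chain detection, kinematics and the release statistic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from magjanus.analysis import (
    ChainPartition,
    ReleaseRecord,
    assembly_efficiency,
    centroid_kinematics,
    detect_chains,
    fragmentation_time,
    mean_speed,
    offset_angle,
    release_percent,
    zigzag_signature,
)
from magjanus.dynamics import Trajectory
from magjanus.units import UnitSystem


def brute_force_components(pos: np.ndarray, cutoff: float) -> list[frozenset]:
    """Union-find oracle over the full distance matrix."""
    n = pos.shape[0]
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(pos[i] - pos[j]) < cutoff:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


def _toy_trajectory(positions, times_tau, units=None):
    positions = np.asarray(positions, dtype=float)
    f, n = positions.shape[:2]
    units = units or UnitSystem()
    from magjanus.arena import build_arena
    from magjanus.dynamics import SimulationConfig
    from magjanus.fields import StaticField
    from magjanus.units import default_reduced_particle

    particle, _ = default_reduced_particle()
    cfg = SimulationConfig(
        positions=positions[0],
        axes=np.tile([0.0, 0.0, 1.0], (n, 1)),
        dipole_dirs=np.tile([1.0, 0.0, 0.0], (n, 1)),
        particles=[particle] * n,
        field_program=StaticField(0.0, (0, 0, 1)),
        arena=build_arena("flat"),
        units=units,
        duration=max(times_tau[-1], 1.0),
    )
    return Trajectory(
        times=np.asarray(times_tau, dtype=float),
        positions=positions,
        axes=np.zeros_like(positions),
        dipole_dirs=np.zeros_like(positions),
        field_mT=np.zeros((f, 3)),
        units=units,
        config=cfg,
    )


class TestDetectChains:
    def test_all_separated(self):
        pos = np.arange(8)[:, None] * np.array([3.0, 0.0, 0.0])
        part = detect_chains(pos)
        assert part.sizes == (1,) * 8

    def test_single_chain_ordered(self):
        pos = np.arange(8)[:, None] * np.array([1.0, 0.0, 0.0])
        part = detect_chains(pos)
        assert part.sizes == (8,)
        # ordered along the chain axis
        order = list(part.largest)
        assert order == sorted(order) or order == sorted(order, reverse=True)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_union_find(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.uniform(0.0, 6.0, size=(20, 3))
        part = detect_chains(pos, 1.1)
        got = {frozenset(c) for c in part.chains}
        expected = set(brute_force_components(pos, 1.1))
        assert got == expected

    def test_permutation_invariant(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0.0, 5.0, size=(15, 3))
        perm = rng.permutation(15)
        a = {frozenset(map(int, c)) for c in detect_chains(pos).chains}
        b = {
            frozenset(int(perm[i]) for i in c)
            for c in detect_chains(pos[perm]).chains
        }
        assert a == b

    def test_cutoff_must_exceed_diameter(self):
        with pytest.raises(ValueError):
            detect_chains(np.zeros((2, 3)), bond_cutoff=0.9)


class TestEfficiency:
    def test_single_chain(self):
        assert assembly_efficiency(ChainPartition(((0, 1, 2, 3, 4, 5, 6, 7),))) == 1.0

    def test_five_three_split(self):
        part = ChainPartition(((0, 1, 2, 3, 4), (5, 6, 7)))
        assert assembly_efficiency(part) == pytest.approx(0.625)

    def test_all_singletons(self):
        part = ChainPartition(tuple((i,) for i in range(5)))
        assert assembly_efficiency(part) == pytest.approx(0.2)


class TestOffsetAngle:
    def test_head_to_tail_is_zero(self):
        pos = np.array([[0.0, 0, 0.5], [1.0, 0, 0.5]])
        mu = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        assert offset_angle(pos, mu) == pytest.approx(0.0, abs=1e-9)

    def test_perpendicular_offset_is_ninety(self):
        pos = np.array([[0.0, 0, 0.5], [0.0, 1.0, 0.5]])
        mu = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        assert offset_angle(pos, mu) == pytest.approx(90.0)

    def test_unbonded_pair_rejected(self):
        pos = np.array([[0.0, 0, 0.5], [3.0, 0, 0.5]])
        mu = np.array([[1.0, 0, 0], [1.0, 0, 0]])
        with pytest.raises(ValueError):
            offset_angle(pos, mu)


class TestKinematics:
    def test_stationary_chain_has_zero_velocity(self):
        pos = np.tile(np.array([[0.0, 0.0, 0.5], [1.0, 0.0, 0.5]]), (5, 1, 1))
        traj = _toy_trajectory(pos, np.arange(5.0))
        _, disp, vel = centroid_kinematics(traj)
        assert np.allclose(disp, 0.0) and np.allclose(vel, 0.0)

    def test_linear_drift_recovered_exactly(self):
        v = np.array([0.2, -0.1, 0.0])
        times = np.arange(10.0)
        base = np.array([[0.0, 0.0, 0.5]])
        pos = np.array([base + t * v for t in times])
        traj = _toy_trajectory(pos, times)
        _, _, vel = centroid_kinematics(traj)
        assert np.allclose(vel, v)

    def test_tumbling_rod_mean_speed(self):
        """Analytic no-slip tumbler: a rod of length L pivoting end over
        end advances 2 L per period, so the mean speed is 2 L f."""
        units = UnitSystem()
        f_hz = 1.0
        period_tau = 1.0 / (f_hz * units.tau)  # 60 tau
        L = 1.0
        n_steps_per_half = 50
        times, centroids = [], []
        y_pivot = 0.0
        t = 0.0
        for half in range(8):
            for k in range(n_steps_per_half):
                phase = k / n_steps_per_half * math.pi
                centre = y_pivot + (L / 2.0) * math.cos(math.pi - phase)
                z = (L / 2.0) * math.sin(phase)
                times.append(t)
                centroids.append([0.0, centre, z + 0.5])
                t += (period_tau / 2.0) / n_steps_per_half
            y_pivot += L
        pos = np.asarray(centroids)[:, None, :]
        traj = _toy_trajectory(pos, np.asarray(times), units)
        speed = mean_speed(traj, f_hz, transient_periods=0.0, axis=1)
        # 2 L per period in reduced units -> 2 L f in mm/s after scaling
        expected_mm_s = 2.0 * L * f_hz * units.sigma * 1e3
        assert speed == pytest.approx(expected_mm_s, rel=0.02)

    def test_window_longer_than_trajectory_rejected(self):
        pos = np.tile(np.array([[0.0, 0.0, 0.5]]), (3, 1, 1))
        traj = _toy_trajectory(pos, np.arange(3.0))
        with pytest.raises(ValueError):
            mean_speed(traj, 1.0)


class TestFragmentation:
    def test_never_breaking_chain_is_infinite(self):
        pos = np.tile(
            np.array([[0.0, 0.0, 0.5], [1.0, 0.0, 0.5], [2.0, 0.0, 0.5]]), (4, 1, 1)
        )
        traj = _toy_trajectory(pos, np.arange(4.0))
        assert fragmentation_time(traj) == math.inf

    def test_scripted_departure_time(self):
        frames = []
        for k in range(6):
            f = np.array([[0.0, 0.0, 0.5], [1.0, 0.0, 0.5], [2.0, 0.0, 0.5]])
            if k >= 3:
                f[2, 0] = 5.0  # third particle departs at frame 3
            frames.append(f)
        traj = _toy_trajectory(np.asarray(frames), np.arange(6.0))
        t = fragmentation_time(traj)
        assert t == pytest.approx(3.0 * traj.units.tau)

    def test_requires_initial_single_chain(self):
        pos = np.tile(np.array([[0.0, 0.0, 0.5], [4.0, 0.0, 0.5]]), (3, 1, 1))
        traj = _toy_trajectory(pos, np.arange(3.0))
        with pytest.raises(ValueError):
            fragmentation_time(traj)


class TestRelease:
    def test_no_release_at_initial_area(self):
        assert release_percent(200.0, 200.0) == 0.0

    def test_complete_release(self):
        assert release_percent(200.0, 0.0) == 100.0

    def test_partial_release(self):
        assert release_percent(200.0, 50.0) == pytest.approx(75.0)

    def test_series_and_validation(self):
        rec = ReleaseRecord(100.0, np.array([100.0, 60.0, 10.0]))
        assert np.allclose(rec.release_series(), [0.0, 40.0, 90.0])
        with pytest.raises(ValueError):
            ReleaseRecord(0.0, np.array([1.0]))
        with pytest.raises(ValueError):
            release_percent(-1.0, 0.5)


def test_zigzag_signature_alternates_for_staggered_chain():
    ys = np.array([0.3 * (-1) ** i for i in range(6)])
    pos = np.stack([np.arange(6) * 0.9, ys, np.full(6, 0.5)], axis=1)
    sig = zigzag_signature(pos, tuple(range(6)))
    assert np.std(sig) > 0.2
    assert np.all(np.sign(sig[:-1]) != np.sign(sig[1:]))
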