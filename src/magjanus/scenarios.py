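"""Scenario registry: reproducible figure-level experiments.

Each scenario builds a :class:`~magjanus.dynamics.SimulationConfig` from a
seed and keyword parameters, and declares how its summary metrics are
computed.  ``run_scenario`` executes a scenario, optionally writing the
trajectory (extended XYZ), per-frame metrics (CSV), and a summary (JSON,
including the resolved parameters and package version) to an output
directory.

Initial placements drop particles upright (cap down) at their resting
height with seeded positional jitter and seeded random dipole azimuths;
chain initialisers start from a straight head-to-tail contact chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np

from . import __version__
from .analysis import (
    assembly_efficiency,
    detect_chains,
    fragmentation_time,
    mean_speed,
)
from .arena import Arena, build_arena
from .dynamics import SimulationConfig, Trajectory, run_simulation
from .fields import FieldProgram, RotatingField, Schedule, preset
from .geometry import DEFAULT_CAP_FRACTION, JanusGeometry, MaterialParams, make_particle
from .io import write_metrics_csv, write_summary_json, write_xyz
from .units import ReducedParticle, UnitSystem

__all__ = ["Scenario", "SCENARIOS", "run_scenario", "scenario_names", "build_scenario"]

#: resting centre height of a particle on the floor (wall-WCA contact)
REST_Z = 0.5612310241546865  # 2^(1/6)/2, the zero-force wall distance


def _make_units_particle(diameter_m: float, cap_fraction: float):
    geom = JanusGeometry(radius=diameter_m / 2.0, cap_fraction=cap_fraction)
    units = UnitSystem.for_diameter(geom.sigma)
    spec = make_particle(geom, MaterialParams())
    return units, ReducedParticle.from_spec(spec, units)


def _upright_frames(n: int, rng: np.random.Generator, azimuth: str = "random"):
    """u = +z (cap down); dipole horizontal with random or fixed azimuth."""
    u = np.tile([0.0, 0.0, 1.0], (n, 1))
    if azimuth == "random":
        phi = rng.uniform(0.0, 2.0 * math.pi, size=n)
    else:
        phi = np.zeros(n)
    muh = np.stack([np.cos(phi), np.sin(phi), np.zeros(n)], axis=1)
    return u, muh


def _line_positions(
    n: int,
    spacing: float,
    rng: np.random.Generator,
    axis: int = 0,
    jitter: float = 0.1,
    z: float = REST_Z,
    start: float | None = None,
):
    pos = np.zeros((n, 3))
    offset = start if start is not None else -(n - 1) * spacing / 2.0
    pos[:, axis] = offset + spacing * np.arange(n)
    pos[:, 2] = z
    if jitter > 0.0:
        pos[:, :2] += rng.uniform(-jitter, jitter, size=(n, 2))
    return pos


def _chain_start(n: int, axis: int, rng: np.random.Generator, start=None):
    """Straight head-to-tail contact chain along a horizontal axis."""
    pos = _line_positions(n, 1.05, rng, axis=axis, jitter=0.0, start=start)
    u = np.tile([0.0, 0.0, 1.0], (n, 1))
    muh = np.zeros((n, 3))
    muh[:, axis] = 1.0
    return pos, u, muh


_RELAX_CACHE: dict = {}


def relaxed_chain(
    n: int,
    axis: int = 1,
    diameter_m: float = 600e-6,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    seed: int = 0,
    relax_tau: float = 60.0,
):
    """Equilibrium zigzag chain of ``n`` particles along a horizontal axis.

    A straight contact chain is annealed under the horizontal oscillating
    assembly field until it adopts its staggered (zigzag) ground state;
    the zigzag state carries the chain's bending stiffness and is the
    physically meaningful starting point of every chain-locomotion
    scenario.  Deterministic for a given seed; results are cached.
    Returns ``(positions, axes, dipole_dirs)`` centred at the origin in
    the horizontal plane.
    """
    key = (n, axis, diameter_m, cap_fraction, seed, relax_tau)
    if key not in _RELAX_CACHE:
        rng = np.random.default_rng(seed)
        units, particle = _make_units_particle(diameter_m, cap_fraction)
        pos, u, muh = _chain_start(n, 0, rng)
        cfg = SimulationConfig(
            positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
            field_program=preset("assemble_oscillation"),
            arena=build_arena("flat"), units=units,
            duration=relax_tau, stride=1000, seed=seed,
        )
        tr = run_simulation(cfg)
        r = tr.positions[-1].copy()
        uu = tr.axes[-1].copy()
        mm = tr.dipole_dirs[-1].copy()
        if axis == 1:  # rotate +90 deg about z so the chain lies along y
            rot = np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]])
            r = r @ rot.T
            uu = uu @ rot.T
            mm = mm @ rot.T
        r[:, :2] -= r[:, :2].mean(axis=0)
        _RELAX_CACHE[key] = (r, uu, mm)
    r, uu, mm = _RELAX_CACHE[key]
    return r.copy(), uu.copy(), mm.copy()


@dataclass(frozen=True)
class Scenario:
    name: str
    builder: Callable[..., SimulationConfig]
    summarise: Callable[[Trajectory, dict], dict]
    description: str = ""


def _summary_common(traj: Trajectory) -> dict:
    end = detect_chains(traj.positions[-1], traj.config.bond_cutoff)
    return {
        "n_particles": traj.n_particles,
        "duration_tau": float(traj.times[-1]),
        "duration_s": float(traj.times[-1] * traj.units.tau),
        "final_n_chains": len(end.chains),
        "final_largest_chain": len(end.largest),
        "assembly_efficiency": assembly_efficiency(end),
        "n_extra_substeps": traj.n_extra_substeps,
        "final_centroid": traj.positions[-1].mean(axis=0).tolist(),
    }


# ---------------------------------------------------------------------------
# builders

def _dimer_assembly(
    seed: int = 0,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    separation: float = 3.0,   # 6 R, reduced
    duration: float = 600.0,
    field: FieldProgram | None = None,
    stride: int = 100,
) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    pos = _line_positions(2, separation, rng, jitter=0.1)
    u, muh = _upright_frames(2, rng)
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * 2,
        field_program=field or preset("assemble_precession"),
        arena=build_arena("flat"), units=units,
        duration=duration, stride=stride, seed=seed,
    )


def _sum_dimer(traj: Trajectory, params: dict) -> dict:
    out = _summary_common(traj)
    part = detect_chains(traj.positions[-1], traj.config.bond_cutoff)
    bonded = len(part.largest) == 2
    out["dimer_formed"] = bool(bonded)
    if bonded:
        mu = traj.dipole_dirs[-1]
        out["dipole_alignment"] = float(np.dot(mu[0], mu[1]))
        sep = traj.positions[-1, 1] - traj.positions[-1, 0]
        out["final_separation"] = float(np.linalg.norm(sep))
        from .analysis import offset_angle

        out["offset_angle_deg"] = offset_angle(
            traj.positions[-1], mu, traj.config.bond_cutoff
        )
    return out


def _chain_assembly(
    seed: int = 0,
    n: int = 8,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    spacing: float = 1.5,
    duration: float = 120.0,
    stride: int = 100,
) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    pos = _line_positions(n, spacing, rng)
    u, muh = _upright_frames(n, rng)
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
        field_program=preset("assemble_oscillation"),
        arena=build_arena("flat"), units=units,
        duration=duration, stride=stride, seed=seed,
    )


def _sum_assembly(traj: Trajectory, params: dict) -> dict:
    return _summary_common(traj)


def _gait(
    gait: str,
    seed: int = 0,
    n: int = 2,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    frequency_hz: float | None = None,
    amplitude_mT: float | None = None,
    n_periods: float = 15.0,
    arena: Arena | None = None,
    axis: int | None = None,
    init: str | None = None,
    stride: int = 100,
) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    overrides = {}
    if frequency_hz is not None:
        overrides["frequency_hz"] = frequency_hz
    if amplitude_mT is not None:
        overrides["amplitude_mT"] = amplitude_mT
    prog = preset(gait, **overrides)
    f = prog.frequency_hz
    # chain axis: along the advance direction (y) for vertical-plane gaits,
    # along x for the horizontal-plane gaits
    ax = axis if axis is not None else (1 if gait in ("walking", "crawling") else 0)
    # Initial state: the vertical-plane gaits are run on the planar
    # (mirror-symmetric) manifold, which the deterministic dynamics
    # preserves exactly and which realises the straight-ahead two-step
    # tumble; the horizontal gaits start from the annealed zigzag chain.
    if init is None:
        init = "straight" if gait in ("walking", "crawling") else "zigzag"
    if init == "straight":
        pos, u, muh = _chain_start(n, ax, rng)
    elif init == "zigzag":
        pos, u, muh = relaxed_chain(n, axis=ax, diameter_m=diameter_m,
                                    cap_fraction=cap_fraction, seed=seed)
    else:
        raise ValueError(f"unknown init {init!r}; expected 'straight' or 'zigzag'")
    duration = n_periods / (f * units.tau)
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
        field_program=prog, arena=arena or build_arena("flat"), units=units,
        duration=duration, stride=stride, seed=seed,
    )


def _sum_gait(direction_axis):
    def inner(traj: Trajectory, params: dict) -> dict:
        out = _summary_common(traj)
        f = traj.config.field_program.frequency_hz
        out["frequency_hz"] = f
        out["mean_speed_mm_s"] = mean_speed(traj, f, axis=direction_axis)
        out["net_displacement"] = (
            traj.positions[-1].mean(axis=0) - traj.positions[0].mean(axis=0)
        ).tolist()
        return out

    return inner


def _stairs(
    seed: int = 0,
    n: int = 8,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    tread: float = 10.0 / 3.0,   # 2 mm for the 0.6 mm robot
    rise: float = 10.0 / 3.0,
    count: int = 3,
    frequency_hz: float = 1.0,
    n_periods: float = 40.0,
    stride: int = 200,
) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    arena = build_arena("stairs", tread=tread, rise=rise, count=count, start=3.0)
    pos, u, muh = relaxed_chain(n, axis=1, diameter_m=diameter_m,
                                cap_fraction=cap_fraction, seed=seed)
    pos[:, 1] -= pos[:, 1].max() + 2.0
    prog = preset("walking", frequency_hz=frequency_hz)
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
        field_program=prog, arena=arena, units=units,
        duration=n_periods / (frequency_hz * units.tau), stride=stride, seed=seed,
    )


def _sum_stairs(traj: Trajectory, params: dict) -> dict:
    out = _summary_common(traj)
    out["max_centroid_z"] = float(traj.centroid()[:, 2].max())
    out["final_centroid_z"] = float(traj.centroid()[-1, 2])
    return out


def _incline(
    seed: int = 0,
    n: int = 4,
    angle_deg: float = 10.0,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    frequency_hz: float = 1.0,
    n_periods: float = 20.0,
    stride: int = 200,
) -> SimulationConfig:
    rng = np.random.default_rng(seed)
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    arena = build_arena("incline", angle_deg=angle_deg, axis="y")
    ang = math.radians(angle_deg)
    # relax on the flat, then rotate the whole state onto the slope (the
    # slope plane passes through the origin, so a rigid rotation suffices)
    pos, u, muh = relaxed_chain(n, axis=1, diameter_m=diameter_m,
                                cap_fraction=cap_fraction, seed=seed)
    rot = np.array([
        [1.0, 0.0, 0.0],
        [0.0, math.cos(ang), -math.sin(ang)],
        [0.0, math.sin(ang), math.cos(ang)],
    ])
    pos = pos @ rot.T
    u = u @ rot.T
    muh = muh @ rot.T
    prog = preset("walking", frequency_hz=frequency_hz)
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
        field_program=prog, arena=arena, units=units,
        duration=n_periods / (frequency_hz * units.tau), stride=stride, seed=seed,
    )


def _sum_incline(traj: Trajectory, params: dict) -> dict:
    out = _summary_common(traj)
    f = traj.config.field_program.frequency_hz
    out["frequency_hz"] = f
    out["mean_speed_mm_s"] = mean_speed(traj, f, axis=None)
    out["climb_z"] = float(traj.centroid()[-1, 2] - traj.centroid()[0, 2])
    return out


def _disassemble_reassemble(
    seed: int = 0,
    n: int = 8,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    f_high_hz: float = 20.0,
    t_high_s: float = 1.5,
    t_gather_s: float = 3.0,
    t_chain_s: float = 4.0,
    box_half: float = 8.0,
    stride: int = 100,
) -> SimulationConfig:
    """Frequency-triggered disassembly and reassembly in a closed chamber.

    Starts from the equilibrium zigzag chain; raising the rotating-field
    frequency to ``f_high_hz`` fragments it within a fraction of a second
    and the debris scatters; the fragments are then gathered by the
    precessing (conical) field and re-chained by the horizontal
    oscillation — the same two programs that assemble chains in the first
    place.  The chamber walls keep the fast-rolling debris within
    interaction range, as in the experimental arena.
    """
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    pos, u, muh = relaxed_chain(n, axis=0, diameter_m=diameter_m,
                                cap_fraction=cap_fraction, seed=seed)
    prog = Schedule(
        (
            (t_high_s, RotatingField(4.0, f_high_hz, "xz", sense=-1)),
            (t_gather_s, preset("assemble_precession")),
            (t_chain_s, preset("assemble_oscillation")),
        )
    )
    arena = build_arena("box", half_extent=box_half, wall_height=4.0)
    duration = (t_high_s + t_gather_s + t_chain_s) / units.tau
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
        field_program=prog, arena=arena, units=units,
        duration=duration, stride=stride, seed=seed,
    )


def _sum_disassemble(traj: Trajectory, params: dict) -> dict:
    out = _summary_common(traj)
    prog: Schedule = traj.config.field_program  # type: ignore[assignment]
    t_end_high_tau = prog.segments[0][0] / traj.units.tau
    out["fragmentation_time_s"] = fragmentation_time(traj, t_from=0.0)
    k_high = min(int(np.searchsorted(traj.times, t_end_high_tau)),
                 traj.n_frames - 1)
    part = detect_chains(traj.positions[k_high], traj.config.bond_cutoff)
    out["efficiency_after_disassembly"] = assembly_efficiency(part)
    out["n_fragments_after_disassembly"] = len(part.chains)
    return out


def _channel_split(
    seed: int = 0,
    n: int = 6,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    clearance: float = 1.6,
    gate_y: float = 6.0,
    t_walk_s: float = 6.0,
    t_split_s: float = 2.0,
    t_pass_s: float = 10.0,
    stride: int = 200,
) -> SimulationConfig:
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    arena = build_arena("gate", clearance=clearance, position=gate_y)
    pos, u, muh = relaxed_chain(n, axis=1, diameter_m=diameter_m,
                                cap_fraction=cap_fraction, seed=seed)
    pos[:, 1] -= pos[:, 1].max() + 3.0
    prog = Schedule(
        (
            (t_walk_s, RotatingField(4.0, 1.0, "yz", sense=-1)),
            (t_split_s, RotatingField(4.0, 20.0, "yz", sense=-1)),
            (t_pass_s, RotatingField(4.0, 1.0, "yz", sense=-1)),
        )
    )
    duration = (t_walk_s + t_split_s + t_pass_s) / units.tau
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
        field_program=prog, arena=arena, units=units,
        duration=duration, stride=stride, seed=seed,
    )


def _sum_channel(traj: Trajectory, params: dict) -> dict:
    out = _summary_common(traj)
    gate_y = params.get("gate_y", 6.0)
    out["n_past_gate"] = int(np.sum(traj.positions[-1, :, 1] > gate_y))
    return out


def _merge_to_climb(
    seed: int = 0,
    fragment_size: int = 2,
    n_fragments: int = 2,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    rise: float = 2.5,
    tread: float = 4.0,
    t_try_s: float = 6.0,
    t_merge_s: float = 3.0,
    t_climb_s: float = 20.0,
    stride: int = 200,
) -> SimulationConfig:
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    n = fragment_size * n_fragments
    arena = build_arena("stairs", tread=tread, rise=rise, count=2, start=3.0)
    # relaxed zigzag fragments separated by a gap along the walk direction
    blocks = []
    y0 = -2.0 - n_fragments * (fragment_size + 2.0)
    for b in range(n_fragments):
        p, u, m = relaxed_chain(fragment_size, axis=1, diameter_m=diameter_m,
                                cap_fraction=cap_fraction, seed=seed + b)
        p[:, 1] += y0 - p[:, 1].min()
        blocks.append((p, u, m))
        y0 += fragment_size * 1.05 + 2.5
    pos = np.vstack([b[0] for b in blocks])
    u = np.vstack([b[1] for b in blocks])
    muh = np.vstack([b[2] for b in blocks])
    prog = Schedule(
        (
            (t_try_s, RotatingField(4.0, 1.0, "yz", sense=-1)),
            (t_merge_s, preset("assemble_oscillation")),
            (t_climb_s, RotatingField(4.0, 1.0, "yz", sense=-1)),
        )
    )
    duration = (t_try_s + t_merge_s + t_climb_s) / units.tau
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
        field_program=prog, arena=arena, units=units,
        duration=duration, stride=stride, seed=seed,
    )


def _sum_merge(traj: Trajectory, params: dict) -> dict:
    out = _summary_common(traj)
    prog: Schedule = traj.config.field_program  # type: ignore[assignment]
    t_merge_end = (prog.segments[0][0] + prog.segments[1][0]) / traj.units.tau
    k = int(np.searchsorted(traj.times, prog.segments[0][0] / traj.units.tau))
    k = min(k, traj.n_frames - 1)
    out["max_z_before_merge"] = float(traj.positions[: k + 1, :, 2].max())
    out["rise"] = params.get("rise", 2.5)
    out["final_max_z"] = float(traj.positions[-1, :, 2].max())
    k2 = int(np.searchsorted(traj.times, t_merge_end))
    k2 = min(k2, traj.n_frames - 1)
    part = detect_chains(traj.positions[k2], traj.config.bond_cutoff)
    out["efficiency_after_merge"] = assembly_efficiency(part)
    return out


def _ring_reversal(
    seed: int = 0,
    n: int = 8,
    cap_fraction: float = DEFAULT_CAP_FRACTION,
    diameter_m: float = 600e-6,
    stride: int = 100,
) -> SimulationConfig:
    units, particle = _make_units_particle(diameter_m, cap_fraction)
    pos, u, muh = relaxed_chain(n, axis=0, diameter_m=diameter_m,
                                cap_fraction=cap_fraction, seed=seed)
    prog = preset("ring_reversal")
    return SimulationConfig(
        positions=pos, axes=u, dipole_dirs=muh, particles=[particle] * n,
        field_program=prog, arena=build_arena("flat"), units=units,
        duration=prog.total_duration / units.tau, stride=stride, seed=seed,
    )


def _sum_ring(traj: Trajectory, params: dict) -> dict:
    out = _summary_common(traj)
    part = detect_chains(traj.positions[-1], traj.config.bond_cutoff)
    chain = part.largest
    ends = np.linalg.norm(
        traj.positions[-1, chain[0]] - traj.positions[-1, chain[-1]]
    )
    out["end_to_end_distance"] = float(ends)
    return out


SCENARIOS: dict[str, Scenario] = {
    "dimer_assembly": Scenario(
        "dimer_assembly", _dimer_assembly, _sum_dimer,
        "two robots under a precessing field approach and dimerise",
    ),
    "chain_assembly_8": Scenario(
        "chain_assembly_8", _chain_assembly, _sum_assembly,
        "eight robots assemble into a single zigzag chain",
    ),
    "walking": Scenario(
        "walking", lambda **kw: _gait("walking", **kw), _sum_gait(1),
        "tumbling walk under a vertical-plane rotating field",
    ),
    "crawling": Scenario(
        "crawling", lambda **kw: _gait("crawling", **kw), _sum_gait(1),
        "bounded vertical oscillation produces a crawl",
    ),
    "swinging": Scenario(
        "swinging", lambda **kw: _gait("swinging", n=4, **kw), _sum_gait(None),
        "full horizontal sweep with a tilted plane; snake-like swing",
    ),
    "lateral": Scenario(
        "lateral", lambda **kw: _gait("lateral", n=4, **kw), _sum_gait(None),
        "pitched horizontal oscillation; sideways translation",
    ),
    "stairs": Scenario(
        "stairs", _stairs, _sum_stairs,
        "chain walks up a staircase",
    ),
    "incline": Scenario(
        "incline", _incline, _sum_incline,
        "chain walks up an inclined floor",
    ),
    "disassemble_reassemble": Scenario(
        "disassemble_reassemble", _disassemble_reassemble, _sum_disassemble,
        "high-frequency rotation fragments the chain; the assembly programs rebuild it",
    ),
    "channel_split": Scenario(
        "channel_split", _channel_split, _sum_channel,
        "chain splits at 20 Hz to pass a low gate",
    ),
    "merge_to_climb": Scenario(
        "merge_to_climb", _merge_to_climb, _sum_merge,
        "fragments merge into a chain long enough to climb a tall riser",
    ),
    "ring_reversal": Scenario(
        "ring_reversal", _ring_reversal, _sum_ring,
        "static-field reversal curls the chain",
    ),
}


def scenario_names() -> list[str]:
    return sorted(SCENARIOS)


def build_scenario(name: str, seed: int = 0, **params) -> SimulationConfig:
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        )
    return SCENARIOS[name].builder(seed=seed, **params)


def run_scenario(
    name: str,
    seed: int = 0,
    outdir: str | Path | None = None,
    **params,
) -> dict:
    """Run a named scenario and return (and optionally write) its summary."""
    if name not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {name!r}; available: {', '.join(scenario_names())}"
        )
    scenario = SCENARIOS[name]
    config = scenario.builder(seed=seed, **params)
    traj = run_simulation(config)
    summary = {
        "scenario": name,
        "seed": seed,
        "params": {k: (v if isinstance(v, (int, float, str, bool)) else str(v))
                   for k, v in params.items()},
        "version": __version__,
        "dt_tau": config.dt,
        "sigma_m": config.units.sigma,
    }
    summary.update(scenario.summarise(traj, params))
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_xyz(traj, outdir / f"{name}.xyz")
        write_metrics_csv(traj, outdir / f"{name}_metrics.csv")
        write_summary_json(summary, outdir / f"{name}_summary.json")
    return summary
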