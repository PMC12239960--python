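"""Programmed external magnetic fields B(t).

All programs are spatially uniform and return the field in mT as a
function of time in seconds.  ``sample`` is vectorised over a time array,
which is how the integrator consumes programs (one sample per timestep).

Variants
--------
static        constant vector
rotating      B0 rotating at frequency f in a coordinate plane
oscillating   B0 swept sinusoidally between two angular bounds about a
              reference axis, optionally with the whole oscillation plane
              tilted by a fixed rotation
conical       B0 precessing on a cone of given half-angle about an axis
schedule      piecewise concatenation of the above

The gait presets encode the actuation protocols: walking (rotating
vertical-plane field), crawling (bounded vertical oscillation), swinging
(full horizontal sweep with a tilted plane), lateral (pitched bounded
horizontal oscillation), plus assembly and disassembly programs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "FieldProgram",
    "StaticField",
    "RotatingField",
    "OscillatingField",
    "ConicalField",
    "Schedule",
    "preset",
    "PRESET_NAMES",
]

_AXES = {
    "x": np.array([1.0, 0.0, 0.0]),
    "y": np.array([0.0, 1.0, 0.0]),
    "z": np.array([0.0, 0.0, 1.0]),
}

_PLANES = {"xy": ("x", "y"), "yz": ("y", "z"), "xz": ("x", "z")}


def _rotation_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation matrix about a unit axis."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + math.sin(angle_rad) * k + (1.0 - math.cos(angle_rad)) * k @ k


def _plane_basis(plane: str) -> tuple[np.ndarray, np.ndarray]:
    try:
        a, b = _PLANES[plane]
    except KeyError:
        raise ValueError(f"unknown plane {plane!r}; expected one of {sorted(_PLANES)}")
    return _AXES[a], _AXES[b]


class FieldProgram:
    """Base class; subclasses implement ``sample``."""

    amplitude_mT: float

    def sample(self, t: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def __call__(self, t: float) -> np.ndarray:
        return self.sample(np.atleast_1d(np.asarray(t, dtype=float)))[0]


def evaluate_field(program: FieldProgram, t) -> np.ndarray:
    """Field vector(s) in mT at time(s) ``t`` (seconds)."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0.0):
        raise ValueError("time must be nonnegative")
    if t.ndim == 0:
        return program(float(t))
    return program.sample(t)


@dataclass(frozen=True)
class StaticField(FieldProgram):
    amplitude_mT: float = 4.0
    direction: tuple[float, float, float] = (1.0, 0.0, 0.0)

    def sample(self, t: np.ndarray) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        return np.broadcast_to(self.amplitude_mT * d, (t.size, 3)).copy()

    def reversed(self) -> "StaticField":
        return StaticField(self.amplitude_mT, tuple(-c for c in self.direction))


@dataclass(frozen=True)
class RotatingField(FieldProgram):
    """B(t) = B0 (e1 cos th + e2 sin th), th = sense * 2 pi f t + phase.

    For ``plane='yz'`` with sense=+1 the field points along +y at t = 0 and
    along +z a quarter period later.
    """

    amplitude_mT: float = 4.0
    frequency_hz: float = 1.0
    plane: str = "yz"
    sense: int = 1
    phase: float = 0.0

    def sample(self, t: np.ndarray) -> np.ndarray:
        e1, e2 = _plane_basis(self.plane)
        th = self.sense * 2.0 * math.pi * self.frequency_hz * t + self.phase
        return self.amplitude_mT * (
            np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2)
        )


@dataclass(frozen=True)
class OscillatingField(FieldProgram):
    """Angle swept sinusoidally between ``bounds`` (radians, measured from
    the first axis of ``plane``): th(t) = mid + half * sin(2 pi f t).

    ``tilt_axis``/``tilt_deg`` apply a fixed rigid rotation to the whole
    oscillation plane after the in-plane sweep (used for the swinging and
    lateral programs, whose oscillation planes are inclined).
    """

    amplitude_mT: float = 6.0
    frequency_hz: float = 3.0
    plane: str = "yz"
    bounds: tuple[float, float] = (-2.0 * math.pi / 3.0, math.pi / 3.0)
    tilt_axis: str | None = None
    tilt_deg: float = 0.0
    pitch_deg: float = 0.0  # fixed rotation about the plane's first axis
    waveform: str = "sin"

    def sample(self, t: np.ndarray) -> np.ndarray:
        e1, e2 = _plane_basis(self.plane)
        lo, hi = self.bounds
        mid, half = 0.5 * (lo + hi), 0.5 * (hi - lo)
        x = self.frequency_hz * t
        if self.waveform == "sin":
            sweep = np.sin(2.0 * math.pi * x)
        elif self.waveform == "triangle":
            sweep = 2.0 * np.abs(2.0 * (x - np.floor(x + 0.5))) - 1.0
        else:
            raise ValueError(f"unknown waveform {self.waveform!r}")
        th = mid + half * sweep
        out = self.amplitude_mT * (
            np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2)
        )
        if self.pitch_deg != 0.0:
            rot = _rotation_matrix(e1, math.radians(self.pitch_deg))
            out = out @ rot.T
        if self.tilt_axis is not None and self.tilt_deg != 0.0:
            rot = _rotation_matrix(_AXES[self.tilt_axis], math.radians(self.tilt_deg))
            out = out @ rot.T
        return out


@dataclass(frozen=True)
class ConicalField(FieldProgram):
    """B0 precessing on a cone of half-angle ``cone_deg`` about ``axis``."""

    amplitude_mT: float = 6.0
    frequency_hz: float = 32.0
    axis: str = "z"
    cone_deg: float = 80.0
    sense: int = 1

    def sample(self, t: np.ndarray) -> np.ndarray:
        a = _AXES[self.axis]
        # orthonormal transverse pair
        e1 = _AXES["x"] if self.axis != "x" else _AXES["y"]
        e1 = e1 - np.dot(e1, a) * a
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(a, e1)
        psi = math.radians(self.cone_deg)
        th = self.sense * 2.0 * math.pi * self.frequency_hz * t
        return self.amplitude_mT * (
            math.cos(psi) * np.outer(np.ones_like(th), a)
            + math.sin(psi) * (np.outer(np.cos(th), e1) + np.outer(np.sin(th), e2))
        )


@dataclass(frozen=True)
class Schedule(FieldProgram):
    """Ordered (duration_s, program) segments; holds the last segment's
    program beyond the end of the schedule."""

    segments: Sequence[tuple[float, FieldProgram]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("schedule needs at least one segment")
        for dur, _ in self.segments:
            if dur <= 0.0:
                raise ValueError("segment durations must be positive")

    @property
    def amplitude_mT(self) -> float:  # type: ignore[override]
        return max(p.amplitude_mT for _, p in self.segments)

    @property
    def total_duration(self) -> float:
        return sum(d for d, _ in self.segments)

    def sample(self, t: np.ndarray) -> np.ndarray:
        out = np.empty((t.size, 3))
        start = 0.0
        edges = []
        for dur, prog in self.segments:
            edges.append((start, start + dur, prog))
            start += dur
        for i, (lo, hi, prog) in enumerate(edges):
            last = i == len(edges) - 1
            mask = (t >= lo) & ((t < hi) | last)
            if np.any(mask):
                # local time within the segment; clock restarts per segment
                out[mask] = prog.sample(t[mask] - lo)
        return out


# ---------------------------------------------------------------------------
# presets

def preset(name: str, **overrides) -> FieldProgram:
    """Named actuation programs with their published parameters.

    walking              4 mT rotating in the yz plane at 1 Hz
    crawling             6 mT oscillating in the yz plane, 3 Hz, angular
                         bounds (-2pi/3, +pi/3) about y
    swinging             6 mT oscillating in the xy plane, 2 Hz, bounds
                         (-pi, pi) about x, plane tilted -30 deg about y
    lateral              6 mT oscillating in the xy plane, 3 Hz, bounds
                         (-pi/3, pi/3), 6 deg pitch, axis inclined -30 deg
    assemble_oscillation 8 mT horizontal oscillation at 60 Hz
    assemble_precession  6 mT conical precession, 32 Hz, 80 deg half-angle
    disassemble_20Hz     rotating field switched to 20 Hz
    ring_reversal        static horizontal field reversed after 2 s
    """
    makers = {
        "walking": lambda: RotatingField(4.0, 1.0, "yz", sense=-1),
        "crawling": lambda: OscillatingField(
            6.0, 3.0, "yz", (-2.0 * math.pi / 3.0, math.pi / 3.0)
        ),
        "swinging": lambda: OscillatingField(
            6.0, 2.0, "xy", (-math.pi, math.pi), tilt_axis="y", tilt_deg=-30.0
        ),
        "lateral": lambda: OscillatingField(
            6.0, 3.0, "xy", (-math.pi / 3.0, math.pi / 3.0),
            tilt_axis="y", tilt_deg=-30.0, pitch_deg=6.0,
        ),
        "assemble_oscillation": lambda: OscillatingField(
            8.0, 60.0, "xy", (-math.pi / 3.0, math.pi / 3.0)
        ),
        "assemble_precession": lambda: ConicalField(6.0, 32.0, "z", 80.0),
        "disassemble_20Hz": lambda: RotatingField(4.0, 20.0, "yz", sense=-1),
        "ring_reversal": lambda: Schedule(
            (
                (2.0, StaticField(4.0, (1.0, 0.0, 0.0))),
                (2.0, StaticField(4.0, (-1.0, 0.0, 0.0))),
            )
        ),
    }
    if name not in makers:
        raise ValueError(
            f"unknown preset {name!r}; available: {', '.join(sorted(makers))}"
        )
    prog = makers[name]()
    if overrides:
        prog = dataclass_replace(prog, **overrides)
    return prog


def dataclass_replace(prog: FieldProgram, **overrides) -> FieldProgram:
    from dataclasses import replace

    return replace(prog, **overrides)


PRESET_NAMES = (
    "walking",
    "crawling",
    "swinging",
    "lateral",
    "assemble_oscillation",
    "assemble_precession",
    "disassemble_20Hz",
    "ring_reversal",
)
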