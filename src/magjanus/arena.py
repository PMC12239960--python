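"""Arena geometry: planar walls and particle-wall contact queries.

All lengths are in reduced units (particle diameters).  A wall is a
(possibly unbounded) rectangle given by its centre, two orthonormal
in-plane axes and half-extents.  Contacts are resolved against the closest
point of the rectangle, so edges and corners produce closest-feature
normals automatically; faces act from both sides.

Builders cover the scenario geometries: a flat floor, inclined floors,
stairs, channels, railings, column arrays and prism-approximated
cylinders.  The coordinate convention is z up, gravity along -z, the base
floor at z = 0, and stairs/inclines ascending along +y (the walking
direction of the vertical-plane rotating field).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np

__all__ = ["Wall", "WallContact", "Arena", "build_arena", "nearest_contacts"]

#: default Coulomb friction coefficients for chain-arranged particles
LAMBDA_STATIC = 0.5
LAMBDA_DYNAMIC = 0.4

#: half-extent used to represent unbounded walls
INFINITE = 1e9


@dataclass(frozen=True)
class Wall:
    """Rectangular wall: centre c, orthonormal in-plane axes e1/e2 and
    half-extents a1/a2 (``INFINITE`` for unbounded directions)."""

    center: tuple[float, float, float]
    e1: tuple[float, float, float]
    e2: tuple[float, float, float]
    a1: float = INFINITE
    a2: float = INFINITE
    lambda_static: float = LAMBDA_STATIC
    lambda_dynamic: float = LAMBDA_DYNAMIC

    def __post_init__(self) -> None:
        e1 = np.asarray(self.e1, dtype=float)
        e2 = np.asarray(self.e2, dtype=float)
        if abs(np.linalg.norm(e1) - 1.0) > 1e-9 or abs(np.linalg.norm(e2) - 1.0) > 1e-9:
            raise ValueError("wall axes must be unit vectors")
        if abs(float(np.dot(e1, e2))) > 1e-9:
            raise ValueError("wall axes must be orthogonal")
        if self.a1 <= 0.0 or self.a2 <= 0.0:
            raise ValueError("wall half-extents must be positive")

    @property
    def normal(self) -> np.ndarray:
        return np.cross(np.asarray(self.e1, float), np.asarray(self.e2, float))

    def closest_point(self, x: np.ndarray) -> np.ndarray:
        c = np.asarray(self.center, float)
        e1 = np.asarray(self.e1, float)
        e2 = np.asarray(self.e2, float)
        d = x - c
        t1 = float(np.clip(np.dot(d, e1), -self.a1, self.a1))
        t2 = float(np.clip(np.dot(d, e2), -self.a2, self.a2))
        return c + t1 * e1 + t2 * e2


@dataclass(frozen=True)
class WallContact:
    """One particle-wall contact candidate."""

    wall_index: int
    normal: np.ndarray      # unit vector from closest wall point to centre
    gap: float              # surface gap: |x - closest| - R
    distance: float         # |x - closest|
    closest: np.ndarray


@dataclass(frozen=True)
class Arena:
    walls: tuple[Wall, ...]
    descriptor: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not any(w.normal[2] > 0.1 or w.normal[2] < -0.1 for w in self.walls):
            raise ValueError("arena must contain at least one floor-like wall")

    def to_arrays(self):
        """Packed arrays for the integration kernel."""
        n = len(self.walls)
        c = np.empty((n, 3))
        e1 = np.empty((n, 3))
        e2 = np.empty((n, 3))
        a = np.empty((n, 2))
        lam = np.empty((n, 2))
        for i, w in enumerate(self.walls):
            c[i] = w.center
            e1[i] = w.e1
            e2[i] = w.e2
            a[i] = (w.a1, w.a2)
            lam[i] = (w.lambda_static, w.lambda_dynamic)
        return c, e1, e2, a, lam


def nearest_contacts(
    x: np.ndarray, radius: float, arena: Arena, margin: float = 0.2
) -> list[WallContact]:
    """Contacts of a particle centre ``x`` with all walls whose closest
    point lies within ``radius * (1 + margin)``.

    The contact normal is the unit vector from the closest wall point to
    the particle centre, which equals the face normal for face contacts
    and the closest-feature direction at edges and corners.
    """
    x = np.asarray(x, dtype=float)
    out: list[WallContact] = []
    for i, w in enumerate(arena.walls):
        cp = w.closest_point(x)
        v = x - cp
        dist = float(np.linalg.norm(v))
        if dist > radius * (1.0 + margin):
            continue
        if dist < 1e-12:
            raise ValueError(f"particle centre lies exactly on wall {i}")
        out.append(WallContact(i, v / dist, dist - radius, dist, cp))
    return out


# ---------------------------------------------------------------------------
# builders

def _floor(z: float = 0.0, **lam) -> Wall:
    return Wall((0.0, 0.0, z), (1.0, 0.0, 0.0), (0.0, 1.0, 0.0), **lam)


def _box_walls(
    center_xy: tuple[float, float],
    size_xy: tuple[float, float],
    height: float,
    **lam,
) -> list[Wall]:
    """Side and top faces of an axis-aligned box sitting on the floor."""
    cx, cy = center_xy
    sx, sy = size_xy
    hz = height / 2.0
    walls = [
        # top
        Wall((cx, cy, height), (1, 0, 0), (0, 1, 0), sx / 2, sy / 2, **lam),
        # +/- x sides (e1 along y, e2 along z -> normal +/- x)
        Wall((cx + sx / 2, cy, hz), (0, 1, 0), (0, 0, 1), sy / 2, hz, **lam),
        Wall((cx - sx / 2, cy, hz), (0, 1, 0), (0, 0, 1), sy / 2, hz, **lam),
        # +/- y sides
        Wall((cx, cy + sy / 2, hz), (1, 0, 0), (0, 0, 1), sx / 2, hz, **lam),
        Wall((cx, cy - sy / 2, hz), (1, 0, 0), (0, 0, 1), sx / 2, hz, **lam),
    ]
    return walls


def build_arena(kind: str, **kw) -> Arena:
    """Construct a named arena.  All lengths in particle diameters.

    kind='flat'                infinite floor at z = 0
    kind='incline'             angle_deg, rising along +y (axis='y') or +x
    kind='stairs'              tread, rise, count, start (first riser y)
    kind='channel'             width, wall_height, length (axis +y), floor
    kind='railing'             height, position (y of the barrier)
    kind='columns'             height, spacing, count, size (square columns)
    kind='cylinder'            radius, height, nfaces (prism approximation)
    """
    lam = {
        "lambda_static": kw.pop("lambda_static", LAMBDA_STATIC),
        "lambda_dynamic": kw.pop("lambda_dynamic", LAMBDA_DYNAMIC),
    }
    walls: list[Wall]
    if kind == "flat":
        walls = [_floor(**lam)]
    elif kind == "incline":
        ang = math.radians(kw.pop("angle_deg"))
        axis = kw.pop("axis", "y")
        if axis == "y":
            e1 = (1.0, 0.0, 0.0)
            e2 = (0.0, math.cos(ang), math.sin(ang))
        elif axis == "x":
            e1 = (math.cos(ang), 0.0, math.sin(ang))
            e2 = (0.0, 1.0, 0.0)
        else:
            raise ValueError("incline axis must be 'x' or 'y'")
        walls = [Wall((0.0, 0.0, 0.0), e1, e2, **lam)]
    elif kind == "stairs":
        tread = kw.pop("tread")
        rise = kw.pop("rise")
        count = int(kw.pop("count"))
        start = kw.pop("start", 0.0)
        if tread <= 0 or rise <= 0 or count < 1:
            raise ValueError("stairs need positive tread/rise and count >= 1")
        walls = [
            # approach floor: centred far on -y so it ends at y = start
            Wall((0.0, start - INFINITE / 2, 0.0), (1, 0, 0), (0, 1, 0),
                 INFINITE, INFINITE / 2, **lam)
        ]
        for k in range(1, count + 1):
            y0 = start + (k - 1) * tread
            zk = k * rise
            # riser at y0 spanning z in [zk - rise, zk]
            walls.append(
                Wall((0.0, y0, zk - rise / 2), (1, 0, 0), (0, 0, 1),
                     INFINITE, rise / 2, **lam)
            )
            if k < count:
                walls.append(
                    Wall((0.0, y0 + tread / 2, zk), (1, 0, 0), (0, 1, 0),
                         INFINITE, tread / 2, **lam)
                )
        # top platform after the last riser
        y_top = start + (count - 1) * tread
        walls.append(
            Wall((0.0, y_top + INFINITE / 2, count * rise), (1, 0, 0),
                 (0, 1, 0), INFINITE, INFINITE / 2, **lam)
        )
    elif kind == "channel":
        width = kw.pop("width")
        height = kw.pop("wall_height")
        length = kw.pop("length", 20.0)
        if width <= 0 or height <= 0 or length <= 0:
            raise ValueError("channel needs positive width/wall_height/length")
        walls = [
            _floor(**lam),
            Wall((-width / 2, 0.0, height / 2), (0, 1, 0), (0, 0, 1),
                 length / 2, height / 2, **lam),
            Wall((width / 2, 0.0, height / 2), (0, 1, 0), (0, 0, 1),
                 length / 2, height / 2, **lam),
        ]
    elif kind == "box":
        # closed chamber: floor plus four side walls
        half = kw.pop("half_extent")
        height = kw.pop("wall_height", 5.0)
        if half <= 0 or height <= 0:
            raise ValueError("box needs positive half_extent/wall_height")
        hz = height / 2.0
        walls = [
            _floor(**lam),
            Wall((half, 0.0, hz), (0, 1, 0), (0, 0, 1), half, hz, **lam),
            Wall((-half, 0.0, hz), (0, 1, 0), (0, 0, 1), half, hz, **lam),
            Wall((0.0, half, hz), (1, 0, 0), (0, 0, 1), half, hz, **lam),
            Wall((0.0, -half, hz), (1, 0, 0), (0, 0, 1), half, hz, **lam),
        ]
    elif kind == "gate":
        # barrier with clearance underneath: passable only by bodies whose
        # tumbling envelope stays below ``clearance``
        clearance = kw.pop("clearance")
        height = kw.pop("height", 10.0)
        pos = kw.pop("position", 0.0)
        if clearance <= 0 or height <= 0:
            raise ValueError("gate needs positive clearance/height")
        walls = [
            _floor(**lam),
            Wall((0.0, pos, clearance + height / 2), (1, 0, 0), (0, 0, 1),
                 INFINITE, height / 2, **lam),
        ]
    elif kind == "railing":
        height = kw.pop("height")
        pos = kw.pop("position", 0.0)
        if height <= 0:
            raise ValueError("railing height must be positive")
        walls = [
            _floor(**lam),
            Wall((0.0, pos, height / 2), (1, 0, 0), (0, 0, 1),
                 INFINITE, height / 2, **lam),
        ]
    elif kind == "columns":
        height = kw.pop("height")
        spacing = kw.pop("spacing")
        count = int(kw.pop("count", 3))
        size = kw.pop("size", 1.0)
        if height <= 0 or spacing <= 0 or size <= 0:
            raise ValueError("columns need positive height/spacing/size")
        walls = [_floor(**lam)]
        x0 = -(count - 1) * spacing / 2.0
        for k in range(count):
            walls += _box_walls((x0 + k * spacing, 0.0), (size, size), height, **lam)
    elif kind == "cylinder":
        radius = kw.pop("radius")
        height = kw.pop("height")
        nfaces = int(kw.pop("nfaces", 24))
        if radius <= 0 or height <= 0 or nfaces < 3:
            raise ValueError("cylinder needs positive radius/height, nfaces >= 3")
        walls = [_floor(**lam)]
        apothem = radius * math.cos(math.pi / nfaces)
        half_edge = radius * math.sin(math.pi / nfaces)
        for k in range(nfaces):
            th = 2.0 * math.pi * k / nfaces
            nx, ny = math.cos(th), math.sin(th)
            walls.append(
                Wall(
                    (apothem * nx, apothem * ny, height / 2),
                    (-ny, nx, 0.0), (0.0, 0.0, 1.0),
                    half_edge, height / 2, **lam,
                )
            )
        walls.append(
            Wall((0.0, 0.0, height), (1, 0, 0), (0, 1, 0), radius, radius, **lam)
        )
    else:
        raise ValueError(f"unknown arena kind {kind!r}")
    if kw:
        raise ValueError(f"unused arena parameters: {sorted(kw)}")
    return Arena(tuple(walls), descriptor={"kind": kind})
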