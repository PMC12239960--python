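"""Trajectory, metrics and configuration I/O.

Trajectories are written as extended XYZ: one block per frame, a comment
line carrying the time, the instantaneous field and the column layout, and
one row per particle with position, symmetry axis and dipole direction
(all reduced units).  Metrics go to tidy CSV (one row per frame), run
summaries to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import assembly_efficiency, detect_chains
from .dynamics import Trajectory

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_metrics_csv",
    "write_summary_json",
    "read_config",
    "ConfigError",
]

_FMT = "%.12g"


def write_xyz(traj: Trajectory, path: str | Path) -> Path:
    """Write an extended-XYZ trajectory (reduced units)."""
    path = Path(path)
    with path.open("w") as fh:
        for k in range(traj.n_frames):
            fh.write(f"{traj.n_particles}\n")
            b = traj.field_mT[k]
            fh.write(
                'Properties=species:S:1:pos:R:3:axis:R:3:dipole:R:3 '
                f'Time={traj.times[k]:.12g} '
                f'Field_mT="{b[0]:.12g} {b[1]:.12g} {b[2]:.12g}"\n'
            )
            for i in range(traj.n_particles):
                row = np.concatenate(
                    [
                        traj.positions[k, i],
                        traj.axes[k, i],
                        traj.dipole_dirs[k, i],
                    ]
                )
                fh.write("MJ " + " ".join(_FMT % v for v in row) + "\n")
    return path


def read_xyz(path: str | Path):
    """Read an extended-XYZ trajectory written by :func:`write_xyz`.

    Returns ``(times, positions, axes, dipole_dirs, field_mT)`` arrays.
    """
    path = Path(path)
    times, fields, frames_r, frames_u, frames_m = [], [], [], [], []
    with path.open() as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            t = 0.0
            b = (0.0, 0.0, 0.0)
            for token in comment.split(" "):
                if token.startswith("Time="):
                    t = float(token[5:])
            if 'Field_mT="' in comment:
                raw = comment.split('Field_mT="', 1)[1].split('"', 1)[0]
                b = tuple(float(x) for x in raw.split())
            r = np.empty((n, 3))
            u = np.empty((n, 3))
            m = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                vals = [float(x) for x in parts[1:10]]
                r[i] = vals[0:3]
                u[i] = vals[3:6]
                m[i] = vals[6:9]
            times.append(t)
            fields.append(b)
            frames_r.append(r)
            frames_u.append(u)
            frames_m.append(m)
    return (
        np.array(times),
        np.array(frames_r),
        np.array(frames_u),
        np.array(frames_m),
        np.array(fields),
    )


def write_metrics_csv(traj: Trajectory, path: str | Path) -> Path:
    """Per-frame metrics: time, centroid, chain statistics, field."""
    path = Path(path)
    rows = []
    for k in range(traj.n_frames):
        part = detect_chains(traj.positions[k], traj.config.bond_cutoff)
        c = traj.positions[k].mean(axis=0)
        b = traj.field_mT[k]
        rows.append(
            {
                "time_tau": traj.times[k],
                "time_s": traj.times[k] * traj.units.tau,
                "centroid_x": c[0],
                "centroid_y": c[1],
                "centroid_z": c[2],
                "n_chains": len(part.chains),
                "largest_chain": len(part.largest),
                "assembly_efficiency": assembly_efficiency(part),
                "field_x_mT": b[0],
                "field_y_mT": b[1],
                "field_z_mT": b[2],
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
    return path


def write_summary_json(summary: dict, path: str | Path) -> Path:
    path = Path(path)
    with path.open("w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
    return path


class ConfigError(ValueError):
    """Configuration file violates the schema; message names the key."""


def read_config(path: str | Path) -> dict:
    """Read and validate a scenario configuration (YAML or JSON).

    Schema: ``scenario`` (required, str), ``seed`` (optional, int),
    ``params`` (optional, mapping of scenario parameters).  Unknown
    top-level keys are rejected by name.
    """
    path = Path(path)
    with path.open() as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    allowed = {"scenario", "seed", "params"}
    for key in data:
        if key not in allowed:
            raise ConfigError(f"{path}: unknown key {key!r}; allowed: {sorted(allowed)}")
    if "scenario" not in data:
        raise ConfigError(f"{path}: missing required key 'scenario'")
    if not isinstance(data["scenario"], str):
        raise ConfigError(f"{path}: key 'scenario' must be a string")
    if "seed" in data and not isinstance(data["seed"], int):
        raise ConfigError(f"{path}: key 'seed' must be an integer")
    if "params" in data and not isinstance(data["params"], dict):
        raise ConfigError(f"{path}: key 'params' must be a mapping")
    data.setdefault("seed", 0)
    data.setdefault("params", {})
    return data
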