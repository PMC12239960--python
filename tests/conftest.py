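"""Shared fixtures: cached scenario runs reused across test modules.

The heavier simulations are session-scoped so that topical tests and the
acceptance suite share a single run of each scenario.
"""

from __future__ import annotations

import pytest

from magjanus.scenarios import run_scenario
from magjanus.units import UnitSystem, default_reduced_particle


@pytest.fixture(scope="session")
def default_units() -> UnitSystem:
    return UnitSystem()


@pytest.fixture(scope="session")
def default_particle():
    particle, _ = default_reduced_particle()
    return particle


@pytest.fixture(scope="session")
def walking_speed_curve():
    """Mean walking speed (mm/s) vs field frequency for dimer and tetramer."""
    out = {}
    for n in (2, 4):
        for f in (0.5, 1.0, 2.0):
            s = run_scenario("walking", seed=1, n=n, frequency_hz=f, n_periods=10.0)
            out[(n, f)] = s["mean_speed_mm_s"]
    return out


@pytest.fixture(scope="session")
def sprint_dimer_summary():
    """Half-millimetre dimer walking at 10 Hz (the fastest published gait)."""
    return run_scenario(
        "walking", seed=1, diameter_m=500e-6, frequency_hz=10.0, n_periods=22.0
    )


@pytest.fixture(scope="session")
def crawling_speed_curve():
    out = {}
    for f in (1.0, 3.0, 6.0):
        s = run_scenario("crawling", seed=1, n=2, frequency_hz=f, n_periods=12.0)
        out[f] = s["mean_speed_mm_s"]
    return out


@pytest.fixture(scope="session")
def swinging_speed_curve():
    out = {}
    for f in (32.0, 128.0, 512.0):
        s = run_scenario("swinging", seed=1, frequency_hz=f, n_periods=16.0)
        out[f] = s["mean_speed_mm_s"]
    return out


@pytest.fixture(scope="session")
def dimer_sweep():
    """Dimerisation outcome vs cap fraction under the precessing field."""
    out = {}
    for h in (0.05, 0.2, 0.32, 0.5, 0.95):
        out[h] = run_scenario("dimer_assembly", seed=1, cap_fraction=h, duration=600.0)
    return out


@pytest.fixture(scope="session")
def assembly8_summary():
    return run_scenario("chain_assembly_8", seed=1)


@pytest.fixture(scope="session")
def disassembly_summary():
    return run_scenario("disassemble_reassemble", seed=1)


@pytest.fixture(scope="session")
def stairs_summary():
    return run_scenario("stairs", seed=1, n_periods=20.0)


@pytest.fixture(scope="session")
def merge_summary():
    return run_scenario("merge_to_climb", seed=1)
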