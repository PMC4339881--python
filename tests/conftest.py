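"""Shared fixtures: synthetic traces and staircases built on the fly."""

from __future__ import annotations

import numpy as np
import pytest

from tweezerlab import BeadTrace, TrapParameters


def force_trace(force: np.ndarray, stiffness: float = 0.01, fs: float = 3000.0) -> BeadTrace:
    """Build a fixed-trap BeadTrace realizing the given force profile."""
    force = np.asarray(force, dtype=float)
    time = np.arange(len(force)) / fs
    bead = force / stiffness
    trap = np.zeros_like(bead)
    return BeadTrace(
        time=time,
        bead_position=bead,
        trap_position=trap,
        force=force,
        stiffness=stiffness,
        metadata={"trap": {"mode": "fixed", "stiffness": stiffness}},
    )


def staircase(
    step_times_s,
    sizes_nm,
    duration_s: float,
    fs: float = 3000.0,
    noise_nm: float = 0.0,
    seed: int = 0,
):
    """Piecewise-constant position trace with steps at the given times."""
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)
    for ti, si in zip(step_times_s, sizes_nm):
        y[t >= ti] += si
    if noise_nm > 0:
        y = y + np.random.default_rng(seed).normal(0.0, noise_nm, n)
    return t, y


def exponential_staircase(
    rate_per_s: float,
    duration_s: float,
    step_nm: float = 8.2,
    backstep_fraction: float = 0.05,
    fs: float = 3000.0,
    noise_nm: float = 1.3,
    seed: int = 0,
):
    """Motor-like staircase with exponential dwells; returns (t, y, times, dirs)."""
    rng = np.random.default_rng(seed)
    dwells = rng.exponential(1.0 / rate_per_s, int(rate_per_s * duration_s * 3) + 50)
    times = np.cumsum(dwells)
    times = times[times < duration_s]
    dirs = np.where(rng.random(len(times)) < backstep_fraction, -1.0, 1.0)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    y = np.zeros(n)
    for ti, di in zip(times, dirs):
        y[t >= ti] += di * step_nm
    if noise_nm > 0:
        y = y + rng.normal(0.0, noise_nm, n)
    return t, y, times, dirs


@pytest.fixture(scope="session")
def dct_fixed_trace():
    """One MD-dCT-like fixed-trap recording (session-cached: simulation is
    the expensive part of these tests)."""
    from tweezerlab import preset, simulate_fixed_trap

    return simulate_fixed_trap(
        preset("md-dct"), TrapParameters(stiffness=0.05), 1000.0, 30.0, seed=11
    )


@pytest.fixture(scope="session")
def dct_clamp_trace():
    """One MD-dCT-like force-clamp recording at 2 pN."""
    from tweezerlab import preset, simulate_force_clamp

    trap = TrapParameters(stiffness=0.05, mode="force_clamp", clamp_setpoint=2.0)
    return simulate_force_clamp(preset("md-dct"), trap, 1000.0, 15.0, seed=21)
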