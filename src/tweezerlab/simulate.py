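"""Stochastic bead–trap–motor simulator.

Generates synthetic optical-trap recordings (fixed-trap and force-clamp
modes) and bead-count motility assays with the statistical structure assumed
by the downstream analyses: a motor stepping in ~8-nm increments with a
force-dependent rate, occasional backward steps and stochastic detachment,
an optically trapped bead obeying overdamped Langevin dynamics, and an
optional proportional-gain force clamp.

Model
-----
The motor position ``m(t)`` on the microtubule is a continuous-time jump
process: stepping attempts occur at a force- and ATP-dependent rate, each
attempt advances the motor by ``+d`` (forward) or ``-d`` (backward), and a
competing detachment hazard ends the engagement.  The bead position ``x(t)``
relaxes toward the motor-imposed equilibrium with the trap (and, optionally,
a series linkage) stiffness under thermal noise:

    gamma dx = -k_tot (x - x_eq(t)) dt + sqrt(2 kBT gamma) dW

where ``x_eq = m`` for a rigid linkage or the stiffness-weighted average of
motor and trap positions for a compliant one.  Because the dynamics are
linear, the trajectory is the superposition of the deterministic relaxation
toward ``x_eq`` and a stationary Ornstein–Uhlenbeck fluctuation; both are
integrated with the exact AR(1) update on a fine grid (``oversample`` times
the output rate), then anti-alias filtered (4th-order Butterworth,
forward–backward) and decimated to the recording rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .processivity import MotileFractionSeries

__all__ = [
    "KBT_ROOM",
    "TrapParameters",
    "MotorModel",
    "BeadTrace",
    "preset",
    "PRESETS",
    "simulate_fixed_trap",
    "simulate_force_clamp",
    "generate_motile_assay",
]

#: Thermal energy at 25 degC, pN nm.
KBT_ROOM = 4.114

#: Water viscosity at 25 degC, pN s nm^-2 (0.89 mPa s).
ETA_WATER = 0.89e-9


def _default_drag(bead_radius_nm: float) -> float:
    """Stokes drag 6*pi*eta*r for a sphere in water, pN s nm^-1."""
    return 6.0 * math.pi * ETA_WATER * bead_radius_nm


class SimulationError(ValueError):
    """Raised for invalid or numerically unsafe simulation settings."""


@dataclass
class TrapParameters:
    """Optical-trap and acquisition settings.

    Parameters
    ----------
    stiffness : float
        Trap spring constant ``k``, pN/nm.
    sample_rate : float
        Output sampling rate, Hz (recordings are acquired at 3 kHz).
    filter_cutoff : float
        Anti-alias low-pass cutoff, Hz (1.5 kHz for 3 kHz acquisition).
    mode : {"fixed", "force_clamp"}
    clamp_setpoint : float
        Force set-point of the clamp, pN.
    clamp_gain : float
        Dimensionless proportional gain of the feedback loop.
    clamp_rate : float
        Feedback update frequency, Hz (instrument range 50–600 Hz).
    clamp_range : float
        Trap travel limit of clamp operation, nm; beyond it the trap
        freezes and behaviour reverts to a fixed trap.
    oversample : int
        Internal integration grid, multiples of ``sample_rate``.
    """

    stiffness: float
    sample_rate: float = 3000.0
    filter_cutoff: float = 1500.0
    mode: str = "fixed"
    clamp_setpoint: float = 0.0
    clamp_gain: float = 1.0
    clamp_rate: float = 300.0
    clamp_range: float = 400.0
    oversample: int = 32

    def __post_init__(self) -> None:
        if self.stiffness <= 0:
            raise SimulationError("trap stiffness must be positive")
        if self.filter_cutoff > self.sample_rate / 2:
            raise SimulationError("filter_cutoff must be <= sample_rate/2 (Nyquist)")
        if self.mode not in ("fixed", "force_clamp"):
            raise SimulationError(f"unknown trap mode {self.mode!r}")
        if self.clamp_setpoint < 0:
            raise SimulationError("clamp_setpoint must be >= 0")
        if self.clamp_rate <= 0:
            raise SimulationError("clamp_rate must be positive")
        if self.oversample < 1:
            raise SimulationError("oversample must be >= 1")


@dataclass
class MotorModel:
    """Phenomenological single-motor stepping model.

    ``unloaded_velocity`` is the net unloaded velocity (nm/s); with backward
    steps present the total stepping-attempt rate at zero load is therefore
    ``v0 / (d * (1 - 2*backstep_fraction))`` so that the force–velocity
    intercept equals ``v0``.

    ``detach_rate_per_dwell`` is the probability that any given dwell ends in
    detachment rather than a step (exact at low load).  Because the stepping
    rate vanishes at stall, a basal detachment hazard ``stall_detach_rate``
    (s^-1) acts as a floor so that stalls terminate in detachment after
    roughly a second, as observed.

    ``stall_force_sd`` models encounter-to-encounter variability of the
    attainable stall force (attachment geometry, motor heterogeneity): a new
    stall force is drawn per engagement from a truncated normal.

    ``linkage_stiffness`` (pN/nm) optionally places a series elastic element
    between bead and motor; ``None`` means a rigid link (the bead relaxes
    toward the motor position with the trap stiffness alone).
    """

    step_size: float = 8.2
    backstep_fraction: float = 0.05
    unloaded_velocity: float = 672.0
    stall_force: float = 5.65
    stepping_kernel: str = "linear_fv"
    atp_kcat: Optional[float] = None
    atp_km: float = 30.0
    detach_rate_per_dwell: float = 0.01
    rebind_rate: float = 2.0
    bead_radius: float = 500.0
    drag: Optional[float] = None
    kBT: float = KBT_ROOM
    linkage_stiffness: Optional[float] = None
    stall_force_sd: float = 0.0
    stall_detach_rate: float = 1.0
    preset_name: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.backstep_fraction < 0.5):
            raise SimulationError("backstep_fraction must be in [0, 0.5)")
        if self.stall_force <= 0:
            raise SimulationError("stall_force must be positive")
        if not (0 <= self.detach_rate_per_dwell <= 1):
            raise SimulationError("detach_rate_per_dwell must be in [0, 1]")
        if self.stepping_kernel not in ("linear_fv", "boltzmann"):
            raise SimulationError(f"unknown stepping kernel {self.stepping_kernel!r}")
        if self.drag is None:
            self.drag = _default_drag(self.bead_radius)

    @property
    def max_attempt_rate(self) -> float:
        """Stepping-attempt rate at saturating ATP and zero load (s^-1):
        ``atp_kcat`` if set, else derived from the net unloaded velocity."""
        if self.atp_kcat is not None:
            return self.atp_kcat
        denom = self.step_size * (1.0 - 2.0 * self.backstep_fraction)
        return self.unloaded_velocity / denom

    # -- stepping kernel ---------------------------------------------------
    def attempt_rate(self, force: float, atp: float, stall_force: Optional[float] = None):
        """Total stepping-attempt rate (s^-1) and backward probability at
        the given load (pN) and ATP (uM)."""
        fs = self.stall_force if stall_force is None else stall_force
        sat = atp / (self.atp_km + atp) if np.isfinite(atp) else 1.0
        if self.stepping_kernel == "linear_fv":
            r = self.max_attempt_rate * sat * max(0.0, 1.0 - force / fs)
            if r < 0:
                raise SimulationError("stepping kernel returned a negative rate")
            return r, self.backstep_fraction
        # boltzmann: forward rate decays exponentially with load; constant
        # backward rate chosen so forward and backward balance at stall.
        b = max(self.backstep_fraction, 1e-6)
        delta = self.kBT * math.log(1.0 / b) / fs
        k0 = self.max_attempt_rate * sat
        rf = k0 * math.exp(-force * delta / self.kBT)
        rb = b * k0
        return rf + rb, rb / (rf + rb)


PRESETS = {
    # Wild-type-like motor-domain dimer: ~1 pN stall, short (~90 nm) runs at
    # k = 0.01 pN/nm, frequent premature detachment.
    "md-wt": MotorModel(
        step_size=8.2,
        backstep_fraction=0.05,
        unloaded_velocity=600.0,
        stall_force=1.0,
        detach_rate_per_dwell=0.05,
        rebind_rate=2.0,
        linkage_stiffness=0.3,
        stall_force_sd=0.35,
        stall_detach_rate=4.5,
        preset_name="md-wt",
    ),
    # CT-cap-deleted-like motor: ~5.65 pN stall (672/119 from the linear F-V
    # relation), rare premature detachment, tenacious ~1 s stalls.
    "md-dct": MotorModel(
        step_size=8.2,
        backstep_fraction=0.05,
        unloaded_velocity=672.0,
        stall_force=5.65,
        detach_rate_per_dwell=0.01,
        rebind_rate=2.0,
        linkage_stiffness=0.3,
        stall_force_sd=1.0,
        stall_detach_rate=1.0,
        preset_name="md-dct",
    ),
}


def preset(name: str) -> MotorModel:
    """Return a fresh copy of a named motor preset ("md-wt" or "md-dct")."""
    key = name.lower().replace("_", "-")
    if key not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    return replace(PRESETS[key])


@dataclass
class BeadTrace:
    """A uniformly sampled trap recording.

    Arrays are aligned: ``time`` (s, uniform grid), ``bead_position`` and
    ``trap_position`` (nm), ``force`` (pN, ``stiffness * (bead - trap)``,
    signed so that positive force opposes motor motion).
    """

    time: np.ndarray
    bead_position: np.ndarray
    trap_position: np.ndarray
    force: np.ndarray
    stiffness: float
    metadata: dict = field(default_factory=dict)
    raw: Optional[dict] = None

    def __post_init__(self) -> None:
        n = len(self.time)
        for name in ("bead_position", "trap_position", "force"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} length mismatch")

    @property
    def sample_rate(self) -> float:
        return 1.0 / float(self.time[1] - self.time[0])

    def __len__(self) -> int:
        return len(self.time)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "bead_nm": self.bead_position,
                "trap_nm": self.trap_position,
                "force_pN": self.force,
            }
        )

    def validate(self, rtol: float = 1e-6) -> None:
        dt = np.diff(self.time)
        if len(dt) and not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("non-uniform time grid")
        if np.any(dt <= 0):
            raise ValueError("time must be strictly increasing")
        recomputed = self.stiffness * (self.bead_position - self.trap_position)
        if np.max(np.abs(recomputed - self.force), initial=0.0) > max(rtol, 1e-6):
            raise ValueError("force column inconsistent with stiffness * displacement")


# ---------------------------------------------------------------------------
# event-driven engine
# ---------------------------------------------------------------------------

_WAITING, _ENGAGED, _FROZEN = 0, 1, 2


def _draw_stall_force(motor: MotorModel, rng: np.random.Generator) -> float:
    if motor.stall_force_sd <= 0:
        return motor.stall_force
    lo = max(0.15 * motor.stall_force, motor.stall_force - 3.5 * motor.stall_force_sd)
    for _ in range(1000):
        f = rng.normal(motor.stall_force, motor.stall_force_sd)
        if f > lo:
            return f
    return motor.stall_force


def _simulate_events(motor, trap, atp, duration, rng):
    """Event-driven simulation of the motor/trap/controller state.

    Returns arrays (event times, motor position, trap position, attached
    flag) describing right-continuous piecewise-constant paths.  Stepping and
    detachment rates and the clamp feedback are evaluated at the noise-free
    (equilibrium) force; thermal fluctuation is superposed afterwards, which
    is exact for the linear bead dynamics.
    """
    k = trap.stiffness
    kl = motor.linkage_stiffness
    # noise-free force transmitted to the motor per nm of (m - x_trap)
    k_c = k if kl is None else k * kl / (k + kl)
    clamp = trap.mode == "force_clamp"
    dt_upd = 1.0 / trap.clamp_rate

    t, m, xt = 0.0, 0.0, 0.0
    attached = True
    state = _WAITING if clamp else -1
    anchor = 0.0
    next_upd = math.inf
    fs_i = _draw_stall_force(motor, rng)
    p = motor.detach_rate_per_dwell

    ev_t, ev_m, ev_xt, ev_att = [0.0], [m], [xt], [True]

    def record():
        ev_t.append(t)
        ev_m.append(m)
        ev_xt.append(xt)
        ev_att.append(attached)

    def force_det():
        return k_c * (m - xt)

    max_events = int(2e6)
    for _ in range(max_events):
        if t >= duration:
            break
        # clamp arming: engage as soon as the load reaches the set-point
        if clamp and state == _WAITING and attached and force_det() >= trap.clamp_setpoint:
            state = _ENGAGED
            anchor = xt
            next_upd = t + dt_upd

        if attached:
            f = force_det()
            rtot, pback = motor.attempt_rate(f, atp, fs_i)
            if p > 0:
                lam_d = max(motor.stall_detach_rate, rtot * p / (1.0 - p))
            else:
                lam_d = 0.0
            r_all = rtot + lam_d
            t_event = t + rng.exponential(1.0 / r_all) if r_all > 0 else math.inf
        else:
            t_event = (
                t + rng.exponential(1.0 / motor.rebind_rate)
                if motor.rebind_rate > 0
                else math.inf
            )
        t_upd = next_upd if (clamp and state == _ENGAGED) else math.inf
        t_next = min(t_event, t_upd, duration)
        if t_next >= duration:
            t = duration
            break
        t = t_next
        if t == t_upd:
            # proportional feedback on the offset from the force set-point
            f = force_det()
            xt += trap.clamp_gain * (f - trap.clamp_setpoint) / k
            next_upd = t + dt_upd
            if abs(xt - anchor) > trap.clamp_range:
                state = _FROZEN  # travel limit: revert to fixed trap
            record()
            continue
        if attached:
            if r_all > 0 and rng.random() < lam_d / r_all:
                attached = False  # detachment ends the encounter
                if clamp:
                    state = _WAITING  # instrument re-arms, trap holds
                    next_upd = math.inf
            else:
                m += -motor.step_size if rng.random() < pback else motor.step_size
        else:
            # re-engagement at the bead's instantaneous (thermally
            # fluctuating) position: dephases the discrete force ladder
            # between encounters, as in real recordings
            attached = True
            m = xt + (
                rng.normal(0.0, math.sqrt(motor.kBT / k)) if motor.kBT > 0 else 0.0
            )
            fs_i = _draw_stall_force(motor, rng)
        record()
    else:
        raise SimulationError("event budget exceeded; rates are implausibly high")

    return (
        np.asarray(ev_t),
        np.asarray(ev_m),
        np.asarray(ev_xt),
        np.asarray(ev_att, dtype=bool),
    )


def _render_trace(motor, trap, ev, duration, rng, keep_raw=False):
    """Turn event paths into a sampled trace: exact OU integration on the
    fine grid, anti-alias filtering, decimation."""
    k = trap.stiffness
    kl = motor.linkage_stiffness
    fs = trap.sample_rate
    os_ = trap.oversample
    fine_rate = fs * os_
    dtf = 1.0 / fine_rate
    k_att = k if kl is None else k + kl
    tau_min = motor.drag / max(k_att, k)
    if dtf >= tau_min:
        raise SimulationError(
            f"integration step {dtf:.3g} s >= bead relaxation time "
            f"{tau_min:.3g} s; increase oversample"
        )

    ev_t, ev_m, ev_xt, ev_att = ev
    n_out = int(round(duration * fs))
    n_fine = n_out * os_
    tg = np.arange(n_fine) * dtf
    idx = np.searchsorted(ev_t, tg, side="right") - 1
    m_g = ev_m[idx]
    xt_g = ev_xt[idx]
    att_g = ev_att[idx]

    if kl is None:
        x_eq = np.where(att_g, m_g, xt_g)
    else:
        x_eq = np.where(att_g, (k * xt_g + kl * m_g) / (k + kl), xt_g)
    k_tot = np.where(att_g, k_att, k)

    # piecewise integration over constant-stiffness segments
    bounds = np.concatenate(
        ([0], np.flatnonzero(np.diff(att_g.astype(np.int8))) + 1, [n_fine])
    )
    x_det = np.empty(n_fine)
    u = np.zeros(n_fine)
    noisy = motor.kBT > 0
    xi = rng.standard_normal(n_fine) if noisy else None
    x_prev = x_eq[0]
    u_prev = rng.normal(0.0, math.sqrt(motor.kBT / k_tot[0])) if noisy else 0.0
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        kt = k_tot[i0]
        a = math.exp(-dtf * kt / motor.drag)
        seg = x_eq[i0:i1]
        x_det[i0:i1], zf = signal.lfilter([1.0 - a], [1.0, -a], seg, zi=[a * x_prev])
        x_prev = x_det[i1 - 1]
        if noisy:
            s = math.sqrt(motor.kBT / kt * (1.0 - a * a))
            u[i0:i1], _ = signal.lfilter([1.0], [1.0, -a], s * xi[i0:i1], zi=[a * u_prev])
            u_prev = u[i1 - 1]
    x_fine = x_det + u

    # anti-alias filter (zero phase) then decimate
    if trap.filter_cutoff < fine_rate / 2 and os_ > 1:
        sos = signal.butter(4, trap.filter_cutoff, fs=fine_rate, output="sos")
        xb = signal.sosfiltfilt(sos, x_fine)
        xtr = signal.sosfiltfilt(sos, xt_g)
    else:
        xb, xtr = x_fine, xt_g
    bead = xb[::os_][:n_out].copy()
    trap_pos = xtr[::os_][:n_out].copy()
    force = k * (bead - trap_pos)
    time = np.arange(n_out) / fs

    raw = None
    if keep_raw:
        raw = {
            "time": tg,
            "bead": x_fine,
            "trap": xt_g,
            "motor": m_g,
            "attached": att_g,
        }
    return time, bead, trap_pos, force, raw


def _simulate(motor, trap, atp, duration, seed, keep_raw):
    if duration <= 0:
        raise SimulationError("duration must be positive")
    rng = np.random.default_rng(seed)
    ev = _simulate_events(motor, trap, atp, duration, rng)
    time, bead, trap_pos, force, raw = _render_trace(
        motor, trap, ev, duration, rng, keep_raw
    )
    meta = {
        "schema_version": 1,
        "trap": asdict(trap),
        "motor": asdict(motor),
        "atp_uM": atp,
        "duration_s": duration,
        "seed": seed,
        "preset": motor.preset_name,
    }
    return BeadTrace(time, bead, trap_pos, force, trap.stiffness, meta, raw)


def simulate_fixed_trap(
    motor: MotorModel,
    trap: TrapParameters,
    atp: float = 1000.0,
    duration: float = 20.0,
    seed: int = 0,
    keep_raw: bool = False,
) -> BeadTrace:
    """Simulate a fixed-trap recording.

    The motor engages at the trap centre and ramps up load as it steps; the
    engagement ends in detachment, after which the bead relaxes to the trap
    centre until re-engagement.  ``keep_raw=True`` attaches the pre-filter
    fine-grid arrays (``trace.raw``) for diagnostics.
    """
    if trap.mode != "fixed":
        raise SimulationError("trap.mode must be 'fixed' for simulate_fixed_trap")
    return _simulate(motor, trap, atp, duration, seed, keep_raw)


def simulate_force_clamp(
    motor: MotorModel,
    trap: TrapParameters,
    atp: float = 1000.0,
    duration: float = 20.0,
    seed: int = 0,
    keep_raw: bool = False,
) -> BeadTrace:
    """Simulate a force-clamp recording.

    The trap position is updated at ``clamp_rate`` by
    ``dx = gain * (F - F_set) / k``; between updates the trap is stationary.
    The clamp engages when the load first reaches the set-point, freezes when
    trap travel exceeds ``clamp_range`` (fixed-trap behaviour: the motor
    stalls or detaches), and re-arms with the trap held in place when the
    motor detaches.
    """
    if trap.mode != "force_clamp":
        raise SimulationError("trap.mode must be 'force_clamp'")
    if trap.clamp_gain <= 0:
        raise SimulationError("clamp_gain must be positive")
    if trap.clamp_gain >= 2:
        raise SimulationError(
            "clamp_gain >= 2 makes the discrete proportional loop unstable"
        )
    k_att = trap.stiffness + (motor.linkage_stiffness or 0.0)
    if 1.0 / trap.clamp_rate < 3.0 * motor.drag / k_att:
        raise SimulationError(
            "clamp_rate too fast for the bead relaxation time: the bead cannot "
            "equilibrate between feedback updates"
        )
    return _simulate(motor, trap, atp, duration, seed, keep_raw)


def generate_motile_assay(
    lambda_per_conc: float,
    concentrations: Sequence[float],
    n_beads,
    mode: str = "processive",
    seed: int = 0,
) -> MotileFractionSeries:
    """Simulate a bead-motility dilution series.

    Per concentration ``C``, the number of active motors on each bead is
    Poisson with mean ``lambda * C``; a bead is motile if it carries at least
    one (processive) or at least two (nonprocessive) motors.  ``n_beads`` may
    be a scalar or one value per concentration.
    """
    if mode not in ("processive", "nonprocessive"):
        raise ValueError("mode must be 'processive' or 'nonprocessive'")
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    n_arr = np.broadcast_to(np.asarray(n_beads, dtype=int), conc.shape)
    if np.any(n_arr < 1):
        raise ValueError("n_beads must be >= 1")
    need = 1 if mode == "processive" else 2
    rng = np.random.default_rng(seed)
    n_motile = [
        int(np.sum(rng.poisson(lambda_per_conc * c, n) >= need))
        for c, n in zip(conc, n_arr)
    ]
    return MotileFractionSeries.from_counts(conc, n_arr, n_motile)
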