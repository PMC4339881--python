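"""Force–velocity and ATP (Michaelis–Menten) analysis of force-clamp runs.

Runs are clamp-engaged intervals of a recording; each run's velocity is a
least-squares line fit to the bead position, and runs shorter than the
minimum length (50 nm) are excluded from downstream fits.  Per-force mean
velocities carry 95% intervals of ``ci_multiplier * s.e.m.``; the
force–velocity relation is a weighted linear fit whose force-axis crossing
(with first-order error propagation) is the extrapolated stall force.
Velocity versus ATP at fixed load follows Michaelis–Menten kinetics,
``V = v_max [ATP] / (K_m + [ATP])``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from ._stats import moving_average
from .config import AnalysisConfig
from .simulate import BeadTrace

__all__ = [
    "RunVelocity",
    "PerForceVelocity",
    "ForceVelocityFit",
    "ForceVelocityModel",
    "MichaelisMentenFit",
    "MichaelisMentenModel",
    "extract_runs",
    "mean_velocity_per_force",
    "fit_force_velocity",
    "fit_michaelis_menten",
]


@dataclass
class RunVelocity:
    """A clamp-engaged run: line-fit velocity under a constant load."""

    force: float  # clamp set-point, pN
    velocity: float  # nm/s
    length: float  # nm
    duration: float  # s
    included: bool = True  # length >= min_run_nm


def clamp_engaged_intervals(trace: BeadTrace, cfg: AnalysisConfig | None = None):
    """Sample intervals during which the force clamp is actively regulating.

    Engagement is reconstructed from the recording itself: the trap is
    repositioned while the clamp operates and stationary otherwise, so
    samples are engaged where the trap has moved within a feedback period.
    Because corrections only happen when the motor has stepped, gaps up to
    ``clamp_close_gap_s`` between trap movements are closed (slow motors
    trigger sparse corrections), and the interval is restricted to samples
    with force within ``clamp_force_band_pn`` of the set-point — this trims
    detachment collapses and post-freeze force ramps.  Returns a list of
    (start, stop) index pairs (stop exclusive) at least 10 samples long.
    """
    cfg = cfg or AnalysisConfig()
    trap_meta = trace.metadata.get("trap", {})
    if trap_meta.get("mode") != "force_clamp":
        raise ValueError("not a force-clamp trace")
    setpoint = float(trap_meta["clamp_setpoint"])
    clamp_rate = float(trap_meta.get("clamp_rate", 300.0))
    fs = trace.sample_rate
    xt = trace.trap_position
    n = len(xt)
    w = max(1, int(round(fs / clamp_rate)))
    moving = np.zeros(n, dtype=bool)
    if n > w:
        core = np.abs(xt[w:] - xt[:-w]) > 1e-6
        moving[:-w] |= core
        moving[w:] |= core
    if not np.any(moving):
        raise ValueError("no clamp-engaged samples in trace")
    # close gaps between sparse corrections
    gap = max(1, int(round(cfg.clamp_close_gap_s * fs)))
    idx = np.flatnonzero(moving)
    closed = moving.copy()
    jumps = np.flatnonzero(np.diff(idx) > 1)
    for j in jumps:
        a, b = idx[j], idx[j + 1]
        if b - a <= gap:
            closed[a:b] = True
    # the band test runs on a lightly smoothed force so single-step force
    # spikes between feedback corrections do not fragment the interval; at
    # low set-points the band shrinks so detached (zero-force) periods
    # cannot fall inside it
    window = max(1, int(round(cfg.smooth_ms / 1000.0 * fs)))
    f_smooth = moving_average(trace.force, window)
    band = min(cfg.clamp_force_band_pn, 0.6 * setpoint) if setpoint > 0 else cfg.clamp_force_band_pn
    engaged = closed & (np.abs(f_smooth - setpoint) <= band)
    bounds = np.concatenate(
        ([0], np.flatnonzero(np.diff(engaged.astype(np.int8))) + 1, [n])
    )
    intervals = []
    for i0, i1 in zip(bounds[:-1], bounds[1:]):
        if not engaged[i0]:
            continue
        # crop to the first/last actual trap correction: the closed mask pads
        # into the pre-engagement approach and the post-freeze deceleration,
        # which would bias run line fits through their end leverage
        inside = np.flatnonzero(moving[i0:i1])
        if len(inside) == 0:
            continue
        j0, j1 = i0 + inside[0], i0 + inside[-1] + 1
        if j1 - j0 >= 10:
            intervals.append((int(j0), int(j1)))
    return intervals


def extract_runs(trace: BeadTrace, cfg: AnalysisConfig | None = None) -> List[RunVelocity]:
    """Extract constant-force runs from a force-clamp recording.

    Runs are the clamp-engaged intervals (``clamp_engaged_intervals``);
    each run's velocity is a least-squares line fit to the bead position.
    Runs shorter than ``cfg.min_run_nm`` are still reported but flagged
    excluded.
    """
    cfg = cfg or AnalysisConfig()
    setpoint = float(trace.metadata.get("trap", {}).get("clamp_setpoint", 0.0))
    runs: List[RunVelocity] = []
    for i0, i1 in clamp_engaged_intervals(trace, cfg):
        tt = trace.time[i0:i1]
        bb = trace.bead_position[i0:i1]
        slope, _ = np.polyfit(tt, bb, 1)
        length = float(bb[-1] - bb[0])
        runs.append(
            RunVelocity(
                force=setpoint,
                velocity=float(slope),
                length=length,
                duration=float(tt[-1] - tt[0]),
                included=abs(length) >= cfg.min_run_nm,
            )
        )
    return runs


@dataclass
class PerForceVelocity:
    force: float
    mean_velocity: float
    ci_halfwidth: float  # ci_multiplier * s.e.m.; 0-width if degenerate
    n: int


def mean_velocity_per_force(
    runs: Sequence[RunVelocity], ci_multiplier: float = 1.96
) -> List[PerForceVelocity]:
    """Arithmetic mean of included run velocities at each force, with a
    ``ci_multiplier * s.e.m.`` interval (point estimate only for n = 1)."""
    by_force = {}
    for r in runs:
        if r.included:
            by_force.setdefault(round(r.force, 6), []).append(r.velocity)
    out = []
    for f in sorted(by_force):
        v = np.asarray(by_force[f])
        n = len(v)
        sem = float(np.std(v, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        hw = ci_multiplier * sem if n > 1 else np.nan
        out.append(PerForceVelocity(f, float(np.mean(v)), hw, n))
    return out


@dataclass
class ForceVelocityFit:
    """Weighted linear force–velocity fit.

    ``v0`` is the velocity-axis intercept (unloaded velocity), ``slope`` the
    (negative) velocity change per pN, and ``stall_extrapolation`` the
    force-axis crossing ``-v0/slope`` — the extrapolated stall force.
    Parameter CIs use a Bonferroni-corrected t quantile for the two
    simultaneously estimated parameters.
    """

    v0: float
    v0_ci: Tuple[float, float]
    slope: float
    slope_ci: Tuple[float, float]
    stall_extrapolation: Optional[float]
    stall_extrapolation_ci: Optional[Tuple[float, float]]
    stall_defined: bool
    per_force: List[PerForceVelocity]
    n_points: int
    weighted: bool

    def summary(self) -> str:
        lines = [
            "Force-velocity fit",
            "=" * 52,
            f"V = {self.v0:.1f} nm/s {self.slope:+.1f} nm/s/pN x F",
            f"velocity-axis intercept v0: {self.v0:.1f} "
            f"(95% CI {self.v0_ci[0]:.1f}, {self.v0_ci[1]:.1f}) nm/s",
            f"slope: {self.slope:.1f} "
            f"(95% CI {self.slope_ci[0]:.1f}, {self.slope_ci[1]:.1f}) nm/s/pN",
        ]
        if self.stall_defined:
            lines.append(
                f"force-axis crossing (stall extrapolation): "
                f"{self.stall_extrapolation:.2f} pN "
                f"(95% CI {self.stall_extrapolation_ci[0]:.2f}, "
                f"{self.stall_extrapolation_ci[1]:.2f})"
            )
        else:
            lines.append("stall extrapolation undefined (non-negative slope)")
        return "\n".join(lines)


class ForceVelocityModel:
    """Weighted linear model of per-force mean velocities.

    Weights are 1/(CI half-width)^2; if any half-width is zero or undefined
    the fit falls back to equal weights (then identical to OLS).
    """

    def __init__(self, per_force: Sequence[PerForceVelocity], alpha: float = 0.05):
        if len(per_force) < 3:
            raise ValueError("need >= 3 distinct forces")
        self.per_force = list(per_force)
        self.alpha = alpha

    @classmethod
    def from_runs(cls, runs: Sequence[RunVelocity], ci_multiplier: float = 1.96):
        return cls(mean_velocity_per_force(runs, ci_multiplier))

    def fit(self) -> ForceVelocityFit:
        f = np.array([p.force for p in self.per_force])
        v = np.array([p.mean_velocity for p in self.per_force])
        hw = np.array([p.ci_halfwidth for p in self.per_force])
        weighted = bool(np.all(np.isfinite(hw)) and np.all(hw > 0))
        w = 1.0 / hw**2 if weighted else np.ones_like(v)
        X = sm.add_constant(f)
        res = sm.WLS(v, X, weights=w).fit()
        v0, slope = res.params
        cov = res.cov_params()
        dof = len(f) - 2
        # Bonferroni for the two simultaneously estimated parameters
        tq = stats.t.ppf(1 - self.alpha / 4, dof)
        se = np.sqrt(np.diag(cov))
        v0_ci = (v0 - tq * se[0], v0 + tq * se[0])
        slope_ci = (slope - tq * se[1], slope + tq * se[1])
        if slope < 0:
            f0 = -v0 / slope
            g = np.array([-1.0 / slope, v0 / slope**2])
            var = float(g @ cov @ g)
            f0_ci = (f0 - tq * np.sqrt(var), f0 + tq * np.sqrt(var))
            defined = True
        else:
            f0, f0_ci, defined = None, None, False
        return ForceVelocityFit(
            v0=float(v0),
            v0_ci=tuple(map(float, v0_ci)),
            slope=float(slope),
            slope_ci=tuple(map(float, slope_ci)),
            stall_extrapolation=f0,
            stall_extrapolation_ci=f0_ci,
            stall_defined=defined,
            per_force=self.per_force,
            n_points=len(f),
            weighted=weighted,
        )


def fit_force_velocity(per_force: Sequence[PerForceVelocity], alpha: float = 0.05) -> ForceVelocityFit:
    """Weighted linear fit of mean velocity versus force."""
    return ForceVelocityModel(per_force, alpha=alpha).fit()


@dataclass
class MichaelisMentenFit:
    v_max: float
    v_max_ci: Tuple[float, float]
    k_m: float
    k_m_ci: Tuple[float, float]
    n_points: int

    def summary(self) -> str:
        return (
            f"Michaelis-Menten fit: v_max = {self.v_max:.1f} nm/s "
            f"(95% CI {self.v_max_ci[0]:.1f}, {self.v_max_ci[1]:.1f}), "
            f"K_m = {self.k_m:.1f} uM "
            f"(95% CI {self.k_m_ci[0]:.1f}, {self.k_m_ci[1]:.1f}); "
            f"n = {self.n_points}"
        )


class MichaelisMentenModel:
    """Hyperbolic saturation of velocity with ATP concentration."""

    def __init__(self, atp_um: Sequence[float], velocity: Sequence[float]):
        atp = np.asarray(atp_um, dtype=float)
        v = np.asarray(velocity, dtype=float)
        if len(atp) < 4:
            raise ValueError("need >= 4 ATP concentrations")
        if np.any(atp <= 0):
            raise ValueError("ATP concentrations must be positive")
        self.atp = atp
        self.v = v

    @staticmethod
    def _model(atp, vmax, km):
        return vmax * atp / (km + atp)

    def fit(self) -> MichaelisMentenFit:
        p0 = [float(np.max(self.v)), float(np.median(self.atp))]
        try:
            popt, pcov = optimize.curve_fit(
                self._model, self.atp, self.v, p0=p0, maxfev=20000
            )
        except RuntimeError as err:
            raise RuntimeError(
                f"Michaelis-Menten fit did not converge (p0={p0}): {err}"
            ) from err
        vmax, km = map(float, popt)
        se = np.sqrt(np.diag(pcov))
        return MichaelisMentenFit(
            v_max=vmax,
            v_max_ci=(vmax - 1.96 * se[0], vmax + 1.96 * se[0]),
            k_m=km,
            k_m_ci=(km - 1.96 * se[1], km + 1.96 * se[1]),
            n_points=len(self.atp),
        )


def fit_michaelis_menten(atp_um, velocity) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of V = v_max [ATP]/(K_m + [ATP])."""
    return MichaelisMentenModel(atp_um, velocity).fit()
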