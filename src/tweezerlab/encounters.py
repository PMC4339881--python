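"""Encounter segmentation and stall-force analysis.

A microtubule encounter is one continuous engagement of a bead-bound motor:
it opens when the opposing force first exceeds the motile threshold (0.5 pN)
and closes when the bead relaxes back toward the trap centre.  A stall is
the maximum force achieved and *sustained* for at least a duration
threshold; because premature detachments masquerade as brief "stalls", the
duration threshold is chosen by walking an increasing ladder (200, 250, 300,
400 ms) and stopping at the first rung where a Lilliefors test no longer
rejects normality of the stall-force sample — true stalls of a homogeneous
motor population are expected to be Gaussian, while a detachment-contaminated
sample is not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.diagnostic import lilliefors

from ._stats import gaussian_histogram_fit, moment_estimates
from .config import AnalysisConfig
from .simulate import BeadTrace

__all__ = [
    "Encounter",
    "StallFitResult",
    "GaussianStallModel",
    "InsufficientStallsError",
    "segment_encounters",
    "classify_stalls",
    "select_stall_threshold",
    "fit_stall_gaussian",
]


class InsufficientStallsError(ValueError):
    """Too few candidate stalls for a meaningful normality test."""


@dataclass
class Encounter:
    """One motor–microtubule engagement."""

    t_start: float
    t_end: float
    peak_force: float
    sustained_force: float
    sustained_ms: float
    run_length: float
    outcome: str = "detached_prestall"  # or "stalled"

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.run_length < 0:
            raise ValueError("run_length must be >= 0")
        # mean over the plateau can only sit at or below the peak
        if self.sustained_force > self.peak_force + 1e-9:
            raise ValueError("sustained_force cannot exceed peak_force")


@dataclass
class StallFitResult:
    """Gaussian stall-force fit with the threshold-selection audit trail.

    ``mean``/``sd`` are the histogram-fit estimates (the convention used in
    figure legends); ``sample_mean``/``sample_sd`` are the direct moments.
    """

    mean: float
    sd: float
    mean_ci: Tuple[float, float]
    sd_ci: Tuple[float, float]
    sample_mean: float
    sample_sd: float
    n_stalls: int
    n_encounters: int
    threshold_ms_used: Optional[float]
    lilliefors_trace: List[Tuple[float, bool]] = field(default_factory=list)
    normal_consistent: bool = True
    amplitude: float = float("nan")
    bin_width: float = float("nan")
    stall_forces: Optional[np.ndarray] = None

    def summary(self) -> str:
        lines = [
            "Stall-force analysis",
            "=" * 52,
            f"encounters: {self.n_encounters}   stalls: {self.n_stalls} "
            f"({100.0 * self.n_stalls / max(self.n_encounters, 1):.0f}%)",
            f"duration threshold: {self.threshold_ms_used} ms "
            f"(normality {'accepted' if self.normal_consistent else 'REJECTED at every rung'})",
            f"Gaussian fit : mean {self.mean:.2f} pN "
            f"(95% CI {self.mean_ci[0]:.2f}, {self.mean_ci[1]:.2f}), "
            f"s.d. {self.sd:.2f} pN (95% CI {self.sd_ci[0]:.2f}, {self.sd_ci[1]:.2f})",
            f"sample moments: mean {self.sample_mean:.2f} pN, "
            f"s.d. {self.sample_sd:.2f} pN",
        ]
        if self.lilliefors_trace:
            trail = ", ".join(
                f"{int(t)} ms: {'reject' if r else 'accept'}"
                for t, r in self.lilliefors_trace
            )
            lines.append(f"normality ladder: {trail}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

from ._stats import moving_average as _smooth


def segment_encounters(trace: BeadTrace, cfg: AnalysisConfig | None = None) -> List[Encounter]:
    """Split a trace into motor–microtubule encounters.

    An encounter opens at an upward crossing of ``motile_force_threshold``
    and closes when the force falls below the release band
    (``release_fraction`` of the threshold).  Encounters shorter than three
    samples or ``min_encounter_ms`` are discarded (thermal excursions of the
    unbound bead can cross the threshold briefly).  Per encounter the peak force, run length
    (maximum bead displacement from engagement) and the terminal sustained
    plateau (samples within ``stall_band_pn`` of the encounter maximum,
    located on a lightly smoothed force) are computed.
    """
    cfg = cfg or AnalysisConfig()
    if len(trace) < 3:
        raise ValueError("trace shorter than 3 samples")
    fs = trace.sample_rate
    force = trace.force
    thr = cfg.motile_force_threshold
    release = cfg.release_fraction * thr
    window = max(1, int(round(cfg.smooth_ms / 1000.0 * fs)))
    fsm = _smooth(force, window)

    encounters: List[Encounter] = []
    n = len(force)
    i = 0
    while i < n:
        if force[i] >= thr and (i == 0 or force[i - 1] < thr):
            j = i + 1
            while j < n and force[j] >= release:
                j += 1
            min_samples = max(3, int(round(cfg.min_encounter_ms / 1000.0 * fs)))
            if j - i >= min_samples:
                seg = force[i:j]
                seg_sm = fsm[i:j]
                peak = float(np.max(seg))
                run_length = float(np.max(trace.bead_position[i:j]) - trace.bead_position[i])
                # terminal plateau: contiguous smoothed samples within the
                # stall band around the encounter maximum
                k_peak = int(np.argmax(seg_sm))
                band = cfg.stall_band_pn
                level = seg_sm[k_peak]
                lo = k_peak
                while lo > 0 and seg_sm[lo - 1] >= level - band:
                    lo -= 1
                hi = k_peak
                while hi < len(seg) - 1 and seg_sm[hi + 1] >= level - band:
                    hi += 1
                # the held level: average the upper half of the band so the
                # slow final approach to the plateau does not drag it down
                plateau = seg[lo : hi + 1]
                top = plateau[seg_sm[lo : hi + 1] >= level - 0.5 * band]
                sustained = float(np.mean(top if len(top) else plateau))
                sustained = min(sustained, peak)
                sustained_ms = (hi - lo + 1) / fs * 1000.0
                enc = Encounter(
                    t_start=float(trace.time[i]),
                    t_end=float(trace.time[j - 1]),
                    peak_force=peak,
                    sustained_force=sustained,
                    sustained_ms=sustained_ms,
                    run_length=max(run_length, 0.0),
                    outcome=(
                        "stalled"
                        if sustained_ms >= cfg.stall_candidate_ms
                        else "detached_prestall"
                    ),
                )
                encounters.append(enc)
            i = j
        else:
            i += 1
    return encounters


def classify_stalls(
    encounters: Sequence[Encounter], threshold_ms: float
) -> Tuple[List[Encounter], List[Encounter]]:
    """Partition encounters into (stalled, detached-before-stall) at the
    given sustained-duration threshold; the sustained force of a stalled
    encounter is its reported stall force."""
    if threshold_ms <= 0:
        raise ValueError("threshold_ms must be positive")
    stalled, detached = [], []
    for enc in encounters:
        if enc.sustained_ms >= threshold_ms:
            enc.outcome = "stalled"
            stalled.append(enc)
        else:
            enc.outcome = "detached_prestall"
            detached.append(enc)
    return stalled, detached


# ---------------------------------------------------------------------------
# stall-force fitting
# ---------------------------------------------------------------------------

class GaussianStallModel:
    """Gaussian model of a stall-force sample.

    ``fit()`` produces both the direct sample moments and a least-squares
    Gaussian fit to the binned histogram (Freedman–Diaconis width with a
    0.25 pN floor); the histogram fit is the headline estimate, matching the
    convention of published stall-force histograms.
    """

    MIN_BIN_PN = 0.25

    def __init__(self, stall_forces, ci_multiplier: float = 1.96):
        forces = np.asarray(stall_forces, dtype=float)
        if len(forces) < 3:
            raise ValueError("need >= 3 stall forces")
        if np.std(forces) == 0:
            raise ValueError("degenerate sample: all stall forces identical")
        self.stall_forces = forces
        self.ci_multiplier = ci_multiplier

    def fit(self) -> StallFitResult:
        x = self.stall_forces
        z = self.ci_multiplier
        sample_mean, sample_sd, mean_ci_m, sd_ci_m = moment_estimates(x, z)
        try:
            h = gaussian_histogram_fit(x, min_bin_width=self.MIN_BIN_PN)
            mean, sd = h["mean"], h["sd"]
            # discreteness (force levels are multiples of the per-step force
            # increment) or sparse histograms can derail the 3-parameter
            # fit; accept it only when it describes the sample
            plausible = (
                x.min() - h["bin_width"] <= mean <= x.max() + h["bin_width"]
                and 0.33 * sample_sd <= sd <= 3.0 * sample_sd
            )
            if not plausible:
                raise RuntimeError("implausible histogram fit")
            mean_ci = (mean - z * h["mean_se"], mean + z * h["mean_se"])
            sd_ci = (max(sd - z * h["sd_se"], 0.0), sd + z * h["sd_se"])
            amplitude, bin_width = h["amplitude"], h["bin_width"]
        except RuntimeError:  # histogram fit unusable: report sample moments
            mean, sd = sample_mean, sample_sd
            mean_ci, sd_ci = mean_ci_m, sd_ci_m
            amplitude, bin_width = float("nan"), float("nan")
        return StallFitResult(
            mean=mean,
            sd=sd,
            mean_ci=mean_ci,
            sd_ci=sd_ci,
            sample_mean=sample_mean,
            sample_sd=sample_sd,
            n_stalls=len(x),
            n_encounters=len(x),
            threshold_ms_used=None,
            amplitude=amplitude,
            bin_width=bin_width,
            stall_forces=x,
        )


def fit_stall_gaussian(stall_forces, ci_multiplier: float = 1.96) -> StallFitResult:
    """Gaussian location/scale of a stall-force sample with 95% CIs."""
    return GaussianStallModel(stall_forces, ci_multiplier).fit()


MIN_STALLS_FOR_TEST = 8


def select_stall_threshold(
    encounters: Sequence[Encounter], cfg: AnalysisConfig | None = None
) -> StallFitResult:
    """Iterative duration-threshold selection for stall classification.

    Walks ``cfg.stall_threshold_ladder`` in order; at each rung classifies
    stalls and applies a Lilliefors test of composite normality to the
    stall forces.  Stops at the first rung where the test fails to reject at
    ``cfg.alpha`` and fits a Gaussian to the surviving sample.  If every
    rung rejects, the last rung's fit is returned flagged
    ``normal_consistent=False``.
    """
    cfg = cfg or AnalysisConfig()
    encounters = list(encounters)
    trail: List[Tuple[float, bool]] = []
    chosen_forces = None
    chosen_thr = None
    normal = False
    for thr in cfg.stall_threshold_ladder:
        stalled, _ = classify_stalls(encounters, thr)
        forces = np.array([e.sustained_force for e in stalled])
        if len(forces) < MIN_STALLS_FOR_TEST:
            raise InsufficientStallsError(
                f"only {len(forces)} stalls at the {thr:.0f} ms rung "
                f"(need >= {MIN_STALLS_FOR_TEST})"
            )
        _, pval = lilliefors(forces, dist="norm", pvalmethod="table")
        rejected = bool(pval < cfg.alpha)
        trail.append((thr, rejected))
        chosen_forces, chosen_thr = forces, thr
        if not rejected:
            normal = True
            break
    result = GaussianStallModel(chosen_forces, cfg.ci_multiplier).fit()
    result.threshold_ms_used = chosen_thr
    result.lilliefors_trace = trail
    result.normal_consistent = normal
    result.n_encounters = len(encounters)
    # re-apply the selected threshold so encounter outcomes match the result
    classify_stalls(encounters, chosen_thr)
    return result
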