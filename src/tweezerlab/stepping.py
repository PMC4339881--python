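"""Step detection and dwell-time analysis for constant-force segments.

The step finder is an iterative stepwise χ² fitter: it repeatedly places the
single step that maximally reduces the residual sum of squares of a
piecewise-constant fit, and judges each candidate step count ``k`` by the
quality ratio ``S(k) = SSE_counter(k) / SSE_fit(k)``, where the counter-fit
puts its steps at the midpoints of the fitted dwells.  Genuine staircases
produce a sharp peak of ``S`` at the true step count; stepless noise keeps
``S`` near one.  The step count at the peak is accepted if the peak exceeds
a quality threshold, and steps smaller than twice the standard error of the
adjoining plateau difference are pruned.

Dwell times are measured between consecutive *forward* steps (intervening
backward steps do not reset the clock); the first and last intervals of a
segment are censored.  Dwells are fitted with a single exponential either on
the binned histogram (``A exp(-k_cat t)``) or on the empirical CDF with a
fixed detection limit ``t_L`` (``1 - exp(-k_cat (t - t_L))``), with a
shifted-exponential maximum-likelihood estimate reported as a cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize

from ._stats import gaussian_histogram_fit

__all__ = [
    "StepRecord",
    "StepSummary",
    "DwellRecord",
    "DwellFit",
    "DwellTimeModel",
    "find_steps",
    "summarize_steps",
    "extract_dwells",
    "fit_dwells",
]


@dataclass
class StepRecord:
    """A detected step: signed size (nm; positive = advance) and plateau
    levels on either side."""

    time: float
    size: float
    level_before: float
    level_after: float
    direction: str = ""
    index: int = 0  # sample index of the first point after the step

    def __post_init__(self) -> None:
        if self.size == 0:
            raise ValueError("step size must be nonzero")
        expected = "forward" if self.size > 0 else "backward"
        if not self.direction:
            self.direction = expected
        elif self.direction != expected:
            raise ValueError("direction inconsistent with step sign")


@dataclass
class DwellRecord:
    duration: float
    preceded_by: str  # forward | backward | censored
    followed_by: str
    contains_backward: bool = False
    below_detection: bool = False

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ValueError("duration must be >= 0")

    @property
    def censored(self) -> bool:
        return "censored" in (self.preceded_by, self.followed_by)


# ---------------------------------------------------------------------------
# step detection
# ---------------------------------------------------------------------------

def _best_split(y2sum_unused, c, i, j, min_seg: int = 1):
    """Best single breakpoint of plateau [i, j): returns (SSE gain, split).

    ``c`` is the prefix-sum array of the data (c[0]=0).  The SSE reduction of
    splitting at ``s`` is sum1^2/n1 + sum2^2/n2 - tot^2/n; vectorised over
    all admissible splits.  ``min_seg`` restricts both sub-plateaus to at
    least that many samples.
    """
    n = j - i
    if n < 2 * min_seg:
        return 0.0, -1
    tot = c[j] - c[i]
    s = np.arange(i + min_seg, j - min_seg + 1)
    if len(s) == 0:
        return 0.0, -1
    n1 = s - i
    n2 = j - s
    sum1 = c[s] - c[i]
    sum2 = tot - sum1
    gain = sum1 * sum1 / n1 + sum2 * sum2 / n2 - tot * tot / n
    b = int(np.argmax(gain))
    return float(gain[b]), int(s[b])


def _sse_for_breakpoints(c, c2, n, bps):
    """SSE of the piecewise-constant fit with the given sorted breakpoints."""
    edges = np.concatenate(([0], bps, [n]))
    sums = c[edges[1:]] - c[edges[:-1]]
    counts = np.diff(edges)
    return float(c2[n] - np.sum(sums * sums / counts))


def find_steps(
    time: np.ndarray,
    position: np.ndarray,
    expected_noise_nm: Optional[float] = None,
    quality_threshold: float = 2.0,
    max_steps: Optional[int] = None,
) -> List[StepRecord]:
    """Detect steps in a constant-force (clamp-engaged) segment.

    Parameters
    ----------
    time, position : array
        Uniformly sampled segment, at least 10 samples.
    expected_noise_nm : float, optional
        Plateau noise s.d.; estimated from the fit residuals if omitted.
    quality_threshold : float
        Minimum counter-fit quality ratio ``S`` for accepting any steps;
        calibrated so that flat noise yields no steps in >= 95% of traces.
    """
    y = np.asarray(position, dtype=float)
    t = np.asarray(time, dtype=float)
    n = len(y)
    if n < 10:
        raise ValueError("segment too short for step detection (< 10 samples)")
    c = np.concatenate(([0.0], np.cumsum(y)))
    c2 = np.concatenate(([0.0], np.cumsum(y * y)))
    sse0 = _sse_for_breakpoints(c, c2, n, np.array([], dtype=int))
    if max_steps is None:
        max_steps = max(4, n // 4)

    # greedy stepwise χ² fitting with cached per-plateau best splits
    splits = {}  # (i, j) -> (gain, split)
    splits[(0, n)] = _best_split(None, c, 0, n)
    breakpoints: List[int] = []
    sse_fit = sse0
    s_curve: List[float] = []
    bp_history: List[int] = []
    best_s, best_k = -np.inf, 0
    tol = max(sse0, 1.0) * 1e-12
    while len(breakpoints) < max_steps:
        plateau, (gain, split) = max(splits.items(), key=lambda kv: kv[1][0])
        if split < 0 or gain <= 0:
            break
        i, j = plateau
        del splits[plateau]
        splits[(i, split)] = _best_split(None, c, i, split)
        splits[(split, j)] = _best_split(None, c, split, j)
        breakpoints.append(split)
        bp_history.append(split)
        sse_fit -= gain
        bps = np.sort(np.array(breakpoints))
        # counter fit: steps at the midpoints of the fitted dwells
        edges = np.concatenate(([0], bps, [n]))
        mids = ((edges[:-1] + edges[1:]) // 2)
        mids = np.unique(mids[(mids > 0) & (mids < n)])
        sse_counter = _sse_for_breakpoints(c, c2, n, mids)
        if sse_fit <= tol:  # essentially noise-free staircase
            s_curve.append(np.inf)
            best_s, best_k = np.inf, len(breakpoints)
            break
        s_curve.append(sse_counter / sse_fit)
        if s_curve[-1] > best_s:
            best_s, best_k = s_curve[-1], len(breakpoints)
        if len(breakpoints) > 2 * best_k + 32:
            break

    # gate: the quality ratio must clear the threshold within a bounded
    # search depth (on stepless noise S_max creeps upward with unbounded
    # depth, so the gate statistic is evaluated on the first few splits)
    gate_depth = max(8, n // 40)
    gate_s = max(s_curve[:gate_depth], default=0.0)
    if best_k == 0 or gate_s < quality_threshold:
        return []
    # the S curve is flat around its peak when short dwells are marginal:
    # take the rightmost candidate count within 3% of the peak
    if np.isinf(best_s):
        k_sel = best_k
    else:
        s_arr = np.array(s_curve)
        near = np.flatnonzero(s_arr >= 0.97 * best_s)
        k_sel = int(near[-1]) + 1 if len(near) else best_k
    bps = np.sort(np.array(bp_history[:k_sel]))

    # noise scale for the refinement and pruning criteria: robust (MAD)
    # residual spread of the current fit, unless supplied by the caller
    def _residual_sigma(bps_arr):
        edges = np.concatenate(([0], bps_arr, [n]))
        sums = c[edges[1:]] - c[edges[:-1]]
        counts = np.diff(edges)
        levels = np.repeat(sums / counts, counts)
        resid = y - levels
        mad = np.median(np.abs(resid - np.median(resid)))
        return 1.4826 * float(mad)

    sigma0 = expected_noise_nm if expected_noise_nm is not None else _residual_sigma(bps)

    # local refinement: recover short dwells the global criterion leaves
    # merged, accepting only splits that are overwhelming relative to the
    # plateau-difference standard error
    if sigma0 > 0:
        refine_z = 5.0
        stack = list(zip(np.concatenate(([0], bps)), np.concatenate((bps, [n]))))
        extra = []
        while stack:
            i, j = stack.pop()
            gain, s = _best_split(None, c, i, j, min_seg=2)
            if s < 0:
                continue
            n1, n2 = s - i, j - s
            size = abs((c[j] - c[s]) / n2 - (c[s] - c[i]) / n1)
            se = sigma0 * np.sqrt(1.0 / n1 + 1.0 / n2)
            if size >= refine_z * se:
                extra.append(s)
                stack.append((i, s))
                stack.append((s, j))
        if extra:
            bps = np.sort(np.concatenate((bps, np.array(extra, dtype=int))))

    # prune steps below 2x the s.e. of the plateau-level difference
    while True:
        edges = np.concatenate(([0], bps, [n]))
        sums = c[edges[1:]] - c[edges[:-1]]
        counts = np.diff(edges)
        levels = sums / counts
        if len(bps) == 0:
            return []
        sse = _sse_for_breakpoints(c, c2, n, bps)
        dof = max(n - len(levels), 1)
        sigma = (
            expected_noise_nm
            if expected_noise_nm is not None
            else float(np.sqrt(max(sse, 0.0) / dof))
        )
        sizes = np.diff(levels)
        se = sigma * np.sqrt(1.0 / counts[:-1] + 1.0 / counts[1:])
        weak = np.abs(sizes) < 2.0 * se
        zero = sizes == 0.0
        bad = weak | zero
        if not np.any(bad):
            break
        drop = int(np.argmin(np.where(bad, np.abs(sizes) - 2.0 * se, np.inf)))
        bps = np.delete(bps, drop)
        if len(bps) == 0:
            return []

    edges = np.concatenate(([0], bps, [n]))
    sums = c[edges[1:]] - c[edges[:-1]]
    counts = np.diff(edges)
    levels = sums / counts
    records = []
    for idx, b in enumerate(bps):
        size = float(levels[idx + 1] - levels[idx])
        records.append(
            StepRecord(
                time=float(0.5 * (t[b - 1] + t[b])),
                size=size,
                level_before=float(levels[idx]),
                level_after=float(levels[idx + 1]),
                index=int(b),
            )
        )
    return records


# ---------------------------------------------------------------------------
# step statistics
# ---------------------------------------------------------------------------

@dataclass
class StepSummary:
    n_steps: int
    n_forward: int
    n_backward: int
    forward_mean: float
    forward_sd: float
    forward_mean_ci: Tuple[float, float]
    backward_mean: float
    backward_sd: float
    backward_fraction: float
    gaussian_mean: float
    gaussian_sd: float
    gaussian_mean_ci: Tuple[float, float]
    gaussian_sd_ci: Tuple[float, float]

    def summary(self) -> str:
        return (
            f"steps: {self.n_steps} ({self.n_forward} forward, "
            f"{self.n_backward} backward; "
            f"{100 * self.backward_fraction:.1f}% backward)\n"
            f"forward : {self.forward_mean:.2f} +- {self.forward_sd:.2f} nm "
            f"(Gaussian fit {self.gaussian_mean:.2f} +- {self.gaussian_sd:.2f} nm)\n"
            f"backward: {self.backward_mean:.2f} +- {self.backward_sd:.2f} nm"
        )


def summarize_steps(steps: Sequence[StepRecord], ci_multiplier: float = 1.96) -> StepSummary:
    """Forward/backward step statistics and a histogram Gaussian fit to the
    forward step sizes (falls back to sample moments for small samples)."""
    if len(steps) < 3:
        raise ValueError("need >= 3 steps to summarize")
    sizes = np.array([s.size for s in steps])
    fwd = sizes[sizes > 0]
    bwd = -sizes[sizes < 0]
    if len(fwd) == 0:
        raise ValueError("no forward steps")
    fmean = float(np.mean(fwd))
    fsd = float(np.std(fwd, ddof=1)) if len(fwd) > 1 else 0.0
    sem = fsd / np.sqrt(len(fwd))
    try:
        h = gaussian_histogram_fit(fwd, min_bin_width=0.5)
        gmean, gsd = h["mean"], h["sd"]
        gmean_ci = (gmean - ci_multiplier * h["mean_se"], gmean + ci_multiplier * h["mean_se"])
        gsd_ci = (max(gsd - ci_multiplier * h["sd_se"], 0.0), gsd + ci_multiplier * h["sd_se"])
    except (RuntimeError, ValueError):
        gmean, gsd = fmean, fsd
        gmean_ci = (fmean - ci_multiplier * sem, fmean + ci_multiplier * sem)
        gsd_ci = (0.0, np.inf)
    return StepSummary(
        n_steps=len(sizes),
        n_forward=len(fwd),
        n_backward=len(bwd),
        forward_mean=fmean,
        forward_sd=fsd,
        forward_mean_ci=(fmean - ci_multiplier * sem, fmean + ci_multiplier * sem),
        backward_mean=float(np.mean(bwd)) if len(bwd) else 0.0,
        backward_sd=float(np.std(bwd, ddof=1)) if len(bwd) > 1 else 0.0,
        backward_fraction=len(bwd) / len(sizes),
        gaussian_mean=gmean,
        gaussian_sd=gsd,
        gaussian_mean_ci=gmean_ci,
        gaussian_sd_ci=gsd_ci,
    )


# ---------------------------------------------------------------------------
# dwell times
# ---------------------------------------------------------------------------

def extract_dwells(
    steps: Sequence[StepRecord],
    t_start: float,
    t_end: float,
    t_L: float = 0.007,
) -> List[DwellRecord]:
    """Dwell times between consecutive forward steps.

    The intervals from the segment start to the first forward step and from
    the last forward step to the segment end are flagged censored (and
    excluded from fits); dwells shorter than ``t_L`` are flagged
    below-detection.  Intervening backward steps do not reset the dwell
    clock but are flagged.
    """
    times = [s.time for s in steps]
    if times != sorted(times):
        raise ValueError("steps must be sorted by time")
    fwd_times = [s.time for s in steps if s.size > 0]
    records: List[DwellRecord] = []
    if not fwd_times:
        return records
    records.append(
        DwellRecord(fwd_times[0] - t_start, "censored", "forward")
    )
    bwd_times = np.array([s.time for s in steps if s.size < 0])
    for a, b in zip(fwd_times[:-1], fwd_times[1:]):
        dur = b - a
        has_bwd = bool(np.any((bwd_times > a) & (bwd_times < b)))
        records.append(
            DwellRecord(
                dur,
                "forward",
                "forward",
                contains_backward=has_bwd,
                below_detection=dur < t_L,
            )
        )
    records.append(DwellRecord(t_end - fwd_times[-1], "forward", "censored"))
    return records


@dataclass
class DwellFit:
    """Single-exponential dwell-time fit."""

    k_cat: float
    k_cat_ci: Tuple[float, float]
    amplitude: float
    t_L: float
    method: str
    n: int
    mle_k_cat: float
    mle_k_cat_ci: Tuple[float, float]

    def summary(self) -> str:
        return (
            f"dwell fit ({self.method}, n={self.n}, t_L={1000 * self.t_L:.0f} ms): "
            f"k_cat = {self.k_cat:.2f} /s "
            f"(95% CI {self.k_cat_ci[0]:.2f}, {self.k_cat_ci[1]:.2f}); "
            f"MLE cross-check {self.mle_k_cat:.2f} /s"
        )


class DwellTimeModel:
    """Exponential model of forward-step dwell times with a detection limit.

    Parameters
    ----------
    dwells : sequence of DwellRecord or float
        Dwell durations (s); DwellRecords flagged censored are dropped.
    t_L : float
        Detection limit (s); dwells below it are excluded and the ECDF model
        is ``1 - exp(-k_cat (t - t_L))``.
    """

    HIST_BIN_S = 0.010  # 10 ms dwell histogram bins

    def __init__(self, dwells, t_L: float = 0.007):
        durations = []
        for d in dwells:
            if isinstance(d, DwellRecord):
                if d.censored:
                    continue
                durations.append(d.duration)
            else:
                durations.append(float(d))
        durations = np.asarray(durations, dtype=float)
        self.t_L = float(t_L)
        self.all_durations = durations
        self.durations = np.sort(durations[durations >= self.t_L])
        if len(durations) and len(self.durations) == 0:
            raise ValueError("all dwells fall below the detection limit t_L")

    def _mle(self):
        t = self.durations
        k = 1.0 / float(np.mean(t - self.t_L))
        half = 1.96 / np.sqrt(len(t))
        return k, (k * (1 - half), k * (1 + half))

    def fit(self, method: str = "ecdf") -> DwellFit:
        t = self.durations
        if len(t) < 20:
            raise ValueError("need >= 20 uncensored dwells")
        mle_k, mle_ci = self._mle()
        if method == "ecdf":
            y = (np.arange(len(t)) + 0.5) / len(t)
            model = lambda tt, k: 1.0 - np.exp(-k * (tt - self.t_L))
            popt, _ = optimize.curve_fit(model, t, y, p0=[mle_k], maxfev=10000)
            k = float(popt[0])
            # sampling-theory interval: the exponential-rate s.e. is k/sqrt(n)
            half = 1.96 / np.sqrt(len(t))
            return DwellFit(
                k, (k * (1 - half), k * (1 + half)), 1.0, self.t_L, "ecdf",
                len(t), mle_k, mle_ci,
            )
        if method == "histogram":
            w = self.HIST_BIN_S
            edges = np.arange(self.t_L, t.max() + 2 * w, w)
            counts, edges = np.histogram(t, bins=edges)
            centers = 0.5 * (edges[:-1] + edges[1:])
            model = lambda tt, amp, k: amp * np.exp(-k * tt)
            p0 = [counts.max() * np.exp(mle_k * centers[0]), mle_k]
            popt, pcov = optimize.curve_fit(model, centers, counts, p0=p0, maxfev=10000)
            amp, k = float(popt[0]), float(popt[1])
            se = float(np.sqrt(pcov[1, 1]))
            return DwellFit(
                k, (k - 1.96 * se, k + 1.96 * se), amp, self.t_L, "histogram",
                len(t), mle_k, mle_ci,
            )
        if method == "mle":
            return DwellFit(
                mle_k, mle_ci, 1.0, self.t_L, "mle", len(t), mle_k, mle_ci
            )
        raise ValueError(f"unknown method {method!r}")


def fit_dwells(dwells, t_L: float = 0.007, method: str = "ecdf") -> DwellFit:
    """Fit a single exponential to forward-step dwell times."""
    return DwellTimeModel(dwells, t_L=t_L).fit(method=method)
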