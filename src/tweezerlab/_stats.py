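"""Shared small statistics helpers (histogram Gaussian fits, binning)."""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with edge padding (window in samples)."""
    if window <= 1:
        return x
    kernel = np.ones(window) / window
    pad = window // 2
    padded = np.pad(x, pad, mode="edge")
    return np.convolve(padded, kernel, mode="same")[pad : pad + len(x)]


def freedman_diaconis_width(x: np.ndarray, minimum: float = 0.0) -> float:
    """Freedman–Diaconis histogram bin width with an optional floor."""
    x = np.asarray(x, dtype=float)
    iqr = np.subtract(*np.percentile(x, [75, 25]))
    width = 2.0 * iqr / len(x) ** (1.0 / 3.0)
    if width <= 0:
        width = np.std(x, ddof=1) or 1.0
    return max(width, minimum)


def _gauss(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def gaussian_histogram_fit(x, bin_width=None, min_bin_width=0.0, min_bins=6):
    """Least-squares Gaussian fit to a histogram of the sample.

    Mirrors the common figure-legend convention of fitting a Gaussian curve
    to binned counts rather than reporting sample moments.  Returns a dict
    with ``mean``, ``sd``, ``amplitude``, their standard errors, and the bin
    width used.
    """
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 values for a histogram fit")
    if np.std(x) == 0:
        raise ValueError("degenerate sample: zero variance")
    if bin_width is None:
        bin_width = freedman_diaconis_width(x, minimum=min_bin_width)
        span = float(x.max() - x.min())
        # a 3-parameter fit needs enough bins to be determined
        if span > 0 and span / bin_width < min_bins:
            bin_width = span / min_bins
    lo = np.floor(x.min() / bin_width) * bin_width
    hi = np.ceil(x.max() / bin_width) * bin_width + 0.5 * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(x, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    p0 = [counts.max(), float(np.mean(x)), float(np.std(x, ddof=1))]
    span = x.max() - x.min()
    bounds = (
        [0.0, x.min() - span, bin_width / 4.0],
        [10.0 * counts.max(), x.max() + span, 2.0 * span + bin_width],
    )
    popt, pcov = optimize.curve_fit(
        _gauss, centers, counts, p0=p0, bounds=bounds, maxfev=10000
    )
    perr = np.sqrt(np.diag(pcov))
    amp, mu, sd = popt
    return {
        "mean": float(mu),
        "sd": float(abs(sd)),
        "amplitude": float(amp),
        "mean_se": float(perr[1]),
        "sd_se": float(perr[2]),
        "bin_width": float(bin_width),
        "n": int(len(x)),
    }


def moment_estimates(x, ci_multiplier: float = 1.96):
    """Sample mean and s.d. with normal-theory 95% intervals."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    sem = sd / np.sqrt(n)
    mean_ci = (mean - ci_multiplier * sem, mean + ci_multiplier * sem)
    # chi-square interval for the standard deviation
    alpha = 2.0 * stats.norm.sf(ci_multiplier)
    lo = sd * np.sqrt((n - 1) / stats.chi2.ppf(1 - alpha / 2, n - 1))
    hi = sd * np.sqrt((n - 1) / stats.chi2.ppf(alpha / 2, n - 1))
    return mean, sd, mean_ci, (float(lo), float(hi))
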