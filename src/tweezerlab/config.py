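"""Analysis configuration.

Units are fixed package-wide: nm, s (ms only where a field name says so),
pN, uM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import List

import yaml

__all__ = ["AnalysisConfig"]


@dataclass
class AnalysisConfig:
    """Tunable parameters of the trace analyses.

    Attributes
    ----------
    motile_force_threshold : float
        Force (pN) a bead must generate to count as motile and to open an
        encounter (default 0.5 pN).
    stall_candidate_ms : float
        Minimum sustained duration (ms) for a candidate stall (default 200).
    stall_threshold_ladder : list of float
        Increasing duration thresholds (ms) walked by the iterative
        normality-test threshold selection (default [200, 250, 300, 400]).
    alpha : float
        Significance level of the Lilliefors normality test.
    min_run_nm : float
        Minimum run length (nm) for inclusion in velocity fits.
    dwell_detection_limit_ms : float
        Dwell-time detection limit t_L of the step finder (default 7 ms).
    ci_multiplier : float
        Multiplier on the s.e.m. for reported confidence intervals (1.96
        for 95%).
    stall_band_pn : float
        Half-width (pN) of the force band defining a sustained plateau
        (0.25 is appropriate for ~1 pN stalls, 0.5 for ~5 pN stalls).
    release_fraction : float
        An encounter closes when force falls below
        ``release_fraction * motile_force_threshold``.
    smooth_ms : float
        Moving-average window (ms) used when locating force plateaus.
    min_encounter_ms : float
        Minimum encounter duration (ms); shorter threshold crossings are
        treated as thermal-noise excursions, not engagements.
    step_quality_threshold : float
        Minimum counter-fit quality ratio for accepting a staircase fit.
    clamp_close_gap_s : float
        Gaps between trap corrections shorter than this (s) count as
        continuous clamp engagement.  Must comfortably exceed the longest
        plausible dwell, or slow periods are excised and dwell statistics
        become length-biased; false bridging is prevented by the force band,
        not by this window.
    clamp_force_band_pn : float
        Clamp-engaged samples must have force within this band (pN) of the
        set-point.
    """

    motile_force_threshold: float = 0.5
    stall_candidate_ms: float = 200.0
    stall_threshold_ladder: List[float] = field(
        default_factory=lambda: [200.0, 250.0, 300.0, 400.0]
    )
    alpha: float = 0.05
    min_run_nm: float = 50.0
    dwell_detection_limit_ms: float = 7.0
    ci_multiplier: float = 1.96
    stall_band_pn: float = 0.5
    release_fraction: float = 0.25
    smooth_ms: float = 20.0
    min_encounter_ms: float = 20.0
    step_quality_threshold: float = 2.0
    clamp_close_gap_s: float = 1.0
    clamp_force_band_pn: float = 0.75

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        ladder = list(self.stall_threshold_ladder)
        if any(b <= a for a, b in zip(ladder, ladder[1:])):
            raise ValueError("stall_threshold_ladder must be strictly increasing")
        if ladder and ladder[0] < self.stall_candidate_ms:
            raise ValueError("ladder must start at or above stall_candidate_ms")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "AnalysisConfig":
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def to_file(self, path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=2))
        else:
            path.write_text(yaml.safe_dump(self.to_dict()))
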