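# tweezerlab

Simulation and analysis of single-molecule optical-trapping recordings of
processive cytoskeletal motors (dynein-like steppers), for biophysicists
who run trap experiments and for method developers who need a fully
synthetic test bed with known ground truth.

A motor pulls a trapped bead along a microtubule in ~8-nm steps against
the trap load F = k·(x_bead − x_trap). `tweezerlab` provides both sides of
such an experiment:

* a **simulator** — overdamped Langevin bead dynamics (drag γ = 6πηr,
  thermal noise k_BT) around an event-driven stepping motor with a
  force- and ATP-dependent rate r(F) = r₀ max(0, 1 − F/F_s) ·
  [ATP]/(K_m + [ATP]), backward steps, competing detachment, rebinding,
  and an optional discrete proportional force clamp
  (Δx_trap = g·(F − F_set)/k at 50–600 Hz), with anti-alias filtering and
  decimation to the 3 kHz recording grid;
* the complete **analysis chain** —
  * stall forces: encounter segmentation, the maximum force *sustained*
    ≥ a duration threshold, iterative threshold selection by Lilliefors
    normality testing (200 → 250 → 300 → 400 ms), Gaussian histogram fits;
  * stepping: iterative stepwise-χ² step detection with a counter-fit
    quality ratio, step-size statistics, censored single-exponential dwell
    fits y = A·e^(−k_cat·t) (histogram) and
    y = 1 − e^(−k_cat·(t−t_L)) (ECDF with detection limit t_L);
  * force–velocity: run extraction from clamp records (lines to runs
    ≥ 50 nm), per-force means with 1.96×s.e.m. intervals, weighted linear
    fit V = v₀ + slope·F and the extrapolated stall force −v₀/slope;
  * Michaelis–Menten velocity vs ATP: V = v_max[ATP]/(K_m+[ATP]);
  * processivity: exact Clopper–Pearson binomial intervals and the
    weighted comparison of the Poisson motile-fraction models
    F = 1 − e^(−λC) (processive) versus
    F = 1 − e^(−λC) − λC·e^(−λC) (nonprocessive).

Two calibrated motor presets ship with the package: `md-wt` (a ~1 pN
staller with short runs and frequent premature detachment) and `md-dct`
(a ~5.65 pN staller with tenacious ~1 s stalls and long runs). The model,
parameter meanings and all numerical conventions are documented in
[docs/methods.md](docs/methods.md).

## Worked example

Simulate six bead recordings of the high-force preset and run the full
stall pipeline:

```python
import tweezerlab as tl
from tweezerlab import AnalysisConfig
from tweezerlab.encounters import segment_encounters, select_stall_threshold

cfg = AnalysisConfig()
motor = tl.preset("md-dct")                      # stall force 5.65 pN
trap = tl.TrapParameters(stiffness=0.05)         # pN/nm, 3 kHz, 1.5 kHz filter
encounters = []
for seed in range(100, 106):
    trace = tl.simulate_fixed_trap(motor, trap, atp=1000.0, duration=30.0, seed=seed)
    encounters.extend(segment_encounters(trace, cfg))
print(select_stall_threshold(encounters, cfg).summary())
```

prints

```
Stall-force analysis
====================================================
encounters: 107   stalls: 67 (63%)
duration threshold: 200.0 ms (normality accepted)
Gaussian fit : mean 5.73 pN (95% CI 5.44, 6.02), s.d. 1.10 pN (95% CI 0.81, 1.40)
sample moments: mean 5.58 pN, s.d. 1.13 pN
normality ladder: 200 ms: accept
```

Reading this: 107 motor–microtubule encounters were segmented from the six
recordings; 67 sustained their maximal force for at least the selected
200 ms threshold and count as stalls; the Lilliefors walk accepted the
first threshold rung (the stall-force sample is consistent with a
Gaussian), and the histogram Gaussian fit recovers the preset's 5.65 pN
stall force within its confidence interval, with the ~1 pN width coming
from the preset's encounter-to-encounter stall variability.

The same workflows are available from the shell:

```bash
tweezerlab simulate --preset md-dct --mode clamp --setpoint-pn 2 \
    --duration-s 30 --seed 7 -o trace.csv
tweezerlab analyze fv trace.csv -o fvfit.json
tweezerlab analyze steps trace.csv -o steps.json
tweezerlab analyze stalls bead*.csv -o stalls.json
tweezerlab analyze processivity counts.csv -o procfit.json
tweezerlab report --preset md-dct --n-beads 10 --seed 1 -o report.json
```

Traces are CSV (`time_s,bead_nm,trap_nm,force_pN`, full float precision)
with a JSON metadata sidecar; bead-count tables are
`concentration,n_total,n_motile` CSV.

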