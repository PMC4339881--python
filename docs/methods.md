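# Methods

`tweezerlab` couples a stochastic simulator of single-molecule optical-trap
recordings to the complete analysis chain used for motor-protein mechanics:
stall-force classification with an iterative normality-based duration
threshold, step and dwell-time analysis of force-clamp records, weighted
force–velocity and Michaelis–Menten fits, and Poisson models of the
fraction of motile beads in a dilution series. This note records the model,
the parameter choices, and the numerical decisions, including the ones that
were genuinely open.

## 1. Bead–trap–motor model

### Mechanics

A bead of radius `r` (default 500 nm) is held in a harmonic trap of
stiffness `k` (pN/nm) and driven by a motor that advances along a
microtubule in discrete steps of size `d` (default 8.2 nm). The bead obeys
overdamped Langevin dynamics,

    gamma dx = -k_tot (x - x_eq(t)) dt + sqrt(2 kBT gamma) dW,

with Stokes drag `gamma = 6 pi eta r ≈ 8.4e-6 pN s/nm` (water at 25 °C,
`kBT = 4.114 pN nm`). Two linkage conventions are supported:

* **rigid** (default for a bare `MotorModel`): the motor dictates the
  bead's equilibrium position, `x_eq = m(t)` while attached, and the bead
  relaxes toward it with the trap stiffness alone (`k_tot = k`). The
  attached bead then satisfies equipartition against the trap,
  `<x²> = kBT/k`, and shows a Lorentzian spectrum with corner
  `k/(2 pi gamma)` — both asserted by the test suite.
* **series linkage** (`linkage_stiffness`, used by both presets at
  0.3 pN/nm, a typical motor/antibody compliance): the bead sits in the
  combined potential of trap and linkage, `x_eq = (k x_trap + k_l m)/(k +
  k_l)`, `k_tot = k + k_l`. This reduces the measured force noise of an
  attached bead to `k sqrt(kBT/(k+k_l))`, which is what makes a 5-pN-scale
  clamp record hold its set-point to ~0.1–0.2 pN s.d. at 3 kHz — matching
  real instruments, where the same physics applies.

Detached beads always relax toward the trap centre with `k_tot = k`.

### Integration

The dynamics are linear, so the trajectory decomposes exactly into the
deterministic relaxation toward `x_eq(t)` plus a stationary
Ornstein–Uhlenbeck fluctuation. Both are integrated with the exact AR(1)
(exponential-integrator) update on a fine grid of `oversample` (default 32)
times the output rate, i.e. dt ≈ 10.4 µs at 3 kHz output. The exact update
is unconditionally stable and has the exact stationary variance at any dt;
the simulator still refuses dt ≥ gamma/k_tot, where a naive scheme would be
unstable and events would be under-resolved. The fine-grid trace is
anti-alias filtered (4th-order Butterworth at `filter_cutoff`, applied
forward–backward for zero phase; bead and trap filtered identically so the
force column stays `k (bead − trap)` exactly) and decimated by stride to
the 3 kHz output grid.

### Stepping, detachment, re-engagement

The motor is an event-driven jump process. Stepping attempts occur at a
force- and ATP-dependent rate; each attempt moves the motor by ±`d`, with
backward probability `backstep_fraction` (default 0.05). Two kernels:

* `linear_fv` (default): attempt rate `r(F) = r0 max(0, 1 − F/F_s)` with
  `r0 = v0 / (d (1 − 2b))` so that the *net* unloaded velocity is `v0` and
  the force–velocity relation is the observed straight line crossing zero
  at the stall force `F_s`.
* `boltzmann`: forward rate `k0 exp(−F δ/kBT)` with a constant backward
  rate `b k0` and `δ` chosen so forward and backward rates balance exactly
  at `F_s`.

ATP multiplies the attempt rate by `[ATP]/(K_m + [ATP])` (default
`K_m = 30 µM`; the main observable constraint is saturation at 1 mM).

Detachment competes with stepping: the hazard is
`max(stall_detach_rate, r(F) p/(1−p))` with `p = detach_rate_per_dwell`, so
at low load the probability that any given dwell ends in detachment is
exactly `p`, while near stall — where the stepping rate vanishes and a
per-dwell probability alone could never terminate the engagement — the
basal hazard `stall_detach_rate` (s⁻¹) ends stalls on a ~0.2–1 s timescale.
One consequence worth knowing when interpreting dwell fits: a dwell of
length `t` is observed *complete* only if no detachment interrupted it
(probability `e^{−λ_d t}`), so observed dwells are distributed
`Exp(r + λ_d)`, not `Exp(r)`. With λ_d ≈ 0.2/s against r ≈ 11/s this is a
~2% effect; a strongly detaching motor would need the correction.

After detachment the bead relaxes to the trap centre and the motor
re-engages at the bead position at rate `rebind_rate`. Each engagement
draws its attainable stall force from a truncated normal
(`stall_force ± stall_force_sd`), modelling attachment-geometry and motor
heterogeneity — this, not the thermal noise, is what gives stall-force
histograms their ~1 pN Gaussian width.

### Force clamp

The controller is a discrete proportional loop: at `clamp_rate` (50–600 Hz)
the trap moves by `Δx_trap = gain (F − F_set)/k`. Feedback acts on the
noise-free (equilibrium) force; because the bead dynamics are linear, the
thermal fluctuation superposes exactly afterwards, and the controller then
never consumes noise — a deliberate simplification equivalent to an
instrument that averages its force signal over the feedback period. The
discrete loop is stable for `0 < gain·k_c/k < 2` (`k_c` is the noise-free
force per nm of motor–trap separation); `gain ≥ 2` and feedback periods
shorter than ~3 bead relaxation times are refused rather than clipped. For
a motor at constant velocity `v` the pre-correction force error converges
to `v k/(gain · clamp_rate)`, which the suite checks against the simulated
sawtooth.

Controller states mirror the experiment: **armed** (trap fixed) until the
load first reaches the set-point; **engaged** (periodic corrections) until
trap travel exceeds `clamp_range` (default 400 nm, the instrument's
detection range), after which the trap **freezes** and behaviour reverts to
a fixed trap (the motor walks up to stall or detaches); on detachment the
clamp re-arms with the trap held, reproducing the repeated
displacement–reset cycles seen in force-clamp records.

### Presets

Two calibrated parameter sets are shipped, named for the two motor-domain
constructs they emulate:

* `md-dct` (CT-cap-deleted-like, the high-force phenotype):
  `v0 = 672 nm/s`, `F_s = 5.65 pN` (the straight force–velocity line
  672 − 119·F crosses zero there), `stall_force_sd = 1.0 pN`,
  `p = 0.01`, basal detachment 1.0/s (~1 s stalls), rebinding 2/s.
* `md-wt` (full-length-like, the low-force phenotype): `F_s = 1.0 pN`,
  `stall_force_sd = 0.35 pN`, `v0 = 600 nm/s`, `p = 0.05`, basal
  detachment 4.5/s. These give short runs, a ~0.9–1.0 pN stall peak and a
  majority of encounters detaching before a 200 ms stall, the qualitative
  signature of the wild-type construct.

The preset numbers were calibrated in-repo against the published summary
statistics (stall means and s.d., stall yields, run and stall durations);
the calibration is part of the generator's definition, not a free dial.

### What the generator does *not* emulate

* The step size is a fixed `d`; detected step-size dispersion therefore
  reflects detection noise only (~0.3 nm), not the ~1.3 nm spread of real
  motors. Recovery tests assert the mean, not the spread.
* Motor and trap forces live on a discrete ladder (`k_c d` per step), so
  simulated stall forces are quantised at ~0.35 pN; real records smear
  this. The Gaussian histogram fit guards against the resulting spiky
  histograms (§3).
* One motor per bead, no multi-motor load sharing or bidirectional
  high-density behaviour; no linkage nonlinearity; no instrument drift,
  low-frequency noise, or bead-size dispersion. Passing recovery tests
  therefore demonstrates correctness of the analysis chain under the
  model's assumptions, not robustness to every artefact of real data.

## 2. Encounter segmentation and stall analysis

An encounter opens at an upward crossing of the motile threshold (0.5 pN)
and closes when the force falls below a release band (0.25× threshold).
Thermal excursions of an unbound bead can cross 0.5 pN for a few
milliseconds at 3 kHz, so encounters shorter than 20 ms (config) are
discarded. Per encounter: peak force; run length (maximum bead
displacement from engagement); and the terminal plateau, located on a
20 ms moving-average force as the contiguous samples within
`stall_band_pn` of the encounter maximum. The *sustained force* is the
mean of the upper half-band of that plateau — averaging the held level
rather than the slow final approach, which for a creeping motor would
otherwise bias the stall force low by ~0.1 pN. The band default (0.5 pN)
suits ~5 pN stalls; 0.25 pN is appropriate at ~1 pN and is what the
low-force analyses use.

A stall is an encounter whose plateau lasts at least the duration
threshold; its sustained force is the reported stall force. The duration
threshold is chosen by walking the ladder 200, 250, 300, 400 ms and
stopping at the first rung where a Lilliefors test (statsmodels'
implementation, table p-values) no longer rejects composite normality of
the stall-force sample at α = 0.05 — the logic being that true stalls of a
homogeneous population are Gaussian, while premature detachments
contaminate the short rungs. At least 8 stalls are required per rung. If
every rung rejects, the last rung's fit is returned flagged non-normal
(with the full decision trail); large simulated samples do resolve the
small kinetic skew of the generator and can reject everywhere, exactly as
a large real data set would.

Stall forces are summarised two ways: sample moments (mean ± s.d. with
normal-theory intervals) and a least-squares Gaussian fit to the binned
histogram (Freedman–Diaconis width, floored at 0.25 pN and capped so at
least six bins span the data), which is the convention of published
stall-force figures and is the headline value. The 3-parameter histogram
fit can be derailed by the quantised force ladder (above) or sparse bins;
a fit whose centre leaves the data range or whose width is implausible
against the sample s.d. (outside 0.33–3×) is discarded in favour of the
moments. Degenerate (zero-variance) samples are an error.

## 3. Step detection and dwell times

The step finder is an iterative stepwise-χ² fitter. Greedily place the
single breakpoint that maximally reduces the residual sum of squares
(vectorised via prefix sums; each split only re-evaluates its two
children); after each placement compute the counter-fit — steps at the
midpoints of the current dwells — and the quality ratio
`S(k) = SSE_counter/SSE_fit`.

* **Gate:** the fitted staircase always beats the counter-fit, so `S > 1`
  even on stepless noise, and `S_max` creeps upward with unbounded search
  depth. The gate statistic is therefore `max S` over the first
  `max(8, n/40)` splits, with threshold 2.0, Monte-Carlo calibrated on
  flat Gaussian noise to a ≤5% false-positive rate (asserted in-repo).
* **Count selection:** `S` is flat around its peak when short dwells are
  marginal; the global argmax under-segments them. The selected count is
  the rightmost one within 3% of the peak.
* **Refinement:** each remaining plateau is recursively split wherever the
  level difference exceeds 5× its standard error (noise scale: MAD of the
  fit residuals, or the caller-supplied `expected_noise_nm`), recovering
  short dwells the global criterion leaves merged while keeping spurious
  splits (which scan at ~3 s.e.) out.
* **Pruning:** steps below 2× the s.e. of the adjoining plateau difference
  are removed, weakest first, until stable.

Dwell times are measured between consecutive *forward* steps; intervening
backward steps are flagged but do not reset the clock (thinning a Poisson
process leaves the forward intervals exponential). The first and last
interval of each segment are censored and excluded from fits; dwells below
the detection limit `t_L` (default 7 ms) are excluded and the ECDF model
`1 − exp(−k_cat (t − t_L))` accounts for the truncation exactly (the
shifted model equals the renormalised truncated exponential). Three
estimators are reported: least squares on the ECDF (plotting positions
`(i+0.5)/n`; Monte-Carlo unbiased for exponential samples), least squares
on the 10 ms-binned histogram `A exp(−k_cat t)`, and the shifted-exponential
maximum-likelihood estimate `1/(mean(t) − t_L)` as cross-check. The ECDF
fit's interval is the sampling-theory `k (1 ± 1.96/sqrt(n))` (an
exponential rate estimate has s.e. `k/sqrt(n)`); the histogram fit uses its
covariance.

## 4. Force-clamp runs, force–velocity, Michaelis–Menten

Clamp engagement is reconstructed from the recording alone (the stored
channels are bead, trap, force): samples are engaged where the trap has
moved within a feedback period; gaps between corrections are closed up to
1 s (corrections only happen when the motor steps — a shorter window was
found to excise long dwells and length-bias the dwell sample); a smoothed
force must stay within a band of the set-point (`min(0.75 pN, 0.6 ×
set-point)`), which separates engagement from detachment collapses,
post-freeze force ramps, and re-engagement climbs; and each interval is
cropped to its first/last actual correction, since the padded edges
(approach and deceleration) otherwise bias the run line fit through their
leverage. These choices matter: engagement fragments that correlate with
stepping activity systematically distort velocity and dwell statistics,
and each rule above closes one such selection channel.

Each engaged interval is a run: velocity from an ordinary least-squares
line through the bead position, length as end-to-end displacement. Runs
shorter than 50 nm are reported but excluded from fits. Per-force mean
velocities carry `1.96 × s.e.m.` intervals; the force–velocity relation is
a weighted linear fit (weights `1/halfwidth²`, falling back to equal
weights when any interval is degenerate, in which case it reduces exactly
to OLS). Parameter intervals use a Bonferroni-corrected t quantile for the
two simultaneous parameters; the force-axis crossing `−v0/slope` (the
extrapolated stall force) gets a first-order delta-method interval from
the parameter covariance. A non-negative slope flags the extrapolation
undefined rather than reporting a crossing.

Two selection effects are worth knowing. The ≥50 nm rule preferentially
drops slow, short runs, and at set-points near stall only engagements
whose drawn stall force exceeds the set-point occur at all — with
per-encounter stall heterogeneity of 1 pN the ensemble crossing sits
~0.5–1 pN above the nominal stall force. Recovery studies therefore use a
kinetically homogeneous motor (`stall_force_sd = 0`), for which the
generator parameter is the actual estimand; the heterogeneous shift is a
real property of such experiments, not an artefact of this code.

Velocity versus ATP at a fixed 0.5 pN load is fitted by nonlinear least
squares to `V = v_max [ATP]/(K_m + [ATP])` with covariance-based
intervals; at least four ATP levels including a near-saturating one are
required, and non-convergence is reported with the starting point.

## 5. Motile-fraction models

Bead motility in a dilution series is binomial sampling; each fraction
carries an exact Clopper–Pearson 95% interval (beta-quantile form, exact
0/1 endpoints at the boundaries). Both Poisson occupancy models —
processive `F = 1 − e^{−λC}` and nonprocessive `F = 1 − e^{−λC} − λC
e^{−λC}` — are fitted by weighted nonlinear least squares with weights
`1/halfwidth²` (zero- and full-count rows take the Jeffreys-interval
half-width so no weight is infinite). R² is computed on weighted
residuals. The models have one parameter each, so no nested F-test exists;
following the stated procedure the comparison uses
`F = (wRSS_worse − wRSS_better)/(wRSS_better/(n−2))` with p from
`F(1, n−2)` (the df convention is recorded in the output), and AIC is
reported alongside as a clearly non-headline sanity metric. Selection:
the lower-residual model when `p < α` or the weighted-R² gap is ≥ 0.02;
otherwise indeterminate.

A caution from in-repo power analysis: at realistic bead counts (~100–150
total) the nonprocessive curve imitates processive data well enough that
this comparison identifies a truly processive motor in only ~50–65% of
simulated assays (the residual-sign ceiling is ~78%, and even an exact
binomial likelihood-ratio tops out near ~85–89%), while the converse
direction is reliable (~95%+). Single published assays that decide in
favour of processivity at these sample sizes should be read with that
asymmetry in mind.

## 6. Problem sizes and reproducibility

The test-suite and acceptance studies simulate 25 beads × 30 s per stall
study (~400–500 encounters), 50 × 38 s recordings for the stepping study
(~250 steps each), 3 × 20 s recordings per clamp force for the
force–velocity study, and 100–200 assays for selection rates; the
acceptance script uses the same studies at 8–12 beads/recordings. All
randomness flows from explicit integer seeds through
`numpy.random.SeedSequence` spawning, and identical seeds reproduce traces
bit-identically. Trace CSVs store full `%.17g` precision and round-trip
exactly.

## 7. Known limitations

* The simulator is phenomenological: no two-head coordination, no AAA-ring
  chemistry, no structural mechanism — it generates the *statistics* the
  analyses assume.
* Clamp engagement is reconstructed from the trace because the file format
  carries no controller channel; instruments that log clamp state should
  prefer that log.
* The Lilliefors table p-values saturate at the tails; only the comparison
  against α matters here.
* The histogram Gaussian fit is a figure-legend convention retained for
  comparability; the sample moments are the statistically preferable
  summary and are always reported alongside.
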