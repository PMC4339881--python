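"""Step detection, step statistics and censored-exponential dwell fits."""

import numpy as np
import pytest

from tweezerlab.stepping import (
    DwellRecord,
    DwellTimeModel,
    StepRecord,
    extract_dwells,
    find_steps,
    fit_dwells,
    summarize_steps,
)
from conftest import exponential_staircase, staircase


class TestFindSteps:
    def test_noiseless_staircase_exact(self):
        t, y = staircase([0.1 * k for k in range(1, 10)], [8.0] * 9, 1.0)
        steps = find_steps(t, y)
        assert len(steps) == 9
        assert all(s.size == pytest.approx(8.0, abs=1e-9) for s in steps)
        # conservation: the fitted staircase spans the full displacement
        assert sum(s.size for s in steps) == pytest.approx(
            steps[-1].level_after - steps[0].level_before
        )

    def test_idempotent_on_own_reconstruction(self):
        t, y = staircase([0.07, 0.2, 0.31, 0.5, 0.62], [8, -8, 8, 8, 8], 0.8)
        steps = find_steps(t, y)
        # rebuild the fitted staircase and refit
        recon = np.zeros_like(y)
        recon[:] = steps[0].level_before
        for s in steps:
            recon[s.index :] = s.level_after
        steps2 = find_steps(t, recon)
        assert [(s.index, round(s.size, 9)) for s in steps] == [
            (s.index, round(s.size, 9)) for s in steps2
        ]

    def test_single_step_matches_brute_force_oracle(self):
        # the first greedy split must coincide with an exhaustive
        # single-breakpoint least-squares search
        hits_truth = 0
        n_trials = 25
        for seed in range(n_trials):
            rng = np.random.default_rng(seed)
            n = 300
            y = np.where(np.arange(n) >= 150, 8.0, 0.0) + rng.normal(0, 2.0, n)
            t = np.arange(n) / 3000.0
            # oracle: brute-force scan of every breakpoint
            best_sse, best_b = np.inf, -1
            for b in range(1, n):
                sse = np.sum((y[:b] - y[:b].mean()) ** 2) + np.sum(
                    (y[b:] - y[b:].mean()) ** 2
                )
                if sse < best_sse:
                    best_sse, best_b = sse, b
            steps = find_steps(t, y)
            assert len(steps) >= 1
            main = max(steps, key=lambda s: abs(s.size))
            assert abs(main.index - best_b) <= 1
            hits_truth += abs(main.index - 150) <= 5
        assert hits_truth / n_trials >= 0.75

    def test_flat_noise_rarely_yields_steps(self):
        false_pos = 0
        n_trials = 40
        for seed in range(n_trials):
            rng = np.random.default_rng(900 + seed)
            y = rng.normal(0.0, 2.0, 300)
            if find_steps(np.arange(300) / 3000.0, y):
                false_pos += 1
        assert false_pos / n_trials <= 0.05

    def test_recovery_bias_small_at_moderate_snr(self):
        # SNR d/sigma >= 2 with >= 30 samples per dwell: size bias < 5%
        means = []
        for seed in range(12):
            t, y = staircase(
                [0.02 * k for k in range(1, 40)], [8.2] * 39, 0.85,
                noise_nm=4.1, seed=seed,
            )
            steps = find_steps(t, y)
            fwd = [s.size for s in steps if s.size > 0]
            if fwd:
                means.append(np.mean(fwd))
        assert abs(np.mean(means) - 8.2) / 8.2 < 0.05

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            find_steps(np.arange(5) / 3000.0, np.zeros(5))


class TestSummarizeSteps:
    def _records(self, sizes):
        return [
            StepRecord(time=0.1 * i, size=s, level_before=0.0, level_after=s)
            for i, s in enumerate(sizes)
        ]

    def test_mixed_directions(self):
        summ = summarize_steps(self._records([8.0, 8.0, 8.0, -8.0]))
        assert summ.backward_fraction == pytest.approx(0.25)
        assert summ.forward_mean == pytest.approx(8.0)
        assert summ.backward_mean == pytest.approx(8.0)

    def test_all_forward(self):
        summ = summarize_steps(self._records([8, 7.5, 8.5, 8.2, 8.0]))
        assert summ.backward_fraction == 0.0
        assert summ.n_backward == 0

    def test_no_forward_steps_rejected(self):
        with pytest.raises(ValueError):
            summarize_steps(self._records([-8.0, -8.0, -8.0]))

    def test_gaussian_fit_on_large_sample(self):
        rng = np.random.default_rng(1)
        sizes = rng.normal(8.2, 1.3, 254)
        summ = summarize_steps(self._records(sizes))
        assert summ.gaussian_mean == pytest.approx(8.2, abs=0.4)
        assert summ.gaussian_sd == pytest.approx(1.3, abs=0.5)


class TestExtractDwells:
    def test_forward_only_definition(self):
        steps = [
            StepRecord(time=t, size=8.0, level_before=0, level_after=8)
            for t in (0.1, 0.2, 0.35)
        ]
        dwells = extract_dwells(steps, 0.0, 1.0)
        uncensored = [d for d in dwells if not d.censored]
        assert [round(d.duration, 9) for d in uncensored] == [0.10, 0.15]
        assert dwells[0].censored and dwells[-1].censored

    def test_backward_step_does_not_reset_clock(self):
        steps = [
            StepRecord(time=0.1, size=8.0, level_before=0, level_after=8),
            StepRecord(time=0.15, size=-8.0, level_before=8, level_after=0),
            StepRecord(time=0.3, size=8.0, level_before=0, level_after=8),
        ]
        dwells = [d for d in extract_dwells(steps, 0.0, 1.0) if not d.censored]
        assert len(dwells) == 1
        assert dwells[0].duration == pytest.approx(0.20)
        assert dwells[0].contains_backward

    def test_below_detection_flagging(self):
        steps = [
            StepRecord(time=t, size=8.0, level_before=0, level_after=8)
            for t in (0.1, 0.104, 0.3)
        ]
        dwells = [d for d in extract_dwells(steps, 0.0, 1.0, t_L=0.007) if not d.censored]
        assert dwells[0].below_detection and not dwells[1].below_detection


class TestDwellFits:
    def test_exact_quantiles_invert_to_rate(self):
        # feed the exact exponential quantiles at the ECDF plotting
        # positions: the fit must return the generating rate
        n, rate = 1000, 12.0
        y = (np.arange(n) + 0.5) / n
        t = -np.log(1 - y) / rate
        fit = fit_dwells(list(t), t_L=0.0, method="ecdf")
        assert fit.k_cat == pytest.approx(12.0, rel=1e-6)

    def test_shifted_sample_recovery(self):
        rng = np.random.default_rng(8)
        t_L = 0.007
        dwells = rng.exponential(1 / 10.6, 300) + t_L
        fit = fit_dwells(list(dwells), t_L=t_L, method="ecdf")
        lo, hi = fit.k_cat_ci
        assert lo <= 10.6 <= hi

    def test_histogram_and_mle_agree(self):
        rng = np.random.default_rng(9)
        dwells = rng.exponential(1 / 11.0, 2000)
        model = DwellTimeModel(list(dwells), t_L=0.0)
        hist = model.fit("histogram")
        assert hist.k_cat == pytest.approx(hist.mle_k_cat, rel=0.05)

    def test_censored_records_excluded(self):
        rng = np.random.default_rng(10)
        recs = [DwellRecord(d, "forward", "forward") for d in rng.exponential(0.1, 50)]
        recs.append(DwellRecord(5.0, "censored", "forward"))
        model = DwellTimeModel(recs, t_L=0.0)
        assert len(model.durations) == 50

    def test_all_below_detection_rejected(self):
        with pytest.raises(ValueError):
            DwellTimeModel([0.001, 0.002, 0.003], t_L=0.007)

    def test_too_few_dwells_rejected(self):
        with pytest.raises(ValueError):
            DwellTimeModel(list(np.linspace(0.05, 0.5, 10)), t_L=0.0).fit("ecdf")


class TestEndToEndStaircase:
    def test_motor_like_recovery(self):
        # 8.2 nm steps, 5% backsteps, exponential dwells at 11/s in 1.3 nm
        # noise: detector statistics must recover the generator
        t, y, times, dirs = exponential_staircase(11.0, 20.0, seed=2)
        steps = find_steps(t, y)
        assert abs(len(steps) - len(times)) <= 0.1 * len(times)
        summ = summarize_steps(steps)
        assert summ.gaussian_mean == pytest.approx(8.2, abs=0.3)
        dwells = extract_dwells(steps, 0.0, 20.0, t_L=0.007)
        fit = DwellTimeModel(dwells, t_L=0.007).fit("ecdf")
        # forward steps are a thinned Poisson process at 0.95 * 11 per s
        assert fit.k_cat == pytest.approx(0.95 * 11.0, rel=0.2)

    def test_conservation_on_noisy_staircase(self):
        t, y, *_ = exponential_staircase(11.0, 6.0, seed=5)
        steps = find_steps(t, y)
        net = steps[-1].level_after - steps[0].level_before
        assert sum(s.size for s in steps) == pytest.approx(net, abs=1e-9)
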