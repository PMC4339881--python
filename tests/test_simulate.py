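"""Simulator physics: equipartition, spectral shape, determinism, stepping
limits, and the force-clamp controller."""

import numpy as np
import pytest
from scipy import optimize, signal

import tweezerlab as tl
from tweezerlab.simulate import SimulationError, _default_drag


def quiet_motor(**kw):
    """An attached but non-stepping, non-detaching motor (rigid link)."""
    defaults = dict(
        unloaded_velocity=0.0,
        stall_force=1.0,
        backstep_fraction=0.0,
        detach_rate_per_dwell=0.0,
        stall_force_sd=0.0,
    )
    defaults.update(kw)
    return tl.MotorModel(**defaults)


class TestBeadThermodynamics:
    def test_equipartition_prefilter_variance(self):
        # stationary motor, rigid link: bead diffuses in the trap potential,
        # so <x^2> = kBT/k (checked on the pre-filter fine grid)
        k = 0.05
        trace = tl.simulate_fixed_trap(
            quiet_motor(),
            tl.TrapParameters(stiffness=k),
            atp=1000.0,
            duration=15.0,
            seed=2,
            keep_raw=True,
        )
        raw = trace.raw["bead"]
        assert len(raw) >= 1_000_000
        expected = tl.KBT_ROOM / k
        assert np.var(raw) == pytest.approx(expected, rel=0.02)

    def test_lorentzian_corner_frequency(self):
        k = 0.02
        motor = quiet_motor()
        trace = tl.simulate_fixed_trap(
            motor, tl.TrapParameters(stiffness=k), 1000.0, 20.0, seed=3, keep_raw=True
        )
        raw = trace.raw["bead"]
        fs_fine = 3000.0 * 32
        f, pxx = signal.welch(raw, fs=fs_fine, nperseg=1 << 15)
        sel = (f > 20) & (f < 5000)

        def lorentz(ff, a, fc):
            return a / (ff**2 + fc**2)

        a0 = float(pxx[sel][0] * (f[sel][0] ** 2 + 300.0**2))
        popt, _ = optimize.curve_fit(
            lambda ff, a, fc: np.log(lorentz(ff, a, fc)),
            f[sel],
            np.log(pxx[sel]),
            p0=[a0, 300.0],
            maxfev=10000,
        )
        fc_expected = k / (2 * np.pi * motor.drag)
        assert abs(popt[1]) == pytest.approx(fc_expected, rel=0.10)

    def test_default_drag_is_stokes(self):
        # 1 um bead in water: gamma = 6*pi*eta*r ~ 8.4e-6 pN s/nm
        assert _default_drag(500.0) == pytest.approx(8.39e-6, rel=0.01)


class TestDeterminism:
    def test_same_seed_bitwise_identical(self):
        motor = tl.preset("md-dct")
        trap = tl.TrapParameters(stiffness=0.05)
        a = tl.simulate_fixed_trap(motor, trap, 1000.0, 5.0, seed=42)
        b = tl.simulate_fixed_trap(motor, trap, 1000.0, 5.0, seed=42)
        assert np.array_equal(a.bead_position, b.bead_position)
        assert np.array_equal(a.trap_position, b.trap_position)
        assert np.array_equal(a.force, b.force)

    def test_different_seeds_differ(self):
        motor = tl.preset("md-dct")
        trap = tl.TrapParameters(stiffness=0.05)
        a = tl.simulate_fixed_trap(motor, trap, 1000.0, 2.0, seed=1)
        b = tl.simulate_fixed_trap(motor, trap, 1000.0, 2.0, seed=2)
        assert not np.array_equal(a.bead_position, b.bead_position)


class TestDeterministicStepping:
    def test_noiseless_staircase_asymptotes_at_stall(self):
        # kBT=0, no backsteps/detachment: the force is a monotone staircase
        # with increments k*d, asymptoting at the stall force
        k, d, fs_stall = 0.05, 8.0, 2.0
        motor = quiet_motor(
            unloaded_velocity=400.0, stall_force=fs_stall, step_size=d, kBT=0.0
        )
        trace = tl.simulate_fixed_trap(
            motor, tl.TrapParameters(stiffness=k), 1e9, 5.0, seed=0, keep_raw=True
        )
        f_raw = k * (trace.raw["motor"] - trace.raw["trap"])
        assert np.all(np.diff(f_raw) >= -1e-12)  # monotone
        jumps = np.diff(f_raw)
        jumps = jumps[jumps > 1e-12]
        assert np.allclose(jumps, k * d)
        assert f_raw[-1] <= fs_stall + k * d  # no overshoot beyond one step
        assert f_raw[-1] >= 0.9 * fs_stall  # approached stall

    def test_filter_chain_preserves_constant_force_mean(self):
        # the stalled plateau is a constant-force segment: the filtered and
        # decimated force must preserve its mean to within 0.01 pN
        k = 0.05
        motor = quiet_motor(unloaded_velocity=400.0, stall_force=2.0, step_size=8.0, kBT=0.0)
        trace = tl.simulate_fixed_trap(
            motor, tl.TrapParameters(stiffness=k), 1e9, 5.0, seed=0, keep_raw=True
        )
        f_raw = k * (trace.raw["motor"] - trace.raw["trap"])
        # interior of the final plateau, away from filter edge effects
        sel = trace.time > 3.0
        assert np.mean(trace.force[sel]) == pytest.approx(f_raw[-1], abs=0.01)

    def test_atp_dependence_scales_rate(self):
        motor = tl.MotorModel(unloaded_velocity=600.0, stall_force=5.0, atp_km=30.0)
        r_sat, _ = motor.attempt_rate(0.0, 1e12)
        r_km, _ = motor.attempt_rate(0.0, 30.0)
        assert r_km == pytest.approx(0.5 * r_sat, rel=1e-9)

    def test_negative_rate_guard(self):
        motor = tl.MotorModel(unloaded_velocity=600.0, stall_force=5.0)
        r, _ = motor.attempt_rate(50.0, 1000.0)  # far beyond stall
        assert r == 0.0


class TestForceClamp:
    def test_clamp_holds_setpoint_tightly(self):
        # the clamp holds the preset motor at 2 pN about as tightly as the
        # instrument it emulates (~2.1 +- 0.3 pN)
        from tweezerlab.force_velocity import clamp_engaged_intervals

        trap = tl.TrapParameters(stiffness=0.05, mode="force_clamp", clamp_setpoint=2.0)
        trace = tl.simulate_force_clamp(tl.preset("md-dct"), trap, 1000.0, 15.0, seed=4)
        mask = np.zeros(len(trace), dtype=bool)
        for i0, i1 in clamp_engaged_intervals(trace):
            mask[i0:i1] = True
        engaged = trace.force[mask]
        assert len(engaged) > 3000
        assert np.mean(engaged) == pytest.approx(2.0, abs=0.1)
        assert np.std(engaged) <= 0.3

    def test_zero_velocity_motor_trap_stationary(self):
        trap = tl.TrapParameters(stiffness=0.05, mode="force_clamp", clamp_setpoint=1.0)
        trace = tl.simulate_force_clamp(quiet_motor(), trap, 1000.0, 5.0, seed=0)
        # motor generates no force, the set-point is never reached, the trap
        # never moves
        assert np.max(np.abs(trace.trap_position)) < 1e-9

    def test_proportional_controller_steady_state_offset(self):
        # noiseless quasi-continuous motor at velocity v: the pre-update
        # force error converges to v*k/(gain*clamp_rate)
        k, v, gain, rate = 0.05, 250.0, 0.8, 250.0
        motor = quiet_motor(
            unloaded_velocity=v, stall_force=1e9, step_size=0.5, kBT=0.0
        )
        trap = tl.TrapParameters(
            stiffness=k,
            mode="force_clamp",
            clamp_setpoint=2.0,
            clamp_gain=gain,
            clamp_rate=rate,
            clamp_range=1e9,
        )
        trace = tl.simulate_force_clamp(motor, trap, 1e9, 4.0, seed=0, keep_raw=True)
        f_det = k * (trace.raw["motor"] - trace.raw["trap"])
        t = trace.raw["time"]
        sel = t > 1.0
        # block maxima over one update period = the pre-update sawtooth peak
        period = int(round(len(t) / (t[-1] + t[1]) / rate))
        f_sel = f_det[sel]
        n_blocks = len(f_sel) // period
        peaks = f_sel[: n_blocks * period].reshape(n_blocks, period).max(axis=1)
        expected = v * k / (gain * rate)
        assert np.mean(peaks) - 2.0 == pytest.approx(expected, rel=0.10)

    def test_invalid_controller_settings_rejected(self):
        motor = tl.preset("md-dct")
        with pytest.raises(SimulationError):
            tl.simulate_force_clamp(
                motor,
                tl.TrapParameters(
                    stiffness=0.05, mode="force_clamp", clamp_setpoint=2, clamp_gain=0.0
                ),
            )
        with pytest.raises(SimulationError):
            tl.simulate_force_clamp(
                motor,
                tl.TrapParameters(
                    stiffness=0.05, mode="force_clamp", clamp_setpoint=2, clamp_gain=2.5
                ),
            )
        with pytest.raises(SimulationError):
            # mode mismatch
            tl.simulate_force_clamp(motor, tl.TrapParameters(stiffness=0.05))


class TestValidationAndErrors:
    def test_nonpositive_duration_rejected(self):
        with pytest.raises(SimulationError):
            tl.simulate_fixed_trap(
                tl.preset("md-dct"), tl.TrapParameters(stiffness=0.05), duration=0.0
            )

    def test_unstable_integration_step_refused(self):
        # oversample=1 at 3 kHz gives dt > gamma/k for a stiff trap+linkage
        trap = tl.TrapParameters(stiffness=0.06, oversample=1, filter_cutoff=1500.0)
        with pytest.raises(SimulationError, match="relaxation"):
            tl.simulate_fixed_trap(tl.preset("md-dct"), trap, duration=1.0)

    def test_trap_parameter_invariants(self):
        with pytest.raises(SimulationError):
            tl.TrapParameters(stiffness=-0.01)
        with pytest.raises(SimulationError):
            tl.TrapParameters(stiffness=0.05, filter_cutoff=2000.0, sample_rate=3000.0)
        with pytest.raises(SimulationError):
            tl.MotorModel(backstep_fraction=0.6)
        with pytest.raises(SimulationError):
            tl.MotorModel(detach_rate_per_dwell=1.5)

    def test_trace_validates_force_consistency(self, dct_fixed_trace):
        dct_fixed_trace.validate()


class TestMotileAssay:
    def test_closed_form_fractions(self):
        # lambda*C = 1: processive -> 1 - 1/e, nonprocessive -> 1 - 2/e
        big = 40000
        s = tl.generate_motile_assay(1.0, [1.0], big, "processive", seed=5)
        assert s.fraction[0] == pytest.approx(1 - np.exp(-1), abs=0.01)
        s = tl.generate_motile_assay(1.0, [1.0], big, "nonprocessive", seed=5)
        assert s.fraction[0] == pytest.approx(1 - 2 * np.exp(-1), abs=0.01)

    def test_zero_motor_density(self):
        s = tl.generate_motile_assay(0.0, [1.0, 2.0], 50, "processive", seed=1)
        assert np.all(s.fraction == 0.0)
        assert np.all(s.table["ci_low"] == 0.0)

    def test_assay_deterministic(self):
        a = tl.generate_motile_assay(1.0, [0.5, 1, 2], 25, "processive", seed=9)
        b = tl.generate_motile_assay(1.0, [0.5, 1, 2], 25, "processive", seed=9)
        assert a.table.equals(b.table)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            tl.generate_motile_assay(1.0, [0.0], 10, "processive", 0)
        with pytest.raises(ValueError):
            tl.generate_motile_assay(1.0, [1.0], 0, "processive", 0)
        with pytest.raises(ValueError):
            tl.generate_motile_assay(1.0, [1.0], 10, "sideways", 0)
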