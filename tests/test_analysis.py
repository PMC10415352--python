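import math

import numpy as np
import pytest

from oscmem.analysis import (FixedPointSet, StaircaseCurve, bump_decode,
                             count_held_levels, find_fixed_points,
                             level_spacing_s, phase_shift_decay, smooth_rate,
                             spikes_per_cycle)
from oscmem.core_models import SynapseParams
from oscmem.experiments import make_fixture


class TestSmoothRate:
    def test_empty_train_is_zero(self):
        t, r = smooth_rate([], 150.0, duration=1000.0)
        assert np.all(r == 0.0)

    def test_steady_train_converges_to_its_rate(self):
        rate_hz = 20.0
        spikes = np.arange(0.0, 5000.0, 1000.0 / rate_hz)
        t, r = smooth_rate(spikes, 150.0, duration=5000.0)
        tail = r[t > 1500.0]
        # converges to the true rate up to the periodic ripple of the
        # exponential filter (+- 1/(2 tau) in rate units)
        ripple = 1000.0 / (2 * 150.0) / (1 - math.exp(-50.0 / 150.0)) * 0.5
        assert abs(tail.mean() - rate_hz) < 1.0
        assert tail.max() - tail.min() < 2 * ripple

    def test_single_spike_impulse_response(self):
        tau = 100.0
        t, r = smooth_rate([0.0], tau, duration=500.0, dt=1.0)
        assert r[0] == pytest.approx(1000.0 / tau, rel=1e-9)
        assert np.allclose(r, r[0] * np.exp(-t / tau), rtol=0.02)

    def test_invalid_filter(self):
        with pytest.raises(ValueError):
            smooth_rate([1.0], 0.0, duration=10.0)


class TestSpikesPerCycle:
    def test_no_spikes_gives_zeros(self):
        counts, _ = spikes_per_cycle([], 0.05, t_start=0.0, t_end=500.0)
        assert np.all(counts == 0)
        assert len(counts) == 3  # 500 ms out of 125.66 ms cycles

    def test_locked_fixture_counts_two_per_cycle(self):
        fx = make_fixture("locked_train")
        sp = fx["spikes"]
        counts, _ = spikes_per_cycle(sp, fx["omega"], fx["phase"],
                                     t_start=sp.min() - 1.0,
                                     t_end=sp.max() + 1.0)
        inner = counts[1:-1]
        assert np.all(inner == fx["spikes_per_cycle"])

    def test_one_spike_at_each_peak(self):
        omega = 0.05
        T = 2 * math.pi / omega
        spikes = np.arange(10) * T  # at the cosine peaks
        counts, _ = spikes_per_cycle(spikes, omega, t_start=-T / 2,
                                     t_end=9.5 * T)
        assert np.all(counts == 1)


class TestFixedPointsFromSyntheticStaircase:
    """Fixed-point extraction on a hand-constructed staircase."""

    def _curve(self, syn, omega, onsets):
        """Nondecreasing staircase: level k from onsets[k] upward."""
        f_cyc = omega / (2 * math.pi) * 1000.0
        s = np.linspace(0.0, 0.55, 111)
        spc = np.zeros_like(s, dtype=int)
        for k in sorted(onsets):
            spc[s >= onsets[k]] = k
        rates = spc * f_cyc
        locked = np.ones_like(s, dtype=bool)
        return StaircaseCurve(s_grid=s, rates=rates, spc=spc, locked=locked)

    def test_expected_stable_and_unstable_points(self):
        syn = SynapseParams(tau_syn=150.0, alpha_syn=0.1)
        omega = 0.05
        ds = level_spacing_s(syn, omega)
        # plateau onsets chosen so levels 1 and 2 are self-consistent
        # (k*ds falls inside plateau k) while level 3 is not: the level-3
        # plateau starts above s = 3*ds
        onsets = {1: 0.6 * ds, 2: 1.5 * ds, 3: 3.2 * ds}
        curve = self._curve(syn, omega, onsets)
        fps = find_fixed_points(curve, 1.0, syn)
        assert fps.stable_levels(omega) == (0, 1, 2)
        kinds = [p.stability for p in fps.points]
        # stabilities alternate stable/unstable along the s axis
        assert kinds[0] == "stable"
        for a, b in zip(kinds, kinds[1:]):
            assert a != b
        # stable locations are exactly the self-consistency points k*ds
        s_stable = sorted(p.s for p in fps.stable)
        assert np.allclose(s_stable, [0.0, ds, 2 * ds], atol=1e-3)

    def test_quiescent_point_always_reported(self):
        syn = SynapseParams()
        curve = self._curve(syn, 0.05, {})
        fps = find_fixed_points(curve, 1.0, syn)
        assert fps.stable_levels(0.05) == (0,)


class TestBumpDecode:
    def test_single_active_neuron(self):
        r = np.zeros(16)
        r[8] = 5.0
        ang, amp = bump_decode(r)
        assert ang == pytest.approx(math.pi)
        assert amp == 5.0

    def test_uniform_rates_have_undefined_angle(self):
        ang, amp = bump_decode(np.full(12, 7.0))
        assert math.isnan(ang)
        assert amp == 7.0

    def test_two_bumps_decode_to_bisector(self):
        N = 64
        theta = 2 * np.pi * np.arange(N) / N
        r = np.exp(-0.5 * ((theta - 1.0) / 0.2) ** 2) \
            + np.exp(-0.5 * ((theta - 2.0) / 0.2) ** 2)
        ang, _ = bump_decode(r)
        oracle = np.angle(np.sum(r * np.exp(1j * theta))) % (2 * np.pi)
        assert ang == pytest.approx(oracle, abs=1e-12)
        assert ang == pytest.approx(1.5, abs=0.05)

    def test_silent_network(self):
        ang, amp = bump_decode(np.zeros(8))
        assert math.isnan(ang) and amp == 0.0


class TestCalibratedStaircaseProperties:
    def test_plateau_rates_are_quantized(self, calibrated_staircase, autapse):
        """Locked plateau rates are integer multiples of the drive frequency."""
        params, _, _, drive = autapse
        f_cyc = drive.omega / (2 * math.pi) * 1000.0
        cur = calibrated_staircase
        locked_nonzero = cur.locked & (cur.spc > 0)
        assert locked_nonzero.sum() >= 10
        rel_err = np.abs(cur.rates[locked_nonzero]
                         - cur.spc[locked_nonzero] * f_cyc) \
            / (cur.spc[locked_nonzero] * f_cyc)
        assert rel_err.max() < 0.01

    def test_spikes_per_cycle_nondecreasing_in_clamp(self, calibrated_staircase):
        assert np.all(np.diff(calibrated_staircase.spc) >= 0)

    def test_memory_range_holds_all_calibrated_levels(self, calibrated_staircase,
                                                      autapse):
        params, model, w, drive = autapse
        fps = find_fixed_points(calibrated_staircase, w, model.syn)
        assert fps.stable_levels(drive.omega) == \
            tuple(range(params["levels"] + 1))


class TestLevelCounting:
    def test_count_held_levels_logic(self):
        unit = 8.0
        rows = [{"rate": 8.0, "drift": 0.5},
                {"rate": 16.1, "drift": 1.0},
                {"rate": 24.0, "drift": 9.0}]   # drifting: not held
        assert count_held_levels(rows, unit) == 2
        rows[2]["drift"] = 0.5
        assert count_held_levels(rows, unit) == 3
        # indistinct levels are not double counted
        rows[1]["rate"] = 8.5
        assert count_held_levels(rows, unit) == 2


class TestPhaseShiftDecayEdgeCases:
    def test_identical_runs_give_zero_constant(self, autapse):
        from oscmem.simulator import SimConfig, simulate_clamped

        params, model, w, drive = autapse
        cfg = SimConfig(duration=1600.0, clamp_s=0.25)
        a = simulate_clamped(model, 0.25, W=[[w]], drives=drive, config=cfg)
        b = simulate_clamped(model, 0.25, W=[[w]], drives=drive, config=cfg)
        res = phase_shift_decay(a, b, drive.omega, t_after=400.0)
        assert res.tau_ms == 0.0
        assert not res.no_decay

    def test_different_counts_raise(self, autapse):
        from oscmem.drives import Pulse, PulseProtocol
        from oscmem.simulator import SimConfig, simulate_clamped

        params, model, w, drive = autapse
        cfg = SimConfig(duration=1600.0, clamp_s=0.25)
        a = simulate_clamped(model, 0.25, W=[[w]], drives=drive, config=cfg)
        proto = PulseProtocol(pulses=[Pulse(400.0, 300.0, 2.0)])
        b = simulate_clamped(model, 0.25, W=[[w]], drives=drive, config=cfg,
                             protocol=proto)
        if len(a.spikes[0]) != len(b.spikes[0]):
            from oscmem.analysis import IncomparableRunsError
            with pytest.raises(IncomparableRunsError):
                phase_shift_decay(a, b, drive.omega, t_after=300.0)
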