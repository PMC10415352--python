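import math

import numpy as np
import pytest

from oscmem.drives import (DriftSpec, DriveSpec, OUParams, Pulse,
                           PulseProtocol, alternating_pulse_protocol,
                           drifting_drive, heterogeneous_phases,
                           oscillatory_input, ou_step, protocol_current)


class TestOscillatoryInput:
    def test_reference_values(self):
        spec = DriveSpec(psi=1.5, omega=0.05)
        assert oscillatory_input(0.0, spec) == pytest.approx(1.5)
        t_quarter = (math.pi / 2) / spec.omega
        assert oscillatory_input(t_quarter, spec) == pytest.approx(0.0, abs=1e-12)

    def test_antiphase_pair_cancels(self):
        spec = DriveSpec(psi=2.0, omega=0.05, phase=np.array([0.0, math.pi]))
        for t in np.linspace(0.0, 500.0, 37):
            total = oscillatory_input(t, spec, 0) + oscillatory_input(t, spec, 1)
            assert total == pytest.approx(0.0, abs=1e-12)

    def test_zero_amplitude_is_silent(self):
        spec = DriveSpec(psi=0.0, omega=0.05)
        assert oscillatory_input(123.4, spec) == 0.0

    def test_omega_must_be_positive(self):
        with pytest.raises(ValueError):
            DriveSpec(psi=1.0, omega=0.0)

    def test_negative_amplitude_shifts_effective_phase(self):
        spec = DriveSpec(psi=-1.0, omega=0.05)
        assert spec.effective_phase() == pytest.approx(math.pi)
        troughs = spec.trough_times(300.0)
        # drive minima of -cos sit at multiples of the period
        assert troughs[0] == pytest.approx(0.0, abs=1e-9)


class TestOUNoise:
    def test_zero_sigma_decays_geometrically(self):
        p = OUParams(sigma_n=0.0, tau_n=10.0)
        rng = np.random.default_rng(0)
        x = 1.0
        for _ in range(5):
            x = ou_step(x, p, dt=1.0, rng=rng)
        assert x == pytest.approx((1.0 - 1.0 / 10.0) ** 5)

    def test_stationary_variance_matches_update_rule(self):
        """Monte-Carlo check of Var = sigma^2 (dt/tau) / (1 - (1-dt/tau)^2)."""
        p = OUParams(sigma_n=0.5, tau_n=10.0)
        dt = 0.5
        rng = np.random.default_rng(1234)
        x = np.zeros(20000)
        for _ in range(600):  # ~30 correlation times
            x = ou_step(x, p, dt, rng)
        a = 1.0 - dt / p.tau_n
        var_expected = p.sigma_n ** 2 * (dt / p.tau_n) / (1.0 - a * a)
        var_mc = float(np.var(x))
        se = var_expected * math.sqrt(2.0 / len(x))  # iid approximation
        assert abs(var_mc - var_expected) < 3.0 * se * 3.0

    def test_seeded_reproducibility(self):
        p = OUParams(sigma_n=0.3, tau_n=5.0)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(42)
            x = 0.0
            out.append([x := ou_step(x, p, 0.1, rng) for _ in range(50)])
        assert out[0] == out[1]

    def test_unstable_step_rejected(self):
        with pytest.raises(ValueError):
            ou_step(0.0, OUParams(sigma_n=1.0, tau_n=1.0), dt=1.0,
                    rng=np.random.default_rng(0))


class TestHeterogeneousPhases:
    def test_range_and_disabled_mode(self):
        rng = np.random.default_rng(7)
        ph = heterogeneous_phases(1, rng)
        assert 0.0 <= ph[0] < 2.0 * math.pi
        assert np.all(heterogeneous_phases(5, rng, enabled=False) == 0.0)

    def test_uniformity_by_rayleigh_statistic(self):
        rng = np.random.default_rng(2024)
        ph = heterogeneous_phases(10_000, rng)
        R = abs(np.mean(np.exp(1j * ph)))
        z = len(ph) * R ** 2
        assert z < -math.log(0.01)  # below the 1% critical value


class TestDriftingDrive:
    def test_reduces_to_plain_oscillation_without_noise(self):
        spec = DriveSpec(psi=1.0, omega=0.05)
        drift = DriftSpec(ou_amp=OUParams(0.0, 100.0),
                          ou_freq=OUParams(0.0, 100.0))
        t = np.arange(0.0, 200.0, 0.5)
        out, info = drifting_drive(spec, drift, t, N=3,
                                   rng=np.random.default_rng(0))
        ref = np.array([oscillatory_input(tk, spec) for tk in t])
        assert np.allclose(out, ref[:, None], atol=1e-10)
        assert info["clipped"] == 0

    def test_correlated_mode_shares_frequency_noise(self):
        spec = DriveSpec(psi=1.0, omega=0.05)
        drift = DriftSpec(ou_amp=OUParams(0.0, 100.0),
                          ou_freq=OUParams(0.01, 100.0), correlated=True)
        t = np.arange(0.0, 500.0, 0.5)
        out, _ = drifting_drive(spec, drift, t, N=4,
                                rng=np.random.default_rng(3))
        # all neurons' instantaneous phases identical -> identical signals
        assert np.allclose(out - out[:, :1], 0.0, atol=1e-12)

    def test_frequency_noise_diffuses_cycle_count(self):
        """Cycle-count variance across neurons grows ~linearly in time."""
        spec = DriveSpec(psi=1.0, omega=0.05)
        drift = DriftSpec(ou_amp=OUParams(0.0, 100.0),
                          ou_freq=OUParams(0.004, 50.0))
        t = np.arange(0.0, 6000.0, 1.0)
        out, _ = drifting_drive(spec, drift, t, N=160,
                                rng=np.random.default_rng(11))
        sign_flips = np.diff(np.signbit(out), axis=0)
        half = len(t) // 2
        cycles_half = sign_flips[:half].sum(axis=0) / 2.0
        cycles_full = sign_flips.sum(axis=0) / 2.0
        v_half, v_full = np.var(cycles_half), np.var(cycles_full)
        assert v_half > 0
        assert 1.4 < v_full / v_half < 3.2  # diffusive (ratio ~ 2)


class TestPulseProtocol:
    def test_current_inside_and_outside_pulses(self):
        proto = PulseProtocol(pulses=[Pulse(100.0, 100.0, 0.5),
                                      Pulse(400.0, 50.0, -0.8)])
        assert protocol_current(proto, 50.0) == 0.0
        assert protocol_current(proto, 150.0) == 0.5
        assert protocol_current(proto, 420.0) == -0.8  # negative pulses allowed
        assert protocol_current(proto, 460.0) == 0.0

    def test_overlapping_pulses_need_disjoint_targets(self):
        with pytest.raises(ValueError):
            PulseProtocol(pulses=[Pulse(0.0, 100.0, 1.0),
                                  Pulse(50.0, 100.0, 1.0)])
        # disjoint explicit targets may overlap in time
        proto = PulseProtocol(pulses=[Pulse(0.0, 100.0, 1.0, target=[0]),
                                      Pulse(50.0, 100.0, 1.0, target=[1])])
        assert protocol_current(proto, 60.0, neuron_index=0, N=2) == 1.0
        assert protocol_current(proto, 60.0, neuron_index=1, N=2) == 1.0

    def test_spatial_window_mask(self):
        p = Pulse(0.0, 10.0, 1.0, target={"center": math.pi,
                                          "width": math.pi / 2,
                                          "profile": "flat"})
        m = p.mask(16)
        assert m[8] == 1.0          # neuron at angle pi
        assert m[0] == 0.0          # opposite side
        g = Pulse(0.0, 10.0, 1.0, target={"center": math.pi,
                                          "width": math.pi / 2}).mask(16)
        assert g[8] == pytest.approx(1.0)
        assert g[8] > g[6] > g[4]   # Gaussian falloff

    def test_round_trip_through_dict(self):
        proto = alternating_pulse_protocol(5, amplitude=0.8, duration=150.0,
                                           spacing=1000.0)
        again = PulseProtocol.from_dict(proto.to_dict())
        assert [p.onset for p in again.pulses] == [p.onset for p in proto.pulses]
        assert [p.amplitude for p in again.pulses] == \
            [p.amplitude for p in proto.pulses]

    def test_alternating_compiler_signs(self):
        proto = alternating_pulse_protocol(4, amplitude=0.8, n_up_first=2)
        signs = [math.copysign(1, p.amplitude) for p in proto.pulses]
        assert signs[:2] == [1, 1]
        assert set(signs[2:]) <= {1.0, -1.0}
        assert len(proto.pulses) == 4
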