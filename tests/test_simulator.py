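import math

import numpy as np
import pytest

from oscmem.core_models import (IFParams, NO_LEAK, SynapseParams, WBParams,
                                wb_resting_state, wb_rhs, WBState)
from oscmem.drives import DriveSpec, OUParams, Pulse, PulseProtocol
from oscmem.simulator import (Drives, ModelSpec, SimConfig, SimulationError,
                              SimResult, detect_spikes, simulate,
                              simulate_clamped)


def wb_model(i0=0.0, **syn):
    return ModelSpec(kind="wb", N=1, wb=WBParams(I0=i0),
                     syn=SynapseParams(**syn))


class TestQuiescenceAndEnergy:
    def test_rest_is_silent_and_bounded(self):
        m = wb_model()
        res = simulate(m, config=SimConfig(duration=2000.0, record_V=1.0))
        assert len(res.spikes[0]) == 0
        assert np.ptp(res.V_trace) < 1e-6
        p = m.wb
        assert np.all(res.V_trace > p.E_K) and np.all(res.V_trace < p.E_Na)

    def test_subthreshold_drive_stays_quiescent(self, autapse):
        """The calibrated oscillation alone (even 5% stronger) never spikes."""
        params, model, w, drive = autapse
        for factor in (1.0, 1.05):
            d = DriveSpec(psi=params["psi"] * factor, omega=params["omega"])
            res = simulate(model, W=[[w]], drives=d,
                           config=SimConfig(duration=5000.0))
            assert len(res.spikes[0]) == 0


class TestNumericsAgainstReference:
    def test_kernel_matches_pure_python_rk4(self):
        """A few compiled steps reproduce an independent RK4 of wb_rhs."""
        m = wb_model(i0=0.3)  # suprathreshold bias: rich transient
        dt, n = 0.01, 400
        from oscmem.core_models import wb_gating_steady_state

        h64, n64 = wb_gating_steady_state(-64.0)
        res = simulate(m, config=SimConfig(duration=n * dt, dt=dt,
                                           record_V=dt),
                       init={"V": -64.0, "h": h64, "n": n64})
        V, h, nn = -64.0, h64, n64

        def rhs(V, h, nn):
            st = WBState(V=V, h=min(max(h, 0), 1), n=min(max(nn, 0), 1), s=0.0)
            dV, dh, dn, _ = wb_rhs(st, m.wb, m.syn, m.wb.I0)
            return dV, dh, dn

        trace = [V]
        for _ in range(n):
            k1 = rhs(V, h, nn)
            k2 = rhs(V + dt / 2 * k1[0], h + dt / 2 * k1[1], nn + dt / 2 * k1[2])
            k3 = rhs(V + dt / 2 * k2[0], h + dt / 2 * k2[1], nn + dt / 2 * k2[2])
            k4 = rhs(V + dt * k3[0], h + dt * k3[1], nn + dt * k3[2])
            V += dt / 6 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
            h += dt / 6 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
            nn += dt / 6 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
            h = min(max(h, 0.0), 1.0)
            nn = min(max(nn, 0.0), 1.0)
            trace.append(V)
        assert np.allclose(res.V_trace[:, 0], trace, atol=1e-8)

    def test_synaptic_decay_closed_form(self):
        m = wb_model(tau_syn=150.0, alpha_syn=0.1)
        res = simulate(m, config=SimConfig(duration=600.0, record_V=1.0),
                       init={"s": 0.5})
        expected = 0.5 * np.exp(-res.t_trace / 150.0)
        assert np.allclose(res.s_trace[:, 0], expected, rtol=1e-6, atol=1e-9)


class TestSpikes:
    def test_detect_spikes_basic(self):
        dt = 0.1
        t = np.arange(0.0, 20.0, dt)
        assert len(detect_spikes(np.full(50, -64.0), dt)) == 0
        V = -60.0 + 90.0 * np.exp(-0.5 * ((t - 10.0) / 0.6) ** 2)
        times = detect_spikes(V, dt)
        assert len(times) == 1
        assert times[0] == pytest.approx(10.0, abs=dt)

    def test_online_detection_matches_offline(self, autapse):
        params, model, w, drive = autapse
        cfg = SimConfig(duration=1500.0, record_V=0.01, clamp_s=0.25)
        res = simulate_clamped(model, 0.25, W=[[w]], drives=drive, config=cfg)
        offline = detect_spikes(res.V_trace[:, 0], 0.01)
        assert len(offline) == len(res.spikes[0]) > 0
        assert np.allclose(offline, res.spikes[0], atol=0.02)

    def test_if_threshold_crossing_and_reset(self):
        # non-leaky, constant current: first crossing at (thresh-reset)/I
        m = ModelSpec(kind="if", N=1, ifp=IFParams(tau=NO_LEAK, I0=0.5),
                      syn=SynapseParams())
        res = simulate(m, config=SimConfig(duration=100.0, record_V=0.01))
        expected_first = (m.ifp.V_thresh - m.ifp.V_reset) / 0.5
        assert res.spikes[0][0] == pytest.approx(expected_first, abs=0.05)
        isi = np.diff(res.spikes[0])
        assert np.allclose(isi, isi[0], atol=0.02)  # linear integration
        assert res.V_trace.min() >= m.ifp.V_reset - 1e-9


class TestDeterminismAndErrors:
    def test_identical_seeds_identical_results_under_noise(self, autapse):
        params, model, w, drive = autapse
        drv = Drives(oscillation=drive, input_noise=OUParams(0.2, 10.0))
        out = []
        for _ in range(2):
            cfg = SimConfig(duration=800.0, record_V=1.0, seed=77)
            out.append(simulate(model, W=[[w]], drives=drv, config=cfg,
                                init={"s": 0.15}))
        assert np.array_equal(out[0].V_trace, out[1].V_trace)
        assert np.array_equal(out[0].spikes[0], out[1].spikes[0])

    def test_runaway_firing_aborts_with_diagnostic(self):
        m = ModelSpec(kind="if", N=1, ifp=IFParams(tau=10.0, I0=0.3),
                      syn=SynapseParams(tau_syn=150.0, alpha_syn=0.1))
        with pytest.raises(SimulationError):
            simulate(m, W=[[50.0]], config=SimConfig(duration=3000.0),
                     init={"s": 1.0})

    def test_dimension_validation(self):
        m = wb_model()
        with pytest.raises(ValueError):
            simulate(m, W=np.ones((2, 2)), config=SimConfig(duration=10.0))
        with pytest.raises(ValueError):
            simulate(m, W=[[float("nan")]], config=SimConfig(duration=10.0))
        with pytest.raises(ValueError):
            SimConfig(duration=10.0, dt=0.0)


class TestClampedMode:
    def test_clamped_zero_without_drive_is_quiescent(self, autapse):
        _, model, w, _ = autapse
        res = simulate_clamped(model, 0.0, W=[[w]],
                               config=SimConfig(duration=1000.0))
        assert len(res.spikes[0]) == 0

    def test_same_plateau_same_spikes_per_cycle(self, autapse, level_ds):
        """Two nearby clamped levels on one staircase step lock identically."""
        from oscmem.analysis import spikes_per_cycle

        params, model, w, drive = autapse
        T = 2 * math.pi / drive.omega
        counts = []
        for s in (2.0 * level_ds * 0.97, 2.0 * level_ds * 1.03):
            res = simulate_clamped(model, s, W=[[w]], drives=drive,
                                   config=SimConfig(duration=16 * T))
            c, _ = spikes_per_cycle(res.spikes[0], drive.omega,
                                    t_start=8 * T, t_end=16 * T)
            counts.append(tuple(c))
        assert counts[0] == counts[1]
        assert len(set(counts[0])) == 1

    def test_nonleaky_if_rate_tracks_clamp_continuously(self):
        """No plateau: nearby clamped levels give different rates."""
        m = ModelSpec(kind="if", N=1, ifp=IFParams(tau=NO_LEAK, I0=-0.4),
                      syn=SynapseParams())
        drive = DriveSpec(psi=-1.0, omega=0.05)
        rates = []
        for s in (0.9, 0.95):
            res = simulate_clamped(m, s, W=[[1.0]], drives=drive,
                                   config=SimConfig(duration=3000.0))
            sp = res.spikes[0]
            rates.append(np.sum(sp >= 1000.0) / 2.0)
        assert rates[1] > rates[0]


class TestPersistenceIO:
    def test_hdf5_round_trip_and_text_export(self, tmp_path, autapse):
        params, model, w, drive = autapse
        proto = PulseProtocol(pulses=[Pulse(200.0, params["pulse_dur"],
                                            params["pulse_amp"])])
        cfg = SimConfig(duration=1200.0, record_V=5.0, seed=3)
        res = simulate(model, W=[[w]], drives=drive, protocol=proto,
                       config=cfg)
        path = tmp_path / "run.h5"
        res.save(path)
        back = SimResult.load(path)
        assert np.array_equal(back.spikes[0], res.spikes[0])
        assert np.array_equal(back.V_trace, res.V_trace)
        assert back.config["model"]["kind"] == "wb"
        txt = tmp_path / "spikes.txt"
        res.export_spikes_text(txt)
        lines = txt.read_text().strip().splitlines()
        assert len(lines) == len(res.spikes[0])
        nid, t0 = lines[0].split("\t")
        assert nid == "0" and float(t0) == pytest.approx(res.spikes[0][0],
                                                         abs=1e-4)
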