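"""Vectorized fixed-step network simulation.

``simulate`` advances a network of Wang-Buzsaki or integrate-and-fire units
with the classical fourth-order Runge-Kutta scheme at a fixed step
(default 0.01 ms).  The recurrent current to neuron i is sum_j w_ij s_j,
recomputed every step; spike-triggered increments of the synaptic
activation are applied at the end of the step in which the spike is
detected.  ``simulate_clamped`` freezes the feedback activation at a
constant, the analysis mode used to map steady-state staircases.

Spikes of the conductance-based model are the times of action-potential
peaks exceeding 0 mV; integrate-and-fire spikes are threshold crossings
followed by a reset (no interpolation within the step).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from . import _kernels
from .core_models import (IFParams, SynapseParams, WBParams, NO_LEAK,
                          wb_resting_state)
from .drives import DriveSpec, DriftSpec, OUParams, PulseProtocol

__all__ = [
    "SimConfig",
    "SimResult",
    "ModelSpec",
    "Drives",
    "simulate",
    "simulate_clamped",
    "detect_spikes",
]


@dataclass
class SimConfig:
    """Integration settings.

    record_V: subsample period of the voltage/activation traces in ms
    (default 1.0; spikes are always recorded at full resolution).
    clamp_s: when set, the feedback activation entering the recurrent
    current is frozen at this constant and the s-dynamics is bypassed.
    """

    duration: float
    dt: float = 0.01
    record_V: float = 1.0
    seed: int = 0
    clamp_s: float | None = None

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.duration <= self.dt:
            raise ValueError("duration must exceed dt")
        if self.record_V < self.dt:
            self.record_V = self.dt
        if self.clamp_s is not None and self.clamp_s < 0:
            raise ValueError("clamp_s must be nonnegative")


@dataclass
class ModelSpec:
    """Which point-neuron model each unit follows, plus synapse parameters.

    kind: 'wb' (Wang-Buzsaki conductance-based) or 'if'
    (integrate-and-fire; the leaky/non-leaky variant is selected by
    ``ifp.tau``).
    """

    kind: str
    N: int = 1
    wb: WBParams = field(default_factory=WBParams)
    ifp: IFParams = field(default_factory=IFParams)
    syn: SynapseParams = field(default_factory=SynapseParams)

    def __post_init__(self) -> None:
        if self.kind not in ("wb", "if"):
            raise ValueError("kind must be 'wb' or 'if'")
        if self.N < 1:
            raise ValueError("N must be at least 1")


@dataclass
class Drives:
    """Bundle of time-dependent inputs for one simulation."""

    oscillation: DriveSpec | None = None
    input_noise: OUParams | None = None
    drift: DriftSpec | None = None


class SimulationError(RuntimeError):
    pass


@dataclass
class SimResult:
    """Simulation output: per-neuron spike times, subsampled traces and
    full provenance (configuration and seeds)."""

    spikes: list
    t_trace: np.ndarray
    V_trace: np.ndarray
    s_trace: np.ndarray
    config: dict
    events: list = field(default_factory=list)
    final_state: dict = field(default_factory=dict)

    @property
    def N(self) -> int:
        return len(self.spikes)

    @property
    def duration(self) -> float:
        return float(self.config["config"]["duration"])

    def rates(self, t_start: float = 0.0, t_end: float | None = None) -> np.ndarray:
        """Mean firing rate (Hz) per neuron over [t_start, t_end]."""
        t_end = self.duration if t_end is None else t_end
        span = (t_end - t_start) / 1000.0
        return np.array([np.sum((sp >= t_start) & (sp < t_end)) / span
                         for sp in self.spikes])

    def all_spikes(self) -> np.ndarray:
        """(time, neuron) pairs sorted by time."""
        times = np.concatenate([sp for sp in self.spikes]) if self.spikes else np.empty(0)
        ids = np.concatenate([np.full(len(sp), i) for i, sp in enumerate(self.spikes)]) \
            if self.spikes else np.empty(0, dtype=int)
        order = np.argsort(times, kind="stable")
        return np.column_stack([times[order], ids[order]]) if len(times) else np.empty((0, 2))

    # -- persistence ---------------------------------------------------
    def save(self, path) -> None:
        """Persist to an HDF5 container (ragged spikes, traces, config)."""
        import h5py

        with h5py.File(path, "w") as f:
            f.attrs["config_json"] = json.dumps(self.config, default=_json_default)
            f.attrs["events_json"] = json.dumps(self.events)
            g = f.create_group("spikes")
            for i, sp in enumerate(self.spikes):
                g.create_dataset(str(i), data=np.asarray(sp))
            f.create_dataset("t_trace", data=self.t_trace)
            f.create_dataset("V_trace", data=self.V_trace)
            f.create_dataset("s_trace", data=self.s_trace)

    @classmethod
    def load(cls, path) -> "SimResult":
        import h5py

        with h5py.File(path, "r") as f:
            config = json.loads(f.attrs["config_json"])
            events = json.loads(f.attrs["events_json"])
            g = f["spikes"]
            spikes = [np.asarray(g[str(i)]) for i in range(len(g))]
            return cls(spikes=spikes, t_trace=np.asarray(f["t_trace"]),
                       V_trace=np.asarray(f["V_trace"]),
                       s_trace=np.asarray(f["s_trace"]),
                       config=config, events=events)

    def export_spikes_text(self, path) -> None:
        """Plain-text spike export: one 'neuron_id time_ms' pair per line."""
        with open(path, "w") as fh:
            for i, sp in enumerate(self.spikes):
                for t in sp:
                    fh.write(f"{i}\t{t:.5f}\n")


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return str(obj)


def _provenance(model, W, drives, protocol, config) -> dict:
    d = {
        "model": {"kind": model.kind, "N": model.N,
                  "wb": asdict(model.wb), "if": asdict(model.ifp),
                  "syn": {"tau_syn": model.syn.tau_syn,
                          "alpha_syn": model.syn.alpha_syn}},
        "config": asdict(config),
        "W_shape": list(np.shape(W)),
        "W_sum": float(np.sum(W)),
    }
    if drives.oscillation is not None:
        osc = drives.oscillation
        d["oscillation"] = {"psi": osc.psi, "omega": osc.omega,
                            "phase": np.asarray(osc.phase).tolist()}
    if drives.input_noise is not None:
        d["input_noise"] = asdict(drives.input_noise)
    if drives.drift is not None:
        d["drift"] = {"ou_amp": asdict(drives.drift.ou_amp),
                      "ou_freq": asdict(drives.drift.ou_freq),
                      "correlated": drives.drift.correlated}
    if protocol is not None:
        d["protocol"] = protocol.to_dict()
    return d


def _as_drives(drives) -> Drives:
    if drives is None:
        return Drives()
    if isinstance(drives, DriveSpec):
        return Drives(oscillation=drives)
    if isinstance(drives, Drives):
        return drives
    raise TypeError("drives must be a DriveSpec, Drives bundle, or None")


def simulate(model: ModelSpec, W=None, drives=None,
             protocol: PulseProtocol | None = None,
             config: SimConfig | None = None,
             init: dict | None = None) -> SimResult:
    """Run one network simulation and return its SimResult.

    W is the (N, N) weight matrix (scalar accepted for the N=1 autapse;
    None means zero coupling).  ``init`` optionally overrides the initial
    state with entries 'V', 'h', 'n', 's' (scalars broadcast).
    """
    if config is None:
        raise ValueError("config is required")
    N = model.N
    if W is None:
        W = np.zeros((N, N))
    W = np.atleast_2d(np.asarray(W, dtype=float))
    if W.shape != (N, N):
        raise ValueError(f"W has shape {W.shape}, expected ({N}, {N})")
    if not np.all(np.isfinite(W)):
        raise ValueError("weight matrix must be finite")
    dr = _as_drives(drives)

    osc = dr.oscillation
    psi = 0.0 if osc is None else float(osc.psi)
    omega = 1.0 if osc is None else float(osc.omega)
    phase0 = np.zeros(N) if osc is None else osc.phases(N)

    noise = dr.input_noise
    nsig = 0.0 if noise is None else float(noise.sigma_n)
    ntau = 1.0 if noise is None else float(noise.tau_n)
    if noise is not None and config.dt >= noise.tau_n:
        raise ValueError("dt must be smaller than the noise correlation time")

    drift = dr.drift
    drift_on = drift is not None
    damp_sig = drift.ou_amp.sigma_n if drift_on else 0.0
    damp_tau = drift.ou_amp.tau_n if drift_on else 1.0
    dfreq_sig = drift.ou_freq.sigma_n if drift_on else 0.0
    dfreq_tau = drift.ou_freq.tau_n if drift_on else 1.0
    drift_corr = bool(drift.correlated) if drift_on else False

    if protocol is None:
        p_onset = np.empty(0)
        p_off = np.empty(0)
        p_amp = np.empty((0, N))
    else:
        p_onset, p_off, p_amp = protocol.arrays(N)

    n_steps = int(round(config.duration / config.dt))
    rec_stride = max(1, int(round(config.record_V / config.dt)))
    n_rec = n_steps // rec_stride + 1
    V_out = np.empty((n_rec, N))
    s_out = np.empty((n_rec, N))
    cap = max(1024, int(N * config.duration * 1.2))  # ~1.2 kHz headroom
    spike_t = np.empty(cap)
    spike_i = np.empty(cap, dtype=np.int64)

    clamp_on = config.clamp_s is not None
    clamp_val = float(config.clamp_s) if clamp_on else 0.0
    seed = int(config.seed) % (2 ** 31)

    events: list[str] = []
    if model.kind == "wb":
        try:
            rest = wb_resting_state(model.wb)
        except ValueError:
            # suprathreshold bias: no equilibrium; start from a generic
            # hyperpolarized state and let the dynamics take over
            from .core_models import WBState, wb_gating_steady_state
            h64, n64 = wb_gating_steady_state(-64.0)
            rest = WBState(V=-64.0, h=h64, n=n64, s=0.0)
        V0 = np.full(N, rest.V)
        h0 = np.full(N, rest.h)
        n0 = np.full(N, rest.n)
        s0 = np.zeros(N)
        _apply_init(init, N, V=V0, h=h0, n=n0, s=s0)
        out = _kernels.run_wb(
            V0, h0, n0, s0,
            model.wb.g_Na, model.wb.g_K, model.wb.g_L,
            model.wb.E_Na, model.wb.E_K, model.wb.E_L,
            model.wb.phi, model.wb.C_m, model.wb.I0,
            W, model.syn.tau_syn, model.syn.alpha_syn, clamp_on, clamp_val,
            psi, omega, phase0, nsig, ntau,
            drift_on, damp_sig, damp_tau, dfreq_sig, dfreq_tau, drift_corr,
            p_onset, p_off, p_amp,
            config.dt, n_steps, rec_stride, seed,
            spike_t, spike_i, V_out, s_out)
        nspk, status, fail_t, fail_i, clips = out
        if clips:
            events.append(f"drift-clipping events: {clips}")
        final = {"V": V0.copy(), "h": h0.copy(), "n": n0.copy(), "s": s0.copy()}
    else:
        ifp = model.ifp
        V0 = np.full(N, ifp.V_reset, dtype=float)
        s0 = np.zeros(N)
        _apply_init(init, N, V=V0, s=s0)
        if drift_on:
            raise NotImplementedError("parameter drift is only wired for the "
                                      "Wang-Buzsaki network")
        nspk, status, fail_t, fail_i = _kernels.run_if(
            V0, s0,
            ifp.leaky, ifp.tau if ifp.leaky else 1.0,
            ifp.V_L, ifp.V_thresh, ifp.V_reset, ifp.I0,
            W, model.syn.tau_syn, model.syn.alpha_syn, clamp_on, clamp_val,
            psi, omega, phase0, nsig, ntau,
            p_onset, p_off, p_amp,
            config.dt, n_steps, rec_stride, seed,
            spike_t, spike_i, V_out, s_out)
        final = {"V": V0.copy(), "s": s0.copy()}

    if status == _kernels.STATUS_NONFINITE:
        raise SimulationError(
            f"non-finite state at t={fail_t:.3f} ms, neuron {fail_i}")
    if status == _kernels.STATUS_OVERFLOW:
        raise SimulationError(
            f"spike buffer overflow at t={fail_t:.3f} ms (runaway firing?)")

    spikes = [spike_t[:nspk][spike_i[:nspk] == i].copy() for i in range(N)]
    t_trace = np.arange(n_rec) * rec_stride * config.dt
    return SimResult(spikes=spikes, t_trace=t_trace, V_trace=V_out,
                     s_trace=s_out,
                     config=_provenance(model, W, dr, protocol, config),
                     events=events, final_state=final)


def _apply_init(init, N, **arrays):
    if not init:
        return
    for key, val in init.items():
        if key not in arrays:
            raise ValueError(f"unknown init key {key!r}")
        arrays[key][:] = np.broadcast_to(np.asarray(val, dtype=float), (N,))


def simulate_clamped(model: ModelSpec, s_const: float, W=None, drives=None,
                     config: SimConfig | None = None,
                     init: dict | None = None,
                     protocol: PulseProtocol | None = None) -> SimResult:
    """Simulation with the feedback activation frozen at ``s_const``.

    Spikes are still emitted and recorded, but they no longer feed back:
    the recurrent current is W @ (s_const * ones) for the whole run.
    """
    if s_const < 0:
        raise ValueError("s_const must be nonnegative")
    if config is None:
        raise ValueError("config is required")
    cfg = SimConfig(duration=config.duration, dt=config.dt,
                    record_V=config.record_V, seed=config.seed,
                    clamp_s=float(s_const))
    return simulate(model, W=W, drives=drives, protocol=protocol,
                    config=cfg, init=init)


def detect_spikes(V_segment: np.ndarray, dt: float,
                  peak_threshold: float = 0.0) -> np.ndarray:
    """Spike times from a contiguous voltage trace.

    A spike is a local maximum of V whose peak exceeds ``peak_threshold``
    (0 mV by convention for the conductance-based model); one spike is
    reported per suprathreshold excursion of a smooth action potential.
    """
    V = np.asarray(V_segment, dtype=float)
    if V.ndim != 1:
        raise ValueError("V_segment must be one-dimensional")
    if len(V) < 3:
        return np.empty(0)
    mid = V[1:-1]
    peaks = (mid > V[:-2]) & (mid > V[2:]) & (mid > peak_threshold)
    return (np.flatnonzero(peaks) + 1) * dt
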