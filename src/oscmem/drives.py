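"""Time-dependent inputs: subthreshold oscillatory drive, Ornstein-Uhlenbeck
input noise, drifting oscillation parameters, heterogeneous phases, and
timed pulse protocols.

The oscillatory drive is an injected current psi*cos(omega*t + phase_i); it
is deliberately not a conductance (no reversal potential).  Pulse protocols
carry the external inputs that the memory circuit must integrate and store,
including negative pulses used for downward memory steps and bump
termination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "DriveSpec",
    "OUParams",
    "DriftSpec",
    "Pulse",
    "PulseProtocol",
    "oscillatory_input",
    "ou_step",
    "heterogeneous_phases",
    "drifting_drive",
    "protocol_current",
    "alternating_pulse_protocol",
    "step_pulse_protocol",
]


@dataclass
class DriveSpec:
    """Oscillatory drive I(t) = psi * cos(omega * t + phase).

    psi: amplitude (uA/cm^2); omega: angular frequency (rad/ms); phase:
    scalar or per-neuron array of phase offsets (rad).
    """

    psi: float
    omega: float
    phase: float | np.ndarray = 0.0

    def __post_init__(self) -> None:
        if self.omega <= 0:
            raise ValueError("omega must be positive")

    @property
    def period(self) -> float:
        """Oscillation period in ms."""
        return 2.0 * math.pi / self.omega

    def phases(self, N: int) -> np.ndarray:
        """Per-neuron phase array of length N."""
        ph = np.asarray(self.phase, dtype=float)
        if ph.ndim == 0:
            return np.full(N, float(ph))
        if ph.shape != (N,):
            raise ValueError(f"phase array has shape {ph.shape}, expected ({N},)")
        return ph.copy()

    def effective_phase(self, neuron_index: int = 0) -> float:
        """Drive phase with a negative amplitude folded in as a pi shift."""
        ph = np.asarray(self.phase, dtype=float)
        phase_i = float(ph) if ph.ndim == 0 else float(ph[neuron_index])
        return phase_i + (math.pi if self.psi < 0 else 0.0)

    def trough_times(self, duration: float, neuron_index: int = 0) -> np.ndarray:
        """Times of drive minima in [0, duration]."""
        first = ((math.pi - self.effective_phase(neuron_index)) / self.omega) \
            % self.period
        return np.arange(first, duration + 1e-9, self.period)


@dataclass
class OUParams:
    """Ornstein-Uhlenbeck noise: amplitude sigma_n (uA ms^0.5 / cm^2) and
    correlation time tau_n (ms)."""

    sigma_n: float
    tau_n: float

    def __post_init__(self) -> None:
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be nonnegative")
        if self.tau_n <= 0:
            raise ValueError("tau_n must be positive")


@dataclass
class DriftSpec:
    """Slow stochastic drift of the oscillation parameters.

    Amplitude and angular frequency each follow baseline + OU deviation.
    Frequency noise is accumulated through the phase (the instantaneous
    frequency advances the phase each step), so the drive stays continuous;
    with ``correlated`` set, a single frequency-noise realization is shared
    by every neuron.
    """

    ou_amp: OUParams
    ou_freq: OUParams
    correlated: bool = False


def oscillatory_input(t, spec: DriveSpec, neuron_index: int = 0):
    """Oscillatory drive current at time(s) t for one neuron.

    Identically zero when psi == 0.
    """
    ph = np.asarray(spec.phase, dtype=float)
    phase_i = float(ph) if ph.ndim == 0 else float(ph[neuron_index])
    if spec.psi == 0.0:
        return np.zeros_like(np.asarray(t, dtype=float)) if np.ndim(t) else 0.0
    return spec.psi * np.cos(spec.omega * np.asarray(t, dtype=float) + phase_i) \
        if np.ndim(t) else spec.psi * math.cos(spec.omega * t + phase_i)


def ou_step(n_prev, params: OUParams, dt: float, rng: np.random.Generator):
    """One step of the discrete Ornstein-Uhlenbeck update.

    n_t = n_prev - n_prev*(dt/tau_n) + sigma_n * eta * sqrt(dt/tau_n),
    eta ~ N(0,1).  Works elementwise on arrays.  Requires dt < tau_n
    (the explicit update is unstable otherwise).
    """
    if dt >= params.tau_n:
        raise ValueError("dt must be smaller than tau_n (unstable update)")
    n_prev = np.asarray(n_prev, dtype=float)
    eta = rng.standard_normal(n_prev.shape) if n_prev.ndim else rng.standard_normal()
    out = n_prev - n_prev * (dt / params.tau_n) \
        + params.sigma_n * eta * math.sqrt(dt / params.tau_n)
    return out if n_prev.ndim else float(out)


def heterogeneous_phases(N: int, rng: np.random.Generator,
                         enabled: bool = True) -> np.ndarray:
    """Per-neuron oscillation phases, i.i.d. uniform on [0, 2*pi).

    With ``enabled=False`` (heterogeneity switched off) returns zeros so
    every neuron receives a perfectly phase-aligned drive.
    """
    if N < 1:
        raise ValueError("N must be at least 1")
    if not enabled:
        return np.zeros(N)
    return rng.uniform(0.0, 2.0 * math.pi, size=N)


def drifting_drive(spec: DriveSpec, drift: DriftSpec, t: np.ndarray,
                   N: int, rng: np.random.Generator,
                   freq_floor: float = 1e-6, amp_floor: float = 0.0):
    """Sample the drifting oscillatory drive on a uniform time grid.

    Returns (current, info) where ``current`` has shape (len(t), N).  The
    amplitude and frequency of each neuron's drive follow independent OU
    deviations around the baselines (one shared frequency process when
    ``drift.correlated``); phase accumulates the instantaneous frequency so
    that frequency noise never produces discontinuities.  Drifted values
    falling at or below zero are clipped at a small floor and the event is
    counted in ``info['clipped']``.

    With both OU amplitudes zero this reduces exactly to
    ``oscillatory_input`` evaluated on the grid.
    """
    t = np.asarray(t, dtype=float)
    if t.ndim != 1 or len(t) < 2:
        raise ValueError("t must be a 1-d grid with at least two points")
    dt = float(t[1] - t[0])
    phases0 = spec.phases(N)

    amp_dev = np.zeros(N)
    freq_dev = np.zeros(1 if drift.correlated else N)
    theta = np.zeros(N)  # accumulated phase beyond omega*t[0]
    out = np.empty((len(t), N))
    clipped = 0
    for k, tk in enumerate(t):
        amp = np.clip(spec.psi + amp_dev, amp_floor, None)
        omega_inst = spec.omega + (np.broadcast_to(freq_dev, (N,))
                                   if drift.correlated else freq_dev)
        omega_clipped = np.clip(omega_inst, freq_floor, None)
        clipped += int(np.sum(omega_inst != omega_clipped))
        clipped += int(np.sum(spec.psi + amp_dev < amp_floor))
        out[k] = amp * np.cos(spec.omega * t[0] + theta + phases0)
        theta = theta + omega_clipped * dt
        if drift.ou_amp.sigma_n > 0:
            amp_dev = ou_step(amp_dev, drift.ou_amp, dt, rng)
        if drift.ou_freq.sigma_n > 0:
            freq_dev = ou_step(freq_dev, drift.ou_freq, dt, rng)
    return out, {"clipped": clipped}


# ---------------------------------------------------------------------------
# Pulse protocols
# ---------------------------------------------------------------------------

@dataclass
class Pulse:
    """One rectangular input pulse.

    ``target`` selects receiving neurons: None (all neurons), an explicit
    index collection, or a spatial window dict
    {"center": angle_rad, "width": angle_rad, "profile": "gauss"|"flat"}
    on the ring coordinate theta_i = 2*pi*i/N.
    """

    onset: float
    duration: float
    amplitude: float
    target: object = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("pulse duration must be positive")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def mask(self, N: int) -> np.ndarray:
        """Per-neuron amplitude profile (length N), in units of amplitude."""
        if self.target is None:
            return np.ones(N)
        if isinstance(self.target, dict):
            center = float(self.target["center"])
            width = float(self.target["width"])
            profile = self.target.get("profile", "gauss")
            theta = 2.0 * math.pi * np.arange(N) / N
            d = np.angle(np.exp(1j * (theta - center)))  # wrapped distance
            if profile == "flat":
                return (np.abs(d) <= width / 2).astype(float)
            return np.exp(-0.5 * (d / (width / 2)) ** 2)
        m = np.zeros(N)
        m[np.asarray(list(self.target), dtype=int)] = 1.0
        return m


@dataclass
class PulseProtocol:
    """Ordered sequence of input pulses (the external input I_ext,i(t)).

    Pulses may overlap in time only when their targets are disjoint.
    """

    pulses: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.pulses = [p if isinstance(p, Pulse) else Pulse(**p) for p in self.pulses]
        self.pulses.sort(key=lambda p: p.onset)
        for a, b in zip(self.pulses, self.pulses[1:]):
            if b.onset < a.offset and _targets_may_overlap(a, b):
                raise ValueError(
                    f"pulses at t={a.onset} and t={b.onset} overlap in time "
                    "with non-disjoint targets")

    def arrays(self, N: int):
        """(onsets, offsets, per-neuron amplitude matrix) for the kernel."""
        P = len(self.pulses)
        onset = np.array([p.onset for p in self.pulses], dtype=float)
        off = np.array([p.offset for p in self.pulses], dtype=float)
        amp = np.zeros((P, N))
        for k, p in enumerate(self.pulses):
            amp[k] = p.amplitude * p.mask(N)
        return onset, off, amp

    def to_dict(self) -> dict:
        return {"pulses": [asdict(p) for p in self.pulses]}

    @classmethod
    def from_dict(cls, d: dict) -> "PulseProtocol":
        return cls(pulses=list(d.get("pulses", [])))


def _targets_may_overlap(a: Pulse, b: Pulse) -> bool:
    if a.target is None or b.target is None:
        return True
    if isinstance(a.target, dict) or isinstance(b.target, dict):
        return True  # spatial windows are treated conservatively
    return len(set(a.target) & set(b.target)) > 0


def protocol_current(protocol: PulseProtocol, t: float, neuron_index: int = 0,
                     N: int = 1) -> float:
    """External pulse current to one neuron at time t (0 outside pulses)."""
    total = 0.0
    for p in protocol.pulses:
        if p.onset <= t < p.offset:
            total += p.amplitude * p.mask(N)[neuron_index]
    return total


def alternating_pulse_protocol(n_pulses: int, amplitude: float,
                               duration: float = 100.0, spacing: float = 1000.0,
                               first_onset: float = 500.0,
                               seed: int | None = None,
                               n_up_first: int = 2) -> PulseProtocol:
    """Compile an up/down pulse sequence for temporal-integration runs.

    Builds ``n_pulses`` pulses of |amplitude| separated by ``spacing`` ms;
    the first ``n_up_first`` are positive, after which signs alternate with
    a seeded random shuffle of the remaining signs (never stepping the
    stored level below zero is the caller's concern).  With ``seed`` None
    the deterministic pattern +,+,-,+,-,... is used.
    """
    signs = [1] * min(n_up_first, n_pulses)
    rest = n_pulses - len(signs)
    if rest > 0:
        alt = [(-1) ** k for k in range(rest)]
        if seed is not None:
            np.random.default_rng(seed).shuffle(alt)
        signs += alt
    pulses = [Pulse(onset=first_onset + k * spacing, duration=duration,
                    amplitude=signs[k] * abs(amplitude))
              for k in range(n_pulses)]
    return PulseProtocol(pulses=pulses)


def step_pulse_protocol(n_steps: int, amplitude: float, duration: float = 100.0,
                        spacing: float = 1500.0, first_onset: float = 500.0,
                        target: object = None) -> PulseProtocol:
    """n_steps identical positive pulses: staircase-up loading protocol."""
    pulses = [Pulse(onset=first_onset + k * spacing, duration=duration,
                    amplitude=amplitude, target=target)
              for k in range(n_steps)]
    return PulseProtocol(pulses=pulses)
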