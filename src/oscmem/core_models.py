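"""Model definitions: Wang-Buzsaki conductance-based neuron, leaky/non-leaky
integrate-and-fire neuron, and a lumped firing-rate model.

All three models share the same positive-feedback memory motif: a unit (or
population) excites itself through a slow synapse, and an external
subthreshold oscillatory current gates the feedback loop.  The right-hand
sides defined here are pure functions used both directly (analysis, unit
tests) and as the reference against which the compiled integrator kernels
are checked.

Units follow the conventions of single-compartment cortical models:
voltages in mV, time in ms, currents in uA/cm^2, capacitance in uF/cm^2,
conductances in mS/cm^2.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np

__all__ = [
    "WBParams",
    "WBState",
    "SynapseParams",
    "IFParams",
    "RateParams",
    "NO_LEAK",
    "wb_rhs",
    "wb_gating_steady_state",
    "wb_resting_state",
    "if_rhs",
    "rate_rhs",
    "rate_feedback",
    "rate_fixed_points",
    "rate_trajectory",
]

#: Sentinel for the time constant of a non-leaky integrate-and-fire neuron.
#: The leak term is removed from the equations entirely (not approximated by
#: a large time constant), so the subthreshold voltage has no restoring drift.
NO_LEAK = math.inf


def _check_finite(*values: float) -> None:
    for v in values:
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite state or current")


@dataclass
class WBParams:
    """Wang-Buzsaki fast-spiking interneuron parameters.

    The kinetic rate functions (``alpha_m`` etc.) follow the original
    published model: instantaneous sodium activation m_inf(V), first-order
    h and n gating scaled by the temperature factor ``phi``.  ``I0`` is a
    constant bias current that shifts the resting potential; the calibrated
    default places rest a safe margin below spike threshold so that the
    oscillatory drive alone is subthreshold.
    """

    C_m: float = 1.0
    g_Na: float = 35.0
    g_K: float = 9.0
    g_L: float = 0.1
    E_Na: float = 55.0
    E_K: float = -90.0
    E_L: float = -65.0
    phi: float = 5.0
    I0: float = 0.0
    spike_peak_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.C_m <= 0:
            raise ValueError("C_m must be positive")
        if min(self.g_Na, self.g_K, self.g_L) < 0:
            raise ValueError("conductances must be nonnegative")
        if not (self.E_K < self.E_L < self.E_Na):
            raise ValueError("require E_K < E_L < E_Na")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class WBState:
    """Dynamical state of one Wang-Buzsaki unit.

    V: membrane potential (mV); h, n: inactivation/activation gating
    variables in [0, 1]; s: synaptic feedback activation (dimensionless,
    nonnegative), the slow variable that carries memory between
    oscillation cycles.
    """

    V: float
    h: float
    n: float
    s: float = 0.0

    def __post_init__(self) -> None:
        _check_finite(self.V, self.h, self.n, self.s)
        if not (0.0 <= self.h <= 1.0 and 0.0 <= self.n <= 1.0):
            raise ValueError("gating variables must lie in [0, 1]")
        if self.s < 0:
            raise ValueError("synaptic activation must be nonnegative")


@dataclass
class SynapseParams:
    """Slow excitatory (NMDA-like) synapse.

    Each presynaptic spike increments the activation ``s`` by ``alpha_syn``;
    between spikes ``s`` decays exponentially with ``tau_syn``.  A unit
    firing steadily at rate r (spikes/ms) therefore sustains a mean
    activation  s = alpha_syn * tau_syn * r,  which is the self-consistency
    relation used to locate memory fixed points.
    """

    tau_syn: float = 150.0
    alpha_syn: float = 0.1

    def __post_init__(self) -> None:
        if self.tau_syn <= 0:
            raise ValueError("tau_syn must be positive")
        if self.alpha_syn <= 0:
            raise ValueError("alpha_syn must be positive")


@dataclass
class IFParams:
    """Integrate-and-fire neuron.

    ``tau`` is the membrane leak time constant in ms; passing ``NO_LEAK``
    (math.inf) selects the non-leaky variant, in which the leak term is
    dropped entirely so that subthreshold voltage perturbations persist
    indefinitely ("voltage memory").  There is no refractory period.
    """

    tau: float = 10.0
    V_L: float = -65.0
    V_thresh: float = -59.9
    V_reset: float = -68.0
    I0: float = -0.4

    def __post_init__(self) -> None:
        if self.V_reset >= self.V_thresh:
            raise ValueError("V_reset must lie below V_thresh")
        if not (self.tau > 0):
            raise ValueError("tau must be positive (use NO_LEAK for no leak)")

    @property
    def leaky(self) -> bool:
        return math.isfinite(self.tau)


@dataclass
class RateParams:
    """Lumped firing-rate model  dr/dt = -r + f(r) + ext.

    nonlinear mode: f(x) = sqrt(w * [x - x_thr]_+), the canonical
    expansive-then-saturating feedback that produces bistability (the
    "low firing-rate problem").  linear mode: f(x) = linear_slope * x,
    which stores a continuum of rates only at exact tuning
    (linear_slope == 1) and otherwise drifts ("fine-tuning problem").
    """

    w: float = 75.0
    x_thr: float = 10.0
    mode: str = "nonlinear"
    linear_slope: float = 1.0

    def __post_init__(self) -> None:
        if self.w < 0 or self.x_thr < 0:
            raise ValueError("w and x_thr must be nonnegative")
        if self.mode not in ("nonlinear", "linear"):
            raise ValueError("mode must be 'nonlinear' or 'linear'")


# ---------------------------------------------------------------------------
# Wang-Buzsaki kinetics
# ---------------------------------------------------------------------------

def _alpha_m(V: float) -> float:
    x = V + 35.0
    if abs(x) < 1e-7:
        return 1.0
    return -0.1 * x / math.expm1(-0.1 * x)


def _beta_m(V: float) -> float:
    return 4.0 * math.exp(-(V + 60.0) / 18.0)


def _alpha_h(V: float) -> float:
    return 0.07 * math.exp(-(V + 58.0) / 20.0)


def _beta_h(V: float) -> float:
    return 1.0 / (math.exp(-0.1 * (V + 28.0)) + 1.0)


def _alpha_n(V: float) -> float:
    x = V + 34.0
    if abs(x) < 1e-7:
        return 0.1
    return -0.01 * x / math.expm1(-0.1 * x)


def _beta_n(V: float) -> float:
    return 0.125 * math.exp(-(V + 44.0) / 80.0)


def wb_gating_steady_state(V: float) -> tuple[float, float]:
    """Voltage-clamped steady-state values (h_inf, n_inf)."""
    ah, bh = _alpha_h(V), _beta_h(V)
    an, bn = _alpha_n(V), _beta_n(V)
    return ah / (ah + bh), an / (an + bn)


def wb_membrane_current(V: float, h: float, n: float, p: WBParams) -> float:
    """Total intrinsic membrane current -I_Na - I_K - I_L at (V, h, n)."""
    am, bm = _alpha_m(V), _beta_m(V)
    m_inf = am / (am + bm)
    i_na = p.g_Na * m_inf ** 3 * h * (V - p.E_Na)
    i_k = p.g_K * n ** 4 * (V - p.E_K)
    i_l = p.g_L * (V - p.E_L)
    return -(i_na + i_k + i_l)


def wb_rhs(state: WBState, params: WBParams, syn: SynapseParams,
           I_total: float) -> tuple[float, float, float, float]:
    """Time derivative (dV/dt, dh/dt, dn/dt, ds/dt) of a W-B unit.

    ``I_total`` is the instantaneous sum of synaptic, bias, oscillatory and
    external currents.  The returned ds/dt contains only the passive decay
    -s/tau_syn; spike-triggered increments of ``s`` are impulsive events
    handled by the simulator between integration steps.
    """
    _check_finite(state.V, state.h, state.n, state.s, I_total)
    V, h, n = state.V, state.h, state.n
    dV = (wb_membrane_current(V, h, n, params) + I_total) / params.C_m
    dh = params.phi * (_alpha_h(V) * (1.0 - h) - _beta_h(V) * h)
    dn = params.phi * (_alpha_n(V) * (1.0 - n) - _beta_n(V) * n)
    ds = -state.s / syn.tau_syn
    return dV, dh, dn, ds


def wb_resting_state(params: WBParams, I_extra: float = 0.0) -> WBState:
    """Resting state found by bisection on the steady-state current balance.

    At rest h and n sit at their voltage-clamped steady states, so the
    equilibrium voltage is the root of the one-dimensional current-balance
    F(V) = membrane current at (V, h_inf(V), n_inf(V)) + I0 + I_extra.
    """

    def F(V: float) -> float:
        h_inf, n_inf = wb_gating_steady_state(V)
        return wb_membrane_current(V, h_inf, n_inf, params) + params.I0 + I_extra

    # The balance F(V) is non-monotonic (persistent-sodium window current),
    # so scan upward for the first +/- sign change: the stable equilibrium.
    grid = np.arange(-90.0, -40.0, 0.25)
    lo = hi = None
    for a, b in zip(grid, grid[1:]):
        if F(a) > 0.0 >= F(b):
            lo, hi = a, b
            break
    if lo is None:
        raise ValueError("no stable resting point found in [-90, -40] mV")
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        if F(lo) * F(mid) <= 0:
            hi = mid
        else:
            lo = mid
    V0 = 0.5 * (lo + hi)
    h0, n0 = wb_gating_steady_state(V0)
    return WBState(V=V0, h=h0, n=n0, s=0.0)


# ---------------------------------------------------------------------------
# Integrate-and-fire
# ---------------------------------------------------------------------------

def if_rhs(V: float, params: IFParams, I_total: float) -> float:
    """Subthreshold voltage derivative of the IF neuron.

    Non-leaky variant: pure current integration, dV/dt = I_total.
    Leaky variant adds the restoring term -(V - V_L)/tau.
    """
    _check_finite(V, I_total)
    if params.leaky:
        return -(V - params.V_L) / params.tau + I_total
    return I_total


# ---------------------------------------------------------------------------
# Rate model
# ---------------------------------------------------------------------------

def rate_feedback(r, params: RateParams):
    """Feedback drive f(r); vectorized over r."""
    r = np.asarray(r, dtype=float)
    if params.mode == "nonlinear":
        out = np.sqrt(params.w * np.clip(r - params.x_thr, 0.0, None))
    else:
        out = params.linear_slope * r
    return out if out.ndim else float(out)


def rate_rhs(r: float, params: RateParams, ext: float = 0.0) -> float:
    """dr/dt = -r + f(r) + ext  (r in Hz, time in units of the rate decay)."""
    if r < 0:
        raise ValueError("rate must be nonnegative")
    return -r + rate_feedback(r, params) + ext


def rate_fixed_points(params: RateParams) -> np.ndarray:
    """Positive fixed points of the autonomous nonlinear rate model.

    Solves f(r) = r above threshold:  sqrt(w (r - x_thr)) = r  gives
    r^2 - w r + w x_thr = 0.  Returns the real positive roots in
    increasing order (the lower root is unstable, the upper stable);
    r = 0 is always a stable fixed point and is not included.
    """
    if params.mode != "nonlinear":
        raise ValueError("fixed-point formula applies to the nonlinear mode")
    roots = np.roots([1.0, -params.w, params.w * params.x_thr])
    roots = np.sort(roots[np.isreal(roots)].real)
    return roots[roots > params.x_thr]


def rate_trajectory(r0: float, params: RateParams, t_end: float,
                    ext=None, n_points: int = 500):
    """Integrate the rate model from r0; returns (t, r(t)).

    ``ext`` may be None, a constant, or a callable of t.  The rate is
    rectified at zero (firing rates cannot be negative).
    """
    from scipy.integrate import solve_ivp

    if ext is None:
        ext_fn = lambda t: 0.0
    elif callable(ext):
        ext_fn = ext
    else:
        ext_fn = lambda t, c=float(ext): c

    def rhs(t, y):
        r = max(y[0], 0.0)
        return [rate_rhs(r, params, ext_fn(t))]

    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), [r0], t_eval=t_eval,
                    rtol=1e-8, atol=1e-10, max_step=t_end / 50)
    return sol.t, np.clip(sol.y[0], 0.0, None)
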