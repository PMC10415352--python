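"""Committed default parameter sets.

The oscillatory-autapse operating point below was produced by
``analysis.calibrate_oscillatory_regime`` (staircase measurement on a fine
clamped-current grid followed by margin-optimal placement of the feedback
line) and verified by free-running persistence and warm-started detuning
runs.  Provenance: calibrated by this package, not taken verbatim from any
published parameter table.

All currents are uA/cm^2, times ms, angular frequencies rad/ms.
"""

from __future__ import annotations

# Oscillatory Wang-Buzsaki autapse: three robust nonzero memory levels
# (spikes-per-cycle 1..3) at an 8 Hz drive, quiescent at zero feedback.
# The strong-drive regime (psi = 3) places the locked plateaus in a nearly
# uniformly spaced part of the f-I relation, which maximizes detuning and
# noise robustness of the level set.
WB_AUTAPSE = {
    "psi": 3.0,           # oscillation amplitude
    "omega": 0.05,        # rad/ms -> period 125.66 ms (7.96 Hz)
    "I0": -2.3894,        # bias current (rest sits well below threshold)
    "w": 3.894,           # autapse weight
    "alpha_syn": 0.1,     # s increment per spike
    "tau_syn": 150.0,     # slow synaptic time constant
    "levels": 3,          # calibrated number of nonzero stable levels
    "pulse_amp": 0.55,    # external pulse stepping the level up by one
    "pulse_amp_down": 0.35,  # pulse stepping the level down by one
    "pulse_dur": 150.0,   # ms
}

# Leaky / non-leaky integrate-and-fire single neuron under oscillatory
# drive (phase-locking analysis).  tau, thresholds and drive follow the
# published operating point for this model class.
IF_NEURON = {
    "tau": 10.0,
    "V_L": -65.0,
    "V_thresh": -59.9,
    "V_reset": -68.0,
    "I0": -0.4,
    "psi": -1.0,
    "omega": 0.05,
}

# Approximately linear spiking autapse (integrator surrogate): leaky IF
# with slow excitatory feedback, no oscillation; the feedback weight is
# produced by analysis.tune_linear_autapse (marginal-stability bisection).
LINEAR_SURROGATE = {
    "tau": 10.0,
    "V_L": -65.0,
    "V_thresh": -59.9,
    "V_reset": -68.0,
    "I0": 0.3,
    "tau_syn": 150.0,
    "alpha_syn": 0.1,
    "w": 3.0,             # placeholder; retuned at run time
    "target_rate": 30.0,  # Hz held by the tuned integrator
}

# Ring network (symmetric bump attractor) and directed (sequence) network.
# A_total/B_total are N * A and N * B so the recurrent drive at a given
# bump shape is independent of network size.  Calibrated so a bump of
# half-width ~pi/4 at level k feeds its center the same current as the
# autapse at level k, with strong surround inhibition.
RING = {
    "A_total": -112.0,
    "B_total": 147.6,
    "N": 200,
    "stim_width": 1.0471975511965976,   # pi/3 Gaussian stimulus window
    "level_amps": [0.8, 1.2, 1.6],      # pulse amplitudes storing levels 1..3
}
DIRECTED = {
    "A_total": -90.0,
    "B_total": 134.0,
    "C_frac": 0.125,      # connection footprint C = C_frac * N
    "N": 200,
    "stim_width": 1.0471975511965976,
}
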