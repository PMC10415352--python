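# Methods

## The model class

`oscmem` simulates positive-feedback spiking memory circuits gated by a
subthreshold oscillatory drive. The membrane potential of each
Wang–Buzsáki (W-B) unit obeys the current-balance equation

    C_m dV_i/dt = -I_Na(V_i, h_i) - I_K(V_i, n_i) - I_L(V_i)
                  + I_syn,i + I_0 + psi*cos(omega*t + phi_i) + I_ext,i(t)

with the published fast-spiking-interneuron kinetics (instantaneous sodium
activation m_inf(V); first-order h and n with temperature factor phi = 5;
g_Na = 35, g_K = 9, g_L = 0.1 mS/cm^2; E_Na = 55, E_K = -90, E_L = -65 mV;
C_m = 1 uF/cm^2). Every kinetic constant is exposed through `WBParams`.
Spikes are the times of action-potential peaks exceeding 0 mV.

The recurrent current is I_syn,i = sum_j w_ij s_j, where the slow
synaptic activation obeys

    ds_j/dt = -s_j / tau_syn  +  (jump of alpha_syn at each spike of j).

A unit firing steadily at rate r (spikes/ms) therefore sustains
s = alpha_syn * tau_syn * r, which is the self-consistency relation used
throughout the analysis. We use the convention that one presynaptic spike
increments s by `alpha_syn` directly; writing the delta-function source
with the time constant on the left-hand side instead only rescales
alpha_syn.

Integrate-and-fire variants (for the phase-locking analysis) evolve
dV/dt = -(V - V_L)/tau + I_total, threshold -59.9 mV, reset -68 mV, no
refractory period; the non-leaky variant drops the leak term entirely
rather than approximating it with a large tau, so subthreshold voltage
offsets persist exactly. The lumped rate model dr/dt = -r + f(r) + input
uses f(x) = sqrt(w [x - x_thr]_+) (w = 75, x_thr = 10 Hz) or a linear
f(x) = slope * x.

## Numerical integration

Fixed-step fourth-order Runge–Kutta at dt = 0.01 ms (halving dt moves no
spike by more than 0.1 ms over a 2 s run; this is asserted in the test
suite). Within one step the recurrent current is attenuated analytically
at the stage times (all s_j share the decay factor exp(-dt/tau_syn)); s
itself is integrated exactly as exponential decay plus spike-triggered
jumps applied at the end of the step in which the peak is detected. At
dt = 0.01 ms the sub-step placement of the jump is below integrator
tolerance.

The network current W @ s is maintained incrementally: each step it is
multiplied by the shared decay factor, and each spike of neuron j adds
alpha_syn * W[:, j]. This is algebraically identical to recomputing the
matrix–vector product every step (a full recomputation resynchronizes the
accumulator every 50 000 steps to cap round-off) and reduces the
per-step cost from O(N^2) to O(N), which is what makes the 1000-neuron
experiments run in minutes on one CPU core.

Integrate-and-fire threshold crossings are detected by sign change within
a step and reset at step end, without interpolation. Ornstein–Uhlenbeck
input noise follows the discrete update
n_t = n_{t-dt} (1 - dt/tau_n) + sigma_n eta sqrt(dt/tau_n), eta ~ N(0,1),
one update per step, held constant within the step. All stochastic terms
run from a single seed; identical seeds reproduce results bit for bit.

## Calibrated operating point

There is no canonical published parameter table for this operating regime
(autapse weight, drive amplitude and frequency, bias current, network
couplings), so the package ships a calibration procedure
(`analysis.calibrate_oscillatory_regime`) and one committed calibrated
default (in `oscmem.defaults`; provenance: produced by that calibration,
not taken from an external table):

    psi = 3.0 uA/cm^2, omega = 0.05 rad/ms (7.96 Hz), I0 = -2.3894,
    w = 3.894, alpha_syn = 0.1, tau_syn = 150 ms, three nonzero levels.

Calibration measures the clamped staircase of spikes-per-cycle against
constant current, extracts the locked plateaus, and places the feedback
line (intercept I0, slope w * ds per level, where ds = alpha_syn *
tau_syn * omega / 2 pi) to maximize the symmetric detuning margin of the
level set {0..3}, subject to the zero-feedback state staying quiescent
with headroom for a 5 % stronger drive. The strong-drive regime was chosen
because the plateaus there are nearly uniformly spaced in current
(spacings 0.54, 0.48, 0.42, 0.42 uA/cm^2 ...), which simultaneously
maximizes detuning robustness and the tolerance of a heterogeneous network
to quenched weight noise: the mean-field loop gain of a noisy network is
approximately (w * ds) / (local plateau spacing), and spacing uniformity
keeps it at or below one across the occupied levels.

Verification (`analysis.verify_regime`) then checks, by free-running
simulation: persistence of every level (a small ensemble of initial
activations probes the orbit, because a cold start at the nominal mean s
can fall outside the basin — within a cycle s is a sawtooth whose phase
the initial condition does not know); spiking termination within each
cycle (a spike-free gap of at least a quarter period); trough bridging
(s at each cycle boundary at least `bridge_frac` — default 0.5, measured
0.70–0.77 at the defaults — of its maximum over the preceding cycle); and
warm-started weight detuning by ±5 %, matching the protocol of detuning a
running memory.

External pulses stepping the stored level by exactly one are calibrated to
+0.55 uA/cm^2 (up) and -0.35 (down), 150 ms each; the down step acts on
the trough-bridging portion of the synaptic sawtooth and needs less
charge. Stepping is reliable at nearly every drive phase (pulses roughly
twice as strong occasionally move two levels). Weight-disordered networks
use a stronger loading pulse (0.8) because the per-neuron stepping charge
is dispersed; it advances the population mean by about one level.

## Analyses

- Staircase (`analysis.staircase`): steady-state rate and modal
  spikes-per-cycle versus clamped feedback, burn-in max(10 cycles,
  5 tau_syn); non-locked grid points (count not constant after burn-in)
  are flagged, never dropped. Fixed-point extraction locates zero
  crossings of g(s) = alpha_syn tau_syn r(s) - s between grid points;
  crossings on flat locked plateaus are stable (the discrete cycle map is
  contracting there), riser crossings unstable, crossings flanked by
  non-locked points are reported as `unlocked`. Detuning comparisons use
  a staircase grid spanning the calibrated memory range
  (0 .. (levels + 0.5) ds): stable fixed points can only sit at s = k ds,
  so this grid compares exactly the in-use level set, as in a staircase
  plot over a finite feedback range.
- Rate estimation: causal exponential filter normalized so a steady train
  converges to its rate; the default filter constant equals tau_syn.
- Phase-shift decay: after a perturbing pulse placed in the
  suprathreshold portion of a cycle, spike-time offsets between perturbed
  and baseline runs are collected per cycle and regressed (log magnitude)
  against cumulative subthreshold time — the leak only acts between
  spikes. Offsets below max(0.1 % of the period, 3 dt) are noise floor;
  in deterministic fixed-step runs the floor is the spike-timing
  resolution. A fitted constant above 50 periods, or non-shrinking
  offsets, is reported as "no decay" (the non-leaky signature).
  `perturbation_experiment` additionally converts spike-time offsets to
  voltage offsets using the analytic subthreshold slope at each crossing
  and fits the voltage offset across a spike-free gap; for the linear
  subthreshold dynamics this recovers the leak constant essentially
  exactly, whereas the raw spike-offset fit absorbs slope asymmetries
  between burst start and burst end (up to tens of percent). The decay
  experiments use a 25 Hz drive: at the 8 Hz operating frequency a 10 ms
  leak erases the offset below timing resolution within a single cycle.
- Linear integrator surrogate: the comparison model is a leaky IF neuron
  with slow excitatory feedback whose weight is bisected to the marginal
  (tangency) point between decay-to-quiescence and growth
  (`tune_linear_autapse`); the exact equations of the original comparison
  model are in an unavailable supplement, and this surrogate reproduces
  its defining property — persistence only under fine tuning. Persistence
  classification uses the final-second rate against the held rate with a
  factor-1.5 band.
- Network level counting: population rate per inter-pulse window; a
  window holds a level when separated from the previous level by at least
  half the level unit (omega/2pi) and its within-window drift is below
  0.35 of the unit. The quiescent baseline counts as one stored level (it
  is a stable fixed point of the memory circuit).

## Spatial networks

Ring (w_ij = A + B cos(2 pi (i-j)/N)) and directed
(w_ij = [A + B cos(4 pi (i-j)/N + 0.1)] H(C - |i-j|)) couplings are
stored as dense matrices; A_total = N*A and B_total = N*B are the
size-invariant parameters. Self-connections are kept (the kernels do not
exclude i = j), the directed |i - j| is the plain index difference (a
wrapped variant exists behind a flag), and stimulus pulses use a Gaussian
angular profile (width pi/3 by default).

Ring defaults (A_total = -112, B_total = 147.6) were derived by solving
for the couplings that place the center of a two-band bump at 75 % of the
second plateau and its outer band at 70 % of the first, then verified:
localized pulses of 0.8 / 1.2 / 1.6 uA/cm^2 store bumps of 8 / 16 / 24 Hz
peak rate at the same decoded angle, persisting for seconds; without the
oscillation the same stimuli store nothing (and much stronger ones only
the saturated state) — binary storage. Termination uses a global
inhibitory pulse.

Directed defaults (A_total = -90, B_total = 134, C = N/8) give a
monotonically drifting, persistent one-spike-per-cycle bump under the
drive and only decay or a single saturated (~330 Hz) traveling level
without it. Graded amplitudes of the *traveling* bump were not attained
at this operating point: the 150 ms synapse (1.2 cycles) low-passes
recruitment at the leading edge, so a drifting bump re-forms at the
lowest level regardless of its initial amplitude, and couplings negative
enough at the band edge to stabilize graded static bumps kill the
traveling wave. The corresponding check in the test suite documents this
as a known limitation of the calibrated regime.

## What the synthetic conditions do and do not show

All inputs are generated by the package itself (configurations, seeds,
pulse protocols); there is no recorded data anywhere in the pipeline.
The noise models are idealized: quenched Gaussian weight disorder,
Ornstein–Uhlenbeck input current (correlation time 10 ms, a typical fast
synaptic background; the reference value is in an unavailable
supplement), OU drift of drive amplitude/frequency with phase-continuous
frequency accumulation (correlated or independent across neurons).
Passing tests show that the phase-locking mechanism and its robustness
ordering hold for conductance-based dynamics under these idealized
perturbations at desk scale; they do not show robustness to conductance
noise, heterogeneous cell parameters, synaptic failure, or biological
oscillation waveforms, none of which are modeled.

## Problem sizes and runtimes

Default problem sizes were chosen so the full test suite and the
acceptance script each run in minutes on a single core: staircases use
30–34 clamped points at 12 measurement cycles per point; detuning sweeps
probe ±{2.5, 5, 7.5, 10, 12.5} %; network experiments use 1000
neurons over ~4.5 s protocols (the scale at which the weight-noise
robustness figures are quoted) (smaller N is a first-class parameter
for quick runs, but note that quenched weight-noise effects scale as
ratio/sqrt(N), so the noise-tolerance figures are only comparable at
matched N).

## Known limitations

- The committed operating point is a calibration product; absolute
  currents and weights are meaningful only within this package, and the
  reproducible content is the mechanism and its robustness properties.
- Storage capacity is three nonzero levels at 8 Hz; more levels require a
  lower drive frequency and correspondingly longer synaptic bridging, at
  the cost of robustness (the frequency/capacity trade-off).
- The down-step pulse can overshoot to quiescence in strongly
  weight-disordered networks (individual neurons sit at heterogeneous
  effective levels).
- Graded traveling bumps in the directed network are not realized (see
  above).
- No plotting beyond text/CSV reports; no adaptive integration; no
  event-driven exact IF integration; no multi-compartment models or
  plasticity.
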