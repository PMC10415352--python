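"""Compiled fixed-step RK4 integrators for the spiking models.

Two kernels (Wang-Buzsaki and integrate-and-fire) share the same structure:
per step the recurrent current W @ s is computed once and its within-step
exponential decay is applied analytically at the Runge-Kutta stage times
(s itself is integrated exactly: pure decay plus spike-triggered jumps).
Drive, noise, pulse and drift terms are evaluated inside the loop so no
per-step input arrays need to be materialized.

Status codes returned by the kernels:
0 = ok, 1 = non-finite state encountered, 2 = spike buffer overflow.
"""

import math

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_NONFINITE = 1
STATUS_OVERFLOW = 2


@njit(cache=True, fastmath=False)
def _pulse_current(t, p_onset, p_off, p_amp, out):
    out[:] = 0.0
    for p in range(p_onset.shape[0]):
        if p_onset[p] <= t < p_off[p]:
            for i in range(out.shape[0]):
                out[i] += p_amp[p, i]


@njit(cache=True, fastmath=False)
def run_wb(V, h, n, s,
           gna, gk, gl, ena, ek, el, phi, cm, i0,
           W, tau_syn, alpha_syn, clamp_on, clamp_val,
           psi, omega, phase0,
           noise_sigma, noise_tau,
           drift_on, damp_sigma, damp_tau, dfreq_sigma, dfreq_tau, drift_corr,
           p_onset, p_off, p_amp,
           dt, n_steps, rec_stride, seed,
           spike_t, spike_i, V_out, s_out):
    N = V.shape[0]
    np.random.seed(seed)

    e_half = math.exp(-0.5 * dt / tau_syn)
    e_full = e_half * e_half
    cap = spike_t.shape[0]
    nspk = 0
    clips = 0

    vprev = V.copy()
    vprev2 = V.copy()
    noise = np.zeros(N)
    amp_dev = np.zeros(N)
    nfreq = N if not drift_corr else 1
    freq_dev = np.zeros(nfreq)
    theta = np.zeros(N)           # accumulated drift phase
    pulse = np.zeros(N)
    # Recurrent current W @ s maintained incrementally: all s_j share the
    # same exponential decay (isyn scales by e_full each step) and spikes
    # add alpha_syn * column j.  Resynced against a full product
    # periodically to cap roundoff accumulation.
    s_eff = np.empty(N)
    if clamp_on:
        for i in range(N):
            s_eff[i] = clamp_val
        isyn = np.dot(W, s_eff)
    else:
        isyn = np.dot(W, s)
    resync = 50000

    drive0 = np.empty(N)
    drive1 = np.empty(N)
    drive2 = np.empty(N)
    omega_i = np.empty(N)
    amp_i = np.empty(N)

    rec_row = 0
    sqn = math.sqrt(dt / noise_tau) if noise_tau > 0 else 0.0

    for k in range(n_steps):
        t = k * dt
        if k % rec_stride == 0:
            for i in range(N):
                V_out[rec_row, i] = V[i]
                s_out[rec_row, i] = s[i] if not clamp_on else clamp_val
            rec_row += 1

        if not clamp_on and k % resync == 0 and k > 0:
            isyn = np.dot(W, s)

        if noise_sigma > 0.0:
            for i in range(N):
                noise[i] += -noise[i] * (dt / noise_tau) \
                    + noise_sigma * np.random.standard_normal() * sqn

        _pulse_current(t, p_onset, p_off, p_amp, pulse)

        # oscillatory drive at the three RK4 stage times
        if drift_on:
            for i in range(N):
                a = psi + amp_dev[i]
                if a < 1e-9:
                    a = 1e-9
                    clips += 1
                amp_i[i] = a
                fd = freq_dev[0] if drift_corr else freq_dev[i]
                om = omega + fd
                if om < 1e-9:
                    om = 1e-9
                    clips += 1
                omega_i[i] = om
                base = theta[i] + phase0[i]
                drive0[i] = a * math.cos(base)
                drive1[i] = a * math.cos(base + om * 0.5 * dt)
                drive2[i] = a * math.cos(base + om * dt)
        else:
            for i in range(N):
                drive0[i] = psi * math.cos(omega * t + phase0[i])
                drive1[i] = psi * math.cos(omega * (t + 0.5 * dt) + phase0[i])
                drive2[i] = psi * math.cos(omega * (t + dt) + phase0[i])

        for i in range(N):
            v0 = V[i]
            h0 = h[i]
            n0 = n[i]
            base_i = i0 + noise[i] + pulse[i]
            if clamp_on:
                is0 = isyn[i]
                is1 = is0
                is2 = is0
            else:
                is0 = isyn[i]
                is1 = is0 * e_half
                is2 = is0 * e_full

            # stage 1
            dv1, dh1, dn1 = _wb_deriv(v0, h0, n0, gna, gk, gl, ena, ek, el,
                                      phi, cm, base_i + is0 + drive0[i])
            # stage 2
            dv2, dh2, dn2 = _wb_deriv(v0 + 0.5 * dt * dv1, h0 + 0.5 * dt * dh1,
                                      n0 + 0.5 * dt * dn1, gna, gk, gl, ena,
                                      ek, el, phi, cm, base_i + is1 + drive1[i])
            # stage 3
            dv3, dh3, dn3 = _wb_deriv(v0 + 0.5 * dt * dv2, h0 + 0.5 * dt * dh2,
                                      n0 + 0.5 * dt * dn2, gna, gk, gl, ena,
                                      ek, el, phi, cm, base_i + is1 + drive1[i])
            # stage 4
            dv4, dh4, dn4 = _wb_deriv(v0 + dt * dv3, h0 + dt * dh3,
                                      n0 + dt * dn3, gna, gk, gl, ena,
                                      ek, el, phi, cm, base_i + is2 + drive2[i])

            V[i] = v0 + dt / 6.0 * (dv1 + 2 * dv2 + 2 * dv3 + dv4)
            h[i] = h0 + dt / 6.0 * (dh1 + 2 * dh2 + 2 * dh3 + dh4)
            n[i] = n0 + dt / 6.0 * (dn1 + 2 * dn2 + 2 * dn3 + dn4)
            if h[i] < 0.0:
                h[i] = 0.0
            elif h[i] > 1.0:
                h[i] = 1.0
            if n[i] < 0.0:
                n[i] = 0.0
            elif n[i] > 1.0:
                n[i] = 1.0

        if not clamp_on:
            for i in range(N):
                s[i] *= e_full
                isyn[i] *= e_full

        # spike = local peak of V exceeding 0 mV, located at time t
        for i in range(N):
            if vprev[i] > vprev2[i] and vprev[i] > V[i] and vprev[i] > 0.0:
                if nspk >= cap:
                    return nspk, STATUS_OVERFLOW, t, i, clips
                spike_t[nspk] = t
                spike_i[nspk] = i
                nspk += 1
                if not clamp_on:
                    s[i] += alpha_syn
                    for j in range(N):
                        isyn[j] += alpha_syn * W[j, i]
            vprev2[i] = vprev[i]
            vprev[i] = V[i]
            if not math.isfinite(V[i]):
                return nspk, STATUS_NONFINITE, t, i, clips

        # advance drift processes
        if drift_on:
            for i in range(N):
                theta[i] += omega_i[i] * dt
            if damp_sigma > 0.0:
                sq = math.sqrt(dt / damp_tau)
                for i in range(N):
                    amp_dev[i] += -amp_dev[i] * (dt / damp_tau) \
                        + damp_sigma * np.random.standard_normal() * sq
            if dfreq_sigma > 0.0:
                sq = math.sqrt(dt / dfreq_tau)
                for i in range(nfreq):
                    freq_dev[i] += -freq_dev[i] * (dt / dfreq_tau) \
                        + dfreq_sigma * np.random.standard_normal() * sq

    if n_steps % rec_stride == 0 and rec_row < V_out.shape[0]:
        for i in range(N):
            V_out[rec_row, i] = V[i]
            s_out[rec_row, i] = s[i] if not clamp_on else clamp_val
    return nspk, STATUS_OK, n_steps * dt, -1, clips


@njit(cache=True, fastmath=False, inline="always")
def _wb_deriv(v, hh, nn, gna, gk, gl, ena, ek, el, phi, cm, itot):
    # instantaneous sodium activation
    x = v + 35.0
    if abs(x) < 1e-7:
        am = 1.0
    else:
        am = -0.1 * x / math.expm1(-0.1 * x)
    bm = 4.0 * math.exp(-(v + 60.0) / 18.0)
    minf = am / (am + bm)

    ah = 0.07 * math.exp(-(v + 58.0) / 20.0)
    bh = 1.0 / (math.exp(-0.1 * (v + 28.0)) + 1.0)

    x = v + 34.0
    if abs(x) < 1e-7:
        an = 0.1
    else:
        an = -0.01 * x / math.expm1(-0.1 * x)
    bn = 0.125 * math.exp(-(v + 44.0) / 80.0)

    ina = gna * minf * minf * minf * hh * (v - ena)
    ik = gk * nn * nn * nn * nn * (v - ek)
    il = gl * (v - el)
    dv = (-(ina + ik + il) + itot) / cm
    dh = phi * (ah * (1.0 - hh) - bh * hh)
    dn = phi * (an * (1.0 - nn) - bn * nn)
    return dv, dh, dn


@njit(cache=True, fastmath=False)
def run_if(V, s,
           leaky, tau_m, v_leak, v_thresh, v_reset, i0,
           W, tau_syn, alpha_syn, clamp_on, clamp_val,
           psi, omega, phase0,
           noise_sigma, noise_tau,
           p_onset, p_off, p_amp,
           dt, n_steps, rec_stride, seed,
           spike_t, spike_i, V_out, s_out):
    N = V.shape[0]
    np.random.seed(seed)

    e_half = math.exp(-0.5 * dt / tau_syn)
    e_full = e_half * e_half
    cap = spike_t.shape[0]
    nspk = 0

    noise = np.zeros(N)
    pulse = np.zeros(N)
    s_eff = np.empty(N)
    if clamp_on:
        for i in range(N):
            s_eff[i] = clamp_val
        isyn = np.dot(W, s_eff)
    else:
        isyn = np.dot(W, s)
    resync = 50000

    rec_row = 0
    sqn = math.sqrt(dt / noise_tau) if noise_tau > 0 else 0.0

    for k in range(n_steps):
        t = k * dt
        if k % rec_stride == 0:
            for i in range(N):
                V_out[rec_row, i] = V[i]
                s_out[rec_row, i] = s[i] if not clamp_on else clamp_val
            rec_row += 1

        if not clamp_on and k % resync == 0 and k > 0:
            isyn = np.dot(W, s)
        if noise_sigma > 0.0:
            for i in range(N):
                noise[i] += -noise[i] * (dt / noise_tau) \
                    + noise_sigma * np.random.standard_normal() * sqn
        _pulse_current(t, p_onset, p_off, p_amp, pulse)

        for i in range(N):
            v0 = V[i]
            base_i = i0 + noise[i] + pulse[i]
            if clamp_on:
                is0 = isyn[i]
                is1 = is0
                is2 = is0
            else:
                is0 = isyn[i]
                is1 = is0 * e_half
                is2 = is0 * e_full
            d0 = psi * math.cos(omega * t + phase0[i])
            d1 = psi * math.cos(omega * (t + 0.5 * dt) + phase0[i])
            d2 = psi * math.cos(omega * (t + dt) + phase0[i])

            if leaky:
                k1 = -(v0 - v_leak) / tau_m + base_i + is0 + d0
                k2 = -(v0 + 0.5 * dt * k1 - v_leak) / tau_m + base_i + is1 + d1
                k3 = -(v0 + 0.5 * dt * k2 - v_leak) / tau_m + base_i + is1 + d1
                k4 = -(v0 + dt * k3 - v_leak) / tau_m + base_i + is2 + d2
            else:
                k1 = base_i + is0 + d0
                k2 = base_i + is1 + d1
                k3 = k2
                k4 = base_i + is2 + d2
            V[i] = v0 + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)

        if not clamp_on:
            for i in range(N):
                s[i] *= e_full
                isyn[i] *= e_full

        # threshold crossing detected within the step; reset at step end
        for i in range(N):
            if V[i] >= v_thresh:
                if nspk >= cap:
                    return nspk, STATUS_OVERFLOW, t, i
                spike_t[nspk] = t + dt
                spike_i[nspk] = i
                nspk += 1
                V[i] = v_reset
                if not clamp_on:
                    s[i] += alpha_syn
                    for j in range(N):
                        isyn[j] += alpha_syn * W[j, i]
            if not math.isfinite(V[i]):
                return nspk, STATUS_NONFINITE, t, i

    if n_steps % rec_stride == 0 and rec_row < V_out.shape[0]:
        for i in range(N):
            V_out[rec_row, i] = V[i]
            s_out[rec_row, i] = s[i] if not clamp_on else clamp_val
    return nspk, STATUS_OK, n_steps * dt, -1
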