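"""Numba kernel for the compartmental cable integrator.

Implements the staggered scheme described in :mod:`ionspike.cable`: exact
exponential (Rush–Larsen) gate updates at the pre-step voltage, exact
bi-exponential synapse updates with events applied at their true offsets,
and a theta-implicit voltage solve (Crank–Nicolson at theta=0.5) via Hines
elimination on the compartment tree.
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _vtrap(x, y):
    if abs(x / y) < 1e-6:
        return y * (1.0 - x / y / 2.0)
    return x / (math.exp(x / y) - 1.0)


@njit(cache=True)
def run_steps(n_steps, step0, dt, theta,
              parent, g_ax, c_nF,
              g_leak, e_leak, gbar_na, gbar_k, e_na, e_k, is_hh, phi,
              v, m, h, n_gate,
              syn_comp, tau_d, tau_r, syn_e, syn_inc, A, B,
              ev_time, ev_syn, ev_ptr,
              clamp_comp, clamp_amp, clamp_on, clamp_off,
              inject_nA, rec_idx, rec_out, err):
    """Advance the model ``n_steps`` steps in place; returns the updated
    synapse event pointer.  ``rec_out`` is (n_recorded, n_steps); on a
    non-finite voltage, ``err`` receives (compartment, step) and the kernel
    returns early."""
    n = v.size
    n_syn = A.size
    n_ev = ev_time.size
    g_chan = np.empty(n)
    b_chan = np.empty(n)
    d = np.empty(n)
    u = np.empty(n)
    rhs = np.empty(n)
    lv = np.empty(n)

    for s in range(n_steps):
        t = (step0 + s) * dt
        t_mid = t + 0.5 * dt
        t_end = t + dt

        # -- gates: exact exponential update at the current voltage --------
        for i in range(n):
            if is_hh[i]:
                vi = v[i]
                a_m = 0.1 * _vtrap(-(vi + 40.0), 10.0)
                b_m = 4.0 * math.exp(-(vi + 65.0) / 18.0)
                a_h = 0.07 * math.exp(-(vi + 65.0) / 20.0)
                b_h = 1.0 / (1.0 + math.exp(-(vi + 35.0) / 10.0))
                a_n = 0.01 * _vtrap(-(vi + 55.0), 10.0)
                b_n = 0.125 * math.exp(-(vi + 65.0) / 80.0)
                p = phi[i]
                sm = a_m + b_m
                m[i] = a_m / sm + (m[i] - a_m / sm) * math.exp(-dt * p * sm)
                sh = a_h + b_h
                h[i] = a_h / sh + (h[i] - a_h / sh) * math.exp(-dt * p * sh)
                sn = a_n + b_n
                n_gate[i] = (a_n / sn
                             + (n_gate[i] - a_n / sn) * math.exp(-dt * p * sn))

        # -- membrane conductances at the step midpoint ---------------------
        for i in range(n):
            gl = g_leak[i]
            g_chan[i] = gl
            b_chan[i] = gl * e_leak[i]
            if is_hh[i]:
                g_na = gbar_na[i] * m[i] ** 3 * h[i]
                g_k = gbar_k[i] * n_gate[i] ** 4
                g_chan[i] += g_na + g_k
                b_chan[i] += g_na * e_na[i] + g_k * e_k[i]

        # -- synapses: exact advance to midpoint, collect, then to end ------
        if n_syn > 0:
            cursor = t
            while ev_ptr < n_ev and ev_time[ev_ptr] < t_mid:
                lag = ev_time[ev_ptr] - cursor
                if lag > 0:
                    for k in range(n_syn):
                        A[k] *= math.exp(-lag / tau_d[k])
                        B[k] *= math.exp(-lag / tau_r[k])
                    cursor = ev_time[ev_ptr]
                kk = ev_syn[ev_ptr]
                A[kk] += syn_inc[kk]
                B[kk] += syn_inc[kk]
                ev_ptr += 1
            lag = t_mid - cursor
            if lag > 0:
                for k in range(n_syn):
                    A[k] *= math.exp(-lag / tau_d[k])
                    B[k] *= math.exp(-lag / tau_r[k])
            for k in range(n_syn):
                g_syn = A[k] - B[k]
                g_chan[syn_comp[k]] += g_syn
                b_chan[syn_comp[k]] += g_syn * syn_e[k]
            cursor = t_mid
            while ev_ptr < n_ev and ev_time[ev_ptr] < t_end:
                lag = ev_time[ev_ptr] - cursor
                if lag > 0:
                    for k in range(n_syn):
                        A[k] *= math.exp(-lag / tau_d[k])
                        B[k] *= math.exp(-lag / tau_r[k])
                    cursor = ev_time[ev_ptr]
                kk = ev_syn[ev_ptr]
                A[kk] += syn_inc[kk]
                B[kk] += syn_inc[kk]
                ev_ptr += 1
            lag = t_end - cursor
            if lag > 0:
                for k in range(n_syn):
                    A[k] *= math.exp(-lag / tau_d[k])
                    B[k] *= math.exp(-lag / tau_r[k])

        # -- axial flow at the current voltage (explicit part) --------------
        for i in range(n):
            lv[i] = 0.0
        for i in range(1, n):
            p_i = parent[i]
            if p_i >= 0:
                flow = g_ax[i] * (v[i] - v[p_i])
                lv[i] += flow
                lv[p_i] -= flow

        for i in range(n):
            cdt = c_nF[i] / dt
            d[i] = cdt + theta * g_chan[i]
            rhs[i] = (cdt * v[i]
                      - (1.0 - theta) * (g_chan[i] * v[i] - b_chan[i] + lv[i])
                      + theta * b_chan[i] + inject_nA[i])
            u[i] = -theta * g_ax[i]
        for c in range(clamp_comp.size):
            if clamp_on[c] <= t_mid < clamp_off[c]:
                rhs[clamp_comp[c]] += clamp_amp[c] * 1e-3
        for i in range(1, n):
            p_i = parent[i]
            if p_i >= 0:
                d[i] += theta * g_ax[i]
                d[p_i] += theta * g_ax[i]

        # -- Hines elimination (children have larger indices) ---------------
        for i in range(n - 1, 0, -1):
            p_i = parent[i]
            if p_i < 0:
                continue
            f = u[i] / d[i]
            d[p_i] -= f * u[i]
            rhs[p_i] -= f * rhs[i]
        v[0] = rhs[0] / d[0]
        for i in range(1, n):
            p_i = parent[i]
            if p_i < 0:
                v[i] = rhs[i] / d[i]
            else:
                v[i] = (rhs[i] - u[i] * v[p_i]) / d[i]

        for i in range(n):
            if not math.isfinite(v[i]):
                err[0] = i
                err[1] = step0 + s + 1
                return ev_ptr

        for k in range(rec_idx.size):
            rec_out[k, s] = v[rec_idx[k]]

    return ev_ptr
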