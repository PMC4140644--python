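"""Time-stepping kernel: backward-Euler voltage solve on a tree (Hines
elimination) with staggered exponential gating and event-driven
double-exponential synapses.  Written as plain loops so it can be
compiled by numba when available; the pure-Python path is functionally
identical, only slower.
"""

from __future__ import annotations

import math


def integrate_kernel(n_steps, dt, v, w, z, parent, g_par, c_over_dt,
                     g_l, e_l, g_h, e_h, gbar, e_k,
                     w_half, w_slope, p_exp, z_half, z_slope, z_floor,
                     twmin, twamp, twv0, twk1, twk2,
                     tzmin, tzamp, tzv0, tzk1, tzk2, rate_scale,
                     drive_idx, drive_cur,
                     syn_comp, syn_gmax, syn_e, syn_decay_d, syn_decay_r,
                     syn_a, syn_b,
                     ev_step, ev_syn,
                     spike_enable, spike_thresh, spike_reset, spike_ref_steps,
                     spike_adapt_inc, spike_adapt_decay, soma_idx,
                     record_idx, record_every, v_out, spike_steps_out):
    n = v.shape[0]
    n_syn = syn_comp.shape[0]
    n_drive = drive_idx.shape[0]
    diag = c_over_dt * 0.0
    rhs = c_over_dt * 0.0
    ev_ptr = 0
    n_ev = ev_step.shape[0]
    n_spk = 0
    theta = 0.0
    ref_count = 0
    rec_col = 0
    for step in range(n_steps):
        # --- gating (exponential update about the previous voltage) ---
        p4 = p_exp == 4.0
        for i in range(n):
            vi = v[i]
            bw = 1.0 / (1.0 + math.exp(-(vi - w_half) / w_slope))
            if p4:
                winf = math.sqrt(math.sqrt(bw))
            else:
                winf = bw ** (1.0 / p_exp)
            sz = 1.0 / (1.0 + math.exp((vi - z_half) / z_slope))
            zinf = z_floor + (1.0 - z_floor) * sz
            uw = vi - twv0
            tw = (twmin + twamp / (math.exp(uw / twk1) + math.exp(-uw / twk2))) / rate_scale
            uz = vi - tzv0
            tz = (tzmin + tzamp / (math.exp(uz / tzk1) + math.exp(-uz / tzk2))) / rate_scale
            w[i] += (winf - w[i]) * (1.0 - math.exp(-dt / tw))
            z[i] += (zinf - z[i]) * (1.0 - math.exp(-dt / tz))
        # --- synapse states ---
        for s in range(n_syn):
            syn_a[s] *= syn_decay_d[s]
            syn_b[s] *= syn_decay_r[s]
        while ev_ptr < n_ev and ev_step[ev_ptr] == step:
            s = ev_syn[ev_ptr]
            syn_a[s] += 1.0
            syn_b[s] += 1.0
            ev_ptr += 1
        # --- assemble ---
        for i in range(n):
            if p4:
                w2 = w[i] * w[i]
                wp = w2 * w2
            else:
                wp = w[i] ** p_exp
            gk = gbar[i] * wp * z[i]
            diag[i] = c_over_dt[i] + g_l[i] + g_h[i] + gk
            rhs[i] = (c_over_dt[i] * v[i] + g_l[i] * e_l[i]
                      + g_h[i] * e_h[i] + gk * e_k)
        for s in range(n_syn):
            g = syn_gmax[s] * (syn_a[s] - syn_b[s])
            i = syn_comp[s]
            diag[i] += g
            rhs[i] += g * syn_e[s]
        for d in range(n_drive):
            rhs[drive_idx[d]] += drive_cur[d, step]
        for i in range(1, n):
            diag[i] += g_par[i]
            diag[parent[i]] += g_par[i]
        # --- Hines elimination (parent[i] < i) ---
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = g_par[i] / diag[i]
            diag[p] -= f * g_par[i]
            rhs[p] += f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] + g_par[i] * v[parent[i]]) / diag[i]
        # --- spiking overlay at the soma ---
        if spike_enable:
            theta *= spike_adapt_decay
            if ref_count > 0:
                ref_count -= 1
                v[soma_idx] = spike_reset
            elif v[soma_idx] >= spike_thresh + theta:
                spike_steps_out[n_spk] = step
                n_spk += 1
                theta += spike_adapt_inc
                v[soma_idx] = spike_reset
                ref_count = spike_ref_steps
        # --- record ---
        if step % record_every == 0:
            for r in range(record_idx.shape[0]):
                v_out[r, rec_col] = v[record_idx[r]]
            rec_col += 1
    return n_spk
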