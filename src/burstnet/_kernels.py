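"""Numba inner loop of the network simulation.

One jitted function advances the full network state by a chunk of Euler steps:
synaptic filter and trace decay, spike delivery (one-step delay), OU background
updates, two-compartment PC and interneuron integration, online burst/calcium
event detection, event-driven plasticity, and thinned recording.  All state is
mutated in place so the Python engine can run chunk-by-chunk, monitor
convergence, and toggle recording between chunks.

Semantics mirror the vectorised reference implementations in ``model_core``,
``network``, ``plasticity`` and ``stimulus`` (a test cross-checks a noise-free
run step for step).  Layout conventions:

* interneurons are one flat population (SOM first, then PV) with per-neuron
  membrane/adaptation parameters;
* synapse groups are concatenated: synapses of group g occupy the contiguous
  id range [syn_off[g], syn_off[g+1]), ordered by postsynaptic neuron with
  fixed in-degree K[g]; a by-presynaptic CSR (pre_ptr/pre_sid) supports spike
  delivery and presynaptic plasticity events;
* plast codes: 0 none, 1 spike-pair rule, 2 burst rule, 3 calcium-event rule,
  4 rate-only tick.  post_trace codes: 0 PC spike, 1 PC burst, 2 PC calcium
  event, 3 interneuron spike;
* spikes of step t are delivered into the (already decayed) synaptic filters
  at the end of step t, so they first contribute — with their full weight —
  to the currents of step t+1.
"""

import numpy as np
from numba import njit

STATUS_OK = 0
STATUS_DIVERGED = 1
STATUS_OVERFLOW = 2

# indices into the float packed PC-parameter vector
(P_TAU_S, P_C_S, P_G_S, P_BWS, P_TAUWS, P_EL, P_TAU_D, P_C_D, P_G_D, P_CD,
 P_TAUWD, P_AWD, P_ED, P_DM, P_VT, P_SOM_ADAPT) = range(16)


@njit(cache=True, fastmath=False)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True, fastmath=False)
def simulate_chunk(
    n_steps, dt, t0_ms, step0,
    # PC parameters / state
    ppc, refrac_steps_pc, bap_on_steps, bap_dur_steps,
    Vs, Vd, ws, wd, refrac_pc,
    ring_on, ring_off, bap_count,
    # interneuron parameters / state (SOM then PV)
    tau_m_in, C_m_in, b_w_in, tau_w_in, refrac_steps_in, EL_in, VT_in,
    V_in, w_in, refrac_in,
    # traces and event-detector state
    tau_stdp, tr_spk_pc, tr_spk_in, tr_burst_pc, tr_ca_pc,
    burst_isi_ms, last_spike_pc, in_burst_pc,
    ca_thresh, ca_merge_ms, prev_above_pc, last_ca_pc,
    # external and background inputs; noise holds pre-drawn N(0,1) deviates,
    # one row per step: somatic block, then dendritic, then interneurons
    ext_s, ext_d, ext_in, sigma_s, sigma_d, sigma_in, tau_ou,
    bg_s, bg_d, bg_in, noise, noise_off_d, noise_off_in,
    # synapse groups
    pre_is_pc, post_comp, sign, dec, plast, post_trace, eta, alpha,
    rate_interval_steps, K, syn_off, syn_post, syn_pre, syn_w,
    pre_ptr, pre_ptr_off, pre_sid, filt, filt_off,
    pre_lo, post_lo,
    # recording
    record, rec_counts,
    pc_si, pc_st, in_si, in_st, ca_ri, ca_rt, bu_ri, bu_rt,
    cur_every_steps, cur_pos0, cur_s_rec, cur_d_rec,
    wmean_every_steps, wmean_pos0, wmean_out,
):
    n_pc = Vs.shape[0]
    n_in = V_in.shape[0]
    G = K.shape[0]
    L = ring_on.shape[0]

    tau_s = ppc[P_TAU_S]; C_s = ppc[P_C_S]; g_s = ppc[P_G_S]
    b_w_s = ppc[P_BWS]; tau_w_s = ppc[P_TAUWS]; E_L = ppc[P_EL]
    tau_d = ppc[P_TAU_D]; C_d = ppc[P_C_D]; g_d = ppc[P_G_D]
    c_d = ppc[P_CD]; tau_w_d = ppc[P_TAUWD]; a_w_d = ppc[P_AWD]
    E_d = ppc[P_ED]; D_m = ppc[P_DM]; V_T = ppc[P_VT]
    som_adapt = ppc[P_SOM_ADAPT] > 0.5

    trace_dec = np.exp(-dt / tau_stdp)
    ou_noise_s = sigma_s * np.sqrt(2.0 * dt / tau_ou)
    ou_noise_d = sigma_d * np.sqrt(2.0 * dt / tau_ou)
    ou_noise_in = np.empty(n_in)
    for j in range(n_in):
        ou_noise_in[j] = sigma_in[j] * np.sqrt(2.0 * dt / tau_ou)

    # per-step event index lists
    pc_spk_idx = np.empty(n_pc, dtype=np.int64)
    in_spk_idx = np.empty(max(n_in, 1), dtype=np.int64)
    burst_idx = np.empty(n_pc, dtype=np.int64)
    ca_idx = np.empty(n_pc, dtype=np.int64)
    I_s = np.empty(n_pc)
    I_d = np.empty(n_pc)
    I_input = np.empty(max(n_in, 1))

    cur_pos = cur_pos0
    wmean_pos = wmean_pos0
    status = STATUS_OK

    for s in range(n_steps):
        gstep = step0 + s
        t_ms = t0_ms + s * dt

        # --- input assembly (filters already decayed + fed at end of last step)
        es = ext_s[s]
        ed = ext_d[s]
        if sigma_s > 0.0:
            for i in range(n_pc):
                bg_s[i] += -dt * bg_s[i] / tau_ou + ou_noise_s * noise[s, i]
        if sigma_d > 0.0:
            for i in range(n_pc):
                bg_d[i] += -dt * bg_d[i] / tau_ou + ou_noise_d * noise[s, noise_off_d + i]
        for i in range(n_pc):
            I_s[i] = es + bg_s[i]
            I_d[i] = ed + bg_d[i]
        for j in range(n_in):
            if sigma_in[j] > 0.0:
                bg_in[j] += (-dt * bg_in[j] / tau_ou
                             + ou_noise_in[j] * noise[s, noise_off_in + j])
            I_input[j] = ext_in[j] + bg_in[j]
        for g in range(G):
            f0 = filt_off[g]
            npost_g = (syn_off[g + 1] - syn_off[g]) // K[g]
            plo = post_lo[g]
            sg = sign[g]
            if post_comp[g] == 0:
                for i in range(npost_g):
                    I_s[plo + i] += sg * filt[f0 + i]
            elif post_comp[g] == 1:
                for i in range(npost_g):
                    I_d[plo + i] += sg * filt[f0 + i]
            else:
                for i in range(npost_g):
                    I_input[plo + i] += sg * filt[f0 + i]

        if record == 1 and cur_s_rec.shape[1] > 0 and gstep % cur_every_steps == 0:
            if cur_pos < cur_s_rec.shape[0]:
                for m in range(cur_s_rec.shape[1]):
                    cur_s_rec[cur_pos, m] = I_s[m]
                    cur_d_rec[cur_pos, m] = I_d[m]
                cur_pos += 1

        # --- BAP ring buffer: activate / deactivate pending pulse windows
        row = gstep % L
        for i in range(n_pc):
            bap_count[i] += ring_on[row, i] - ring_off[row, i]
            ring_on[row, i] = 0
            ring_off[row, i] = 0

        # --- PC integration, spike/burst/calcium detection, trace updates
        n_pc_spk = 0
        n_burst = 0
        n_ca = 0
        for i in range(n_pc):
            f = _sigmoid((Vd[i] - E_d) / D_m)
            dVd = (-(Vd[i] - E_L) / tau_d
                   + (g_d * f + c_d * bap_count[i] + I_d[i] + wd[i]) / C_d)
            dwd = (-wd[i] + a_w_d * (Vd[i] - E_L)) / tau_w_d
            if refrac_pc[i] > 0:
                Vs[i] = E_L
            else:
                Vs[i] += dt * (-(Vs[i] - E_L) / tau_s + (g_s * f + I_s[i] + ws[i]) / C_s)
            Vd[i] += dt * dVd
            ws[i] += dt * (-ws[i] / tau_w_s)
            wd[i] += dt * dwd

            spiked = False
            if Vs[i] >= V_T and refrac_pc[i] <= 0:
                spiked = True
                Vs[i] = E_L
                refrac_pc[i] = refrac_steps_pc + 1  # decremented below
                on_row = (gstep + bap_on_steps) % L
                off_row = (gstep + bap_on_steps + bap_dur_steps) % L
                ring_on[on_row, i] += 1
                ring_off[off_row, i] += 1
                if som_adapt:
                    ws[i] += b_w_s
                pc_spk_idx[n_pc_spk] = i
                n_pc_spk += 1
            if refrac_pc[i] > 0:
                refrac_pc[i] -= 1

            # online burst detection (16 ms first-ISI convention)
            burst = False
            if spiked:
                short = (t_ms - last_spike_pc[i]) < burst_isi_ms
                if short and not in_burst_pc[i]:
                    burst = True
                    burst_idx[n_burst] = i
                    n_burst += 1
                in_burst_pc[i] = short
                last_spike_pc[i] = t_ms
            # calcium event: upward threshold crossing with merge window
            above = Vd[i] >= ca_thresh
            ca = False
            if above and not prev_above_pc[i] and (t_ms - last_ca_pc[i]) >= ca_merge_ms:
                ca = True
                last_ca_pc[i] = t_ms
                ca_idx[n_ca] = i
                n_ca += 1
            prev_above_pc[i] = above

            tr_spk_pc[i] = tr_spk_pc[i] * trace_dec + (1.0 if spiked else 0.0)
            tr_burst_pc[i] = tr_burst_pc[i] * trace_dec + (1.0 if burst else 0.0)
            tr_ca_pc[i] = tr_ca_pc[i] * trace_dec + (1.0 if ca else 0.0)

            if record == 1:
                if spiked:
                    if rec_counts[0] < pc_si.shape[0]:
                        pc_si[rec_counts[0]] = i
                        pc_st[rec_counts[0]] = t_ms
                        rec_counts[0] += 1
                    else:
                        status = STATUS_OVERFLOW
                if ca:
                    if rec_counts[2] < ca_ri.shape[0]:
                        ca_ri[rec_counts[2]] = i
                        ca_rt[rec_counts[2]] = t_ms
                        rec_counts[2] += 1
                    else:
                        status = STATUS_OVERFLOW
                if burst:
                    if rec_counts[3] < bu_ri.shape[0]:
                        bu_ri[rec_counts[3]] = i
                        bu_rt[rec_counts[3]] = t_ms
                        rec_counts[3] += 1
                    else:
                        status = STATUS_OVERFLOW

        # --- interneuron integration
        n_in_spk = 0
        for j in range(n_in):
            if refrac_in[j] > 0:
                V_in[j] = EL_in
            else:
                V_in[j] += dt * (-(V_in[j] - EL_in) / tau_m_in[j]
                                 + (I_input[j] + w_in[j]) / C_m_in[j])
            w_in[j] += dt * (-w_in[j] / tau_w_in[j])
            spiked = False
            if V_in[j] >= VT_in and refrac_in[j] <= 0:
                spiked = True
                V_in[j] = EL_in
                refrac_in[j] = refrac_steps_in + 1
                if b_w_in[j] != 0.0:
                    w_in[j] += b_w_in[j]
                in_spk_idx[n_in_spk] = j
                n_in_spk += 1
            if refrac_in[j] > 0:
                refrac_in[j] -= 1
            tr_spk_in[j] = tr_spk_in[j] * trace_dec + (1.0 if spiked else 0.0)
            if record == 1 and spiked:
                if rec_counts[1] < in_si.shape[0]:
                    in_si[rec_counts[1]] = j
                    in_st[rec_counts[1]] = t_ms
                    rec_counts[1] += 1
                else:
                    status = STATUS_OVERFLOW

        # --- plasticity: presynaptic events first, then postsynaptic events
        for g in range(G):
            if plast[g] == 0:
                continue
            if plast[g] != 4:
                p0 = pre_ptr_off[g]
                plo = pre_lo[g]
                n_pre_g = pre_ptr_off[g + 1] - p0 - 1
                # presynaptic spikes: depress by eta*(x_post - alpha)
                if pre_is_pc[g] == 1:
                    n_ev, ev_idx = n_pc_spk, pc_spk_idx
                else:
                    n_ev, ev_idx = n_in_spk, in_spk_idx
                for e in range(n_ev):
                    jj = ev_idx[e] - plo
                    if jj < 0 or jj >= n_pre_g:
                        continue
                    lo = pre_ptr[p0 + jj]
                    hi = pre_ptr[p0 + jj + 1]
                    for q in range(lo, hi):
                        sid = pre_sid[q]
                        ip = post_lo[g] + syn_post[sid]
                        if post_trace[g] == 0:
                            xp = tr_spk_pc[ip]
                        elif post_trace[g] == 1:
                            xp = tr_burst_pc[ip]
                        elif post_trace[g] == 2:
                            xp = tr_ca_pc[ip]
                        else:
                            xp = tr_spk_in[ip]
                        syn_w[sid] += eta[g] * (xp - alpha[g])
                        if syn_w[sid] < 0.0:
                            syn_w[sid] = 0.0
                # postsynaptic events: potentiate by eta*x_pre
                if post_trace[g] == 0:
                    n_ev, ev_idx = n_pc_spk, pc_spk_idx
                elif post_trace[g] == 1:
                    n_ev, ev_idx = n_burst, burst_idx
                elif post_trace[g] == 2:
                    n_ev, ev_idx = n_ca, ca_idx
                else:
                    n_ev, ev_idx = n_in_spk, in_spk_idx
                npost_g = (syn_off[g + 1] - syn_off[g]) // K[g]
                for e in range(n_ev):
                    i = ev_idx[e] - post_lo[g]
                    if i < 0 or i >= npost_g:
                        continue
                    s0_g = syn_off[g] + i * K[g]
                    for sid in range(s0_g, s0_g + K[g]):
                        jp = pre_lo[g] + syn_pre[sid]
                        if pre_is_pc[g] == 1:
                            xq = tr_spk_pc[jp]
                        else:
                            xq = tr_spk_in[jp]
                        syn_w[sid] += eta[g] * xq
            else:
                # rate-only tick: every update interval, no pre dependence
                if (gstep + 1) % rate_interval_steps[g] == 0:
                    for sid in range(syn_off[g], syn_off[g + 1]):
                        ip = post_lo[g] + syn_post[sid]
                        if post_trace[g] == 1:
                            xp = tr_burst_pc[ip]
                        elif post_trace[g] == 2:
                            xp = tr_ca_pc[ip]
                        else:
                            xp = tr_spk_pc[ip]
                        syn_w[sid] += eta[g] * (xp - alpha[g])
                        if syn_w[sid] < 0.0:
                            syn_w[sid] = 0.0

        # --- weight-mean recording
        if wmean_out.shape[1] > 0 and gstep % wmean_every_steps == 0:
            if wmean_pos < wmean_out.shape[0]:
                for g in range(G):
                    acc = 0.0
                    for sid in range(syn_off[g], syn_off[g + 1]):
                        acc += syn_w[sid]
                    wmean_out[wmean_pos, g] = acc / (syn_off[g + 1] - syn_off[g])
                wmean_pos += 1

        # --- end of step: decay filters, then feed this step's spikes so they
        # first contribute (undecayed) to the next step's currents
        for g in range(G):
            f0 = filt_off[g]
            npost_g = (syn_off[g + 1] - syn_off[g]) // K[g]
            dg = dec[g]
            for i in range(f0, f0 + npost_g):
                filt[i] *= dg
        for g in range(G):
            f0 = filt_off[g]
            p0 = pre_ptr_off[g]
            plo = pre_lo[g]
            n_pre_g = pre_ptr_off[g + 1] - p0 - 1
            if pre_is_pc[g] == 1:
                n_ev, ev_idx = n_pc_spk, pc_spk_idx
            else:
                n_ev, ev_idx = n_in_spk, in_spk_idx
            for e in range(n_ev):
                jj = ev_idx[e] - plo
                if jj < 0 or jj >= n_pre_g:
                    continue
                lo = pre_ptr[p0 + jj]
                hi = pre_ptr[p0 + jj + 1]
                for q in range(lo, hi):
                    sid = pre_sid[q]
                    filt[f0 + syn_post[sid]] += syn_w[sid]

        # spiking compartments are bounded above by threshold+reset; the lower
        # bound only catches runaway inhibition or non-finite state
        if s % 200 == 0:
            bad = False
            for i in range(n_pc):
                if (not (np.isfinite(Vs[i]) and np.isfinite(Vd[i]))
                        or Vs[i] > 100.0 or Vd[i] > 200.0
                        or Vs[i] < -5000.0 or Vd[i] < -5000.0):
                    bad = True
            for j in range(n_in):
                if not np.isfinite(V_in[j]) or V_in[j] > 100.0 or V_in[j] < -5000.0:
                    bad = True
            if bad:
                return STATUS_DIVERGED, cur_pos, wmean_pos

    return status, cur_pos, wmean_pos
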