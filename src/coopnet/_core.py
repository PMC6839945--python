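"""Numba-compiled inner loop of the network simulation.

All state advancing happens here, one explicit step at a time, in the
documented order: synaptic kernels <- impulses, conductances, lagged NMDA
gates, patch voltages, applied currents, neuron updates, resets.

Kept free of Python objects so the whole loop compiles to machine code;
the friendly interface lives in :mod:`coopnet.network_sim`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# column indices into the Izhikevich parameter vectors
_CM, _KLOW, _KHIGH, _VR, _VT, _VPEAK, _A, _B, _C, _D = range(10)


@njit(cache=True)
def _izh_update(v, u, I, par, dt):
    """One forward-Euler step + reset for one neuron. Returns (v, u, spike)."""
    k = par[_KLOW] if v <= par[_VT] else par[_KHIGH]
    dv = (k * (v - par[_VR]) * (v - par[_VT]) - u + I) / par[_CM]
    du = par[_A] * (par[_B] * (v - par[_VR]) - u)
    v2 = v + dt * dv
    u2 = u + dt * du
    if v2 >= par[_VPEAK]:
        return par[_C], u2 + par[_D], True
    return v2, u2, False


@njit(cache=True)
def simulate_network(
    n_sub,
    n_pyr,
    n_steps,
    dt,
    ext_counts,      # (n_sub*n_pyr, n_steps) int16 external spike counts
    D,               # (n_pyr, n_pyr) distance matrix
    pyr_par,         # (10,) Izhikevich parameters, pyramidal
    pv_par,          # (10,) Izhikevich parameters, PV
    tau_ext,         # (2,) ext kernel taus (pyr AMPA kinetics)
    tau_fba,         # (2,) feedback AMPA taus (PV kinetics)
    tau_nmda,        # (2,)
    tau_gpyr,        # (2,) GABA onto pyramidal taus
    tau_gpv,         # (2,) GABA onto PV taus
    kA,              # k_pv_AMPA * ampar_scale
    kN,              # k_pv_NMDA * nmdar_scale
    k_pv_gaba,
    k_pv_ext,
    k_pyr_gaba,
    k_pyr_ext,
    k_syn,
    C_syn,
    g_leak,
    e_leak,
    e_glu,
    e_gaba,
    gate_at_sender,  # bool; False gates NMDA at the receiving patch
    cross_w,         # GABA weight across subnetworks (within-sub weight 1)
    rec_stride,      # record voltage/current traces every rec_stride steps
    patch_stride,    # record patch voltages every patch_stride steps; 0 off
    max_spikes,
):
    n_tot_pyr = n_sub * n_pyr
    n_rec = n_steps // rec_stride
    n_patch_rec = (n_steps // patch_stride) if patch_stride > 0 else 0

    # --- states -----------------------------------------------------
    v_pyr = np.empty(n_tot_pyr)
    u_pyr = np.zeros(n_tot_pyr)
    for i in range(n_tot_pyr):
        v_pyr[i] = pyr_par[_VR]
    v_pv = np.empty(n_sub)
    u_pv = np.zeros(n_sub)
    for s in range(n_sub):
        v_pv[s] = pv_par[_VR]
    v_patch = np.full(n_tot_pyr, e_leak)

    e1 = np.zeros(n_tot_pyr)   # external kernel (onto pyramidal)
    e2 = np.zeros(n_tot_pyr)
    a1 = np.zeros(n_tot_pyr)   # feedback AMPA kernel (onto PV)
    a2 = np.zeros(n_tot_pyr)
    m1 = np.zeros(n_tot_pyr)   # feedback NMDA kernel (onto PV)
    m2 = np.zeros(n_tot_pyr)
    gp1 = np.zeros(n_sub)      # GABA kernel onto pyramidal, per source PV
    gp2 = np.zeros(n_sub)
    gv1 = np.zeros(n_sub)      # GABA kernel onto PV, per source PV
    gv2 = np.zeros(n_sub)

    spk_pyr = np.zeros(n_tot_pyr, np.bool_)
    spk_pv = np.zeros(n_sub, np.bool_)

    # exact decay factors
    de1 = np.exp(-dt / tau_ext[0]);  de2 = np.exp(-dt / tau_ext[1])
    da1 = np.exp(-dt / tau_fba[0]);  da2 = np.exp(-dt / tau_fba[1])
    dm1 = np.exp(-dt / tau_nmda[0]); dm2 = np.exp(-dt / tau_nmda[1])
    dp1 = np.exp(-dt / tau_gpyr[0]); dp2 = np.exp(-dt / tau_gpyr[1])
    dv1 = np.exp(-dt / tau_gpv[0]);  dv2 = np.exp(-dt / tau_gpv[1])
    inv_ext = 1.0 / (tau_ext[1] - tau_ext[0])
    inv_fba = 1.0 / (tau_fba[1] - tau_fba[0])
    inv_nmda = 1.0 / (tau_nmda[1] - tau_nmda[0])
    inv_gpyr = 1.0 / (tau_gpyr[1] - tau_gpyr[0])
    inv_gpv = 1.0 / (tau_gpv[1] - tau_gpv[0])
    patch_decay = np.exp(-dt * g_leak / C_syn)

    # --- outputs ----------------------------------------------------
    spike_cell = np.empty(max_spikes, np.int32)
    spike_time = np.empty(max_spikes, np.float64)
    n_spk = 0
    v_pv_rec = np.zeros((n_sub, n_rec))
    I_rec = np.zeros((n_sub, 4, n_rec))        # nmda, ampa, gaba, ext
    I_tot_rec = np.zeros((n_sub, n_rec))
    patch_rec = np.zeros((n_patch_rec, n_tot_pyr))
    err_step = -1

    w = np.empty(n_pyr)
    w2 = np.empty(n_pyr)
    coop_a = np.zeros(n_pyr)
    g_gaba_pyr = np.empty(n_sub)
    g_gaba_pv = np.empty(n_sub)

    for t in range(n_steps):
        # 1. kernels: exact decay, then impulses binned to this step's end
        for i in range(n_tot_pyr):
            e1[i] = e1[i] * de1 + ext_counts[i, t]
            e2[i] = e2[i] * de2 + ext_counts[i, t]
            if spk_pyr[i]:
                a1[i] = a1[i] * da1 + 1.0
                a2[i] = a2[i] * da2 + 1.0
                m1[i] = m1[i] * dm1 + 1.0
                m2[i] = m2[i] * dm2 + 1.0
            else:
                a1[i] *= da1
                a2[i] *= da2
                m1[i] *= dm1
                m2[i] *= dm2
        for s in range(n_sub):
            inc = 1.0 if spk_pv[s] else 0.0
            gp1[s] = gp1[s] * dp1 + inc
            gp2[s] = gp2[s] * dp2 + inc
            gv1[s] = gv1[s] * dv1 + inc
            gv2[s] = gv2[s] * dv2 + inc
            g_gaba_pyr[s] = (gp2[s] - gp1[s]) * inv_gpyr
            g_gaba_pv[s] = (gv2[s] - gv1[s]) * inv_gpv

        rec_now = (t + 1) % rec_stride == 0
        r = (t + 1) // rec_stride - 1

        for s in range(n_sub):
            lo = s * n_pyr
            # 2. conductances of this subnetwork's afferents
            g_ext_sum = 0.0
            for i in range(n_pyr):
                g_ext_sum += (e2[lo + i] - e1[lo + i]) * inv_ext
            g_ext_pv = g_ext_sum / n_pyr  # mean of afferent drives

            # 3. lagged NMDA gates from pre-step patch voltages
            # 4. patch current and exponential-Euler update
            sum_ga = 0.0
            sum_gn_gated = 0.0
            for i in range(n_pyr):
                ga = (a2[lo + i] - a1[lo + i]) * inv_fba
                gn = (m2[lo + i] - m1[lo + i]) * inv_nmda
                gate = 0.5 * np.tanh((v_patch[lo + i] + 50.0) / 10.0) + 0.5
                sum_ga += ga
                sum_gn_gated += gn * gate
                if gate_at_sender:
                    w[i] = kA * ga + kN * gn * gate
                else:
                    w[i] = kN * gn  # gated per receiver below
                    w2[i] = kA * ga
            coop = np.dot(D, w)
            if not gate_at_sender:
                coop_a = np.dot(D, w2)
            for i in range(n_pyr):
                c = coop[i]
                if not gate_at_sender:
                    gate_i = 0.5 * np.tanh((v_patch[lo + i] + 50.0) / 10.0) + 0.5
                    c = coop_a[i] + gate_i * c
                # k_syn * c is a conductance; exact exponential update keeps
                # the patch voltage bounded by e_glu
                g_syn = k_syn * c
                g_tot = g_leak + g_syn
                v_inf = (g_leak * e_leak + g_syn * e_glu) / g_tot
                dec = np.exp(-dt * g_tot / C_syn)
                v_patch[lo + i] = v_inf + (v_patch[lo + i] - v_inf) * dec

            # 5. interneuron applied current (Eq 7 form)
            gaba_pv = 0.0
            for src in range(n_sub):
                wgt = 1.0 if src == s else cross_w
                gaba_pv += wgt * g_gaba_pv[src]
            drive = e_glu - v_pv[s]
            # feedback enters as the scaled mean over afferents (matching
            # the external-drive convention); the patch equation keeps the
            # full gains since D rows already average over afferents.
            I_nmda = kN * sum_gn_gated / n_pyr * drive
            I_ampa = kA * sum_ga / n_pyr * drive
            I_ext = k_pv_ext * g_ext_pv * drive
            I_gaba = k_pv_gaba * gaba_pv * (e_gaba - v_pv[s])
            I_pv = I_nmda + I_ampa + I_ext + I_gaba
            if rec_now:
                v_pv_rec[s, r] = v_pv[s]
                I_rec[s, 0, r] = I_nmda
                I_rec[s, 1, r] = I_ampa
                I_rec[s, 2, r] = I_gaba
                I_rec[s, 3, r] = I_ext
                I_tot_rec[s, r] = I_pv

            # 6.-7. neuron updates and spike bookkeeping
            gaba_pyr = 0.0
            for src in range(n_sub):
                wgt = 1.0 if src == s else cross_w
                gaba_pyr += wgt * g_gaba_pyr[src]
            for i in range(n_pyr):
                gi = lo + i
                g_ext = (e2[gi] - e1[gi]) * inv_ext
                I = k_pyr_ext * g_ext * (e_glu - v_pyr[gi]) + k_pyr_gaba * gaba_pyr * (
                    e_gaba - v_pyr[gi]
                )
                v_pyr[gi], u_pyr[gi], sp = _izh_update(
                    v_pyr[gi], u_pyr[gi], I, pyr_par, dt
                )
                spk_pyr[gi] = sp
                if sp and n_spk < max_spikes:
                    spike_cell[n_spk] = gi
                    spike_time[n_spk] = (t + 1) * dt
                    n_spk += 1
            v_pv[s], u_pv[s], sp = _izh_update(v_pv[s], u_pv[s], I_pv, pv_par, dt)
            spk_pv[s] = sp
            if sp and n_spk < max_spikes:
                spike_cell[n_spk] = n_sub * n_pyr + s
                spike_time[n_spk] = (t + 1) * dt
                n_spk += 1

        if patch_stride > 0 and (t + 1) % patch_stride == 0:
            pr = (t + 1) // patch_stride - 1
            for i in range(n_tot_pyr):
                patch_rec[pr, i] = v_patch[i]

        if rec_now:
            ok = True
            for s in range(n_sub):
                if not np.isfinite(v_pv[s]):
                    ok = False
            if not np.isfinite(v_pyr[0]) or not np.isfinite(v_patch[0]):
                ok = False
            if not ok:
                err_step = t + 1
                break

    return (
        spike_cell[:n_spk].copy(),
        spike_time[:n_spk].copy(),
        v_pv_rec,
        I_rec,
        I_tot_rec,
        patch_rec,
        err_step,
    )
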