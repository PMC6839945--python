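"""Numba inner loop for the tree cable solver.

Crank-Nicolson on the branched cable with Hines elimination (parents
precede children in the compartment ordering), exponential-Euler channel
gating, and per-synapse bi-exponential kernels with instantaneous
voltage-dependent factors (Jahr-Stevens Mg block for NMDA, optional
polyamine rectification for AMPA) evaluated at the pre-step voltage.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PHI = 5.0


@njit(cache=True)
def _vtrap(x, y):
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - np.exp(-x / y))


@njit(cache=True)
def _rates(v):
    """WB rates at (already shifted) voltage. Returns 6 scalars."""
    alpha_m = 0.1 * _vtrap(v + 35.0, 10.0)
    beta_m = 4.0 * np.exp(-(v + 60.0) / 18.0)
    alpha_h = PHI * 0.07 * np.exp(-(v + 58.0) / 20.0)
    beta_h = PHI * 1.0 / (np.exp(-0.1 * (v + 28.0)) + 1.0)
    alpha_n = PHI * 0.01 * _vtrap(v + 34.0, 10.0)
    beta_n = PHI * 0.125 * np.exp(-(v + 44.0) / 80.0)
    return alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n


@njit(cache=True)
def _mg_block(v, mg):
    return 1.0 / (1.0 + (mg / 3.57) * np.exp(-0.062 * v))


@njit(cache=True)
def _rect_factor(v):
    """Polyamine inward-rectification factor, 1 at -65 mV."""
    ref = 1.0 / (1.0 + np.exp((-65.0 + 20.0) / 20.0))
    return (1.0 / (1.0 + np.exp((v + 20.0) / 20.0))) / ref


@njit(cache=True)
def simulate_tree(
    parent,        # (n,) int64, parent compartment (-1 for root)
    g_axial,       # (n,) nS coupling to parent (0 for root)
    C,             # (n,) pF
    g_leak,        # (n,) nS
    e_leak,
    gNa,           # (n,) nS (max conductance per compartment)
    gK,            # (n,) nS
    e_na,
    e_k,
    v_shift,
    v_init,       # (n,) initial voltage per compartment
    # synapses
    syn_comp,      # (m,) int64 target compartment
    syn_g_ampa,    # (m,) nS peak-normalized AMPA gmax
    syn_g_nmda,    # (m,) nS peak-normalized NMDA gmax
    syn_act_bin,   # (m,) int64 activation step (<0: never)
    tau_ampa,      # (2,)
    tau_nmda,      # (2,)
    mg,            # mM
    rectify,       # bool
    # stimulation / recording
    i_inj_comp,    # int64, compartment receiving the current step (-1 none)
    i_inj_pa,      # pA
    record_idx,    # (r,) int64
    n_steps,
    dt,
):
    n = parent.shape[0]
    m = syn_comp.shape[0]
    v = v_init.copy()
    h = np.empty(n)
    ng = np.empty(n)
    for i in range(n):
        am, bm, ah, bh, an, bn = _rates(v[i] + v_shift)
        h[i] = ah / (ah + bh)
        ng[i] = an / (an + bn)

    # normalize kernels to unit peak so gmax is the actual peak conductance
    def_peak_a = _kernel_peak(tau_ampa[0], tau_ampa[1])
    def_peak_n = _kernel_peak(tau_nmda[0], tau_nmda[1])

    a1 = np.zeros(m)
    a2 = np.zeros(m)
    n1 = np.zeros(m)
    n2 = np.zeros(m)
    da1 = np.exp(-dt / tau_ampa[0]); da2 = np.exp(-dt / tau_ampa[1])
    dn1 = np.exp(-dt / tau_nmda[0]); dn2 = np.exp(-dt / tau_nmda[1])
    inv_a = 1.0 / (tau_ampa[1] - tau_ampa[0])
    inv_n = 1.0 / (tau_nmda[1] - tau_nmda[0])

    diag = np.empty(n)
    rhs = np.empty(n)
    off = np.empty(n)

    v_rec = np.empty((record_idx.shape[0], n_steps + 1))
    for r in range(record_idx.shape[0]):
        v_rec[r, 0] = v[record_idx[r]]

    err_step = -1
    for t in range(n_steps):
        # --- synapse kernels ----------------------------------------
        for s in range(m):
            a1[s] *= da1; a2[s] *= da2
            n1[s] *= dn1; n2[s] *= dn2
            if syn_act_bin[s] == t:
                a1[s] += 1.0; a2[s] += 1.0
                n1[s] += 1.0; n2[s] += 1.0

        # --- gates (exponential Euler at v_old) + CN assembly -------
        for i in range(n):
            g_tot = g_leak[i]
            b = g_leak[i] * e_leak
            if gNa[i] > 0.0 or gK[i] > 0.0:
                am, bm, ah, bh, an, bn = _rates(v[i] + v_shift)
                tau_h = 1.0 / (ah + bh)
                tau_n = 1.0 / (an + bn)
                h[i] += (ah * tau_h - h[i]) * (1.0 - np.exp(-dt / tau_h))
                ng[i] += (an * tau_n - ng[i]) * (1.0 - np.exp(-dt / tau_n))
                if gNa[i] > 0.0:
                    m_inf = am / (am + bm)
                    gna = gNa[i] * m_inf * m_inf * m_inf * h[i]
                    g_tot += gna
                    b += gna * e_na
                if gK[i] > 0.0:
                    gk = gK[i] * ng[i] ** 4
                    g_tot += gk
                    b += gk * e_k
            diag[i] = C[i] / dt + 0.5 * g_tot
            rhs[i] = (C[i] / dt - 0.5 * g_tot) * v[i] + b
        if i_inj_comp >= 0:
            rhs[i_inj_comp] += i_inj_pa
        for s in range(m):
            i = syn_comp[s]
            ga = syn_g_ampa[s] * (a2[s] - a1[s]) * inv_a / def_peak_a
            if rectify:
                ga *= _rect_factor(v[i])
            gn = syn_g_nmda[s] * (n2[s] - n1[s]) * inv_n / def_peak_n
            gn *= _mg_block(v[i], mg)
            g_syn = ga + gn
            # e_syn = 0 mV -> contributes only to the conductance terms
            diag[i] += 0.5 * g_syn
            rhs[i] -= 0.5 * g_syn * v[i]

        # axial terms (symmetric)
        for i in range(1, n):
            p = parent[i]
            ga = g_axial[i]
            off[i] = -0.5 * ga
            diag[i] += 0.5 * ga
            diag[p] += 0.5 * ga
            rhs[i] += 0.5 * ga * (v[p] - v[i])
            rhs[p] += 0.5 * ga * (v[i] - v[p])

        # --- Hines elimination (children before parents) ------------
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = off[i] / diag[i]
            diag[p] -= f * off[i]
            rhs[p] -= f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] - off[i] * v[parent[i]]) / diag[i]

        for r in range(record_idx.shape[0]):
            v_rec[r, t + 1] = v[record_idx[r]]
        if not np.isfinite(v[0]):
            err_step = t + 1
            break

    return v_rec, v, err_step


@njit(cache=True)
def _kernel_peak(t1, t2):
    tp = t1 * t2 / (t2 - t1) * np.log(t2 / t1)
    return (np.exp(-tp / t2) - np.exp(-tp / t1)) / (t2 - t1)
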