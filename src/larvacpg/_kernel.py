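"""Compiled integration loop.

The loop body mirrors :func:`larvacpg.engine._step_numpy` exactly; the two
backends are cross-checked against each other in the test suite.  Kept in its
own module so importing the package does not trigger compilation.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def run_kernel(
    n_steps, dt, every,
    V, m, ca, T, msyn,
    g_leak, E_leak, g_ca, v_mid, s_ca, tau_m,
    C, b_eff, tau_ca, ca_min, nernst_pref,
    ca_e_nm, opto_g, opto_E,
    pre, post, e_syn, r_max, ca_mid, s_r,
    tau_t, s_bind, g_eff,
    ev_step, ev_cell, ev_damp, ev_dslope, ev_dacc,
    op_step, op_cell, op_delta,
    rec_V, rec_m, rec_ca, rec_stim, rec_T, rec_msyn,
    conn_rec,
):
    nc = V.shape[0]
    nco = pre.shape[0]
    base = np.zeros(nc)
    slope = np.zeros(nc)
    acc = np.zeros(nc)
    opto_ct = np.zeros(nc, dtype=np.int64)
    gsum = np.zeros(nc)
    gesum = np.zeros(nc)
    # per-entity exponential decay factors (dt fixed over the run)
    am = np.exp(-dt / tau_m)
    aca = np.exp(-dt / tau_ca)
    at = np.exp(-dt / tau_t)
    ie = 0
    io = 0
    n_ev = ev_step.shape[0]
    n_op = op_step.shape[0]
    for k in range(n_steps):
        while ie < n_ev and ev_step[ie] == k:
            c = ev_cell[ie]
            base[c] += ev_damp[ie]
            slope[c] += ev_dslope[ie]
            acc[c] += ev_dacc[ie]
            ie += 1
        while io < n_op and op_step[io] == k:
            opto_ct[op_cell[io]] += op_delta[io]
            io += 1
        if k % every == 0:
            r = k // every
            for c in range(nc):
                rec_V[r, c] = V[c]
                rec_m[r, c] = m[c]
                rec_ca[r, c] = ca[c]
                rec_stim[r, c] = base[c] + acc[c]
            if conn_rec == 1:
                for j in range(nco):
                    rec_T[r, j] = T[j]
                    rec_msyn[r, j] = msyn[j]
        # synapses advance on presynaptic calcium from the step start
        for c in range(nc):
            gsum[c] = 0.0
            gesum[c] = 0.0
        for j in range(nco):
            rate = r_max[j] / (1.0 + np.exp((ca_mid[j] - ca[pre[j]]) / s_r[j]))
            tt = rate * tau_t[j]
            tj = tt + (T[j] - tt) * at[j]
            if tj < 0.0:
                tj = 0.0
            T[j] = tj
            ms = 2.0 / (1.0 + np.exp(-tj / s_bind[j])) - 1.0
            msyn[j] = ms
            g = g_eff[j] * ms
            p = post[j]
            gsum[p] += g
            gesum[p] += g * e_syn[j]
        # neurons: gate, calcium pool, then membrane potential
        for c in range(nc):
            minf = 1.0 / (1.0 + np.exp((v_mid[c] - V[c]) / s_ca[c]))
            mc = minf + (m[c] - minf) * am[c]
            m[c] = mc
            e_ca = nernst_pref[c] * np.log(ca_e_nm[c] / ca[c])
            g_ca_now = mc * g_ca[c]
            i_ca = g_ca_now * (V[c] - e_ca)
            inflow = 0.0
            if i_ca < 0.0:
                inflow = -b_eff[c] * i_ca
            ca_t = ca_min[c] + inflow * tau_ca[c]
            cc = ca_t + (ca[c] - ca_t) * aca[c]
            if cc < ca_min[c]:
                cc = ca_min[c]
            ca[c] = cc
            go = 0.0
            if opto_ct[c] > 0:
                go = opto_g[c]
            gs = g_leak[c] + g_ca_now + gsum[c] + go
            ge = g_leak[c] * E_leak[c] + g_ca_now * e_ca + gesum[c] \
                + go * opto_E[c]
            vinf = (ge + base[c] + acc[c]) / gs
            vc = vinf + (V[c] - vinf) * np.exp(-dt * gs / C[c])
            if not np.isfinite(vc):
                return np.array([k, c], dtype=np.int64)
            V[c] = vc
        for c in range(nc):
            acc[c] += slope[c] * dt
    return np.array([-1, -1], dtype=np.int64)
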