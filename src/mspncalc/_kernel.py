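"""Numba time-stepping kernel for the compartmental model.

One backward-Euler/exponential-Euler hybrid step per dt:

* ionic/synaptic conductances are evaluated from the gate states and
  voltages at the start of the step (conductance lagging);
* the voltage cable system is solved implicitly on the tree with the Hines
  elimination (compartments are ordered so every parent precedes its
  children);
* gates advance with the exponential-Euler update using tabulated
  steady-state and per-step decay-factor tables (BK and SK, which depend on
  calcium, use their closed forms);
* GHK calcium currents and the NMDA calcium component are treated as
  explicit current sources and feed first-order calcium pools via an exact
  exponential update.

All quantities are SI (V, s, S, F, A, m); concentrations are mM (mol/m^3);
the gate tables are indexed in mV.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# gate "special" codes
GATE_TABLE = 0
GATE_BK = 1
GATE_SK = 2

# pool indices
POOL_NR = 0
POOL_VGCC = 1
POOL_NMDA = 2

FARADAY = 96485.33212
GAS_CONSTANT = 8.31446


@njit(cache=True, fastmath=True)
def _ghk_drive(v, ca_in, ca_out, rt_inv):
    """GHK driving term for unit permeability-area (A per m^3/s); v in volts."""
    u = 2.0 * FARADAY * v * rt_inv
    if abs(u) < 1e-9:
        return 2.0 * FARADAY * (ca_in - ca_out)
    em = np.exp(-u)
    return 2.0 * FARADAY * u * (ca_in - ca_out * em) / (1.0 - em)


@njit(cache=True, fastmath=True)
def _ipow(x, e):
    if e == 1:
        return x
    if e == 2:
        return x * x
    return x * x * x


@njit(cache=True, fastmath=True)
def run_kernel(
    nsteps, dt,
    # topology / passive
    parent, cm, ga, gleak, eleak,
    # current steps: onset, offset (s, relative to kernel start), amp (A), comp
    stim_on, stim_off, stim_amp, stim_comp,
    # gate tables: [ngk, nv]; voltage grid vmin..(vmin+dv*(nv-1)) in mV
    special, inf_tab, fac_tab, vmin, dv,
    # BK / SK closed-form parameters
    bk_a_d, bk_a_k, bk_a_b, bk_b_d, bk_b_k, bk_b_b, sk_ec50, sk_hill, sk_fac,
    # channels: [nch] metadata, [nch, n] absolute conductances/permeabilities
    ch_mode, ch_erev, ch_g1, ch_g2, ch_e1, ch_e2, ch_gbar, ch_pool,
    # GHK / calcium constants
    ca_out, rt_inv,
    # pools: [3] rest (mM), per-step decay factor, tau; [3, n] tau/(2 F vol)
    pool_rest, pool_decay, pool_tau2fv,
    # synapses
    syn_comp, syn_gmax, syn_k, syn_faca, syn_facb, syn_erev, syn_mga,
    syn_mgscale, mg_conc, syn_kappa, nmda_ca_linear, eca,
    ev_t, ev_syn,
    # state (mutated in place)
    v, gates, ca_pools, syn_a, syn_b,
    # recording
    rec_stride, rec_v_idx, rec_ca_idx,
):
    n = v.shape[0]
    ngk = inf_tab.shape[0]
    nv_tab = inf_tab.shape[1]
    nch = ch_mode.shape[0]
    ns = syn_comp.shape[0]
    nst = stim_on.shape[0]
    nrec = nsteps // rec_stride + 1
    vrec = np.empty((nrec, rec_v_idx.shape[0]))
    carec = np.empty((nrec, rec_ca_idx.shape[0]))
    ok = True

    gtot = np.empty(n)
    itot = np.empty(n)
    i_ca_nr = np.empty(n)
    i_ca_vg = np.empty(n)
    i_ca_nm = np.empty(n)
    diag = np.empty(n)
    rhs = np.empty(n)
    off = np.empty(n)
    vidx = np.empty(n, dtype=np.int64)
    vw = np.empty(n)

    # record initial state
    for r in range(rec_v_idx.shape[0]):
        vrec[0, r] = v[rec_v_idx[r]]
    for r in range(rec_ca_idx.shape[0]):
        carec[0, r] = ca_pools[POOL_NMDA, rec_ca_idx[r]]

    ev_ptr = 0
    nev = ev_t.shape[0]
    rec_row = 1

    for step in range(nsteps):
        t = step * dt

        # --- synaptic state: decay, then apply events in (t, t+dt]
        for s in range(ns):
            syn_a[s] *= syn_faca[s]
            syn_b[s] *= syn_facb[s]
        while ev_ptr < nev and ev_t[ev_ptr] <= t + dt:
            syn_a[ev_syn[ev_ptr]] += 1.0
            syn_b[ev_syn[ev_ptr]] += 1.0
            ev_ptr += 1

        # --- assemble membrane conductances and explicit currents
        for i in range(n):
            gtot[i] = gleak[i]
            itot[i] = gleak[i] * eleak
            i_ca_nr[i] = 0.0
            i_ca_vg[i] = 0.0
            i_ca_nm[i] = 0.0

        for k in range(nch):
            g1 = ch_g1[k]
            g2 = ch_g2[k]
            e1 = ch_e1[k]
            e2 = ch_e2[k]
            if ch_mode[k] == 0:
                erev = ch_erev[k]
                for i in range(n):
                    gb = ch_gbar[k, i]
                    if gb == 0.0:
                        continue
                    o = _ipow(gates[g1, i], e1)
                    if g2 >= 0:
                        o *= _ipow(gates[g2, i], e2)
                    g = gb * o
                    gtot[i] += g
                    itot[i] += g * erev
            else:
                tgt = ch_pool[k]
                for i in range(n):
                    pb = ch_gbar[k, i]
                    if pb == 0.0:
                        continue
                    o = _ipow(gates[g1, i], e1)
                    if g2 >= 0:
                        o *= _ipow(gates[g2, i], e2)
                    ca_in = ca_pools[tgt, i]
                    ic = pb * o * _ghk_drive(v[i], ca_in, ca_out, rt_inv)
                    itot[i] -= ic
                    if tgt == POOL_NR:
                        i_ca_nr[i] += ic
                    else:
                        i_ca_vg[i] += ic

        # --- synapses (conductance implicit, Mg factor and Ca flux lagged)
        for s in range(ns):
            i = syn_comp[s]
            g = syn_gmax[s] * syn_k[s] * (syn_b[s] - syn_a[s])
            if g < 0.0:
                g = 0.0
            if syn_mga[s] > 0.0:
                blk = 1.0 / (1.0 + (mg_conc / syn_mga[s])
                             * np.exp(-v[i] * 1e3 / syn_mgscale))
                g *= blk
            gtot[i] += g
            itot[i] += g * syn_erev[s]
            if syn_kappa[s] > 0.0 and g > 0.0:
                if nmda_ca_linear:
                    icn = syn_kappa[s] * g * (v[i] - eca)
                else:
                    icn = syn_kappa[s] * g * _ghk_drive(
                        v[i], ca_pools[POOL_NMDA, i], ca_out, rt_inv)
                i_ca_nm[i] += icn

        # --- injected current steps
        for q in range(nst):
            if stim_on[q] <= t < stim_off[q]:
                itot[stim_comp[q]] += stim_amp[q]

        # --- implicit cable solve (Hines: parents precede children)
        for i in range(n):
            diag[i] = cm[i] / dt + gtot[i]
            rhs[i] = cm[i] / dt * v[i] + itot[i]
            off[i] = -ga[i]
        for i in range(n):
            if parent[i] >= 0:
                diag[i] += ga[i]
                diag[parent[i]] += ga[i]
        for i in range(n - 1, 0, -1):
            p = parent[i]
            f = off[i] / diag[i]
            diag[p] -= f * off[i]
            rhs[p] -= f * rhs[i]
        v[0] = rhs[0] / diag[0]
        for i in range(1, n):
            v[i] = (rhs[i] - off[i] * v[parent[i]]) / diag[i]
            if v[i] > 0.2 or v[i] < -0.2:
                ok = False
        if not ok:
            break

        # --- gate updates (exponential Euler at the post-solve voltage:
        # the staggered alignment that makes the scheme second order)
        for i in range(n):
            x = (v[i] * 1e3 - vmin) / dv
            if x < 0.0:
                x = 0.0
            elif x > nv_tab - 1.001:
                x = nv_tab - 1.001
            j = int(x)
            vidx[i] = j
            vw[i] = x - j
        for gk in range(ngk):
            sp = special[gk]
            if sp == GATE_TABLE:
                for i in range(n):
                    j = vidx[i]
                    w = vw[i]
                    inf = inf_tab[gk, j] * (1.0 - w) + inf_tab[gk, j + 1] * w
                    fac = fac_tab[gk, j] * (1.0 - w) + fac_tab[gk, j + 1] * w
                    gates[gk, i] += (inf - gates[gk, i]) * fac
            elif sp == GATE_BK:
                for i in range(n):
                    ca = ca_pools[POOL_NR, i]
                    vm = v[i]
                    ea = np.exp(2.0 * vm * bk_a_d * FARADAY * rt_inv)
                    eb = np.exp(2.0 * vm * bk_b_d * FARADAY * rt_inv)
                    al = bk_a_b * ca / (ca + bk_a_k * ea)
                    be = bk_b_b / (1.0 + ca / (bk_b_k * eb))
                    s_ab = al + be
                    inf = al / s_ab
                    gates[gk, i] += (inf - gates[gk, i]) * (1.0 - np.exp(-dt * s_ab))
            else:  # SK
                for i in range(n):
                    ca = ca_pools[POOL_NR, i]
                    x = (ca / sk_ec50) ** sk_hill
                    inf = x / (1.0 + x)
                    gates[gk, i] += (inf - gates[gk, i]) * sk_fac

        # --- calcium pools (exact first-order update toward shifted target)
        for i in range(n):
            for pidx in range(3):
                if pidx == POOL_NR:
                    ic = i_ca_nr[i]
                elif pidx == POOL_VGCC:
                    ic = i_ca_vg[i]
                else:
                    ic = i_ca_nm[i]
                tgt = pool_rest[pidx] - ic * pool_tau2fv[pidx, i]
                c = tgt + (ca_pools[pidx, i] - tgt) * pool_decay[pidx]
                if c < 0.0:
                    c = 0.0
                ca_pools[pidx, i] = c

        if (step + 1) % rec_stride == 0:
            for r in range(rec_v_idx.shape[0]):
                vrec[rec_row, r] = v[rec_v_idx[r]]
            for r in range(rec_ca_idx.shape[0]):
                carec[rec_row, r] = ca_pools[POOL_NMDA, rec_ca_idx[r]]
            rec_row += 1

    return vrec, carec, ok, rec_row
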