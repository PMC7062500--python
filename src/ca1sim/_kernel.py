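"""Numba kernels: Hines tree solve and the Crank–Nicolson time stepper.

The stepper advances the branched cable equation with staggered gating-state
updates (states move on half-step offsets, voltages by CN with per-step
linearization of the ionic currents), mirroring the standard second-order
scheme of compartmental simulators.  All state lives in flat float64 arrays;
the kernel is deliberately monolithic so a full simulation runs without
Python-level per-step overhead.
"""

import math

import numpy as np
from numba import njit

F_FARADAY = 96485.33212  # C/mol
R_GAS = 8.31446261815    # J/(mol·K)


@njit(cache=True)
def hines_solve_kernel(diag, offdiag, parent, rhs, x):
    n = diag.shape[0]
    for i in range(n - 1, 0, -1):
        if diag[i] == 0.0:
            return False
        p = parent[i]
        f = offdiag[i] / diag[i]
        diag[p] -= f * offdiag[i]
        rhs[p] -= f * rhs[i]
    if diag[0] == 0.0:
        return False
    x[0] = rhs[0] / diag[0]
    for i in range(1, n):
        x[i] = (rhs[i] - offdiag[i] * x[parent[i]]) / diag[i]
    return True


@njit(cache=True, inline="always")
def _vtrap(x, y):
    # x/(1-exp(-x/y)) with the removable singularity handled
    if abs(x / y) < 1e-6:
        return y + x / 2.0
    return x / (1.0 - math.exp(-x / y))


@njit(cache=True, inline="always")
def _na_rates(v, scale):
    am = 0.1 * _vtrap(v + 40.0, 10.0)
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    return am * scale, bm * scale, ah * scale, bh * scale


@njit(cache=True, inline="always")
def _kdr_rates(v, scale):
    an = 0.01 * _vtrap(v + 55.0, 10.0)
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    return an * scale, bn * scale


@njit(cache=True, inline="always")
def _ka_steady(v):
    a_inf = 1.0 / (1.0 + math.exp(-(v + 15.0) / 10.0))
    b_inf = 1.0 / (1.0 + math.exp((v + 56.0) / 8.0))
    return a_inf, 2.0, b_inf, 20.0  # (a_inf, tau_a, b_inf, tau_b) in ms


@njit(cache=True, inline="always")
def _cal_steady(v):
    m_inf = 1.0 / (1.0 + math.exp(-(v + 15.0) / 6.0))
    return m_inf, 1.5


@njit(cache=True, inline="always")
def _gate_step(x, x_inf, tau, dt):
    return x + (1.0 - math.exp(-dt / tau)) * (x_inf - x)


@njit(cache=True, inline="always")
def _ncx_phi(v, ca, vmax, allo_scale, gamma, ksat, kmna, kmca, kmcaact,
             nhill, nai, nao, cao, krt):
    # krt = 1e-3 * F / (R*T), per mV
    allo = allo_scale / (1.0 + (kmcaact / ca) ** nhill)
    if allo > 1.0:
        allo = 1.0
    e1 = math.exp(gamma * krt * v)
    e2 = math.exp((gamma - 1.0) * krt * v)
    num = nai ** 3 * cao * e1 - nao ** 3 * ca * e2
    den = (kmna ** 3 + nao ** 3) * (kmca + cao) * (1.0 + ksat * e2)
    return allo * vmax * num / den


@njit(cache=True)
def simulate_kernel(
    # geometry / passive (per compartment)
    parent, area, g_ax, cm, g_leak, e_leak,
    # densities (per compartment)
    gna, gkdr, gka, gcal, gkca, ncx_vmax, allo_scale,
    # scalar channel parameters
    e_na, e_k, e_ca, rate_scale,
    kca_alpha, kca_beta, kca_n, kca_taumin,
    ncx_gamma, ncx_ksat, ncx_kmna, ncx_kmca, ncx_kmcaact, ncx_nhill,
    nai, nao, cao, temp_k,
    ca_depth_um, ca_tau, ca_rest, ca_min,
    # current clamps
    ic_comp, ic_amp, ic_start, ic_dur,
    # synapses
    syn_comp, syn_kind, syn_erev, syn_weight, syn_tau1, syn_tau2,
    syn_ev_times, syn_ev_off,
    # numerics / recording
    v_init, dt, n_steps, rec_every, record_currents,
):
    n = parent.shape[0]
    n_syn = syn_comp.shape[0]
    krt = 1e-3 * F_FARADAY / (R_GAS * temp_k)
    depth_cm = ca_depth_um * 1e-4
    ca_flux_fac = 1.0 / (2.0 * F_FARADAY * depth_cm)  # (mA/cm²) -> mM/ms

    # state
    v = np.full(n, v_init)
    ca = np.full(n, ca_rest)
    m_na = np.empty(n); h_na = np.empty(n); n_kdr = np.empty(n)
    a_ka = np.empty(n); b_ka = np.empty(n); m_cal = np.empty(n)
    m_kca = np.empty(n)
    for i in range(n):
        am, bm, ah, bh = _na_rates(v_init, rate_scale)
        m_na[i] = am / (am + bm); h_na[i] = ah / (ah + bh)
        an, bn = _kdr_rates(v_init, rate_scale)
        n_kdr[i] = an / (an + bn)
        ai, _, bi, _ = _ka_steady(v_init)
        a_ka[i] = ai; b_ka[i] = bi
        mi, _ = _cal_steady(v_init)
        m_cal[i] = mi
        acan = kca_alpha * ca_rest ** kca_n
        m_kca[i] = acan / (acan + kca_beta)

    # synapse states
    syn_a = np.zeros(n_syn)
    syn_b = np.zeros(n_syn)
    syn_dec1 = np.empty(n_syn)
    syn_dec2 = np.empty(n_syn)
    syn_norm = np.empty(n_syn)
    syn_ptr = np.zeros(n_syn, dtype=np.int64)
    for s in range(n_syn):
        if syn_kind[s] == 0:
            syn_dec1[s] = math.exp(-dt / syn_tau2[s])
            syn_dec2[s] = 1.0
            syn_norm[s] = 1.0
        else:
            t1 = syn_tau1[s]; t2 = syn_tau2[s]
            syn_dec1[s] = math.exp(-dt / t1)
            syn_dec2[s] = math.exp(-dt / t2)
            tp = t1 * t2 / (t2 - t1) * math.log(t2 / t1)
            syn_norm[s] = 1.0 / (-math.exp(-tp / t1) + math.exp(-tp / t2))

    # recording buffers
    n_rec = n_steps // rec_every + 1
    t_rec = np.empty(n_rec)
    v_rec = np.empty((n_rec, n))
    ca_rec = np.empty((n_rec, n))
    if record_currents:
        incx_rec = np.empty((n_rec, n))
        ikca_rec = np.empty((n_rec, n))
        ik_rec = np.empty((n_rec, n))
        ina_rec = np.empty((n_rec, n))
    else:
        incx_rec = np.empty((1, 1))
        ikca_rec = np.empty((1, 1))
        ik_rec = np.empty((1, 1))
        ina_rec = np.empty((1, 1))

    diag = np.empty(n)
    off = np.empty(n)
    rhs = np.empty(n)
    dv = np.empty(n)
    i_mem = np.empty(n)
    g_mem = np.empty(n)
    i_ncx = np.empty(n)
    i_kca_a = np.empty(n)
    i_k_a = np.empty(n)
    i_na_a = np.empty(n)

    status = 0
    bad_comp = -1
    bad_step = -1
    rec_i = 0

    for step in range(n_steps + 1):
        # ---- membrane currents at current state (also used for recording)
        for i in range(n):
            vi = v[i]
            if abs(vi) > 1000.0 or not math.isfinite(vi):
                status = 1; bad_comp = i; bad_step = step
                break
            ii = g_leak[i] * (vi - e_leak[i])
            gi = g_leak[i]
            ina = 0.0; ik = 0.0
            if gna[i] > 0.0:
                gch = gna[i] * m_na[i] ** 3 * h_na[i]
                cur = gch * (vi - e_na)
                ii += cur; gi += gch; ina += cur
            if gkdr[i] > 0.0:
                gch = gkdr[i] * n_kdr[i] ** 4
                cur = gch * (vi - e_k)
                ii += cur; gi += gch; ik += cur
            if gka[i] > 0.0:
                gch = gka[i] * a_ka[i] * b_ka[i]
                cur = gch * (vi - e_k)
                ii += cur; gi += gch; ik += cur
            ical = 0.0
            if gcal[i] > 0.0:
                gch = gcal[i] * m_cal[i] ** 2
                ical = gch * (vi - e_ca)
                ii += ical; gi += gch
            ikca = 0.0
            if gkca[i] > 0.0:
                gch = gkca[i] * m_kca[i] ** 2
                ikca = gch * (vi - e_k)
                ii += ikca; gi += gch; ik += ikca
            phi = 0.0
            if ncx_vmax[i] > 0.0:
                phi = _ncx_phi(vi, ca[i], ncx_vmax[i], allo_scale[i],
                               ncx_gamma, ncx_ksat, ncx_kmna, ncx_kmca,
                               ncx_kmcaact, ncx_nhill, nai, nao, cao, krt)
                dvn = 0.25
                phi_p = _ncx_phi(vi + dvn, ca[i], ncx_vmax[i], allo_scale[i],
                                 ncx_gamma, ncx_ksat, ncx_kmna, ncx_kmca,
                                 ncx_kmcaact, ncx_nhill, nai, nao, cao, krt)
                phi_m = _ncx_phi(vi - dvn, ca[i], ncx_vmax[i], allo_scale[i],
                                 ncx_gamma, ncx_ksat, ncx_kmna, ncx_kmca,
                                 ncx_kmcaact, ncx_nhill, nai, nao, cao, krt)
                gch = (phi_p - phi_m) / (2.0 * dvn)
                ii += phi
                if gch > 0.0:
                    gi += gch
                ina += 3.0 * phi
            i_mem[i] = ii
            g_mem[i] = gi
            i_ncx[i] = phi
            i_kca_a[i] = ikca
            i_k_a[i] = ik
            i_na_a[i] = ina
        if status != 0:
            break

        # ---- record
        if step % rec_every == 0:
            t_rec[rec_i] = step * dt
            for i in range(n):
                v_rec[rec_i, i] = v[i]
                ca_rec[rec_i, i] = ca[i]
            if record_currents:
                for i in range(n):
                    incx_rec[rec_i, i] = i_ncx[i]
                    ikca_rec[rec_i, i] = i_kca_a[i]
                    ik_rec[rec_i, i] = i_k_a[i]
                    ina_rec[rec_i, i] = i_na_a[i]
            rec_i += 1
        if step == n_steps:
            break

        t = step * dt
        t_mid = t + 0.5 * dt

        # ---- advance gating states (staggered half-step update at V(t))
        for i in range(n):
            vi = v[i]
            if gna[i] > 0.0:
                am, bm, ah, bh = _na_rates(vi, rate_scale)
                m_na[i] = _gate_step(m_na[i], am / (am + bm), 1.0 / (am + bm), dt)
                h_na[i] = _gate_step(h_na[i], ah / (ah + bh), 1.0 / (ah + bh), dt)
            if gkdr[i] > 0.0:
                an, bn = _kdr_rates(vi, rate_scale)
                n_kdr[i] = _gate_step(n_kdr[i], an / (an + bn), 1.0 / (an + bn), dt)
            if gka[i] > 0.0:
                ai, ta, bi, tb = _ka_steady(vi)
                a_ka[i] = _gate_step(a_ka[i], ai, ta, dt)
                b_ka[i] = _gate_step(b_ka[i], bi, tb, dt)
            if gcal[i] > 0.0:
                mi, tm = _cal_steady(vi)
                m_cal[i] = _gate_step(m_cal[i], mi, tm, dt)
            if gkca[i] > 0.0:
                acan = kca_alpha * ca[i] ** kca_n
                tau = 1.0 / (acan + kca_beta)
                if tau < kca_taumin:
                    tau = kca_taumin
                m_kca[i] = _gate_step(m_kca[i], acan / (acan + kca_beta), tau, dt)

        # ---- calcium pool (sources at current V with updated gates)
        for i in range(n):
            i_ca_tot = 0.0
            if gcal[i] > 0.0:
                i_ca_tot += gcal[i] * m_cal[i] ** 2 * (v[i] - e_ca)
            if ncx_vmax[i] > 0.0:
                phi = _ncx_phi(v[i], ca[i], ncx_vmax[i], allo_scale[i],
                               ncx_gamma, ncx_ksat, ncx_kmna, ncx_kmca,
                               ncx_kmcaact, ncx_nhill, nai, nao, cao, krt)
                i_ca_tot += -2.0 * phi
            src = -i_ca_tot * ca_flux_fac
            ca[i] = (ca[i] + dt * (src + ca_rest / ca_tau)) / (1.0 + dt / ca_tau)
            if ca[i] < ca_min:
                ca[i] = ca_min

        # ---- synapse state decay + event delivery (events snap to steps)
        for s in range(n_syn):
            syn_a[s] *= syn_dec1[s]
            syn_b[s] *= syn_dec2[s]
            p0 = syn_ptr[s]
            p_end = syn_ev_off[s + 1]
            while p0 < p_end and syn_ev_times[p0] < t_mid:
                if syn_kind[s] == 0:
                    syn_a[s] += syn_weight[s]
                else:
                    syn_a[s] += syn_weight[s] * syn_norm[s]
                    syn_b[s] += syn_weight[s] * syn_norm[s]
                p0 += 1
            syn_ptr[s] = p0

        # ---- assemble CN system for dV
        for i in range(n):
            c_dt = cm[i] * area[i] * 1e-3 / dt      # S
            diag[i] = c_dt + 0.5 * g_mem[i] * area[i]
            rhs[i] = -i_mem[i] * area[i]            # mA
            off[i] = 0.0
        for i in range(1, n):
            p = parent[i]
            g = g_ax[i]
            diag[i] += 0.5 * g
            diag[p] += 0.5 * g
            off[i] = -0.5 * g
            rhs[i] -= g * (v[i] - v[p])             # S × mV = mA
            rhs[p] -= g * (v[p] - v[i])
        # synaptic conductances (μS) and clamp currents (nA)
        for s in range(n_syn):
            if syn_kind[s] == 0:
                gs = syn_a[s] * 1e-6                # μS -> S
            else:
                gs = (syn_b[s] - syn_a[s]) * 1e-6
            if gs != 0.0:
                i = syn_comp[s]
                rhs[i] -= gs * (v[i] - syn_erev[s])
                diag[i] += 0.5 * gs
        for k in range(ic_comp.shape[0]):
            if ic_start[k] <= t_mid < ic_start[k] + ic_dur[k]:
                rhs[ic_comp[k]] += ic_amp[k] * 1e-6  # nA -> mA

        ok = hines_solve_kernel(diag, off, parent, rhs, dv)
        if not ok:
            status = 2; bad_step = step
            break
        for i in range(n):
            v[i] += dv[i]

    return (t_rec[:rec_i], v_rec[:rec_i], ca_rec[:rec_i],
            incx_rec[:rec_i] if record_currents else incx_rec,
            ikca_rec[:rec_i] if record_currents else ikca_rec,
            ik_rec[:rec_i] if record_currents else ik_rec,
            ina_rec[:rec_i] if record_currents else ina_rec,
            status, bad_comp, bad_step)
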