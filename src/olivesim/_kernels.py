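"""Numba inner loops for the fixed-step (forward Euler) simulations.

All kernels work in the canonical unit system ms / mV / nS / pA / pF, in
which ``nS * mV = pA`` and ``pF / nS = ms``.  Synaptic input spikes arrive
as sorted arrays of integer step indices (one entry per spike, repeats
allowed).  Alpha-function synapses use the exact two-state exponential
recursion

    u(t) = sum_i exp(-(t-t_i)/tau)          u <- d*u          (+1 at spikes)
    s(t) = sum_i ((t-t_i)/tau) e^{-(t-t_i)/tau}
                                            s <- d*(s + (dt/tau)*u)

with ``d = exp(-dt/tau)``, so the alpha conductance is ``A * e * s`` and no
spike history needs to be stored.
"""

import numpy as np
from numba import njit

E = 2.718281828459045235


@njit(cache=False)
def alpha_conductance(steps, n_steps, dt, tau, amp):
    """Summed alpha-kernel conductance sampled on the integration grid."""
    d = np.exp(-dt / tau)
    c = dt / tau
    g = np.empty(n_steps)
    u = 0.0
    s = 0.0
    p = 0
    m = steps.size
    for i in range(n_steps):
        if i > 0:
            s = d * (s + c * u)
            u = d * u
        while p < m and steps[p] == i:
            u += 1.0
            p += 1
        g[i] = amp * E * s
    return g


@njit(cache=False)
def stein_loop(
    ex_steps,
    inh_steps,
    n_steps,
    dt,
    alpha_kind,      # False: exponential kernels, True: alpha kernels
    theta,
    tau_ex,
    h,
    tau_inh,
    tref_steps,
    persist,         # inputs arriving during the refractory period persist
    record,
):
    dex = np.exp(-dt / tau_ex)
    din = np.exp(-dt / tau_inh)
    cex = dt / tau_ex
    cin = dt / tau_inh
    uex = 0.0
    sex = 0.0
    uin = 0.0
    sin = 0.0
    pex = 0
    pin = 0
    nex = ex_steps.size
    nin = inh_steps.size
    refr = 0
    max_spk = n_steps // max(tref_steps, 1) + 2
    spikes = np.empty(max_spk, np.int64)
    nspk = 0
    v_tr = np.empty(n_steps if record else 0)
    for i in range(n_steps):
        if i > 0:
            if alpha_kind:
                sex = dex * (sex + cex * uex)
                uex = dex * uex
                sin = din * (sin + cin * uin)
                uin = din * uin
            else:
                uex = dex * uex
                uin = din * uin
        skip_inputs = (refr > 0) and (not persist)
        while pex < nex and ex_steps[pex] == i:
            if not skip_inputs:
                uex += 1.0
            pex += 1
        while pin < nin and inh_steps[pin] == i:
            if not skip_inputs:
                uin += 1.0
            pin += 1
        if alpha_kind:
            v = E * sex - h * E * sin
        else:
            v = uex - h * uin
        if refr > 0:
            refr -= 1
            if record:
                v_tr[i] = 0.0
            continue
        if v >= theta:
            spikes[nspk] = i
            nspk += 1
            uex = 0.0
            sex = 0.0
            uin = 0.0
            sin = 0.0
            # clamp covers [t_sp, t_sp + T_ref); threshold detection is
            # possible again exactly T_ref after the spike
            refr = max(tref_steps - 1, 0)
            v = 0.0
        if record:
            v_tr[i] = v
    return spikes[:nspk], v_tr


@njit(cache=False)
def passive_if_loop(
    ex_steps,
    inh_steps,
    n_steps,
    dt,
    cap,
    g_l,
    e_l,
    v_reset,
    v_theta,
    tref_steps,
    a_ex,
    tau_ex,
    e_ex,
    a_inh,
    tau_inh,
    e_inh,
    i_const,
    i_arr,
    spikes_enabled,
    v0,
    record,
):
    dex = np.exp(-dt / tau_ex)
    din = np.exp(-dt / tau_inh)
    cex = dt / tau_ex
    cin = dt / tau_inh
    uex = 0.0
    sex = 0.0
    uin = 0.0
    sin = 0.0
    pex = 0
    pin = 0
    nex = ex_steps.size
    nin = inh_steps.size
    use_arr = i_arr.size > 0
    v = v0
    refr = 0
    max_spk = n_steps // max(tref_steps, 1) + 2
    spikes = np.empty(max_spk, np.int64)
    nspk = 0
    v_tr = np.empty(n_steps if record else 0)
    for i in range(n_steps):
        if i > 0:
            sex = dex * (sex + cex * uex)
            uex = dex * uex
            sin = din * (sin + cin * uin)
            uin = din * uin
        while pex < nex and ex_steps[pex] == i:
            uex += 1.0
            pex += 1
        while pin < nin and inh_steps[pin] == i:
            uin += 1.0
            pin += 1
        if refr > 0:
            refr -= 1
            v = v_reset
            if record:
                v_tr[i] = v
            continue
        g_ex = a_ex * E * sex
        g_inh = a_inh * E * sin
        i_ext = i_const + (i_arr[i] if use_arr else 0.0)
        i_tot = g_l * (e_l - v) + g_ex * (e_ex - v) + g_inh * (e_inh - v) + i_ext
        v += dt * i_tot / cap
        if spikes_enabled and v >= v_theta:
            spikes[nspk] = i
            nspk += 1
            v = v_reset
            refr = max(tref_steps - 1, 0)
        if record:
            v_tr[i] = v
        if not np.isfinite(v):
            raise ValueError("membrane potential diverged (non-finite state)")
    state = np.empty(1)
    state[0] = v
    return spikes[:nspk], v_tr, state


@njit(cache=False)
def active_if_loop(
    ex_steps,
    inh_steps,
    n_steps,
    dt,
    cap,
    g_l,
    g_kl,
    e_l,
    e_k,
    v_theta,
    tref_steps,
    a_ex,
    tau_ex,
    e_ex,
    a_inh,
    tau_inh,
    e_inh,
    i_const,
    i_arr,
    spikes_enabled,
    v0,
    d0,
    record,
):
    dex = np.exp(-dt / tau_ex)
    din = np.exp(-dt / tau_inh)
    cex = dt / tau_ex
    cin = dt / tau_inh
    # spike-associated current: 24 nA e^{-t/0.15} - 12 nA e^{-t/0.30}, in pA
    dsa = np.exp(-dt / 0.15)
    dsb = np.exp(-dt / 0.30)
    sa = 0.0
    sb = 0.0
    uex = 0.0
    sex = 0.0
    uin = 0.0
    sin = 0.0
    pex = 0
    pin = 0
    nex = ex_steps.size
    nin = inh_steps.size
    use_arr = i_arr.size > 0
    v = v0
    d = d0
    d_min = d0
    d_max = d0
    last_spk = -tref_steps - 1
    max_spk = n_steps // max(tref_steps, 1) + 2
    spikes = np.empty(max_spk, np.int64)
    nspk = 0
    v_tr = np.empty(n_steps if record else 0)
    for i in range(n_steps):
        if i > 0:
            sex = dex * (sex + cex * uex)
            uex = dex * uex
            sin = din * (sin + cin * uin)
            uin = din * uin
            sa = dsa * sa
            sb = dsb * sb
        while pex < nex and ex_steps[pex] == i:
            uex += 1.0
            pex += 1
        while pin < nin and inh_steps[pin] == i:
            uin += 1.0
            pin += 1
        g_ex = a_ex * E * sex
        g_inh = a_inh * E * sin
        # KLVA gate kinetics (rates in 1/ms)
        ad = 0.5 * np.exp((v + 50.0) / 16.0)
        bd = 0.5 * np.exp(-(v + 50.0) / 16.0)
        denom = ad + bd
        d_inf = ad / denom
        i_ext = i_const + (i_arr[i] if use_arr else 0.0)
        i_spike = 24000.0 * sa - 12000.0 * sb
        i_tot = (
            g_l * (e_l - v)
            + g_kl * d * (e_k - v)
            + g_ex * (e_ex - v)
            + g_inh * (e_inh - v)
            + i_spike
            + i_ext
        )
        v += dt * i_tot / cap
        if not np.isfinite(v):
            raise ValueError("membrane potential diverged (non-finite state)")
        # forward Euler on d; snap to steady state if the step would overshoot
        # (only reachable at non-physiological voltages, e.g. clamp bracketing)
        dfac = dt * denom
        if dfac > 1.0 or not np.isfinite(dfac):
            d = d_inf
        else:
            d += dfac * (d_inf - d)
        if d < d_min:
            d_min = d
        if d > d_max:
            d_max = d
        if spikes_enabled and v >= v_theta and i - last_spk >= tref_steps:
            spikes[nspk] = i
            nspk += 1
            last_spk = i
            sa += 1.0
            sb += 1.0
        if record:
            v_tr[i] = v
    state = np.empty(2)
    state[0] = v
    state[1] = d
    return spikes[:nspk], v_tr, state, d_min, d_max


@njit(cache=False)
def wc_loop(
    ex_steps,
    inh_steps,
    n_steps,
    dt,
    cap,
    g_l,
    g_kl,
    g_kh,
    g_na,
    e_l,
    e_k,
    e_na,
    v_shift,
    phi,
    a_ex,
    tau_ex,
    e_ex,
    a_inh,
    tau_inh,
    e_inh,
    i_const,
    i_arr,
    count_spikes,
    state0,          # [v, w, z, n, p, m, h]
    record,
):
    dex = np.exp(-dt / tau_ex)
    din = np.exp(-dt / tau_inh)
    cex = dt / tau_ex
    cin = dt / tau_inh
    uex = 0.0
    sex = 0.0
    uin = 0.0
    sin = 0.0
    pex = 0
    pin = 0
    nexs = ex_steps.size
    nins = inh_steps.size
    use_arr = i_arr.size > 0
    v = state0[0]
    w = state0[1]
    z = state0[2]
    n = state0[3]
    p = state0[4]
    m = state0[5]
    h = state0[6]
    gate_min = 1.0
    gate_max = 0.0
    for g0 in state0[1:]:
        if g0 < gate_min:
            gate_min = g0
        if g0 > gate_max:
            gate_max = g0
    max_spk = n_steps // 50 + 16
    spikes = np.empty(max_spk, np.int64)
    nspk = 0
    armed = False
    arm_step = 0
    v_tr = np.empty(n_steps if record else 0)
    for i in range(n_steps):
        if i > 0:
            sex = dex * (sex + cex * uex)
            uex = dex * uex
            sin = din * (sin + cin * uin)
            uin = din * uin
        while pex < nexs and ex_steps[pex] == i:
            uex += 1.0
            pex += 1
        while pin < nins and inh_steps[pin] == i:
            uin += 1.0
            pin += 1
        g_ex = a_ex * E * sex
        g_inh = a_inh * E * sin

        vs = v - v_shift
        # Rothman-Manis (2003) type-II kinetics, evaluated at the shifted V
        w_inf = (1.0 / (1.0 + np.exp(-(vs + 48.0) / 6.0))) ** 0.25
        tau_w = 1.5 + 100.0 / (
            6.0 * np.exp((vs + 60.0) / 6.0) + 16.0 * np.exp(-(vs + 60.0) / 45.0)
        )
        z_inf = 0.5 + 0.5 / (1.0 + np.exp((vs + 71.0) / 10.0))
        tau_z = 50.0 + 1000.0 / (
            np.exp((vs + 60.0) / 20.0) + np.exp(-(vs + 60.0) / 8.0)
        )
        n_inf = (1.0 / (1.0 + np.exp(-(vs + 15.0) / 5.0))) ** 0.5
        tau_n = 0.7 + 100.0 / (
            11.0 * np.exp((vs + 60.0) / 24.0) + 21.0 * np.exp(-(vs + 60.0) / 23.0)
        )
        p_inf = 1.0 / (1.0 + np.exp(-(vs + 23.0) / 6.0))
        tau_p = 5.0 + 100.0 / (
            4.0 * np.exp((vs + 60.0) / 32.0) + 5.0 * np.exp(-(vs + 60.0) / 22.0)
        )
        m_inf = 1.0 / (1.0 + np.exp(-(vs + 38.0) / 7.0))
        tau_m = 0.04 + 10.0 / (
            5.0 * np.exp((vs + 60.0) / 18.0) + 36.0 * np.exp(-(vs + 60.0) / 25.0)
        )
        h_inf = 1.0 / (1.0 + np.exp((vs + 65.0) / 6.0))
        tau_h = 0.6 + 100.0 / (
            7.0 * np.exp((vs + 60.0) / 11.0) + 10.0 * np.exp(-(vs + 60.0) / 25.0)
        )

        i_ext = i_const + (i_arr[i] if use_arr else 0.0)
        w4 = w * w * w * w
        i_kl = g_kl * w4 * z * (e_k - v)
        i_kh = g_kh * (0.85 * n * n + 0.15 * p) * (e_k - v)
        i_na = g_na * m * m * m * h * (e_na - v)
        i_tot = (
            g_l * (e_l - v)
            + i_kl
            + i_kh
            + i_na
            + g_ex * (e_ex - v)
            + g_inh * (e_inh - v)
            + i_ext
        )
        v += dt * i_tot / cap
        w += dt * phi * (w_inf - w) / tau_w
        z += dt * phi * (z_inf - z) / tau_z
        n += dt * phi * (n_inf - n) / tau_n
        p += dt * phi * (p_inf - p) / tau_p
        m += dt * phi * (m_inf - m) / tau_m
        h += dt * phi * (h_inf - h) / tau_h
        lo = min(min(min(w, z), min(n, p)), min(m, h))
        hi = max(max(max(w, z), max(n, p)), max(m, h))
        if lo < gate_min:
            gate_min = lo
        if hi > gate_max:
            gate_max = hi
        # spike = depolarization above -30 mV followed by repolarization
        # below -45 mV; the spike time is the upward -30 mV crossing
        if count_spikes:
            if not armed and v > -30.0:
                armed = True
                arm_step = i
            elif armed and v < -45.0:
                armed = False
                spikes[nspk] = arm_step
                nspk += 1
        if record:
            v_tr[i] = v
        if not np.isfinite(v):
            raise ValueError("membrane potential diverged (non-finite state)")
    state = np.empty(7)
    state[0] = v
    state[1] = w
    state[2] = z
    state[3] = n
    state[4] = p
    state[5] = m
    state[6] = h
    return spikes[:nspk], v_tr, state, gate_min, gate_max
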