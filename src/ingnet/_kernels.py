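"""Numba integration kernels.

All quantities use the package unit system: mV, ms, nS, pA, pF
(nS*mV = pA; pA/pF = mV/ms).

Gate ordering everywhere: 0=m (Na activation), 1=h (Na inactivation),
2=n (Kv3 activation), 3=a (Kv1 activation).
Kinetics array layout: kin[gate, 0:5] = (theta, sigma1, sigma2, k1, k2).
"""

import numpy as np
from numba import njit

ENA = 50.0
EK = -90.0
ECHR = 0.0

# status codes returned by kernels
OK = 0
BLOWUP = 1
SPIKE_OVERFLOW = 2

V_BLOWUP = 200.0


@njit(cache=True, inline="always")
def _singular_rate(u, sigma, k):
    # k*u/(exp(u/sigma)-1) with the analytic limit k*sigma at u=0
    x = u / sigma
    if abs(x) < 1e-12:
        return k * sigma
    return k * u / (np.exp(x) - 1.0)


@njit(cache=True, inline="always")
def _gate_rates_all(V, kin, out):
    """Opening/closing rates for all four gates -> out[4, 2].

    Activation gates (m, n, a): opening = k1(theta-V)/(exp((theta-V)/s1)-1),
    closing = k2*exp(V/s2).  Inactivation gate (h): the (k, sigma) pairs
    attach to the opposite functional forms, which is the only assignment
    that keeps both rates positive: opening = k1*exp(V/s1), closing =
    k2(theta-V)/(exp((theta-V)/s2)-1)  (positive for all V when s2 > 0).
    """
    for g in range(4):
        th = kin[g, 0]
        s1 = kin[g, 1]
        s2 = kin[g, 2]
        k1 = kin[g, 3]
        k2 = kin[g, 4]
        if g == 1:
            out[g, 0] = k1 * np.exp(V / s1)
            out[g, 1] = _singular_rate(th - V, s2, k2)
        else:
            out[g, 0] = _singular_rate(th - V, s1, k1)
            out[g, 1] = k2 * np.exp(V / s2)


@njit(cache=True, inline="always")
def _intrinsic_current(V, m, h, n, a, gNa, gKv1, gKv3, gL, EL):
    return (gNa * m ** 3 * h * (ENA - V)
            + gKv1 * a ** 4 * (EK - V)
            + gKv3 * n ** 4 * (EK - V)
            + gL * (EL - V))


@njit(cache=True, inline="always")
def _drive_g(t, mode, g0, gmax, freq_hz):
    if mode == 0:
        return g0
    # raised sinusoid: 0 at cycle start, gmax at the theta peak
    return 0.5 * gmax * (1.0 - np.cos(2.0 * np.pi * freq_hz * t / 1000.0))


@njit(cache=True)
def _deriv_single(y, kin, C, gL, EL, gNa, gKv1, gKv3, iapp, gchr, gsyn, esyn, rates):
    V = y[0]
    _gate_rates_all(V, kin, rates)
    I = (_intrinsic_current(V, y[1], y[2], y[3], y[4], gNa, gKv1, gKv3, gL, EL)
         + iapp + gchr * (ECHR - V) + gsyn * (esyn - V))
    d = np.empty(5)
    d[0] = I / C
    for g in range(4):
        d[1 + g] = rates[g, 0] * (1.0 - y[1 + g]) - rates[g, 1] * y[1 + g]
    return d


@njit(cache=True)
def integrate_single(y0, kin, C, gL, EL, gNa, gKv1, gKv3,
                     iapp, drive_mode, g0, gmax, freq_hz,
                     pert_t, pert_g, pert_E, tau1, tau2,
                     duration, dt, method, lockout,
                     rec_stride, rec_state):
    """Integrate one neuron.

    method: 0 = forward Euler, 1 = classic RK4.
    pert_t >= 0 schedules a single biexponential conductance (peak pert_g nS,
    reversal pert_E) whose onset is the first step with t >= pert_t.
    rec_stride > 0 records V (or the full state if rec_state) every stride steps.

    Returns (spikes, trace, states, final_state, status, status_step).
    """
    nsteps = int(round(duration / dt))
    y = y0.copy()
    tpk = tau1 * tau2 / (tau1 - tau2) * np.log(tau1 / tau2)
    fnorm = 1.0 / (np.exp(-tpk / tau1) - np.exp(-tpk / tau2))
    d1 = np.exp(-dt / tau1)
    d2 = np.exp(-dt / tau2)
    A = 0.0
    B = 0.0
    pert_pending = pert_t >= 0.0 and pert_g > 0.0

    nrec = nsteps // rec_stride + 1 if rec_stride > 0 else 0
    trace = np.empty(nrec)
    states = np.empty((nrec if rec_state else 0, 5))
    spikes = np.empty(int(duration * 1.0) + 8)  # 1 kHz cap
    nsp = 0
    last = -1e9
    rates = np.empty((4, 2))
    status = OK
    status_step = -1
    irec = 0

    for k in range(nsteps):
        t = k * dt
        if pert_pending and t >= pert_t:
            A += pert_g * fnorm
            B += pert_g * fnorm
            pert_pending = False
        gsyn = A - B
        gchr = _drive_g(t, drive_mode, g0, gmax, freq_hz)
        Vold = y[0]
        if method == 0:
            d = _deriv_single(y, kin, C, gL, EL, gNa, gKv1, gKv3, iapp, gchr, gsyn, pert_E, rates)
            for j in range(5):
                y[j] += dt * d[j]
        else:
            k1v = _deriv_single(y, kin, C, gL, EL, gNa, gKv1, gKv3, iapp, gchr, gsyn, pert_E, rates)
            k2v = _deriv_single(y + 0.5 * dt * k1v, kin, C, gL, EL, gNa, gKv1, gKv3, iapp, gchr, gsyn, pert_E, rates)
            k3v = _deriv_single(y + 0.5 * dt * k2v, kin, C, gL, EL, gNa, gKv1, gKv3, iapp, gchr, gsyn, pert_E, rates)
            k4v = _deriv_single(y + dt * k3v, kin, C, gL, EL, gNa, gKv1, gKv3, iapp, gchr, gsyn, pert_E, rates)
            y = y + dt / 6.0 * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
        for g in range(4):
            if y[1 + g] < 0.0:
                y[1 + g] = 0.0
            elif y[1 + g] > 1.0:
                y[1 + g] = 1.0
        A *= d1
        B *= d2
        if not np.isfinite(y[0]) or abs(y[0]) > V_BLOWUP:
            status = BLOWUP
            status_step = k
            break
        if y[0] >= -30.0 and Vold < -30.0 and t - last > lockout:
            if nsp < spikes.shape[0]:
                frac = (-30.0 - Vold) / (y[0] - Vold)
                spikes[nsp] = t + frac * dt
                nsp += 1
            last = t
        if rec_stride > 0 and (k + 1) % rec_stride == 0:
            trace[irec] = y[0]
            if rec_state:
                for j in range(5):
                    states[irec, j] = y[j]
            irec += 1
    return spikes[:nsp], trace[:irec], states[:irec], y, status, status_step


@njit(cache=True)
def integrate_network(V, m, h, n, a, kin, C, gL, EL, gNa, gKv1, gKv3,
                      syn_post, syn_w, syn_dsteps, out_ptr, out_idx,
                      esyn, tau1, tau2,
                      std_on, std_x0, tau_r, u_se,
                      gap_ptr, gap_idx, gap_g,
                      drive_mode, g0, gmax, freq_hz, iapp,
                      duration, dt, lockout,
                      rec_idx, rec_stride):
    """Forward-Euler network integration.

    Chemical synapses: per-neuron biexponential states (A, B); a spike of
    neuron i schedules, for each outgoing synapse e (CSR out_ptr/out_idx),
    an increment w[e]*F*x_i at delivery step k + syn_dsteps[e] via a ring
    buffer, where x_i is i's depression state read at spike time.
    Gap junctions (CSR gap_ptr/gap_idx/gap_g): current sum_j g*(V_j - V_i)
    computed from same-step (pre-update) voltages.

    Returns (sp_t, sp_i, traces, x_final, status, status_step).
    """
    N = V.shape[0]
    nsteps = int(round(duration / dt))
    tpk = tau1 * tau2 / (tau1 - tau2) * np.log(tau1 / tau2)
    fnorm = 1.0 / (np.exp(-tpk / tau1) - np.exp(-tpk / tau2))
    d1 = np.exp(-dt / tau1)
    d2 = np.exp(-dt / tau2)

    A = np.zeros(N)
    B = np.zeros(N)
    maxd = 1
    for e in range(syn_dsteps.shape[0]):
        if syn_dsteps[e] > maxd:
            maxd = syn_dsteps[e]
    Lbuf = maxd + 1
    ring = np.zeros((Lbuf, N))

    x = np.full(N, std_x0)
    x_last_t = np.zeros(N)

    last = np.full(N, -1e9)
    cap = int(N * duration * 1.0) + 64
    sp_t = np.empty(cap)
    sp_i = np.empty(cap, np.int64)
    nsp = 0

    nrec_neur = rec_idx.shape[0]
    nrec = nsteps // rec_stride + 1 if (rec_stride > 0 and nrec_neur > 0) else 0
    traces = np.empty((nrec_neur, nrec))
    irec = 0

    Vold = np.empty(N)
    rates = np.empty((4, 2))
    status = OK
    status_step = -1

    for k in range(nsteps):
        t = k * dt
        row = k % Lbuf
        for i in range(N):
            inc = ring[row, i]
            if inc != 0.0:
                A[i] += inc
                B[i] += inc
                ring[row, i] = 0.0
        gchr = _drive_g(t, drive_mode, g0, gmax, freq_hz)
        for i in range(N):
            Vold[i] = V[i]
        for i in range(N):
            Vi = Vold[i]
            _gate_rates_all(Vi, kin[i], rates)
            igap = 0.0
            for s in range(gap_ptr[i], gap_ptr[i + 1]):
                igap += gap_g[s] * (Vold[gap_idx[s]] - Vi)
            I = (_intrinsic_current(Vi, m[i], h[i], n[i], a[i],
                                    gNa[i], gKv1[i], gKv3[i], gL[i], EL[i])
                 + iapp[i] + gchr * (ECHR - Vi)
                 + (A[i] - B[i]) * (esyn - Vi) + igap)
            Vn = Vi + dt * I / C[i]
            mm = m[i] + dt * (rates[0, 0] * (1.0 - m[i]) - rates[0, 1] * m[i])
            hh = h[i] + dt * (rates[1, 0] * (1.0 - h[i]) - rates[1, 1] * h[i])
            nn = n[i] + dt * (rates[2, 0] * (1.0 - n[i]) - rates[2, 1] * n[i])
            aa = a[i] + dt * (rates[3, 0] * (1.0 - a[i]) - rates[3, 1] * a[i])
            m[i] = min(max(mm, 0.0), 1.0)
            h[i] = min(max(hh, 0.0), 1.0)
            n[i] = min(max(nn, 0.0), 1.0)
            a[i] = min(max(aa, 0.0), 1.0)
            A[i] *= d1
            B[i] *= d2
            if not np.isfinite(Vn) or abs(Vn) > V_BLOWUP:
                status = BLOWUP
                status_step = k
                V[i] = Vn
                return sp_t[:nsp], sp_i[:nsp], traces[:, :irec], x, status, status_step
            if Vn >= -30.0 and Vi < -30.0 and t - last[i] > lockout:
                last[i] = t
                if nsp >= cap:
                    status = SPIKE_OVERFLOW
                    status_step = k
                    return sp_t[:nsp], sp_i[:nsp], traces[:, :irec], x, status, status_step
                frac = (-30.0 - Vi) / (Vn - Vi)
                sp_t[nsp] = t + frac * dt
                sp_i[nsp] = i
                nsp += 1
                if std_on:
                    # lazy recovery since the previous presynaptic spike
                    xr = 1.0 - (1.0 - x[i]) * np.exp(-(t - x_last_t[i]) / tau_r)
                    amp_x = xr
                    x[i] = xr * (1.0 - u_se)
                    x_last_t[i] = t
                else:
                    amp_x = 1.0
                for s in range(out_ptr[i], out_ptr[i + 1]):
                    e = out_idx[s]
                    ring[(k + syn_dsteps[e]) % Lbuf, syn_post[e]] += syn_w[e] * fnorm * amp_x
            V[i] = Vn
        if rec_stride > 0 and nrec_neur > 0 and (k + 1) % rec_stride == 0:
            for r in range(nrec_neur):
                traces[r, irec] = V[rec_idx[r]]
            irec += 1
    return sp_t[:nsp], sp_i[:nsp], traces[:, :irec], x, status, status_step
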