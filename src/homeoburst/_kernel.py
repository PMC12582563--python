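"""Compiled right-hand side and adaptive integrator for the full 40-ODE system.

State vector layout (index: quantity):

* 0: V (mV)
* 1–7: activation gates m (Na, CaT, CaS, H, Kd, KCa, A)
* 8–11: inactivation gates h (Na, CaT, CaS, A)
* 12: intracellular calcium (µM)
* 13–17: sensor gates M_F, H_F, M_S, H_S, M_D
* 18–20: filtered mismatches E_F, E_S, E_D
* 21: activity sensor α
* 22–28: maximal conductances g̅ (µS)
* 29–35: activation-curve shifts (mV)
* 36–39: inactivation-curve shifts (mV)

Everything is integrated in ms. The regulation block is stated per second and
scaled by 1e-3 inside the RHS. Frozen mechanisms multiply their whole
derivative block by 0, so regulated parameters are bit-constant when frozen.

The integrator is a Dormand–Prince 5(4) embedded pair with PI-free step
control, FSAL, and cubic-Hermite sampling onto a fixed save grid.
"""

import math

import numpy as np
from numba import njit

N_STATE = 40
IDX_V = 0
IDX_M = 1  # 7 gates
IDX_H = 8  # 4 gates
IDX_CA = 12
IDX_SENS = 13  # M_F, H_F, M_S, H_S, M_D
IDX_E = 18  # E_F, E_S, E_D
IDX_ALPHA = 21
IDX_GBAR = 22  # 7
IDX_SM = 29  # 7
IDX_SH = 36  # 4

# parameter vector offsets
P_C = 0
P_GLEAK = 1
P_ENA = 2
P_EH = 3
P_EK = 4
P_EL = 5
P_CAOUT = 6
P_RT2F = 7  # mV, precomputed 1000*R*T/(2F)
P_FCA = 8
P_TAUCA = 9
P_CAREST = 10
P_GF = 11
P_GS = 12
P_GD = 13
P_ZMF = 14
P_ZHF = 15
P_ZMS = 16
P_ZHS = 17
P_ZMD = 18
P_TMF = 19
P_THF = 20
P_TMS = 21
P_THS = 22
P_TMD = 23
P_TARGF = 24
P_TARGS = 25
P_TARGD = 26
P_DF = 27
P_DS = 28
P_DD = 29
P_TAUERR = 30
P_RHO = 31
P_DALPHA = 32
P_NORM = 33
P_TAUALPHA = 34
P_ACTIVE_G = 35  # 1.0 active, 0.0 frozen
P_ACTIVE_H = 36
P_TAUG = 37  # s
P_TAUHALF = 38  # s
P_GAMMA = 39
P_GAMMAHAT = 40
P_COEF = 41  # 7*3 conductance, 7*3 activation, 4*3 inactivation
N_PARAMS = P_COEF + 21 + 21 + 12

INACT_CHAN = np.array([0, 1, 2, 6], dtype=np.int64)


@njit(cache=True, inline="always")
def _tau_eval(form, c, u):
    if form == 0:  # sigmoid
        return c[0] - c[1] / (1.0 + math.exp((u - c[2]) / c[3]))
    elif form == 1:  # biexp
        return c[0] + c[1] / (math.exp((u - c[2]) / c[3]) + math.exp((u - c[4]) / c[5]))
    else:  # product
        return (c[0] / (1.0 + math.exp((u - c[2]) / c[3]))) * (
            c[1] + 1.0 / (1.0 + math.exp((u - c[4]) / c[5]))
        )


@njit(cache=True)
def rhs(y, dy, p, q, mvh, mk, kca_half, hvh, hk, tmf, tmc, thf, thc, revcode):
    """Full-system derivative; writes into ``dy``."""
    v = y[IDX_V]
    ca = y[IDX_CA]

    e_ca = p[P_RT2F] * math.log(p[P_CAOUT] * 1000.0 / ca)

    # ionic currents (positive outward)
    i_total = p[P_GLEAK] * (v - p[P_EL])
    i_ca_pool = 0.0
    for i in range(7):
        g = y[IDX_GBAR + i]
        m = y[IDX_M + i]
        gate = m
        for _ in range(1, int(q[i])):
            gate *= m
        h = 1.0
        for j in range(4):
            if INACT_CHAN[j] == i:
                h = y[IDX_H + j]
        if revcode[i] == 0:
            e_rev = p[P_ENA]
        elif revcode[i] == 1:
            e_rev = p[P_EH]
        elif revcode[i] == 2:
            e_rev = p[P_EK]
        else:
            e_rev = e_ca
        cur = g * gate * h * (v - e_rev)
        i_total += cur
        if revcode[i] == 3:
            i_ca_pool += cur
    dy[IDX_V] = -i_total / p[P_C]

    # activation gates
    for i in range(7):
        s = y[IDX_SM + i]
        minf = 1.0 / (1.0 + math.exp((v - (mvh[i] + s)) / mk[i]))
        if revcode[i] == 2 and kca_half[i] > 0.0:
            minf *= ca / (ca + kca_half[i])
        tau = _tau_eval(tmf[i], tmc[i], v - s)
        if tau < 1e-3:
            tau = 1e-3
        dy[IDX_M + i] = (minf - y[IDX_M + i]) / tau
    # inactivation gates
    for j in range(4):
        i = INACT_CHAN[j]
        s = y[IDX_SH + j]
        hinf = 1.0 / (1.0 + math.exp((v - (hvh[j] + s)) / hk[j]))
        tau = _tau_eval(thf[j], thc[j], v - s)
        if tau < 1e-3:
            tau = 1e-3
        dy[IDX_H + j] = (hinf - y[IDX_H + j]) / tau

    # calcium
    dy[IDX_CA] = (-p[P_FCA] * i_ca_pool - ca + p[P_CAREST]) / p[P_TAUCA]

    # sensor gates
    mf_inf = 1.0 / (1.0 + math.exp(p[P_ZMF] - ca))
    hf_inf = 1.0 / (1.0 + math.exp(ca - p[P_ZHF]))
    ms_inf = 1.0 / (1.0 + math.exp(p[P_ZMS] - ca))
    hs_inf = 1.0 / (1.0 + math.exp(ca - p[P_ZHS]))
    md_inf = 1.0 / (1.0 + math.exp(p[P_ZMD] - ca))
    dy[IDX_SENS + 0] = (mf_inf - y[IDX_SENS + 0]) / p[P_TMF]
    dy[IDX_SENS + 1] = (hf_inf - y[IDX_SENS + 1]) / p[P_THF]
    dy[IDX_SENS + 2] = (ms_inf - y[IDX_SENS + 2]) / p[P_TMS]
    dy[IDX_SENS + 3] = (hs_inf - y[IDX_SENS + 3]) / p[P_THS]
    dy[IDX_SENS + 4] = (md_inf - y[IDX_SENS + 4]) / p[P_TMD]

    f_out = p[P_GF] * y[IDX_SENS + 0] * y[IDX_SENS + 0] * y[IDX_SENS + 1]
    s_out = p[P_GS] * y[IDX_SENS + 2] * y[IDX_SENS + 2] * y[IDX_SENS + 3]
    d_out = p[P_GD] * y[IDX_SENS + 4] * y[IDX_SENS + 4]

    # filtered mismatches
    e_f = y[IDX_E + 0]
    e_s = y[IDX_E + 1]
    e_d = y[IDX_E + 2]
    dy[IDX_E + 0] = ((f_out - p[P_TARGF]) - e_f) / p[P_TAUERR]
    dy[IDX_E + 1] = ((s_out - p[P_TARGS]) - e_s) / p[P_TAUERR]
    dy[IDX_E + 2] = ((d_out - p[P_TARGD]) - e_d) / p[P_TAUERR]

    # match score (L^p) and gate
    pw = p[P_NORM]
    score = (
        abs(e_f / p[P_DF]) ** pw + abs(e_s / p[P_DS]) ** pw + abs(e_d / p[P_DD]) ** pw
    ) ** (1.0 / pw)
    x = (score - p[P_RHO]) / p[P_DALPHA]
    if x > 500.0:
        gate = 0.0
    elif x < -500.0:
        gate = 1.0
    else:
        gate = 1.0 / (1.0 + math.exp(x))
    alpha = y[IDX_ALPHA]
    dy[IDX_ALPHA] = ((1.0 - gate) - alpha) / p[P_TAUALPHA]

    # regulation (α gates the whole law, cubic included; τ in ms here);
    # drives consume tolerance-normalized mismatches
    nf = -e_f / p[P_DF]
    ns = -e_s / p[P_DS]
    nd = -e_d / p[P_DD]
    ag = p[P_ACTIVE_G] * alpha
    ah = p[P_ACTIVE_H] * alpha
    for i in range(7):
        g = y[IDX_GBAR + i]
        drv = p[P_COEF + 3 * i] * nf + p[P_COEF + 3 * i + 1] * ns + p[P_COEF + 3 * i + 2] * nd
        dy[IDX_GBAR + i] = ag * (g * drv / p[P_TAUG] - p[P_GAMMA] * g * g * g)
        o = P_COEF + 21 + 3 * i
        drv_m = p[o] * nf + p[o + 1] * ns + p[o + 2] * nd
        sm = y[IDX_SM + i]
        dy[IDX_SM + i] = ah * (drv_m / p[P_TAUHALF] - p[P_GAMMAHAT] * sm * sm * sm)
    for j in range(4):
        o = P_COEF + 42 + 3 * j
        drv_h = p[o] * nf + p[o + 1] * ns + p[o + 2] * nd
        sh = y[IDX_SH + j]
        dy[IDX_SH + j] = ah * (drv_h / p[P_TAUHALF] - p[P_GAMMAHAT] * sh * sh * sh)


# Dormand–Prince 5(4) coefficients
_A = np.zeros((7, 7))
_A[1, 0] = 1 / 5
_A[2, :2] = (3 / 40, 9 / 40)
_A[3, :3] = (44 / 45, -56 / 15, 32 / 9)
_A[4, :4] = (19372 / 6561, -25360 / 2187, 64448 / 6561, -212 / 729)
_A[5, :5] = (9017 / 3168, -355 / 33, 46732 / 5247, 49 / 176, -5103 / 18656)
_A[6, :6] = (35 / 384, 0.0, 500 / 1113, 125 / 192, -2187 / 6784, 11 / 84)
_B5 = _A[6].copy()
_B4 = np.array([5179 / 57600, 0.0, 7571 / 16695, 393 / 640, -92097 / 339200, 187 / 2100, 1 / 40])
_C = np.array([0.0, 1 / 5, 3 / 10, 4 / 5, 8 / 9, 1.0, 1.0])

STATUS_OK = 0
STATUS_UNDERFLOW = 1
STATUS_MAXSTEPS = 2


@njit(cache=True)
def integrate(y0, p, q, mvh, mk, kca_half, hvh, hk, tmf, tmc, thf, thc, revcode,
              t0, t1, save_dt, rtol, atol, max_steps, save_full, snap_dt):
    """Integrate from t0 to t1, sampling on the fixed save grid.

    Returns ``(saved, snaps, y_final, status, t_reached, n_steps)`` where
    ``saved`` is (n_save, 3) [V, Ca, alpha] or (n_save, N_STATE) if
    ``save_full``, and ``snaps`` is (n_snap, N_STATE) coarse full-state
    snapshots every ``snap_dt`` ms (starting at t0).
    """
    n_save = int(math.floor((t1 - t0) / save_dt + 1e-9)) + 1
    width = N_STATE if save_full else 3
    saved = np.empty((n_save, width))
    n_snap = int(math.floor((t1 - t0) / snap_dt + 1e-9)) + 1
    snaps = np.empty((n_snap, N_STATE))

    y = y0.copy()
    k = np.empty((7, N_STATE))
    ytmp = np.empty(N_STATE)
    dy = np.empty(N_STATE)

    rhs(y, dy, p, q, mvh, mk, kca_half, hvh, hk, tmf, tmc, thf, thc, revcode)
    k[0] = dy

    t = t0
    h = 0.05  # ms, initial guess
    hmin = 1e-7
    hmax = 10.0

    # record t0 samples
    if save_full:
        saved[0] = y
    else:
        saved[0, 0] = y[IDX_V]
        saved[0, 1] = y[IDX_CA]
        saved[0, 2] = y[IDX_ALPHA]
    isave = 1
    snaps[0] = y
    isnap = 1

    status = STATUS_OK
    steps = 0
    while t < t1 - 1e-9:
        if steps >= max_steps:
            status = STATUS_MAXSTEPS
            break
        if h > hmax:
            h = hmax
        if t + h > t1:
            h = t1 - t

        # stages 2..7 (k1 is FSAL from previous step)
        bad = False
        for s in range(1, 7):
            for n in range(N_STATE):
                acc = 0.0
                for m in range(s):
                    acc += _A[s, m] * k[m, n]
                ytmp[n] = y[n] + h * acc
            if ytmp[IDX_CA] <= 1e-9:
                ytmp[IDX_CA] = 1e-9
            rhs(ytmp, dy, p, q, mvh, mk, kca_half, hvh, hk, tmf, tmc, thf, thc, revcode)
            k[s] = dy
        # ytmp now holds the 5th-order solution (stage 7 uses the b5 row)
        ynew = ytmp

        # error estimate
        err = 0.0
        finite = True
        for n in range(N_STATE):
            e = 0.0
            for s in range(7):
                e += (_B5[s] - _B4[s]) * k[s, n]
            e *= h
            sc = atol + rtol * max(abs(y[n]), abs(ynew[n]))
            err += (e / sc) ** 2
            if not math.isfinite(ynew[n]):
                finite = False
        err = math.sqrt(err / N_STATE)

        if (not finite) or err > 1.0:
            fac = 0.2 if not finite else max(0.2, 0.9 * err ** -0.2)
            h *= fac
            if h < hmin:
                status = STATUS_UNDERFLOW
                break
            # recompute k1 unchanged; retry
            continue

        # accept
        tnew = t + h
        # sample the save grid inside (t, tnew] with cubic Hermite interpolation
        while isave < n_save and t0 + isave * save_dt <= tnew + 1e-9:
            ts = t0 + isave * save_dt
            theta = (ts - t) / h
            h00 = (1 + 2 * theta) * (1 - theta) ** 2
            h10 = theta * (1 - theta) ** 2
            h01 = theta * theta * (3 - 2 * theta)
            h11 = theta * theta * (theta - 1)
            if save_full:
                for n in range(N_STATE):
                    saved[isave, n] = (
                        h00 * y[n] + h10 * h * k[0, n] + h01 * ynew[n] + h11 * h * k[6, n]
                    )
            else:
                for col, n in enumerate((IDX_V, IDX_CA, IDX_ALPHA)):
                    saved[isave, col] = (
                        h00 * y[n] + h10 * h * k[0, n] + h01 * ynew[n] + h11 * h * k[6, n]
                    )
            isave += 1
        while isnap < n_snap and t0 + isnap * snap_dt <= tnew + 1e-9:
            snaps[isnap] = ynew  # coarse diagnostics: nearest accepted step
            isnap += 1

        y[:] = ynew
        if y[IDX_CA] <= 1e-9:
            y[IDX_CA] = 1e-9
        k[0] = k[6]  # FSAL
        t = tnew
        steps += 1
        if err > 1e-12:
            h *= min(5.0, max(0.2, 0.9 * err ** -0.2))
        else:
            h *= 5.0

    return saved[:isave], snaps[:isnap], y, status, t, steps
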