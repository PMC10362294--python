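"""Numba-compiled numerical core.

All flux laws and the fixed-step RK4 day integrator live here as scalar
``njit`` functions; the public modules (:mod:`environment`,
:mod:`metabolic_core`, :mod:`fe_allocation`, :mod:`simulator`) are thin
validated wrappers over these kernels, so the fast integrator and the
documented API share one implementation.

Parameter vectors are packed in the order of ``params.PARAM_ORDER``; the
``I_*`` index constants below must match that order (checked at import time
in :mod:`params` consumers and in the test suite).

State vector layout: [CH2O, CS, N, O2, FePS, FeNF_act, FeNF_inact, FeBF].
Flux vector layout (per recorded step): see ``FLUX_NAMES``.
"""

import numpy as np
from numba import njit

# --- parameter indices (must match params.PARAM_ORDER) ---
I_Q_MAX = 0
I_K_FE = 1
I_F_STO_MAX = 2
I_K_STO = 3
I_F_MAINT = 4
I_VPETMAX = 5
I_KFEPS = 6
I_ALPHA_I = 7
I_BETA = 8
I_KFENF = 9
I_KO2NF = 10
I_N_MAX = 11
I_KCS = 12
I_E_PER_O2 = 13
I_NADPH_PER_E_LPET = 14
I_ATP_PER_E_LPET = 15
I_ATP_PER_E_AET = 16
I_ATP_PER_C_CF = 17
I_NADPH_PER_C_CF = 18
I_ATP_PER_N_NF = 19
I_NADPH_PER_N_NF = 20
I_ATP_MAINT = 21
I_ATP_PER_C_RESP = 22
I_VRPMAX = 23
I_KO2RP = 24
I_KAPPA_O2 = 25
I_RHO_C = 26
I_VCSMAX = 27
I_KCH2O = 28
I_KCSI = 29
I_TPSMAXBF = 30
I_KFEPS_SYN = 31
I_TBFMAXPS = 32
I_KFEPS_DEC = 33
I_TNFMAXBF = 34
I_KFEBF_SYN = 35
I_TNFMAXNA = 36
I_Q_N = 37
I_C_BIO = 38
N_PARAMS = 42

# state indices
S_CH2O, S_CS, S_N, S_O2, S_FEPS, S_FENFA, S_FENFI, S_FEBF = range(8)
N_STATE = 8

FLUX_NAMES = (
    "V_PET", "x_LPET", "V_CF", "V_NF", "V_NFmax", "V_RP", "V_RESP", "V_CS",
    "O2_net_bio", "O2_exchange", "Phi",
    "T_PS_syn", "T_PS_dec", "T_NF_syn", "T_NF_inact",
)
N_FLUX = len(FLUX_NAMES)

INTEGRAL_NAMES = (
    "CF", "NF", "RP", "RESP", "CS_prod",
    "O2_prod_conc", "O2_bio_conc", "O2_exch_conc",
)
N_INTEGRAL = len(INTEGRAL_NAMES)

# forcing mode flags
LIGHT_CONSTANT = 0
LIGHT_SINUSOIDAL = 1

# Substrate half-saturations used by the integrator to realize non-negativity
# flux limiting smoothly: respiratory protection needs both intracellular O2
# and carbohydrate as substrates, so its realized rate rolls off continuously
# as either pool empties (the hard per-step caps remain as a backstop).
# Numerical constants, not calibration targets.
SUB_O2 = 0.02     # mol O2 m^-3
SUB_CH2O = 0.01   # mol C (mol C)^-1


@njit(cache=True)
def mm(x, k):
    """Michaelis-Menten saturation x/(x+k), 0 at the origin."""
    if x <= 0.0:
        return 0.0
    return x / (x + k)


@njit(cache=True)
def light_kernel(mode, I_param, day_length, t):
    if mode == LIGHT_CONSTANT:
        return I_param
    return I_param * np.sin(np.pi * t / day_length)


@njit(cache=True)
def pet_rate_kernel(P, FePS, I, V_RP):
    lf = 1.0 - np.exp(-P[I_ALPHA_I] * I)
    return P[I_VPETMAX] * mm(FePS, P[I_KFEPS]) * lf * np.exp(-P[I_BETA] * V_RP)


@njit(cache=True)
def nf_requirement_kernel(P, I, CS, N):
    lf = 1.0 - np.exp(-P[I_ALPHA_I] * I)
    head = P[I_N_MAX] - N
    if head < 0.0:
        head = 0.0
    return lf * mm(CS, P[I_KCS]) * head / P[I_N_MAX]


@njit(cache=True)
def rp_rate_kernel(P, Phi, O2):
    return P[I_VRPMAX] * Phi * P[I_KO2RP] / (O2 + P[I_KO2RP])


@njit(cache=True)
def nf_rate_kernel(P, V_NFmax, FeNF, O2):
    fO2 = 1.0 - O2 / (O2 + P[I_KO2NF]) if O2 > 0.0 else 1.0
    return V_NFmax * mm(FeNF, P[I_KFENF]) * fO2


@njit(cache=True)
def cs_production_kernel(P, CH2O, CS):
    return P[I_VCSMAX] * mm(CH2O, P[I_KCH2O]) * P[I_KCSI] / (CS + P[I_KCSI])


@njit(cache=True)
def ps_synthesis_kernel(P, I, FePS):
    lf = 1.0 - np.exp(-P[I_ALPHA_I] * I)
    return P[I_TPSMAXBF] * lf * (1.0 - mm(FePS, P[I_KFEPS_SYN]))


@njit(cache=True)
def ps_decomposition_kernel(P, FePS, V_RP):
    return P[I_TBFMAXPS] * mm(FePS, P[I_KFEPS_DEC]) * np.exp(-P[I_BETA] * V_RP)


@njit(cache=True)
def nf_synthesis_kernel(P, Phi, FeBF):
    return P[I_TNFMAXBF] * Phi * mm(FeBF, P[I_KFEBF_SYN])


@njit(cache=True)
def nf_inactivation_kernel(P, FeNF_act, O2):
    fO2 = O2 / (O2 + P[I_KO2NF]) if O2 > 0.0 else 0.0
    return P[I_TNFMAXNA] * mm(FeNF_act, P[I_KFENF]) * fO2


@njit(cache=True)
def close_budget_kernel(P, V_PET, FeNF, O2, N_headroom_rate):
    """ATP/NADPH budget closure at one instant.

    Returns (x_LPET, V_NFmax, V_NF, V_CF, V_RESP).  The linear-PET fraction
    x is chosen so that, after the maintenance drain, supply and demand of
    both currencies balance exactly: first for the N2-fixation ceiling
    V_NFmax, then (with the realized, Fe/O2-limited V_NF) for carbon
    fixation, which absorbs the remainder.  When the split saturates at
    x = 0 or 1 the scarcer currency limits the flux and the surplus of the
    other is dissipated.  A maintenance deficit is closed by ordinary
    respiration.
    """
    nL = P[I_NADPH_PER_E_LPET]
    aL = P[I_ATP_PER_E_LPET]
    aA = P[I_ATP_PER_E_AET]
    aC = P[I_ATP_PER_C_CF]
    nC = P[I_NADPH_PER_C_CF]
    aN = P[I_ATP_PER_N_NF]
    nN = P[I_NADPH_PER_N_NF]
    m = P[I_ATP_MAINT]
    aR = P[I_ATP_PER_C_RESP]

    a_hi = aL if aL > aA else aA
    if V_PET * a_hi <= m:
        # photic ATP cannot cover maintenance at any split
        x = 0.0 if aA >= aL else 1.0
        atp = V_PET * (x * aL + (1.0 - x) * aA)
        return x, 0.0, 0.0, 0.0, (m - atp) / aR

    # split that lets N2 fixation alone exhaust both currencies; when the
    # balanced split falls outside [0, 1] the scarcer currency limits the
    # flux at the better boundary
    denomN = V_PET * (aL - aA - nL * aN / nN)
    xN = (m - V_PET * aA) / denomN if denomN != 0.0 else -1.0
    V_NFmax = -1.0
    for xc in (xN, 0.0, 1.0):
        if xc < 0.0 or xc > 1.0:
            continue
        v1 = (V_PET * (xc * aL + (1.0 - xc) * aA) - m) / aN
        v2 = V_PET * xc * nL / nN
        v = v1 if v1 < v2 else v2
        if v > V_NFmax:
            V_NFmax = v
    if V_NFmax < 0.0:
        V_NFmax = 0.0

    V_NF = nf_rate_kernel(P, V_NFmax, FeNF, O2)
    if V_NF > N_headroom_rate:
        V_NF = N_headroom_rate
    if V_NF < 0.0:
        V_NF = 0.0

    # split that lets carbon fixation exhaust the remainder
    denomC = V_PET * (aL - aA - nL * aC / nC)
    num = m + V_NF * (aN - nN * aC / nC) - V_PET * aA
    xC = num / denomC if denomC != 0.0 else -1.0
    V_CF = -1.0e30
    x = 0.0
    for xc in (xC, 0.0, 1.0):
        if xc < 0.0 or xc > 1.0:
            continue
        c1 = (V_PET * (xc * aL + (1.0 - xc) * aA) - m - V_NF * aN) / aC
        c2 = (V_PET * xc * nL - V_NF * nN) / nC
        c = c1 if c1 < c2 else c2
        if c > V_CF:
            V_CF = c
            x = xc
    if V_CF < 0.0:
        V_CF = 0.0

    V_RESP = 0.0
    atp_bal = V_PET * (x * aL + (1.0 - x) * aA) - m - V_NF * aN - V_CF * aC
    if atp_bal < 0.0:
        V_RESP = -atp_bal / aR
    return x, V_NFmax, V_NF, V_CF, V_RESP


@njit(cache=True)
def rhs_kernel(P, t, y, light_mode, I_param, day_length, O2_ambient,
               fixed_mode, decompose_inactivated, dt):
    """Instantaneous tendencies, fluxes and integrands at state ``y``.

    ``dt`` enters only through the non-negativity flux limiter: any flux
    consuming a pool is scaled so the pool cannot be driven below zero
    within one step of size ``dt``.
    """
    dy = np.zeros(N_STATE)
    F = np.zeros(N_FLUX)
    G = np.zeros(N_INTEGRAL)

    CH2O = y[S_CH2O] if y[S_CH2O] > 0.0 else 0.0
    CS = y[S_CS] if y[S_CS] > 0.0 else 0.0
    N = y[S_N] if y[S_N] > 0.0 else 0.0
    O2 = y[S_O2] if y[S_O2] > 0.0 else 0.0
    FePS = y[S_FEPS] if y[S_FEPS] > 0.0 else 0.0
    FeNFa = y[S_FENFA] if y[S_FENFA] > 0.0 else 0.0
    FeBF = y[S_FEBF] if y[S_FEBF] > 0.0 else 0.0

    kappa = P[I_KAPPA_O2]
    rho = P[I_RHO_C]

    I = light_kernel(light_mode, I_param, day_length, t)
    Phi = nf_requirement_kernel(P, I, CS, N)

    # respiratory protection, rolled off smoothly as its substrates (O2 and
    # carbohydrate) empty, then hard-limited by per-step availability
    V_RP = rp_rate_kernel(P, Phi, O2) * mm(O2, SUB_O2) * mm(CH2O, SUB_CH2O)
    influx = kappa * (O2_ambient - O2)
    avail_O2 = O2 / dt + (influx if influx > 0.0 else 0.0)
    if rho > 0.0 and V_RP > avail_O2 / rho:
        V_RP = avail_O2 / rho

    # carbohydrate consumers share the CH2O pool
    V_CS = cs_production_kernel(P, CH2O, CS)
    tot = V_CS + V_RP
    cap = CH2O / dt
    if tot > cap:
        s = cap / tot if tot > 0.0 else 0.0
        V_CS *= s
        V_RP *= s

    V_PET = pet_rate_kernel(P, FePS, I, V_RP)
    head_rate = (P[I_N_MAX] - N) / dt
    if head_rate < 0.0:
        head_rate = 0.0
    x, V_NFmax, V_NF, V_CF, V_RESP = close_budget_kernel(P, V_PET, FeNFa, O2, head_rate)
    room = cap - V_CS - V_RP
    if room < 0.0:
        room = 0.0
    if V_RESP > room:
        V_RESP = room

    # Fe translocation
    if fixed_mode:
        T_ps_syn = 0.0
        T_ps_dec = 0.0
        T_nf_syn = 0.0
    else:
        T_ps_syn = ps_synthesis_kernel(P, I, FePS)
        T_nf_syn = nf_synthesis_kernel(P, Phi, FeBF)
        out = T_ps_syn + T_nf_syn
        capB = FeBF / dt
        if out > capB:
            s = capB / out if out > 0.0 else 0.0
            T_ps_syn *= s
            T_nf_syn *= s
        T_ps_dec = ps_decomposition_kernel(P, FePS, V_RP)
        capPS = FePS / dt + T_ps_syn
        if T_ps_dec > capPS:
            T_ps_dec = capPS
    T_nf_inact = nf_inactivation_kernel(P, FeNFa, O2)
    capNF = FeNFa / dt + T_nf_syn
    if T_nf_inact > capNF:
        T_nf_inact = capNF

    o2_bio_pc = x * V_PET / P[I_E_PER_O2] - V_RP - V_RESP
    o2_exch = kappa * (O2_ambient - y[S_O2])

    dy[S_CH2O] = V_CF - V_CS - V_RP - V_RESP
    dy[S_CS] = V_CS
    dy[S_N] = V_NF
    dy[S_O2] = rho * o2_bio_pc + o2_exch
    dy[S_FEPS] = T_ps_syn - T_ps_dec
    dy[S_FENFA] = T_nf_syn - T_nf_inact
    if decompose_inactivated:
        dy[S_FENFI] = 0.0
        dy[S_FEBF] = T_ps_dec - T_ps_syn - T_nf_syn + T_nf_inact
    else:
        dy[S_FENFI] = T_nf_inact
        dy[S_FEBF] = T_ps_dec - T_ps_syn - T_nf_syn

    F[0] = V_PET
    F[1] = x
    F[2] = V_CF
    F[3] = V_NF
    F[4] = V_NFmax
    F[5] = V_RP
    F[6] = V_RESP
    F[7] = V_CS
    F[8] = o2_bio_pc
    F[9] = o2_exch
    F[10] = Phi
    F[11] = T_ps_syn
    F[12] = T_ps_dec
    F[13] = T_nf_syn
    F[14] = T_nf_inact

    G[0] = V_CF
    G[1] = V_NF
    G[2] = V_RP
    G[3] = V_RESP
    G[4] = V_CS
    G[5] = rho * x * V_PET / P[I_E_PER_O2]
    G[6] = rho * o2_bio_pc
    G[7] = o2_exch
    return dy, F, G


@njit(cache=True)
def run_day_kernel(P, light_mode, I_param, day_length, O2_ambient,
                   fixed_mode, decompose_inactivated, y0, dt):
    """Classical RK4 over the light period with flux-limited tendencies.

    Daily integrals are accumulated with the same RK4 stage weights as the
    state update, so discrete budget identities (e.g. the O2 budget) close
    to machine precision.

    Returns (Y, F, Ints): states at every step boundary, stage-1 fluxes at
    every step boundary, and the cumulative RK4-weighted integrals at every
    step boundary (row ``n`` holds the daily totals).
    """
    n = int(round(day_length / dt))
    Y = np.empty((n + 1, N_STATE))
    Fs = np.empty((n + 1, N_FLUX))
    Ints = np.zeros((n + 1, N_INTEGRAL))

    y = y0.copy()
    Y[0] = y
    for i in range(n):
        t = i * dt
        k1, f1, g1 = rhs_kernel(P, t, y, light_mode, I_param, day_length,
                                O2_ambient, fixed_mode, decompose_inactivated, dt)
        Fs[i] = f1
        k2, f2, g2 = rhs_kernel(P, t + 0.5 * dt, y + 0.5 * dt * k1, light_mode,
                                I_param, day_length, O2_ambient, fixed_mode,
                                decompose_inactivated, dt)
        k3, f3, g3 = rhs_kernel(P, t + 0.5 * dt, y + 0.5 * dt * k2, light_mode,
                                I_param, day_length, O2_ambient, fixed_mode,
                                decompose_inactivated, dt)
        k4, f4, g4 = rhs_kernel(P, t + dt, y + dt * k3, light_mode, I_param,
                                day_length, O2_ambient, fixed_mode,
                                decompose_inactivated, dt)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        Ints[i + 1] = Ints[i] + (dt / 6.0) * (g1 + 2.0 * g2 + 2.0 * g3 + g4)
        Y[i + 1] = y
    kT, fT, gT = rhs_kernel(P, n * dt, y, light_mode, I_param, day_length,
                            O2_ambient, fixed_mode, decompose_inactivated, dt)
    Fs[n] = fT
    return Y, Fs, Ints
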