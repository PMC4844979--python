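"""Compiled fixed-step RK4 method-of-steps kernel for the delayed system.

The melanoma population is propagated in log space (``u = ln M``): the
per-capita loss rate sampled in the virtual-patient screen can reach
~10^4/day (``k_iap * k_atg / (1 + k_iev)`` up to ~2.5e3 with T of order
a few n.u.), which an explicit scheme cannot follow in linear space at the
0.05-day default step, whereas in log space the only self-coupling of
``ln M`` is the logistic term (|h * dlnM'/dlnM| <= k_pmc * h ~ 0.25).
T remains linear; its stiffest contribution (cubic depletion) stays well
inside the RK4 stability region for all sampled parameter sets.

Parameter vector layout follows :data:`micromet.model.PARAM_ORDER`.
"""

import math

import numpy as np
from numba import njit

#: ln M floor; exp(U_FLOOR) ~ 1e-300, i.e. numerically extinct.
U_FLOOR = -690.0
#: divergence guard on either population (n.u.).
DIVERGENCE_LIMIT = 1.0e3
_LN_DIV = math.log(DIVERGENCE_LIMIT)

STATUS_OK = 0
STATUS_DIVERGED = 1


@njit(cache=True)
def _delayed_T(T_hist, s, t_dtc, step, T0):
    """T(s - t_dtc) by linear interpolation on the stored grid; constant
    pre-history T0 for arguments at or before t = 0."""
    tau = s - t_dtc
    if tau <= 0.0:
        return T0
    x = tau / step
    i0 = int(math.floor(x))
    frac = x - i0
    return T_hist[i0] * (1.0 - frac) + T_hist[i0 + 1] * frac


@njit(cache=True)
def _deriv(p, t, T, u, T_del, m_zero,
           vac_on, cyc_end, cyc_len, pulse_len, amp,
           il2_on, ifna_on, il2_f, ifna_f, window):
    """(dT/dt, d ln M/dt) at time t with the delayed T value supplied."""
    k_pmc = p[0]
    M_T = p[1]
    k_iap = p[2]
    k_ink = p[3]
    k_atg = p[4]
    k_iev = p[5]
    k_nkc = p[6]
    g_nk = p[7]
    k_apc = p[8]
    k_gir = p[9]
    k_atc = p[10]
    k_tapc = p[11]
    g_1 = p[12]
    k_tatc = p[13]
    g_2 = p[14]
    k_dtc = p[15]
    rho_mem = p[16]

    if (il2_on or ifna_on) and t >= 0.0 and t < window:
        if il2_on:
            k_iap = k_iap * il2_f
            k_atc = k_atc * il2_f
        if ifna_on:
            k_atg = k_atg * ifna_f

    vc = 0.0
    if vac_on and t < cyc_end:
        phase = t % cyc_len
        if 0.0 < phase < pulse_len:
            vc = amp

    M = 0.0 if m_zero else math.exp(u)
    am = k_atg * M
    act = 0.0
    expand = 0.0
    if am > 0.0:
        amg1 = am ** g_1
        act = (k_apc + k_gir * vc) * amg1 / (k_tapc ** g_1 + amg1)
        amg2 = am ** g_2
        expand = k_atc * T * amg2 / (k_tatc ** g_2 + amg2)
    dT = act + expand - k_dtc * (T * T * T + rho_mem * T_del)

    if m_zero:
        return dT, 0.0
    nk_hill = k_nkc ** g_nk / (k_nkc ** g_nk + k_atg ** g_nk)
    du = (k_pmc * (1.0 - M / M_T)
          - (k_iap * k_atg / (1.0 + k_iev)) * T
          - k_ink * nk_hill)
    return dT, du


@njit(cache=True)
def rk4_dde(p, T0, M0, n_steps, step,
            vac_on, cyc_end, cyc_len, pulse_len, amp,
            il2_on, ifna_on, il2_f, ifna_f, window, u_ext):
    """Integrate the delayed system over ``n_steps`` fixed RK4 steps.

    Returns ``(T_hist, u_hist, status, fail_index)``; ``u_hist`` is ln M
    (ignore when ``M0 == 0``). ``status`` is nonzero on divergence and
    ``fail_index`` then names the offending grid index.

    ``u_ext`` is the absorbing extinction threshold on ln M: once the
    melanoma population drops below it (fewer than one cell) it is treated
    as eradicated and pinned at zero. Pass ``-inf`` to disable.
    """
    t_dtc = p[17]
    m_zero = M0 == 0.0
    T_hist = np.empty(n_steps + 1)
    u_hist = np.empty(n_steps + 1)
    T_hist[0] = T0
    u_hist[0] = U_FLOOR if m_zero else math.log(M0)

    h = step
    for i in range(n_steps):
        t = i * h
        T = T_hist[i]
        u = u_hist[i]

        Td0 = _delayed_T(T_hist, t, t_dtc, h, T0)
        k1T, k1u = _deriv(p, t, T, u, Td0, m_zero,
                          vac_on, cyc_end, cyc_len, pulse_len, amp,
                          il2_on, ifna_on, il2_f, ifna_f, window)
        tm = t + 0.5 * h
        Tdm = _delayed_T(T_hist, tm, t_dtc, h, T0)
        k2T, k2u = _deriv(p, tm, T + 0.5 * h * k1T, u + 0.5 * h * k1u, Tdm, m_zero,
                          vac_on, cyc_end, cyc_len, pulse_len, amp,
                          il2_on, ifna_on, il2_f, ifna_f, window)
        k3T, k3u = _deriv(p, tm, T + 0.5 * h * k2T, u + 0.5 * h * k2u, Tdm, m_zero,
                          vac_on, cyc_end, cyc_len, pulse_len, amp,
                          il2_on, ifna_on, il2_f, ifna_f, window)
        te = t + h
        Tde = _delayed_T(T_hist, te, t_dtc, h, T0)
        k4T, k4u = _deriv(p, te, T + h * k3T, u + h * k3u, Tde, m_zero,
                          vac_on, cyc_end, cyc_len, pulse_len, amp,
                          il2_on, ifna_on, il2_f, ifna_f, window)

        Tn = T + (h / 6.0) * (k1T + 2.0 * k2T + 2.0 * k3T + k4T)
        un = u + (h / 6.0) * (k1u + 2.0 * k2u + 2.0 * k3u + k4u)
        if Tn < 0.0:
            Tn = 0.0  # clip negative round-off
        if not m_zero and un < u_ext:
            m_zero = True  # population below one cell: eradicated, absorbing
        if m_zero or un < U_FLOOR:
            un = U_FLOOR
        if (not math.isfinite(Tn)) or (not math.isfinite(un)) \
                or Tn > DIVERGENCE_LIMIT or un > _LN_DIV:
            return T_hist, u_hist, STATUS_DIVERGED, i + 1
        T_hist[i + 1] = Tn
        u_hist[i + 1] = un

    return T_hist, u_hist, STATUS_OK, -1
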