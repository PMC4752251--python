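"""Compiled daily-projection kernel.

Same model as :mod:`tigerpop.population` (the reference route), restated over
flat arrays for numba.  Cohort queues are stored as parallel (size, dev)
arrays compacted in place each day.  The parameter layout is the canonical
48-entry order of :data:`tigerpop.life_history.PARAM_NAMES`.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_kernel"]


@njit(cache=True, inline="always")
def _expit(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def _advance(sizes, devs, n, rate, surv):
    developed = 0.0
    m = 0
    for i in range(n):
        s = sizes[i] * surv
        d = devs[i] + rate
        if d >= 1.0 - 1e-9:
            developed += s
        elif s > 1e-30:
            sizes[m] = s
            devs[m] = d
            m += 1
    return m, developed


@njit(cache=True)
def simulate_kernel(Ta, precip, pp, p_dens, theta, mu_max, floor, pause_ramp):
    n = Ta.shape[0]
    out = np.zeros((n, 14))

    # parameter unpacking (canonical order)
    d1a0, d1a1, d1a2 = theta[0], theta[1], theta[2]
    d2a0, d2a1, d2a2 = theta[3], theta[4], theta[5]
    d3a0, d3a1, d3a2 = theta[6], theta[7], theta[8]
    tba0, tba1, tba2 = theta[9], theta[10], theta[11]
    f4a0, f4a1, f4a2 = theta[12], theta[13], theta[14]
    p0b0, p0b1 = theta[15], theta[16]
    p1m, p1lo, p1hi, p1s = theta[17], theta[18], theta[19], theta[20]
    p2m, p2lo, p2hi, p2s = theta[21], theta[22], theta[23], theta[24]
    p3m, p3lo, p3hi, p3s = theta[25], theta[26], theta[27], theta[28]
    p4m, p4lo, p4hi, p4s = theta[29], theta[30], theta[31], theta[32]
    a_a, a_b, a_c, a_d, a_e = theta[33], theta[34], theta[35], theta[36], theta[37]
    a_LD = theta[38]
    a_pdens, a_dprec, a_evap = theta[39], theta[40], theta[41]
    T_crt, CPP, p_s, p_n = theta[42], theta[43], theta[44], theta[45]
    delta_T, E0 = theta[46], theta[47]

    cap = n + 2
    egg_s = np.zeros(cap); egg_d = np.zeros(cap); egg_n = 0
    tag_s = np.zeros(cap); tag_d = np.zeros(cap); tag_n = 0
    lar_s = np.zeros(cap); lar_d = np.zeros(cap); lar_n = 0
    pup_s = np.zeros(cap); pup_d = np.zeros(cap); pup_n = 0
    nai_s = np.zeros(cap); nai_d = np.zeros(cap); nai_n = 0

    B = 0.0
    egg_diap = E0
    adult = 0.0
    t_dp = -1
    unfav_days = 0

    for t in range(n):
        Tat = Ta[t]
        Tw = Tat - delta_T
        adult_t = adult

        # 1. capacity
        B = a_pdens * p_dens + a_dprec * precip[t] + a_evap * B
        K = (1.0 - a_evap) / (1.0 - a_evap ** (t + 1)) * B

        # 2. immature density
        larva = 0.0
        for i in range(lar_n):
            larva += lar_s[i]
        pupa = 0.0
        for i in range(pup_n):
            pupa += pup_s[i]
        lp = larva + pupa
        if K <= 0.0:
            mu = 0.0 if lp == 0.0 else mu_max
        else:
            mu = lp / K
            if mu > mu_max:
                mu = mu_max

        # 3. rates and survivals
        if mu > 0.0:
            tau = a_a + a_b * Tw + a_c * Tw * Tw
            d23 = a_d * mu ** a_e * tau
            if d23 < 1.0:
                d23 = 1.0
            p_LD = np.exp(-a_LD * mu)
        else:
            d23 = 1.0
            p_LD = 1.0
        d1 = d1a0 + d1a1 * Tw + d1a2 * Tw * Tw
        if d1 < floor:
            d1 = floor
        d2 = d2a0 + d2a1 * Tw + d2a2 * Tw * Tw
        if d2 < floor:
            d2 = floor
        d2 *= d23
        d3 = d3a0 + d3a1 * Tw + d3a2 * Tw * Tw
        if d3 < floor:
            d3 = floor
        d3 *= d23
        tbm = tba0 + tba1 * Tat + tba2 * Tat * Tat
        if tbm < floor:
            tbm = floor
        F4 = f4a0 + f4a1 * Tat + f4a2 * Tat * Tat
        if F4 < 0.0:
            F4 = 0.0
        p0 = p0b0 + p0b1 * Tat
        if p0 < 0.0:
            p0 = 0.0
        elif p0 > 1.0:
            p0 = 1.0
        p1 = p1m * _expit(p1s * (Tw - p1lo)) * _expit(-p1s * (Tw - p1hi))
        p2 = p2m * _expit(p2s * (Tw - p2lo)) * _expit(-p2s * (Tw - p2hi)) * p_LD
        p3 = p3m * _expit(p3s * (Tw - p3lo)) * _expit(-p3s * (Tw - p3hi)) * p_LD
        p4 = p4m * _expit(p4s * (Tat - p4lo)) * _expit(-p4s * (Tat - p4hi))

        # 4. season indicators and tagged fraction
        fav = 1.0 if (Tat >= T_crt and pp[t] >= CPP) else 0.0
        unfav = 1.0 if (Tat < T_crt and pp[t] < CPP) else 0.0
        if fav == 1.0:
            t_dp = -1
            unfav_days = 0
            p_dp = 0.0
        elif unfav == 1.0:
            if t_dp < 0:
                t_dp = t
                unfav_days = 0
            unfav_days += 1
            if pause_ramp:
                p_dp = unfav_days * p_s
            else:
                p_dp = (1 + t - t_dp) * p_s
            if p_dp > 1.0:
                p_dp = 1.0
        else:
            p_dp = 0.0

        # 5. cohort development
        egg_n, egg_dev = _advance(egg_s, egg_d, egg_n, 1.0 / d1, p1)
        tag_n, tag_dev = _advance(tag_s, tag_d, tag_n, 1.0 / d1, p1)
        lar_n, lar_dev = _advance(lar_s, lar_d, lar_n, 1.0 / d2, p2)
        pup_n, pup_dev = _advance(pup_s, pup_d, pup_n, 1.0 / d3, p3)
        nai_n, nai_dev = _advance(nai_s, nai_d, nai_n, 1.0 / tbm, p4)

        # 6. stock survival and diapause hatching
        hatched = fav * p0 * p_n * egg_diap
        egg_diap = p0 * (1.0 - fav * p_n) * egg_diap + tag_dev
        adult = p4 * adult_t + nai_dev

        # 7. oviposition
        laid = F4 * adult_t
        laid_tagged = unfav * p_dp * laid
        laid_normal = laid - laid_tagged
        if laid_normal > 0.0:
            egg_s[egg_n] = laid_normal
            egg_d[egg_n] = 0.0
            egg_n += 1
        if laid_tagged > 0.0:
            tag_s[tag_n] = laid_tagged
            tag_d[tag_n] = 0.0
            tag_n += 1
        inflow_l = egg_dev + hatched
        if inflow_l > 0.0:
            lar_s[lar_n] = inflow_l
            lar_d[lar_n] = 0.0
            lar_n += 1
        if lar_dev > 0.0:
            pup_s[pup_n] = lar_dev
            pup_d[pup_n] = 0.0
            pup_n += 1
        if pup_dev > 0.0:
            nai_s[nai_n] = 0.5 * pup_dev
            nai_d[nai_n] = 0.0
            nai_n += 1

        egg_tot = 0.0
        for i in range(egg_n):
            egg_tot += egg_s[i]
        tag_tot = 0.0
        for i in range(tag_n):
            tag_tot += tag_s[i]
        lar_tot = 0.0
        for i in range(lar_n):
            lar_tot += lar_s[i]
        pup_tot = 0.0
        for i in range(pup_n):
            pup_tot += pup_s[i]
        nai_tot = 0.0
        for i in range(nai_n):
            nai_tot += nai_s[i]

        out[t, 0] = egg_tot
        out[t, 1] = tag_tot
        out[t, 2] = egg_diap
        out[t, 3] = lar_tot
        out[t, 4] = pup_tot
        out[t, 5] = nai_tot
        out[t, 6] = adult
        out[t, 7] = laid_normal
        out[t, 8] = laid_tagged
        out[t, 9] = tag_dev
        out[t, 10] = K
        out[t, 11] = fav
        out[t, 12] = unfav
        out[t, 13] = mu
    return out
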