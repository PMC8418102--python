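"""Event-driven simulation kernels (numba-compiled).

All three simulators — the full Markovian integrate-and-fire network (MIF),
the two-state reduced network (RN) and the coarse-grained four-variable
chain (CG) — are continuous-time Markov processes driven by exponential
waiting times.  Each kernel repeatedly selects the first occurring event by
an exponential race over the per-category total rates and applies it.

The kernels log, per kick-effect event, the sufficient statistic needed by
the reduced-network estimator: the kick class, target population, target
pre-state (base/gate), the conditioning count (base count for base targets,
gate count for gate targets, taken *before* the event), and whether the
state flipped.  Key codes below; inhibitory kicks on base neurons are never
logged because they cannot flip a base neuron.
"""

import numpy as np
from numba import njit

# Transition-table key codes: (kick class, target pre-state, target pop).
K_EXT_B_E = 0
K_EXT_B_I = 1
K_EXT_G_E = 2
K_EXT_G_I = 3
K_E_B_E = 4
K_E_B_I = 5
K_E_G_E = 6
K_E_G_I = 7
K_I_G_E = 8
K_I_G_I = 9
N_KEYS = 10


@njit(cache=True)
def _grow_f8(a):
    out = np.empty(a.shape[0] * 2, np.float64)
    out[: a.shape[0]] = a
    return out


@njit(cache=True)
def _grow_i8(a):
    out = np.empty(a.shape[0] * 2, np.int8)
    out[: a.shape[0]] = a
    return out


@njit(cache=True)
def _grow_i32(a):
    out = np.empty(a.shape[0] * 2, np.int32)
    out[: a.shape[0]] = a
    return out


@njit(cache=True)
def mif_kernel(rng, T, n_e, n_i, vrev, v_r, v_th, v_c,
               s_ee, s_ie, s_ei, s_ii,
               p_ee, p_ie, p_ei, p_ii,
               lam_e, lam_i, tau_ee, tau_ie, tau_i, tau_re, tau_ri,
               stride, log_events):
    n = n_e + n_i
    v = np.full(n, v_r, np.int64)
    refr = np.zeros(n, np.uint8)
    gate = np.zeros(n, np.uint8)
    he = np.zeros(n, np.int64)  # per-neuron pending-E pools
    hi = np.zeros(n, np.int64)  # per-neuron pending-I pools
    n_ge = 0
    n_gi = 0
    she_e = 0  # sum of pending-E pools over E neurons
    she_i = 0  # ... over I neurons
    shi = 0    # sum of pending-I pools over all neurons
    nref_e = 0
    nref_i = 0
    # pool bookkeeping counters
    inc_e = 0
    cons_e = 0
    inc_i = 0
    cons_i = 0

    r_ext_e = n_e * lam_e / 1000.0  # events per ms
    r_ext_i = n_i * lam_i / 1000.0

    spk_t = np.empty(4096, np.float64)
    spk_id = np.empty(4096, np.int32)
    ns = 0

    n_samp = int(T / stride) + 1
    samp_t = np.empty(n_samp, np.float64)
    s_nge = np.empty(n_samp, np.int64)
    s_ngi = np.empty(n_samp, np.int64)
    s_he = np.empty(n_samp, np.int64)
    s_hi = np.empty(n_samp, np.int64)
    m_samp = 0
    next_s = 0.0

    cap0 = 1 << 16
    log_key = np.empty(cap0, np.int8)
    log_cnt = np.empty(cap0, np.int32)
    log_out = np.empty(cap0, np.int8)
    nl = 0

    t = 0.0
    while True:
        r_pe_e = she_e / tau_ee
        r_pe_i = she_i / tau_ie
        r_pi = shi / tau_i
        r_re = nref_e / tau_re
        r_ri = nref_i / tau_ri
        rtot = r_ext_e + r_ext_i + r_pe_e + r_pe_i + r_pi + r_re + r_ri
        if rtot <= 0.0:
            break
        t_new = t + -np.log1p(-rng.random()) / rtot
        # record samples falling strictly before the next event
        while next_s <= T and next_s < t_new and m_samp < n_samp:
            samp_t[m_samp] = next_s
            s_nge[m_samp] = n_ge
            s_ngi[m_samp] = n_gi
            s_he[m_samp] = she_e + she_i
            s_hi[m_samp] = shi
            m_samp += 1
            next_s += stride
        if t_new > T:
            break
        t = t_new

        u = rng.random() * rtot
        fire_i = -1
        lkey = -1
        lcnt = 0
        lout = 0
        # ---- pick category and target, apply the kick -------------------
        up_kick = False
        i = -1
        s = 0
        koff = 0
        if u < r_ext_e:
            i = int(rng.random() * n_e)
            s = 1
            koff = K_EXT_B_E
            up_kick = True
        elif u < r_ext_e + r_ext_i:
            i = n_e + int(rng.random() * n_i)
            s = 1
            koff = K_EXT_B_E
            up_kick = True
        elif u < r_ext_e + r_ext_i + r_pe_e:
            # pending E-kick on an E neuron, weighted by pool size
            x = rng.random() * she_e
            c = 0
            for j in range(n_e):
                c += he[j]
                if x < c:
                    i = j
                    break
            s = s_ee
            koff = K_E_B_E
            up_kick = True
            he[i] -= 1
            she_e -= 1
            cons_e += 1
        elif u < r_ext_e + r_ext_i + r_pe_e + r_pe_i:
            x = rng.random() * she_i
            c = 0
            for j in range(n_e, n):
                c += he[j]
                if x < c:
                    i = j
                    break
            s = s_ie
            koff = K_E_B_E
            up_kick = True
            he[i] -= 1
            she_i -= 1
            cons_e += 1
        elif u < r_ext_e + r_ext_i + r_pe_e + r_pe_i + r_pi:
            # pending I-kick on any neuron, weighted by pool size
            x = rng.random() * shi
            c = 0
            for j in range(n):
                c += hi[j]
                if x < c:
                    i = j
                    break
            hi[i] -= 1
            shi -= 1
            cons_i += 1
            if refr[i] == 0:
                si = s_ei if i < n_e else s_ii
                dstar = (v[i] - vrev) / (v_th - vrev) * si
                d = int(np.floor(dstar))
                if rng.random() < dstar - d:
                    d += 1
                was_gate = gate[i]
                if was_gate == 1:
                    if i < n_e:
                        lkey = K_I_G_E
                        lcnt = n_ge
                    else:
                        lkey = K_I_G_I
                        lcnt = n_gi
                v[i] -= d
                if v[i] < vrev:
                    v[i] = vrev
                if was_gate == 1 and v[i] < v_c:
                    gate[i] = 0
                    if i < n_e:
                        n_ge -= 1
                    else:
                        n_gi -= 1
                    lout = 1
        elif u < r_ext_e + r_ext_i + r_pe_e + r_pe_i + r_pi + r_re:
            # refractory exit, E population
            m = int(rng.random() * nref_e)
            c = 0
            for j in range(n_e):
                if refr[j] == 1:
                    if c == m:
                        i = j
                        break
                    c += 1
            refr[i] = 0
            nref_e -= 1
            v[i] = v_r
            if v[i] >= v_c:
                gate[i] = 1
                n_ge += 1
        else:
            m = int(rng.random() * nref_i)
            c = 0
            for j in range(n_e, n):
                if refr[j] == 1:
                    if c == m:
                        i = j
                        break
                    c += 1
            refr[i] = 0
            nref_i -= 1
            v[i] = v_r
            if v[i] >= v_c:
                gate[i] = 1
                n_gi += 1

        if up_kick:
            # shared handling for external and pending-E kicks (upward)
            if i < n_e:
                bkey = koff
                gkey = koff + 2
                nb = n_e - n_ge
                ng = n_ge
            else:
                bkey = koff + 1
                gkey = koff + 3
                nb = n_i - n_gi
                ng = n_gi
            if refr[i] == 1:
                lkey = bkey
                lcnt = nb
                lout = 0
            elif gate[i] == 1:
                lkey = gkey
                lcnt = ng
                v[i] += s
                if v[i] >= v_th:
                    lout = 1
                    fire_i = i
                else:
                    lout = 0
            else:
                lkey = bkey
                lcnt = nb
                v[i] += s
                if v[i] >= v_th:
                    lout = 0  # fired straight out of base: ends refractory/base
                    fire_i = i
                elif v[i] >= v_c:
                    gate[i] = 1
                    if i < n_e:
                        n_ge += 1
                    else:
                        n_gi += 1
                    lout = 1
                else:
                    lout = 0

        if fire_i >= 0:
            i = fire_i
            if ns == spk_t.shape[0]:
                spk_t = _grow_f8(spk_t)
                spk_id = _grow_i32(spk_id)
            spk_t[ns] = t
            spk_id[ns] = i
            ns += 1
            if gate[i] == 1:
                gate[i] = 0
                if i < n_e:
                    n_ge -= 1
                else:
                    n_gi -= 1
            refr[i] = 1
            v[i] = v_r
            if i < n_e:
                nref_e += 1
                for j in range(n):
                    p = p_ee if j < n_e else p_ie
                    if rng.random() < p:
                        he[j] += 1
                        inc_e += 1
                        if j < n_e:
                            she_e += 1
                        else:
                            she_i += 1
            else:
                nref_i += 1
                for j in range(n):
                    p = p_ei if j < n_e else p_ii
                    if rng.random() < p:
                        hi[j] += 1
                        inc_i += 1
                        shi += 1

        if log_events and lkey >= 0:
            if nl == log_key.shape[0]:
                log_key = _grow_i8(log_key)
                log_cnt = _grow_i32(log_cnt)
                log_out = _grow_i8(log_out)
            log_key[nl] = lkey
            log_cnt[nl] = lcnt
            log_out[nl] = lout
            nl += 1

    # trailing samples: state is constant after the last event
    while next_s <= T and m_samp < n_samp:
        samp_t[m_samp] = next_s
        s_nge[m_samp] = n_ge
        s_ngi[m_samp] = n_gi
        s_he[m_samp] = she_e + she_i
        s_hi[m_samp] = shi
        m_samp += 1
        next_s += stride

    return (spk_t[:ns].copy(), spk_id[:ns].copy(),
            samp_t[:m_samp].copy(), s_nge[:m_samp].copy(),
            s_ngi[:m_samp].copy(), s_he[:m_samp].copy(), s_hi[:m_samp].copy(),
            log_key[:nl].copy(), log_cnt[:nl].copy(), log_out[:nl].copy(),
            inc_e, cons_e, inc_i, cons_i,
            she_e + she_i, shi)


@njit(cache=True)
def rn_kernel(rng, T, n_e, n_i,
              p_ee, p_ie, p_ei, p_ii,
              lam_e, lam_i, tau_ee, tau_ie, tau_i,
              P, stride):
    """Two-state reduced network: same exponential race as the MIF but
    neurons only carry a base/gate label; kick effects flip states with the
    learned probabilities ``P[key, count]``.  A gate neuron flipped down by
    an upward (external or E) kick fires; I-kicks flip gate->base silently.
    """
    n = n_e + n_i
    gate = np.zeros(n, np.uint8)
    he = np.zeros(n, np.int64)
    hi = np.zeros(n, np.int64)
    n_ge = 0
    n_gi = 0
    she_e = 0
    she_i = 0
    shi = 0

    r_ext_e = n_e * lam_e / 1000.0
    r_ext_i = n_i * lam_i / 1000.0

    spk_t = np.empty(4096, np.float64)
    spk_id = np.empty(4096, np.int32)
    ns = 0

    n_samp = int(T / stride) + 1
    samp_t = np.empty(n_samp, np.float64)
    s_nge = np.empty(n_samp, np.int64)
    s_ngi = np.empty(n_samp, np.int64)
    s_he = np.empty(n_samp, np.int64)
    s_hi = np.empty(n_samp, np.int64)
    m_samp = 0
    next_s = 0.0

    t = 0.0
    while True:
        r_pe_e = she_e / tau_ee
        r_pe_i = she_i / tau_ie
        r_pi = shi / tau_i
        rtot = r_ext_e + r_ext_i + r_pe_e + r_pe_i + r_pi
        if rtot <= 0.0:
            break
        t_new = t + -np.log1p(-rng.random()) / rtot
        while next_s <= T and next_s < t_new and m_samp < n_samp:
            samp_t[m_samp] = next_s
            s_nge[m_samp] = n_ge
            s_ngi[m_samp] = n_gi
            s_he[m_samp] = she_e + she_i
            s_hi[m_samp] = shi
            m_samp += 1
            next_s += stride
        if t_new > T:
            break
        t = t_new

        u = rng.random() * rtot
        fire_i = -1
        up_kick = False
        i = -1
        koff = 0
        if u < r_ext_e:
            i = int(rng.random() * n_e)
            koff = K_EXT_B_E
            up_kick = True
        elif u < r_ext_e + r_ext_i:
            i = n_e + int(rng.random() * n_i)
            koff = K_EXT_B_E
            up_kick = True
        elif u < r_ext_e + r_ext_i + r_pe_e:
            x = rng.random() * she_e
            c = 0
            for j in range(n_e):
                c += he[j]
                if x < c:
                    i = j
                    break
            koff = K_E_B_E
            up_kick = True
            he[i] -= 1
            she_e -= 1
        elif u < r_ext_e + r_ext_i + r_pe_e + r_pe_i:
            x = rng.random() * she_i
            c = 0
            for j in range(n_e, n):
                c += he[j]
                if x < c:
                    i = j
                    break
            koff = K_E_B_E
            up_kick = True
            he[i] -= 1
            she_i -= 1
        else:
            x = rng.random() * shi
            c = 0
            for j in range(n):
                c += hi[j]
                if x < c:
                    i = j
                    break
            hi[i] -= 1
            shi -= 1
            if gate[i] == 1:
                if i < n_e:
                    p = P[K_I_G_E, n_ge]
                else:
                    p = P[K_I_G_I, n_gi]
                if rng.random() < p:
                    gate[i] = 0
                    if i < n_e:
                        n_ge -= 1
                    else:
                        n_gi -= 1

        if up_kick:
            if gate[i] == 1:
                if i < n_e:
                    p = P[koff + 2, n_ge]
                else:
                    p = P[koff + 3, n_gi]
                if rng.random() < p:
                    fire_i = i
            else:
                if i < n_e:
                    p = P[koff, n_e - n_ge]
                else:
                    p = P[koff + 1, n_i - n_gi]
                if rng.random() < p:
                    gate[i] = 1
                    if i < n_e:
                        n_ge += 1
                    else:
                        n_gi += 1

        if fire_i >= 0:
            i = fire_i
            if ns == spk_t.shape[0]:
                spk_t = _grow_f8(spk_t)
                spk_id = _grow_i32(spk_id)
            spk_t[ns] = t
            spk_id[ns] = i
            ns += 1
            gate[i] = 0
            if i < n_e:
                n_ge -= 1
                for j in range(n):
                    p = p_ee if j < n_e else p_ie
                    if rng.random() < p:
                        he[j] += 1
                        if j < n_e:
                            she_e += 1
                        else:
                            she_i += 1
            else:
                n_gi -= 1
                for j in range(n):
                    p = p_ei if j < n_e else p_ii
                    if rng.random() < p:
                        hi[j] += 1
                        shi += 1

    while next_s <= T and m_samp < n_samp:
        samp_t[m_samp] = next_s
        s_nge[m_samp] = n_ge
        s_ngi[m_samp] = n_gi
        s_he[m_samp] = she_e + she_i
        s_hi[m_samp] = shi
        m_samp += 1
        next_s += stride

    return (spk_t[:ns].copy(), spk_id[:ns].copy(),
            samp_t[:m_samp].copy(), s_nge[:m_samp].copy(),
            s_ngi[:m_samp].copy(), s_he[:m_samp].copy(), s_hi[:m_samp].copy())


@njit(cache=True)
def cg_kernel(rng, T, n_e, n_i, lam_e, lam_i, tau_ee, tau_ie, tau_i,
              a_ee, a_ie, a_ei, a_ii, m_e, m_i, m_e_int, m_i_int,
              stoch_inc, cap_e, cap_i, P, stride,
              nge0, ngi0, he0, hi0):
    """Four-variable coarse-grained chain (N_GE, N_GI, H_E, H_I).

    Only effective (non-self) transitions enter the race: external
    kicks that neither flip nor fire are no-ops and are dropped from the
    event stream, which leaves the law of the chain unchanged.  When
    ``cap_e``/``cap_i`` are non-negative the truncated chain is simulated:
    transitions that would push a pool past its cap have rate zero.
    """
    nge = nge0
    ngi = ngi0
    he = he0
    hi = hi0
    lam_e_ms = lam_e / 1000.0
    lam_i_ms = lam_i / 1000.0

    spk_t = np.empty(4096, np.float64)
    spk_pop = np.empty(4096, np.int8)
    ns = 0

    n_samp = int(T / stride) + 1
    samp_t = np.empty(n_samp, np.float64)
    s_nge = np.empty(n_samp, np.int64)
    s_ngi = np.empty(n_samp, np.int64)
    s_he = np.empty(n_samp, np.int64)
    s_hi = np.empty(n_samp, np.int64)
    m_samp = 0
    next_s = 0.0

    r = np.empty(12, np.float64)
    t = 0.0
    while True:
        nbe = n_e - nge
        nbi = n_i - ngi
        fhe = float(he)
        fhi = float(hi)
        # external flips and fires
        r[0] = P[K_EXT_B_E, nbe] * nbe * lam_e_ms
        r[1] = P[K_EXT_B_I, nbi] * nbi * lam_i_ms
        r[2] = P[K_EXT_G_E, nge] * nge * lam_e_ms
        r[3] = P[K_EXT_G_I, ngi] * ngi * lam_i_ms
        # pending E-kick effects
        r[4] = P[K_E_B_E, nbe] * a_ee * (nbe / n_e) * fhe / tau_ee
        r[5] = P[K_E_B_I, nbi] * a_ie * (nbi / n_i) * fhe / tau_ie
        r[6] = P[K_E_G_E, nge] * a_ee * (nge / n_e) * fhe / tau_ee
        r[7] = P[K_E_G_I, ngi] * a_ie * (ngi / n_i) * fhe / tau_ie
        # pending E consumption with no flip
        r[10] = ((1.0 - P[K_E_B_E, nbe]) * a_ee * (nbe / n_e) * fhe / tau_ee
                 + (1.0 - P[K_E_B_I, nbi]) * a_ie * (nbi / n_i) * fhe / tau_ie
                 + (1.0 - P[K_E_G_E, nge]) * a_ee * (nge / n_e) * fhe / tau_ee
                 + (1.0 - P[K_E_G_I, ngi]) * a_ie * (ngi / n_i) * fhe / tau_ie)
        # pending I-kick effects
        r[8] = P[K_I_G_E, nge] * a_ei * (nge / n_e) * fhi / tau_i
        r[9] = P[K_I_G_I, ngi] * a_ii * (ngi / n_i) * fhi / tau_i
        r[11] = ((1.0 - P[K_I_G_E, nge] * a_ei * (nge / n_e)
                  - P[K_I_G_I, ngi] * a_ii * (ngi / n_i)) * fhi / tau_i)
        if cap_e >= 0:
            if he + m_e_int > cap_e:
                r[2] = 0.0
            if he - 1 + m_e_int > cap_e:
                r[6] = 0.0
        if cap_i >= 0:
            if hi + m_i_int > cap_i:
                r[3] = 0.0
                r[7] = 0.0
        rtot = 0.0
        for k in range(12):
            if r[k] < 0.0:
                r[k] = 0.0
            rtot += r[k]
        if rtot <= 0.0:
            break
        t_new = t + -np.log1p(-rng.random()) / rtot
        while next_s <= T and next_s < t_new and m_samp < n_samp:
            samp_t[m_samp] = next_s
            s_nge[m_samp] = nge
            s_ngi[m_samp] = ngi
            s_he[m_samp] = he
            s_hi[m_samp] = hi
            m_samp += 1
            next_s += stride
        if t_new > T:
            break
        t = t_new

        u = rng.random() * rtot
        ev = 0
        c = 0.0
        for k in range(12):
            c += r[k]
            if u < c:
                ev = k
                break

        spike_pop = -1
        if ev == 0:
            nge += 1
        elif ev == 1:
            ngi += 1
        elif ev == 2 or ev == 6:
            # E neuron fires (by external kick, or by an E-kick consuming
            # one pending kick)
            if stoch_inc:
                de = int(np.floor(m_e))
                if rng.random() < m_e - np.floor(m_e):
                    de += 1
            else:
                de = m_e_int
            nge -= 1
            he += de
            if ev == 6:
                he -= 1
            spike_pop = 0
        elif ev == 3 or ev == 7:
            if stoch_inc:
                di = int(np.floor(m_i))
                if rng.random() < m_i - np.floor(m_i):
                    di += 1
            else:
                di = m_i_int
            ngi -= 1
            hi += di
            if ev == 7:
                he -= 1
            spike_pop = 1
        elif ev == 4:
            nge += 1
            he -= 1
        elif ev == 5:
            ngi += 1
            he -= 1
        elif ev == 8:
            nge -= 1
            hi -= 1
        elif ev == 9:
            ngi -= 1
            hi -= 1
        elif ev == 10:
            he -= 1
        else:
            hi -= 1

        if spike_pop >= 0:
            if ns == spk_t.shape[0]:
                spk_t = _grow_f8(spk_t)
                spk_pop = _grow_i8(spk_pop)
            spk_t[ns] = t
            spk_pop[ns] = spike_pop
            ns += 1

    while next_s <= T and m_samp < n_samp:
        samp_t[m_samp] = next_s
        s_nge[m_samp] = nge
        s_ngi[m_samp] = ngi
        s_he[m_samp] = he
        s_hi[m_samp] = hi
        m_samp += 1
        next_s += stride

    return (spk_t[:ns].copy(), spk_pop[:ns].copy(),
            samp_t[:m_samp].copy(), s_nge[:m_samp].copy(),
            s_ngi[:m_samp].copy(), s_he[:m_samp].copy(), s_hi[:m_samp].copy())
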