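"""Numba kernels for the component-wise adaptive random-walk Metropolis
sampler.  The Python-facing wrapper lives in :mod:`beetlekern.inference`.

All state mutation happens through arrays passed in from the wrapper so a
chain can be continued block by block with identical results to a single
long run (given the per-block seeds).
"""

import math

import numpy as np
from numba import njit


@njit(cache=True)
def _cauchy_logpdf(x, scale):
    return -math.log(math.pi * scale) - math.log(1.0 + (x / scale) ** 2)


@njit(cache=True)
def _csum(k, active, theta):
    s = 0.0
    for ii in range(active.size):
        ki = float(k[active[ii]])
        s += math.lgamma(ki + theta) - math.lgamma(theta) - math.lgamma(ki + 1.0)
    return s


@njit(cache=True)
def _nb_ll(m, k, active, theta, csum):
    lt = math.log(theta)
    s = csum
    for ii in range(active.size):
        i = active[ii]
        mi = m[i]
        mu = math.exp(mi)
        lden = math.log(theta + mu)
        s += theta * (lt - lden) + float(k[i]) * (mi - lden)
    return s


@njit(cache=True)
def _fill_logS(
    logS, g, bd, bdt, T, inv,
    point_group, has_source,
    x0, h, C, ylo, yhi, slo, shi,
):
    U = point_group.shape[0]
    nseg = C.shape[1]
    xe = x0 + nseg * h
    for t in range(T):
        lin = bd + bdt * t
        delta = 1.0 / lin if inv else lin
        lx = math.log(delta)
        if lx <= x0:
            mode = 0
            dx = lx - x0
            idx = 0
        elif lx >= xe:
            mode = 1
            dx = lx - xe
            idx = 0
        else:
            mode = 2
            idx = int((lx - x0) / h)
            if idx >= nseg:
                idx = nseg - 1
            dx = lx - (x0 + idx * h)
        for u in range(U):
            if point_group[u] != g or not has_source[u]:
                continue
            if mode == 0:
                y = ylo[u] + slo[u] * dx
            elif mode == 1:
                y = yhi[u] + shi[u] * dx
            else:
                y = ((C[u, idx, 0] * dx + C[u, idx, 1]) * dx + C[u, idx, 2]) * dx + C[u, idx, 3]
            logS[u, t] = y


@njit(cache=True)
def run_chain(
    seed, n_iter, adapt, target, adapt_window, adapt_step,
    x, scales,
    k, active,
    col_indptr, col_rows,
    n_beta, T, inv,
    obs_point, obs_date, point_group, has_source,
    sp_x0, sp_h, sp_c, sp_ylo, sp_yhi, sp_slo, sp_shi,
    cauchy_scale,
    samples, ll_out, lp_out, acc_out,
):
    """One block of component-wise random-walk Metropolis.

    Mutates ``x``/``scales`` in place and fills ``samples`` (n_iter x d),
    ``ll_out``/``lp_out`` (n_iter) and ``acc_out`` (d, accepted counts).
    """
    np.random.seed(seed)
    d = x.size
    n = k.size
    U = point_group.shape[0]
    p_coef = d - 2 * n_beta - 1
    has_kernel = n_beta > 0

    # --- initial state
    eta = np.zeros(n)
    for j in range(p_coef):
        v = x[2 * n_beta + j]
        for ptr in range(col_indptr[j], col_indptr[j + 1]):
            eta[col_rows[ptr]] += v
    logS = np.zeros((U, T))
    if has_kernel:
        for g in range(n_beta):
            _fill_logS(
                logS, g, x[g], x[n_beta + g], T, inv,
                point_group, has_source,
                sp_x0, sp_h, sp_c, sp_ylo, sp_yhi, sp_slo, sp_shi,
            )
    m = np.zeros(n)
    for i in range(n):
        m[i] = eta[i]
        if has_kernel:
            m[i] += logS[obs_point[i], obs_date[i]]
    theta = math.exp(x[d - 1])
    csum = _csum(k, active, theta)
    ll = _nb_ll(m, k, active, theta, csum)
    prior = 0.0
    for j in range(p_coef):
        prior += _cauchy_logpdf(x[2 * n_beta + j], cauchy_scale)

    acc_win = np.zeros(d, dtype=np.int64)
    for it in range(n_iter):
        for j in range(d):
            prop = x[j] + scales[j] * np.random.normal()
            if j < 2 * n_beta:
                g = j if j < n_beta else j - n_beta
                bd = x[g]
                bdt = x[n_beta + g]
                if j < n_beta:
                    bd = prop
                else:
                    bdt = prop
                if bd <= 0.0 or bd + bdt * (T - 1) <= 0.0:
                    continue
                logS_new = logS.copy()
                _fill_logS(
                    logS_new, g, bd, bdt, T, inv,
                    point_group, has_source,
                    sp_x0, sp_h, sp_c, sp_ylo, sp_yhi, sp_slo, sp_shi,
                )
                m_new = m.copy()
                for ii in range(active.size):
                    i = active[ii]
                    u = obs_point[i]
                    if point_group[u] == g:
                        m_new[i] = eta[i] + logS_new[u, obs_date[i]]
                ll_new = _nb_ll(m_new, k, active, theta, csum)
                if math.log(np.random.random()) < ll_new - ll:
                    x[j] = prop
                    logS = logS_new
                    m = m_new
                    ll = ll_new
                    acc_win[j] += 1
                    acc_out[j] += 1
            elif j < d - 1:
                dc = prop - x[j]
                m_new = m.copy()
                for ptr in range(col_indptr[j - 2 * n_beta], col_indptr[j - 2 * n_beta + 1]):
                    m_new[col_rows[ptr]] += dc
                ll_new = _nb_ll(m_new, k, active, theta, csum)
                dpr = _cauchy_logpdf(prop, cauchy_scale) - _cauchy_logpdf(x[j], cauchy_scale)
                if math.log(np.random.random()) < ll_new - ll + dpr:
                    for ptr in range(col_indptr[j - 2 * n_beta], col_indptr[j - 2 * n_beta + 1]):
                        eta[col_rows[ptr]] += dc
                    x[j] = prop
                    m = m_new
                    ll = ll_new
                    prior += dpr
                    acc_win[j] += 1
                    acc_out[j] += 1
            else:
                if abs(prop) > 30.0:
                    continue
                theta_new = math.exp(prop)
                csum_new = _csum(k, active, theta_new)
                ll_new = _nb_ll(m, k, active, theta_new, csum_new)
                if math.log(np.random.random()) < ll_new - ll:
                    x[j] = prop
                    theta = theta_new
                    csum = csum_new
                    ll = ll_new
                    acc_win[j] += 1
                    acc_out[j] += 1
        if adapt and (it + 1) % adapt_window == 0:
            for j in range(d):
                rate = acc_win[j] / adapt_window
                scales[j] *= math.exp(adapt_step * (rate - target))
                if scales[j] < 1e-8:
                    scales[j] = 1e-8
                elif scales[j] > 1e6:
                    scales[j] = 1e6
                acc_win[j] = 0
        for j in range(d):
            samples[it, j] = x[j]
        ll_out[it] = ll
        lp_out[it] = ll + prior
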