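"""Compiled log-density/gradient kernel for the unconstrained posterior.

A loop-level translation of ``UnconstrainedPosterior.logp_grad_numpy``
compiled with numba; it cuts a gradient evaluation from ~0.4 ms to ~0.01 ms,
which is what makes reduced-scale simulation-recovery experiments cheap.
The NumPy implementation remains the reference; the test suite asserts
agreement at random points to ~1e-10.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_LOG_2PI = float(np.log(2.0 * np.pi))


@njit(cache=True)
def _softplus(x: float) -> float:
    if x > 35.0:
        return x
    if x < -35.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True)
def _expit(x: float) -> float:
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=True)
def logp_grad_kernel(
    q,
    T, W, M,
    widx, winter_mask,
    Ef, Sn, O, C, A_c, H, Bc, A_b, D, A_d,
    use_road, use_harvest, use_block, use_carcass,
    nl1_sd, rl1_sd, rsl_init_sd, coef_sd, sig_scale,
    lgamma_const,
):
    dim = q.shape[0]
    grad = np.zeros(dim)
    neg_inf = -np.inf

    n_rates = M + 2
    U0 = 4
    RATES0 = 10
    NL0 = RATES0 + n_rates
    ZRL0 = NL0 + T
    HL0 = ZRL0 + T
    DL0 = HL0 + (T - 1)
    RSL0 = DL0 + W

    hm, rho, b, a = q[0], q[1], q[2], q[3]
    sigma = np.empty(6)
    for j in range(6):
        sigma[j] = np.exp(q[U0 + j])
    rates = np.empty(n_rates)
    for k in range(n_rates):
        rates[k] = _expit(q[RATES0 + k])
    bc = rates[M]
    rD = rates[M + 1]
    s0 = rsl_init_sd if rsl_init_sd > 0.0 else sigma[5]

    NL = q[NL0 : NL0 + T]
    hl = q[HL0 : HL0 + T - 1]
    dl = q[DL0 : DL0 + W]
    rsl = q[RSL0 : RSL0 + T]

    for i in range(T):
        if NL[i] > 690.0:
            return neg_inf, grad

    rl = np.empty(T)
    rl[0] = rl1_sd * q[ZRL0]
    for i in range(1, T):
        rl[i] = rl[i - 1] + sigma[2] * q[ZRL0 + i]

    N = np.empty(T)
    rS = np.empty(T)
    for i in range(T):
        N[i] = np.exp(NL[i])
        rS[i] = _expit(rsl[i])
    h = np.empty(T - 1)
    for i in range(T - 1):
        h[i] = _expit(hl[i])
    d = np.empty(W)
    for w in range(W):
        d[w] = _expit(dl[w])

    lp = 0.0

    # ---- priors
    lp += -0.5 * (NL[0] / nl1_sd) ** 2 - np.log(nl1_sd) - 0.5 * _LOG_2PI
    grad[NL0] += -NL[0] / (nl1_sd * nl1_sd)
    for i in range(4):
        lp += -0.5 * q[i] * q[i] / (coef_sd * coef_sd) \
            - np.log(coef_sd) - 0.5 * _LOG_2PI
        grad[i] += -q[i] / (coef_sd * coef_sd)
    for j in range(6):
        lp += np.log(2.0 / np.pi) - np.log(sig_scale) \
            - np.log1p((sigma[j] / sig_scale) ** 2) + q[U0 + j]
        grad[U0 + j] += 1.0 - 2.0 * sigma[j] ** 2 / (sig_scale**2 + sigma[j] ** 2)
    for k in range(n_rates):
        lp += np.log(rates[k]) + np.log1p(-rates[k])
        grad[RATES0 + k] += 1.0 - 2.0 * rates[k]
    for i in range(T):
        z = q[ZRL0 + i]
        lp += -0.5 * z * z - 0.5 * _LOG_2PI
        grad[ZRL0 + i] -= z

    # ---- process terms (centred NL); e = d logp / d mu
    g_rl = np.zeros(T)
    w = 0
    for i in range(1, T):
        mu = NL[i - 1] + rl[i] - _softplus(hl[i - 1])
        if winter_mask[i]:
            mu += rl[i] - _softplus(dl[w])
            s = sigma[1]
        else:
            s = sigma[0]
        resid = (NL[i] - mu) / s
        lp += -0.5 * resid * resid - np.log(s) - 0.5 * _LOG_2PI
        e = resid / s
        grad[NL0 + i] += -e
        grad[NL0 + i - 1] += e
        if winter_mask[i]:
            grad[U0 + 1] += resid * resid - 1.0
            g_rl[i] = 2.0 * e
            grad[DL0 + w] += -e * d[w]
            w += 1
        else:
            grad[U0 + 0] += resid * resid - 1.0
            g_rl[i] = e
        grad[HL0 + i - 1] += -e * h[i - 1]

    # ---- rl random walk backprop
    acc = 0.0
    for i in range(T - 1, 0, -1):
        acc += g_rl[i]
        grad[ZRL0 + i] += acc * sigma[2]
        grad[U0 + 2] += sigma[2] * acc * q[ZRL0 + i]
    acc += g_rl[0]
    grad[ZRL0] += acc * rl1_sd

    # ---- hunting submodel
    for i in range(T - 1):
        fh = (hl[i] - (hm + rho * Ef[i + 1])) / sigma[3]
        lp += -0.5 * fh * fh - np.log(sigma[3]) - 0.5 * _LOG_2PI
        grad[HL0 + i] += -fh / sigma[3]
        grad[0] += fh / sigma[3]
        grad[1] += fh * Ef[i + 1] / sigma[3]
        grad[U0 + 3] += fh * fh - 1.0

    # ---- winter mortality submodel
    for w in range(W):
        fd = (dl[w] - (b + a * Sn[w])) / sigma[4]
        lp += -0.5 * fd * fd - np.log(sigma[4]) - 0.5 * _LOG_2PI
        grad[DL0 + w] += -fd / sigma[4]
        grad[2] += fd / sigma[4]
        grad[3] += fd * Sn[w] / sigma[4]
        grad[U0 + 4] += fd * fd - 1.0

    # ---- seasonal observability
    for i in range(3):
        z = rsl[i] / s0
        lp += -0.5 * z * z - np.log(s0) - 0.5 * _LOG_2PI
        grad[RSL0 + i] += -rsl[i] / (s0 * s0)
        if rsl_init_sd <= 0.0:
            grad[U0 + 5] += z * z - 1.0
    for i in range(3, T):
        S = rsl[i] + rsl[i - 1] + rsl[i - 2] + rsl[i - 3]
        z = S / sigma[5]
        lp += -0.5 * z * z - np.log(sigma[5]) - 0.5 * _LOG_2PI
        wr = S / (sigma[5] * sigma[5])
        for k in range(4):
            grad[RSL0 + i - k] += -wr
        grad[U0 + 5] += z * z - 1.0

    # ---- observation channels
    if use_road:
        for i in range(T):
            for m in range(M):
                if O[i, m] > 0.0:
                    mu = N[i] * rates[m] * rS[i] * O[i, m] * A_c[m]
                    c = C[i, m]
                    if c > 0.0:
                        if mu < 1e-12:
                            return neg_inf, np.zeros(dim)
                        lp += c * np.log(mu) - mu
                    else:
                        lp += -mu
                    resid = c - mu
                    grad[NL0 + i] += resid
                    grad[RSL0 + i] += resid * (1.0 - rS[i])
                    grad[RATES0 + m] += resid * (1.0 - rates[m])
    if use_harvest:
        for i in range(1, T):
            lam = N[i] * h[i - 1]
            c = H[i]
            if c > 0.0:
                if lam < 1e-12:
                    return neg_inf, np.zeros(dim)
                lp += c * np.log(lam) - lam
            else:
                lp += -lam
            resid = c - lam
            grad[NL0 + i] += resid
            grad[HL0 + i - 1] += resid * (1.0 - h[i - 1])
    if use_block:
        for w in range(W):
            theta = N[widx[w]] * bc * A_b[w]
            c = Bc[w]
            if c > 0.0:
                if theta < 1e-12:
                    return neg_inf, np.zeros(dim)
                lp += c * np.log(theta) - theta
            else:
                lp += -theta
            resid = c - theta
            grad[NL0 + widx[w]] += resid
            grad[RATES0 + M] += resid * (1.0 - bc)
    if use_carcass:
        for w in range(W):
            eta = N[widx[w]] * d[w] * rD * A_d[w]
            c = D[w]
            if c > 0.0:
                if eta < 1e-12:
                    return neg_inf, np.zeros(dim)
                lp += c * np.log(eta) - eta
            else:
                lp += -eta
            resid = c - eta
            grad[NL0 + widx[w]] += resid
            grad[DL0 + w] += resid * (1.0 - d[w])
            grad[RATES0 + M + 1] += resid * (1.0 - rD)
    lp += lgamma_const

    if not np.isfinite(lp):
        return neg_inf, np.zeros(dim)
    for i in range(dim):
        if not np.isfinite(grad[i]):
            return neg_inf, np.zeros(dim)
    return lp, grad
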