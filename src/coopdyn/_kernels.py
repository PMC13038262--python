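"""Compiled negative log-likelihood kernels, one per model.

These mirror the ChoiceModel state machines in models.py exactly (a test
asserts agreement to 1e-10) but run as numba machine code, which makes the
multi-start MLE and the recovery analyses tractable on a single core.

Each kernel takes (theta, own, partner, payoff) where theta is the model's
parameter vector in signature order, own/partner are int8 arrays coded
1=cooperate / 0=defect, and payoff is the participant's token outcome.  Per
the likelihood guard, trial probabilities are clipped to
[1e-10, 1 - 1e-10] before the log.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LIK_EPS = 1e-10
P_CLIP = 1e-3  # influence-model belief clip
P_INIT = 0.5
V_INIT = 3.0


@njit(cache=False)
def _log_choice(q_coop, own_t):
    prob = q_coop if own_t == 1 else 1.0 - q_coop
    if prob < LIK_EPS:
        prob = LIK_EPS
    elif prob > 1.0 - LIK_EPS:
        prob = 1.0 - LIK_EPS
    return np.log(prob)


@njit(cache=False)
def _softmax(u_c, u_d, beta):
    z = beta * (u_d - u_c)
    if z == 0.0:
        return 0.5
    e = np.exp(-abs(z))
    small = e / (1.0 + e)
    return small if z > 0.0 else 1.0 - small


@njit(cache=False)
def nll_m1(theta, own, partner, payoff):
    b = theta[0]
    ll = 0.0
    for t in range(own.size):
        ll += _log_choice(b, own[t])
    return -ll


@njit(cache=False)
def nll_m2(theta, own, partner, payoff):
    eps = theta[0]
    ll = 0.0
    q = 0.5  # no history on the first trial
    for t in range(own.size):
        ll += _log_choice(q, own[t])
        repeat = 1.0 - eps / 2.0 if payoff[t] >= 4 else eps / 2.0
        q = repeat if own[t] == 1 else 1.0 - repeat
    return -ll


@njit(cache=False)
def nll_m3(theta, own, partner, payoff):
    alpha, beta = theta[0], theta[1]
    v_c = V_INIT
    v_d = V_INIT
    ll = 0.0
    for t in range(own.size):
        ll += _log_choice(_softmax(v_c, v_d, beta), own[t])
        if own[t] == 1:
            v_c += alpha * (payoff[t] - v_c)
        else:
            v_d += alpha * (payoff[t] - v_d)
    return -ll


@njit(cache=False)
def nll_m4(theta, own, partner, payoff):
    phi, nu, beta = theta[0], theta[1], theta[2]
    p = P_INIT
    c_self = 4.0 * p
    c_other = 6.0 - 2.0 * p
    d_self = 4.0 * p + 2.0
    d_other = 2.0 - 2.0 * p
    u_c = c_self - phi * max(c_other - c_self, 0.0) - nu * max(c_self - c_other, 0.0)
    u_d = d_self - phi * max(d_other - d_self, 0.0) - nu * max(d_self - d_other, 0.0)
    q = _softmax(u_c, u_d, beta)
    ll = 0.0
    for t in range(own.size):
        ll += _log_choice(q, own[t])
    return -ll


@njit(cache=False)
def nll_m5(theta, own, partner, payoff):
    omega, beta = theta[0], theta[1]
    q = _softmax(P_INIT * (4.0 + omega), 4.0 * P_INIT + 2.0, beta)
    ll = 0.0
    for t in range(own.size):
        ll += _log_choice(q, own[t])
    return -ll


@njit(cache=False)
def nll_m6(theta, own, partner, payoff):
    alpha, omega, beta = theta[0], theta[1], theta[2]
    p = P_INIT
    ll = 0.0
    for t in range(own.size):
        ll += _log_choice(_softmax(p * (4.0 + omega), 4.0 * p + 2.0, beta), own[t])
        p += alpha * (partner[t] - p)
    return -ll


@njit(cache=False)
def nll_m7(theta, own, partner, payoff):
    alpha, kappa, omega, beta = theta[0], theta[1], theta[2], theta[3]
    p = P_INIT
    ll = 0.0
    for t in range(own.size):
        q = _softmax(p * (4.0 + omega), 4.0 * p + 2.0, beta)
        ll += _log_choice(q, own[t])
        p += alpha * (partner[t] - p) + kappa * (own[t] - q)
        if p < P_CLIP:
            p = P_CLIP
        elif p > 1.0 - P_CLIP:
            p = 1.0 - P_CLIP
    return -ll


@njit(cache=False)
def nll_m8(theta, own, partner, payoff):
    alpha_pos, alpha_neg, omega, beta = theta[0], theta[1], theta[2], theta[3]
    p = P_INIT
    ll = 0.0
    for t in range(own.size):
        ll += _log_choice(_softmax(p * (4.0 + omega), 4.0 * p + 2.0, beta), own[t])
        pe = partner[t] - p
        if pe > 0.0:
            p += alpha_pos * pe
        elif pe < 0.0:
            p += alpha_neg * pe
    return -ll


NLL_KERNELS = {
    "M1": nll_m1,
    "M2": nll_m2,
    "M3": nll_m3,
    "M4": nll_m4,
    "M5": nll_m5,
    "M6": nll_m6,
    "M7": nll_m7,
    "M8": nll_m8,
}
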