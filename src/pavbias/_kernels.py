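"""Numba-compiled inner loops for trial-sequence likelihood and simulation.

These kernels operate on the expanded six-parameter vector
(alpha0, alpha1, tau, xi, b, pi); models that lack a parameter pass its
neutral value (alpha0 == alpha1 == alpha, xi = b = pi = 0). Q-values are
tracked per (condition, action) with only the chosen action's cell updated.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TINY = 1e-300


@njit(cache=False)
def _pgo(w_go: float, w_nogo: float, tau: float, xi: float) -> float:
    d = tau * (w_go - w_nogo)
    if d >= 0.0:
        p = 1.0 / (1.0 + math.exp(-d))
    else:
        e = math.exp(d)
        p = e / (1.0 + e)
    return p * (1.0 - xi) + 0.5 * xi


@njit(cache=False)
def _effective_alpha(resp: int, reward: int, valence: int, a0: float, a1: float) -> float:
    # Bias-congruent pairings (go followed by a displayed immediate reward,
    # no-go followed by a displayed delayed reward) learn at a0; everything
    # else, including no-reward feedback, at a1.
    if reward == 1 and ((resp == 1 and valence == 1) or (resp == 0 and valence == -1)):
        return a0
    return a1


@njit(cache=False)
def loglik_kernel(
    cond: np.ndarray,
    resp: np.ndarray,
    reward: np.ndarray,
    included: np.ndarray,
    valence: np.ndarray,
    a0: float,
    a1: float,
    tau: float,
    xi: float,
    b: float,
    pi: float,
) -> float:
    """Log-likelihood of an observed response sequence.

    Excluded trials contribute no likelihood term but still drive learning
    (the participant saw the feedback).
    """
    q = np.zeros((4, 2))
    ll = 0.0
    for t in range(cond.shape[0]):
        c = cond[t]
        w_go = q[c, 1] + b + pi * valence[c]
        w_nogo = q[c, 0]
        p_go = _pgo(w_go, w_nogo, tau, xi)
        a = resp[t]
        if included[t]:
            p = p_go if a == 1 else 1.0 - p_go
            ll += math.log(p if p > _TINY else _TINY)
        r = reward[t]
        alpha = _effective_alpha(a, r, valence[c], a0, a1)
        q[c, a] += alpha * (r - q[c, a])
    return ll


@njit(cache=False)
def simulate_kernel(
    cond: np.ndarray,
    valence: np.ndarray,
    required_go: np.ndarray,
    u_resp: np.ndarray,
    u_flip: np.ndarray,
    p_incongruent: float,
    a0: float,
    a1: float,
    tau: float,
    xi: float,
    b: float,
    pi: float,
):
    """Generative run of one agent: sampled responses and displayed feedback.

    Returns (responses, feedback_reward, feedback_congruent) as int/bool
    arrays; feedback_reward is 1 when a reward was displayed.
    """
    n = cond.shape[0]
    q = np.zeros((4, 2))
    resp = np.empty(n, dtype=np.int64)
    fb_reward = np.empty(n, dtype=np.int64)
    fb_congruent = np.empty(n, dtype=np.bool_)
    for t in range(n):
        c = cond[t]
        w_go = q[c, 1] + b + pi * valence[c]
        w_nogo = q[c, 0]
        p_go = _pgo(w_go, w_nogo, tau, xi)
        a = 1 if u_resp[t] < p_go else 0
        correct = 1 if a == required_go[c] else 0
        congruent = u_flip[t] >= p_incongruent
        shown = correct if congruent else 1 - correct
        resp[t] = a
        fb_reward[t] = shown
        fb_congruent[t] = congruent
        alpha = _effective_alpha(a, shown, valence[c], a0, a1)
        q[c, a] += alpha * (shown - q[c, a])
    return resp, fb_reward, fb_congruent
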