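"""Row-vectorized trial-loop likelihoods (numba kernels).

Each "row" pairs one parameter vector with one choice/outcome sequence; the
compiled kernels loop rows x trials with scalar arithmetic. Used by the
hierarchical sampler (rows = chains x subjects) and by pointwise
log-likelihood extraction (rows = posterior draws x subjects). Semantics
match models.session_loglik exactly; the equivalence is pinned by tests.

Parameter column order per model:
    pvl_delta / pvl_decay: alpha, lam, a, c
    vpp:                   alpha, lam, a, c, k, ep_p, ep_n, w
    orl:                   a_rew, a_pun, k_prime, beta_f, beta_p

Padded (ragged) sessions use choice -1; padded trials contribute zero.
"""

from __future__ import annotations

import numpy as np
from numba import njit

PARAM_ORDER = {
    "pvl_delta": ("alpha", "lam", "a", "c"),
    "pvl_decay": ("alpha", "lam", "a", "c"),
    "vpp": ("alpha", "lam", "a", "c", "k", "ep_p", "ep_n", "w"),
    "orl": ("a_rew", "a_pun", "k_prime", "beta_f", "beta_p"),
}


@njit(cache=True)
def _log_softmax_entry(v0, v1, v2, v3, ch):
    m = v0
    if v1 > m:
        m = v1
    if v2 > m:
        m = v2
    if v3 > m:
        m = v3
    lse = m + np.log(np.exp(v0 - m) + np.exp(v1 - m) + np.exp(v2 - m) + np.exp(v3 - m))
    if ch == 0:
        return v0 - lse
    if ch == 1:
        return v1 - lse
    if ch == 2:
        return v2 - lse
    return v3 - lse


@njit(cache=True)
def _loglik_pvl(params, choices, xs, use_decay, out):
    R, T = choices.shape
    for r in range(R):
        alpha = params[r, 0]
        lam = params[r, 1]
        a = params[r, 2]
        theta = 3.0 ** params[r, 3] - 1.0
        E = np.zeros(4)
        for t in range(T):
            ch = choices[r, t]
            if ch < 0:
                continue
            out[r, t] = _log_softmax_entry(
                theta * E[0], theta * E[1], theta * E[2], theta * E[3], ch
            )
            x = xs[r, t]
            if x >= 0.0:
                u = x**alpha
            else:
                u = -lam * (-x) ** alpha
            if use_decay:
                for d in range(4):
                    E[d] *= a
                E[ch] += u
            else:
                E[ch] += a * (u - E[ch])


@njit(cache=True)
def _loglik_vpp(params, choices, xs, out):
    R, T = choices.shape
    for r in range(R):
        alpha = params[r, 0]
        lam = params[r, 1]
        a = params[r, 2]
        theta = 3.0 ** params[r, 3] - 1.0
        k = params[r, 4]
        ep_p = params[r, 5]
        ep_n = params[r, 6]
        w = params[r, 7]
        E = np.zeros(4)
        P = np.zeros(4)
        for t in range(T):
            ch = choices[r, t]
            if ch < 0:
                continue
            v0 = w * E[0] + (1.0 - w) * P[0]
            v1 = w * E[1] + (1.0 - w) * P[1]
            v2 = w * E[2] + (1.0 - w) * P[2]
            v3 = w * E[3] + (1.0 - w) * P[3]
            out[r, t] = _log_softmax_entry(theta * v0, theta * v1, theta * v2, theta * v3, ch)
            x = xs[r, t]
            if x >= 0.0:
                u = x**alpha
            else:
                u = -lam * (-x) ** alpha
            E[ch] += a * (u - E[ch])
            for d in range(4):
                P[d] *= k
            P[ch] += ep_p if x >= 0.0 else ep_n


@njit(cache=True)
def _loglik_orl(params, choices, xs, same_rate_fictive, out):
    R, T = choices.shape
    for r in range(R):
        a_rew = params[r, 0]
        a_pun = params[r, 1]
        K = 3.0 ** params[r, 2] - 1.0
        beta_f = params[r, 3]
        beta_p = params[r, 4]
        decay = 1.0 + K
        EV = np.zeros(4)
        EF = np.zeros(4)
        PS = np.zeros(4)
        for t in range(T):
            ch = choices[r, t]
            if ch < 0:
                continue
            v0 = EV[0] + beta_f * EF[0] + beta_p * PS[0]
            v1 = EV[1] + beta_f * EF[1] + beta_p * PS[1]
            v2 = EV[2] + beta_f * EF[2] + beta_p * PS[2]
            v3 = EV[3] + beta_f * EF[3] + beta_p * PS[3]
            out[r, t] = _log_softmax_entry(v0, v1, v2, v3, ch)
            x = xs[r, t]
            gain = x >= 0.0
            a_ch = a_rew if gain else a_pun
            if same_rate_fictive:
                a_fic = a_ch
            else:
                a_fic = a_pun if gain else a_rew
            sgn = 0.0
            if x > 0.0:
                sgn = 1.0
            elif x < 0.0:
                sgn = -1.0
            EV[ch] += a_ch * (x - EV[ch])
            ef_ch = EF[ch] + a_ch * (sgn - EF[ch])
            for d in range(4):
                EF[d] += a_fic * (-sgn / 3.0 - EF[d])
            EF[ch] = ef_ch
            for d in range(4):
                PS[d] /= decay
            PS[ch] = 1.0 / decay


def batch_loglik(
    model: str,
    params: np.ndarray,
    choices: np.ndarray,
    xs: np.ndarray,
    same_rate_fictive: bool = False,
) -> np.ndarray:
    """Per-trial log-probabilities, shape (n_rows, n_trials).

    params: (n_rows, n_params) natural-scale values in PARAM_ORDER;
    choices: (n_rows, n_trials) deck indices 0..3, -1 for padding;
    xs: (n_rows, n_trials) scaled net outcomes (0 where padded).
    """
    params = np.ascontiguousarray(params, dtype=np.float64)
    choices = np.ascontiguousarray(choices, dtype=np.int64)
    xs = np.ascontiguousarray(xs, dtype=np.float64)
    out = np.zeros(choices.shape)
    if model == "pvl_delta":
        _loglik_pvl(params, choices, xs, False, out)
    elif model == "pvl_decay":
        _loglik_pvl(params, choices, xs, True, out)
    elif model == "vpp":
        _loglik_vpp(params, choices, xs, out)
    elif model == "orl":
        _loglik_orl(params, choices, xs, same_rate_fictive, out)
    else:
        raise ValueError(f"unknown model id {model!r}")
    return out


def pack_sessions(sessions, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Pad sessions to a common length; returns (choices, scaled nets)."""
    T = max(len(s) for s in sessions)
    choices = np.full((len(sessions), T), -1, dtype=np.int64)
    xs = np.zeros((len(sessions), T))
    for i, s in enumerate(sessions):
        n = len(s)
        choices[i, :n] = s.choices
        xs[i, :n] = s.nets / scale
    return choices, xs
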