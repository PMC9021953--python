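"""Independent straight-line reimplementations of the four choice models.

Deliberately naive: plain floats, lists, and one loop per trial, written
directly from the model equations with no shared code or containers from
the package. Used as the reference for likelihood equivalence tests.
"""

import math


def softmax4(v, theta):
    z = [theta * x for x in v]
    m = max(z)
    e = [math.exp(x - m) for x in z]
    s = sum(e)
    return [x / s for x in e]


def pvl_loglik(trials, alpha, lam, a, c, rule, scale=100.0):
    """trials: list of (choice 0..3, net in euros). Returns per-trial log-probs."""
    theta = 3.0**c - 1.0
    E = [0.0, 0.0, 0.0, 0.0]
    out = []
    for ch, net in trials:
        p = softmax4(E, theta)
        out.append(math.log(p[ch]))
        x = net / scale
        u = x**alpha if x >= 0 else -lam * abs(x) ** alpha
        if rule == "delta":
            E[ch] = E[ch] + a * (u - E[ch])
        else:
            E = [a * e for e in E]
            E[ch] += u
    return out


def vpp_loglik(trials, alpha, lam, a, c, k, ep_p, ep_n, w, scale=100.0):
    theta = 3.0**c - 1.0
    E = [0.0] * 4
    P = [0.0] * 4
    out = []
    for ch, net in trials:
        V = [w * e + (1 - w) * p for e, p in zip(E, P)]
        probs = softmax4(V, theta)
        out.append(math.log(probs[ch]))
        x = net / scale
        u = x**alpha if x >= 0 else -lam * abs(x) ** alpha
        E[ch] = E[ch] + a * (u - E[ch])
        P = [k * p for p in P]
        P[ch] += ep_p if x >= 0 else ep_n
    return out


def orl_loglik(trials, a_rew, a_pun, k_prime, beta_f, beta_p, scale=100.0, same_rate=False):
    K = 3.0**k_prime - 1.0
    EV = [0.0] * 4
    EF = [0.0] * 4
    PS = [0.0] * 4
    out = []
    for ch, net in trials:
        V = [ev + beta_f * ef + beta_p * ps for ev, ef, ps in zip(EV, EF, PS)]
        probs = softmax4(V, 1.0)
        out.append(math.log(probs[ch]))
        x = net / scale
        if x >= 0:
            a_c, a_f = a_rew, (a_rew if same_rate else a_pun)
        else:
            a_c, a_f = a_pun, (a_pun if same_rate else a_rew)
        sgn = (x > 0) - (x < 0)
        EV[ch] = EV[ch] + a_c * (x - EV[ch])
        new_EF = [ef + a_f * (-sgn / 3.0 - ef) for ef in EF]
        new_EF[ch] = EF[ch] + a_c * (sgn - EF[ch])
        EF = new_EF
        PS = [ps / (1.0 + K) for ps in PS]
        PS[ch] = 1.0 / (1.0 + K)
    return out
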