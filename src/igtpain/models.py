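"""Reinforcement-learning models of IGT choice: PVL-Delta, PVL-Decay, VPP, ORL.

All four models map a history of (chosen deck, net outcome) pairs to softmax
choice probabilities over the four decks.

PVL models combine a prospect-theory utility u(x) = x^alpha for gains and
-lam*|x|^alpha for losses with either Rescorla-Wagner (delta) or
multiplicative-decay expectancy updating, and a softmax with sensitivity
theta = 3^c - 1.

VPP extends PVL-Delta with a decaying perseverance trace P, incremented on
the chosen deck by a gain-impact (ep_p) or loss-impact (ep_n) parameter, and
values V = w*E + (1-w)*P.

ORL tracks expected value EV (learning rate A+ after gains, A- after losses)
and win frequency EF separately; unchosen decks receive a fictive frequency
update toward -sgn(x)/3 with the opposite-valence rate. A perseverance trace
PS decays at rate 1/(1+K), K = 3^K' - 1. Values are
V = EV + beta_f*EF + beta_p*PS with unit softmax sensitivity.

Net outcomes are divided by the scheme's outcome_scale (default 100) before
entering utilities and learning, keeping x^alpha and softmax arguments tame.
Initial latent state is all-zero, so the first choice is uniform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .task import DECKS, PayoffScheme, SessionRecord, Trial, new_cycle_state, draw_outcome

N_DECKS = 4

MODEL_IDS = ("pvl_delta", "pvl_decay", "vpp", "orl")


class ParameterError(ValueError):
    """A cognitive parameter is outside its admissible range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass(frozen=True)
class PVLParams:
    """Prospect Valence Learning parameters (delta or decay rule).

    alpha: outcome sensitivity, (0,1); lam: loss aversion, (0,10);
    a: learning (delta) or decay (decay) rate, [0,1];
    c: response consistency, [0,5] (softmax sensitivity theta = 3^c - 1).
    """

    alpha: float
    lam: float
    a: float
    c: float
    rule: str = "delta"

    def __post_init__(self):
        _check(0 < self.alpha < 1, f"alpha must be in (0,1), got {self.alpha}")
        _check(0 < self.lam < 10, f"lam must be in (0,10), got {self.lam}")
        _check(0 <= self.a <= 1, f"a must be in [0,1], got {self.a}")
        _check(0 <= self.c <= 5, f"c must be in [0,5], got {self.c}")
        _check(self.rule in ("delta", "decay"), f"rule must be delta|decay, got {self.rule}")

    @property
    def theta(self) -> float:
        return consistency_to_sensitivity(self.c)


@dataclass(frozen=True)
class VPPParams:
    """Values-Plus-Perseverance parameters (PVL-Delta plus perseverance trace).

    k: perseverance decay in [0,1]; ep_p / ep_n: gain / loss impacts
    (unbounded); w: expectancy weight in [0,1].
    """

    alpha: float
    lam: float
    a: float
    c: float
    k: float
    ep_p: float
    ep_n: float
    w: float

    def __post_init__(self):
        _check(0 < self.alpha < 1, f"alpha must be in (0,1), got {self.alpha}")
        _check(0 < self.lam < 10, f"lam must be in (0,10), got {self.lam}")
        _check(0 <= self.a <= 1, f"a must be in [0,1], got {self.a}")
        _check(0 <= self.c <= 5, f"c must be in [0,5], got {self.c}")
        _check(0 <= self.k <= 1, f"k must be in [0,1], got {self.k}")
        _check(0 <= self.w <= 1, f"w must be in [0,1], got {self.w}")
        _check(np.isfinite(self.ep_p) and np.isfinite(self.ep_n), "ep_p/ep_n must be finite")

    @property
    def theta(self) -> float:
        return consistency_to_sensitivity(self.c)


@dataclass(frozen=True)
class ORLParams:
    """Outcome-Representation Learning parameters.

    a_rew / a_pun: reward / punishment learning rates, (0,1);
    k_prime: decay in [0,5], giving K = 3^k_prime - 1 in [0,242];
    beta_f: outcome-frequency weight; beta_p: perseverance weight (unbounded).
    same_rate_fictive switches the fictive frequency update for unchosen
    decks from the opposite-valence rate (default) to the same-valence rate.
    """

    a_rew: float
    a_pun: float
    k_prime: float
    beta_f: float
    beta_p: float
    same_rate_fictive: bool = field(default=False, compare=False)

    def __post_init__(self):
        _check(0 < self.a_rew < 1, f"a_rew must be in (0,1), got {self.a_rew}")
        _check(0 < self.a_pun < 1, f"a_pun must be in (0,1), got {self.a_pun}")
        _check(0 <= self.k_prime <= 5, f"k_prime must be in [0,5], got {self.k_prime}")
        _check(np.isfinite(self.beta_f) and np.isfinite(self.beta_p), "betas must be finite")

    @property
    def k(self) -> float:
        return consistency_to_sensitivity(self.k_prime)


ModelParams = PVLParams | VPPParams | ORLParams


def consistency_to_sensitivity(c: float) -> float:
    """3^c - 1: maps consistency in [0,5] to softmax sensitivity in [0,242]."""
    return 3.0**c - 1.0


# ---------------------------------------------------------------------------
# Elementary update rules (scalar/vector building blocks)


def prospect_utility(x: float, alpha: float, lam: float) -> float:
    """Prospect-theory utility of a scaled net outcome."""
    if x >= 0:
        return x**alpha
    return -lam * (-x) ** alpha


def delta_update(E: np.ndarray, chosen: int, u: float, a: float) -> np.ndarray:
    """Rescorla-Wagner update: only the chosen deck moves toward u."""
    E = E.copy()
    E[chosen] += a * (u - E[chosen])
    return E


def decay_update(E: np.ndarray, chosen: int, u: float, a: float) -> np.ndarray:
    """All expectancies decay by a; the chosen deck additionally gains u."""
    E = a * E
    E[chosen] += u
    return E


def softmax_probs(V: np.ndarray, sensitivity: float) -> np.ndarray:
    """Stable softmax over deck values; sensitivity 0 gives the uniform choice."""
    if not np.all(np.isfinite(V)):
        raise FloatingPointError("non-finite deck values in softmax")
    z = sensitivity * np.asarray(V, dtype=float)
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def vpp_perseverance_update(
    P: np.ndarray, chosen: int, net: float, k: float, ep_p: float, ep_n: float
) -> np.ndarray:
    """Decay the perseverance trace; bump the chosen deck by gain or loss impact."""
    P = k * P
    P[chosen] += ep_p if net >= 0 else ep_n
    return P


def vpp_value(E: np.ndarray, P: np.ndarray, w: float) -> np.ndarray:
    return w * E + (1.0 - w) * P


@dataclass
class LatentState:
    """Per-deck latent vectors; all-zero before the first trial."""

    E: np.ndarray = field(default_factory=lambda: np.zeros(N_DECKS))
    P: np.ndarray = field(default_factory=lambda: np.zeros(N_DECKS))
    EV: np.ndarray = field(default_factory=lambda: np.zeros(N_DECKS))
    EF: np.ndarray = field(default_factory=lambda: np.zeros(N_DECKS))
    PS: np.ndarray = field(default_factory=lambda: np.zeros(N_DECKS))


def orl_update(state: LatentState, chosen: int, x: float, params: ORLParams) -> LatentState:
    """One ORL trial update of (EV, EF, PS) given scaled net outcome x."""
    a_chosen = params.a_rew if x >= 0 else params.a_pun
    if params.same_rate_fictive:
        a_fictive = a_chosen
    else:
        a_fictive = params.a_pun if x >= 0 else params.a_rew
    sgn = float(np.sign(x))

    EV = state.EV.copy()
    EV[chosen] += a_chosen * (x - EV[chosen])

    EF = state.EF + a_fictive * (-sgn / (N_DECKS - 1) - state.EF)
    EF[chosen] = state.EF[chosen] + a_chosen * (sgn - state.EF[chosen])

    decay = 1.0 + params.k
    PS = state.PS / decay
    PS[chosen] = 1.0 / decay
    return LatentState(E=state.E, P=state.P, EV=EV, EF=EF, PS=PS)


def orl_value(
    EV: np.ndarray, EF: np.ndarray, PS: np.ndarray, beta_f: float, beta_p: float
) -> np.ndarray:
    return EV + beta_f * EF + beta_p * PS


# ---------------------------------------------------------------------------
# Sequential likelihood and generative agent

def _trial_values(model: str, params: ModelParams, state: LatentState) -> tuple[np.ndarray, float]:
    """Deck values and softmax sensitivity for the next choice."""
    if model in ("pvl_delta", "pvl_decay"):
        return state.E, params.theta
    if model == "vpp":
        return vpp_value(state.E, state.P, params.w), params.theta
    if model == "orl":
        return orl_value(state.EV, state.EF, state.PS, params.beta_f, params.beta_p), 1.0
    raise ValueError(f"unknown model id {model!r}; expected one of {MODEL_IDS}")


def _trial_probs(model: str, params: ModelParams, state: LatentState) -> np.ndarray:
    V, sens = _trial_values(model, params, state)
    return softmax_probs(V, sens)


def _advance(model: str, params: ModelParams, state: LatentState, chosen: int, x: float) -> LatentState:
    if model == "orl":
        return orl_update(state, chosen, x, params)
    u = prospect_utility(x, params.alpha, params.lam)
    rule = "decay" if model == "pvl_decay" else "delta"
    E = decay_update(state.E, chosen, u, params.a) if rule == "decay" else delta_update(
        state.E, chosen, u, params.a
    )
    P = state.P
    if model == "vpp":
        P = vpp_perseverance_update(state.P, chosen, x, params.k, params.ep_p, params.ep_n)
    return LatentState(E=E, P=P, EV=state.EV, EF=state.EF, PS=state.PS)


def session_loglik(
    model: str,
    params: ModelParams,
    session: SessionRecord,
    scale: float | None = None,
) -> np.ndarray:
    """Per-trial log-probability of the observed choices under the model.

    Entry t is log Pr(choice_t | history 1..t-1) from the all-zero initial
    state; the first entry is log(1/4). Outcomes are divided by ``scale``
    (default 100) before utilities and learning.
    """
    if len(session) == 0:
        raise ValueError("session has no trials")
    scale = 100.0 if scale is None else scale
    choices = session.choices
    xs = session.nets / scale
    state = LatentState()
    out = np.empty(len(choices))
    for t, (ch, x) in enumerate(zip(choices, xs)):
        V, sens = _trial_values(model, params, state)
        z = sens * V
        z = z - z.max()
        out[t] = z[ch] - np.log(np.exp(z).sum())
        state = _advance(model, params, state, int(ch), float(x))
    return out


def simulate_agent(
    model: str,
    params: ModelParams,
    scheme: PayoffScheme,
    n_trials: int = 100,
    seed: int = 0,
    subject_id: str = "agent",
    group: str = "healthy",
    endowment: float = 2000,
) -> SessionRecord:
    """Generative counterpart of session_loglik: sample choices trial by trial."""
    rng = np.random.default_rng(seed)
    cycle_state = new_cycle_state(scheme)
    session = SessionRecord(subject_id=subject_id, group=group, endowment=endowment, rng_seed=seed)
    state = LatentState()
    for t in range(1, n_trials + 1):
        probs = _trial_probs(model, params, state)
        ch = int(rng.choice(N_DECKS, p=probs))
        reward, loss, net = draw_outcome(scheme, DECKS[ch], cycle_state, rng)
        session.trials.append(Trial(t=t, deck=DECKS[ch], reward=reward, loss=loss))
        state = _advance(model, params, state, ch, net / scheme.outcome_scale)
    return session


def params_from_file(model: str, path) -> ModelParams:
    """Load parameters from a flat YAML/JSON mapping keyed by field name."""
    import json
    from pathlib import Path

    import yaml

    text = Path(path).read_text()
    values = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return params_from_dict(model, values)


def params_from_dict(model: str, values: dict) -> ModelParams:
    """Build a parameter object from a flat mapping keyed by field name."""
    cls = {"pvl_delta": PVLParams, "pvl_decay": PVLParams, "vpp": VPPParams, "orl": ORLParams}[
        model
    ]
    if cls is PVLParams:
        values = {**values, "rule": "decay" if model == "pvl_decay" else "delta"}
    return cls(**values)
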