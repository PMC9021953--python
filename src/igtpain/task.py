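"""Iowa Gambling Task environment: payoff structure, session execution, behavioral summaries.

The task presents four decks (A-D). Every draw from a deck pays a constant
reward; within each 10-draw cycle from a deck, a fixed number of draws also
carry a loss, so that the net outcome per complete cycle is constant
(A, B: -250; C, D: +250 in euros). Decks A and B are disadvantageous
("bad"), C and D advantageous ("good"); A and C lose frequently (5/10),
B and D rarely (1/10). Where the losses fall inside a cycle is unpublished,
so each cycle's loss positions are a seeded uniform random permutation,
with the cycle's total loss split equally across loss trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

DECKS = ("A", "B", "C", "D")
GOOD_DECKS = frozenset({"C", "D"})
BAD_DECKS = frozenset({"A", "B"})

DEFAULT_ENDOWMENT = 2000
DEFAULT_N_TRIALS = 100


class ConfigurationError(ValueError):
    """Invalid payoff-scheme configuration."""


class ProtocolError(RuntimeError):
    """A policy or session violated the task protocol."""


@dataclass(frozen=True)
class DeckSpec:
    """Payoff parameters of one deck.

    reward_per_trial: constant reward (EUR) paid on every draw.
    total_loss_per_cycle: summed loss (EUR, <= 0) over one complete cycle.
    n_loss_trials_per_cycle: number of draws per cycle that carry a loss.
    cycle_length: draws per cycle (default 10).
    """

    name: str
    reward_per_trial: int
    total_loss_per_cycle: int
    n_loss_trials_per_cycle: int
    cycle_length: int = 10

    def __post_init__(self) -> None:
        if self.cycle_length < 1:
            raise ConfigurationError(f"deck {self.name}: cycle_length must be >= 1")
        if not 0 <= self.n_loss_trials_per_cycle <= self.cycle_length:
            raise ConfigurationError(
                f"deck {self.name}: n_loss_trials_per_cycle "
                f"({self.n_loss_trials_per_cycle}) exceeds cycle_length ({self.cycle_length})"
            )
        if self.total_loss_per_cycle > 0:
            raise ConfigurationError(f"deck {self.name}: total_loss_per_cycle must be <= 0")
        if self.n_loss_trials_per_cycle == 0 and self.total_loss_per_cycle != 0:
            raise ConfigurationError(
                f"deck {self.name}: nonzero loss with zero loss trials"
            )

    @property
    def loss_per_loss_trial(self) -> float:
        if self.n_loss_trials_per_cycle == 0:
            return 0.0
        return self.total_loss_per_cycle / self.n_loss_trials_per_cycle

    @property
    def net_per_cycle(self) -> float:
        return self.cycle_length * self.reward_per_trial + self.total_loss_per_cycle


@dataclass(frozen=True)
class PayoffScheme:
    """Four-deck payoff schedule.

    outcome_scale divides euro amounts before they enter cognitive models
    (stored trial records stay in unscaled euros).
    """

    decks: tuple[DeckSpec, ...]
    outcome_scale: float = 100.0

    def __post_init__(self) -> None:
        if len(self.decks) != 4:
            raise ConfigurationError("a payoff scheme needs exactly 4 decks")
        if self.outcome_scale <= 0:
            raise ConfigurationError("outcome_scale must be positive")

    @property
    def n_alternatives(self) -> int:
        return len(self.decks) - 1

    def deck(self, name: str) -> DeckSpec:
        for d in self.decks:
            if d.name == name:
                return d
        raise KeyError(f"unknown deck id {name!r}; expected one of {DECKS}")


#: Published payoff table: (reward/trial, loss/10 trials, n loss trials/10).
_DEFAULT_DECKS = {
    "A": (100, -1250, 5),
    "B": (100, -1250, 1),
    "C": (50, -250, 5),
    "D": (50, -250, 1),
}


def build_payoff_scheme(overrides: dict | None = None) -> PayoffScheme:
    """Build the payoff scheme; with no overrides, the standard IGT schedule.

    ``overrides`` may contain ``outcome_scale``, ``cycle_length``, and per-deck
    dicts keyed by deck name with any of ``reward_per_trial``,
    ``total_loss_per_cycle``, ``n_loss_trials_per_cycle``, ``cycle_length``.
    """
    overrides = dict(overrides or {})
    outcome_scale = overrides.pop("outcome_scale", 100.0)
    global_cycle = overrides.pop("cycle_length", 10)
    decks = []
    for name in DECKS:
        reward, loss, n_loss = _DEFAULT_DECKS[name]
        spec_kw = {
            "reward_per_trial": reward,
            "total_loss_per_cycle": loss,
            "n_loss_trials_per_cycle": n_loss,
            "cycle_length": global_cycle,
        }
        deck_over = overrides.pop(name, None)
        if deck_over:
            unknown = set(deck_over) - set(spec_kw)
            if unknown:
                raise ConfigurationError(f"unknown deck override keys {sorted(unknown)}")
            spec_kw.update(deck_over)
        decks.append(DeckSpec(name=name, **spec_kw))
    if overrides:
        raise ConfigurationError(f"unknown scheme override keys {sorted(overrides)}")
    return PayoffScheme(decks=tuple(decks), outcome_scale=outcome_scale)


@dataclass(frozen=True)
class Trial:
    """One card draw: 1-based index, deck id, reward (>=0), loss (<=0), net."""

    t: int
    deck: str
    reward: float
    loss: float

    @property
    def net(self) -> float:
        return self.reward + self.loss


@dataclass
class SessionRecord:
    """One subject's ordered IGT trials."""

    subject_id: str
    group: str
    trials: list[Trial] = field(default_factory=list)
    endowment: float = DEFAULT_ENDOWMENT
    rng_seed: int | None = None

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def choices(self) -> np.ndarray:
        """Deck indices 0..3 per trial."""
        return np.array([DECKS.index(tr.deck) for tr in self.trials], dtype=np.int64)

    @property
    def nets(self) -> np.ndarray:
        return np.array([tr.net for tr in self.trials], dtype=float)

    def validate(self) -> None:
        for k, tr in enumerate(self.trials, start=1):
            if tr.t != k:
                raise ProtocolError(f"trial indices must be 1..n without gaps (got {tr.t} at {k})")
            if tr.deck not in DECKS:
                raise ProtocolError(f"trial {k}: unknown deck {tr.deck!r}")


class DeckState:
    """Per-deck draw counter plus the shuffled loss positions of the current cycle."""

    def __init__(self, spec: DeckSpec):
        self.spec = spec
        self.draws_in_cycle = 0
        self.loss_positions: set[int] = set()

    def _new_cycle(self, rng: np.random.Generator) -> None:
        self.draws_in_cycle = 0
        positions = rng.permutation(self.spec.cycle_length)[: self.spec.n_loss_trials_per_cycle]
        self.loss_positions = set(int(p) for p in positions)

    def draw(self, rng: np.random.Generator) -> tuple[float, float]:
        """Advance the deck one draw; return (reward, loss)."""
        if self.draws_in_cycle == 0:
            self._new_cycle(rng)
        loss = self.spec.loss_per_loss_trial if self.draws_in_cycle in self.loss_positions else 0.0
        self.draws_in_cycle += 1
        if self.draws_in_cycle == self.spec.cycle_length:
            self.draws_in_cycle = 0
        return float(self.spec.reward_per_trial), float(loss)


def draw_outcome(
    scheme: PayoffScheme,
    deck: str,
    cycle_state: dict[str, DeckState],
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """Draw one card from ``deck``; returns (reward, loss, net).

    ``cycle_state`` maps deck id -> DeckState and is mutated in place.
    """
    if deck not in cycle_state:
        spec = scheme.deck(deck)  # raises KeyError for unknown ids
        cycle_state[deck] = DeckState(spec)
    reward, loss = cycle_state[deck].draw(rng)
    return reward, loss, reward + loss


def new_cycle_state(scheme: PayoffScheme) -> dict[str, DeckState]:
    return {d.name: DeckState(d) for d in scheme.decks}


def run_session(
    policy: Callable[[SessionRecord], str],
    scheme: PayoffScheme,
    n_trials: int = DEFAULT_N_TRIALS,
    seed: int = 0,
    subject_id: str = "anon",
    group: str = "healthy",
    endowment: float = DEFAULT_ENDOWMENT,
) -> SessionRecord:
    """Play ``n_trials`` draws against ``policy`` (session-so-far -> deck id).

    The same (policy, scheme, seed) triple reproduces a bit-identical session.
    """
    if n_trials < 1:
        raise ProtocolError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    session = SessionRecord(subject_id=subject_id, group=group, endowment=endowment, rng_seed=seed)
    state = new_cycle_state(scheme)
    for t in range(1, n_trials + 1):
        deck = policy(session)
        if deck not in DECKS:
            raise ProtocolError(f"trial {t}: policy returned invalid deck {deck!r}")
        reward, loss, _ = draw_outcome(scheme, deck, state, rng)
        session.trials.append(Trial(t=t, deck=deck, reward=reward, loss=loss))
    return session


@dataclass(frozen=True)
class BlockSummary:
    """Good/bad-deck tallies for one block of trials."""

    block_index: int
    n_good: int
    n_bad: int

    @property
    def learning_score(self) -> int:
        return self.n_good - self.n_bad

    @property
    def prop_good(self) -> float:
        return self.n_good / (self.n_good + self.n_bad)


def block_scores(session: SessionRecord, block_size: int = 20) -> list[BlockSummary]:
    """Partition the session into consecutive blocks and tally good-deck choices."""
    n = len(session)
    if n % block_size != 0:
        raise ProtocolError(
            f"session length {n} is not divisible by block size {block_size}"
        )
    out = []
    for b in range(n // block_size):
        chunk = session.trials[b * block_size : (b + 1) * block_size]
        n_good = sum(1 for tr in chunk if tr.deck in GOOD_DECKS)
        out.append(BlockSummary(block_index=b + 1, n_good=n_good, n_bad=block_size - n_good))
    return out


def total_gain(session: SessionRecord) -> float:
    """Final running tally: endowment plus summed net outcomes."""
    return session.endowment + float(sum(tr.net for tr in session.trials))


# ---------------------------------------------------------------------------
# Trial-log CSV interface

TRIAL_LOG_COLUMNS = ["subject_id", "group", "trial", "deck", "reward", "loss", "net"]


def sessions_to_frame(sessions: Sequence[SessionRecord]) -> pd.DataFrame:
    rows = [
        (s.subject_id, s.group, tr.t, tr.deck, tr.reward, tr.loss, tr.net)
        for s in sessions
        for tr in s.trials
    ]
    return pd.DataFrame(rows, columns=TRIAL_LOG_COLUMNS)


def write_trial_log(sessions: Sequence[SessionRecord], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_trial_log(path, endowment: float = DEFAULT_ENDOWMENT) -> list[SessionRecord]:
    """Read a trial-log CSV back into SessionRecords (ordered by trial index)."""
    df = pd.read_csv(path)
    missing = set(TRIAL_LOG_COLUMNS) - {"net"} - set(df.columns)
    if missing:
        raise ProtocolError(f"trial log missing columns {sorted(missing)}")
    sessions = []
    for (sid, grp), sub in df.groupby(["subject_id", "group"], sort=False):
        sub = sub.sort_values("trial")
        trials = [
            Trial(t=int(r.trial), deck=str(r.deck), reward=float(r.reward), loss=float(r.loss))
            for r in sub.itertuples()
        ]
        rec = SessionRecord(subject_id=str(sid), group=str(grp), trials=trials, endowment=endowment)
        rec.validate()
        sessions.append(rec)
    return sessions


def load_task_config(path) -> dict:
    """Read a YAML task config: scheme overrides, n_trials, endowment, seed."""
    import yaml

    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    allowed = {"scheme", "n_trials", "endowment", "seed"}
    unknown = set(cfg) - allowed
    if unknown:
        raise ConfigurationError(f"unknown task config keys {sorted(unknown)}")
    return cfg


def replace_deck(scheme: PayoffScheme, name: str, **changes) -> PayoffScheme:
    """Return a scheme with one deck's parameters replaced (testing helper)."""
    decks = tuple(replace(d, **changes) if d.name == name else d for d in scheme.decks)
    return PayoffScheme(decks=decks, outcome_scale=scheme.outcome_scale)
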