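"""Repeated Prisoner's Dilemma game (rPDG) engine.

Two players simultaneously choose to cooperate (C) or defect (D) over many
rounds.  The partner is a pre-programmed schedule: its cooperation
probability is stable at 78% for one 60-trial session and switches between
20%, 80% and 20% in blocks of 20 trials in the other.  Every 15 rounds the
participant rates the partner's cooperativeness on a 0-9 scale.

Actions are encoded internally as ``1`` (cooperate) / ``0`` (defect) and
serialized as ``C`` / ``D`` in tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

COOPERATE = "C"
DEFECT = "D"
ACTIONS = (COOPERATE, DEFECT)

#: default token payoffs, keyed by (own action, partner action)
DEFAULT_PAYOFFS: Mapping[tuple[str, str], int] = {
    ("C", "C"): 4,
    ("D", "D"): 2,
    ("C", "D"): 0,
    ("D", "C"): 6,
}

SESSION_COLUMNS = [
    "participant_id",
    "group",
    "trial",
    "own_action",
    "partner_action",
    "own_payoff",
    "partner_payoff",
]


def encode_action(a) -> int:
    """Map an action label (or 0/1 code) to the internal 1=C / 0=D code."""
    if a in (1, COOPERATE):
        return 1
    if a in (0, DEFECT):
        return 0
    raise ValueError(f"unknown action label {a!r}; expected 'C'/'D' or 1/0")


def decode_action(code: int) -> str:
    return COOPERATE if code == 1 else DEFECT


@dataclass(frozen=True)
class PayoffMatrix:
    """Symmetric 2x2 token payoffs; partner payoff = entry with roles swapped."""

    entries: Mapping[tuple[str, str], int] = field(
        default_factory=lambda: dict(DEFAULT_PAYOFFS)
    )

    def __post_init__(self):
        for own in ACTIONS:
            for partner in ACTIONS:
                if (own, partner) not in self.entries:
                    raise ValueError(f"payoff matrix missing entry {(own, partner)}")
                v = self.entries[(own, partner)]
                if v < 0 or int(v) != v:
                    raise ValueError("payoffs must be non-negative integers")

    def payoff(self, own, partner) -> tuple[int, int]:
        """Return (own tokens, partner tokens) for one round of play."""
        o, p = decode_action(encode_action(own)), decode_action(encode_action(partner))
        return self.entries[(o, p)], self.entries[(p, o)]

    def payoff_codes(self, own: int, partner: int) -> tuple[int, int]:
        """Fast path for the internal 1/0 encoding (no label validation)."""
        o, p = decode_action(own), decode_action(partner)
        return self.entries[(o, p)], self.entries[(p, o)]


def payoff(own, partner, matrix: PayoffMatrix | None = None) -> tuple[int, int]:
    """Token payoffs of one round: (C,C)->(4,4), (D,D)->(2,2), (C,D)->(0,6)."""
    return (matrix or PayoffMatrix()).payoff(own, partner)


@dataclass(frozen=True)
class ScheduleConfig:
    """Partner schedule layout.

    The game has one stable session (i.i.d. Bernoulli(``stable_prob``)) and
    one volatile session of equal length made of ``volatile_block_len``-trial
    blocks with cooperation probabilities ``volatile_probs``; ``order``
    selects which session comes first.
    """

    n_trials: int = 120
    stable_prob: float = 0.78
    volatile_probs: tuple[float, ...] = (0.20, 0.80, 0.20)
    volatile_block_len: int = 20
    order: str = "stable_first"
    probe_interval: int = 15
    seed: int | None = None

    def __post_init__(self):
        if self.order not in ("stable_first", "volatile_first"):
            raise ValueError(f"unknown session order {self.order!r}")
        probs = (self.stable_prob, *self.volatile_probs)
        if any(not 0.0 <= q <= 1.0 for q in probs):
            raise ValueError("cooperation probabilities must lie in [0, 1]")
        volatile_len = self.volatile_block_len * len(self.volatile_probs)
        if self.n_trials != 2 * volatile_len:
            raise ValueError(
                f"n_trials={self.n_trials} does not split into a stable session "
                f"plus {len(self.volatile_probs)} volatile blocks of "
                f"{self.volatile_block_len} trials"
            )
        if self.n_trials % self.probe_interval != 0:
            raise ValueError("probe_interval must divide n_trials")

    @property
    def session_len(self) -> int:
        return self.n_trials // 2

    def trial_coop_probs(self) -> np.ndarray:
        """Per-trial partner cooperation probability, length ``n_trials``."""
        stable = np.full(self.session_len, self.stable_prob)
        volatile = np.repeat(self.volatile_probs, self.volatile_block_len)
        if self.order == "stable_first":
            return np.concatenate([stable, volatile])
        return np.concatenate([volatile, stable])

    def with_seed(self, seed: int | None) -> "ScheduleConfig":
        return replace(self, seed=seed)


def generate_partner_schedule(
    cfg: ScheduleConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Draw the partner's pre-determined action sequence (int8, 1=C / 0=D).

    Each trial is an independent Bernoulli draw with its block's cooperation
    probability; identical (cfg, seed) gives a bit-identical sequence.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    probs = cfg.trial_coop_probs()
    return (rng.random(cfg.n_trials) < probs).astype(np.int8)


def probe_trials(cfg: ScheduleConfig) -> np.ndarray:
    """1-based trial indices of the cooperativeness probes (every 15 rounds)."""
    return np.arange(cfg.probe_interval, cfg.n_trials + 1, cfg.probe_interval)


@dataclass
class Session:
    """One participant's full game: aligned per-trial arrays (1-based trials)."""

    own: np.ndarray  # int8, 1=C / 0=D  (Q_t)
    partner: np.ndarray  # int8, 1=C / 0=D  (P_t)
    own_payoff: np.ndarray  # tokens R_t
    partner_payoff: np.ndarray
    participant_id: str = "p0"
    group: str = ""

    def __post_init__(self):
        n = len(self.own)
        if not (len(self.partner) == len(self.own_payoff) == len(self.partner_payoff) == n):
            raise ValueError("session arrays must have equal length")
        self.own = np.asarray(self.own, dtype=np.int8)
        self.partner = np.asarray(self.partner, dtype=np.int8)
        self.own_payoff = np.asarray(self.own_payoff, dtype=np.int64)
        self.partner_payoff = np.asarray(self.partner_payoff, dtype=np.int64)

    @property
    def n_trials(self) -> int:
        return len(self.own)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "participant_id": self.participant_id,
                "group": self.group,
                "trial": np.arange(1, self.n_trials + 1),
                "own_action": [decode_action(a) for a in self.own],
                "partner_action": [decode_action(a) for a in self.partner],
                "own_payoff": self.own_payoff,
                "partner_payoff": self.partner_payoff,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Session":
        df = df.sort_values("trial")
        return cls(
            own=np.array([encode_action(a) for a in df["own_action"]], dtype=np.int8),
            partner=np.array(
                [encode_action(a) for a in df["partner_action"]], dtype=np.int8
            ),
            own_payoff=df["own_payoff"].to_numpy(),
            partner_payoff=df["partner_payoff"].to_numpy(),
            participant_id=str(df["participant_id"].iloc[0]),
            group=str(df["group"].iloc[0]) if "group" in df else "",
        )


def sessions_from_frame(df: pd.DataFrame) -> list[Session]:
    """Split a long-format session table into per-participant Sessions."""
    return [
        Session.from_frame(g) for _, g in df.groupby("participant_id", sort=True)
    ]


def sessions_to_frame(sessions: Sequence[Session]) -> pd.DataFrame:
    return pd.concat([s.to_frame() for s in sessions], ignore_index=True)


def run_session(
    agent_policy,
    schedule: np.ndarray,
    rng: np.random.Generator | int | None = None,
    matrix: PayoffMatrix | None = None,
    participant_id: str = "p0",
    group: str = "",
) -> Session:
    """Play an agent against a scheduled partner, trial by trial.

    ``agent_policy`` must expose ``coop_prob() -> float`` (probability of
    cooperating on the upcoming trial) and
    ``update(own, partner, own_payoff)`` called after each round.  The agent
    samples its action from ``coop_prob``; both actions and payoffs are
    recorded.
    """
    schedule = np.asarray(schedule, dtype=np.int8)
    if schedule.size == 0:
        raise ValueError("partner schedule is empty")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    matrix = matrix or PayoffMatrix()

    n = schedule.size
    own = np.empty(n, dtype=np.int8)
    own_pay = np.empty(n, dtype=np.int64)
    partner_pay = np.empty(n, dtype=np.int64)
    for t in range(n):
        q = agent_policy.coop_prob()
        own[t] = 1 if rng.random() < q else 0
        own_pay[t], partner_pay[t] = matrix.payoff_codes(int(own[t]), int(schedule[t]))
        agent_policy.update(int(own[t]), int(schedule[t]), int(own_pay[t]))
    return Session(
        own=own,
        partner=schedule,
        own_payoff=own_pay,
        partner_payoff=partner_pay,
        participant_id=participant_id,
        group=group,
    )
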