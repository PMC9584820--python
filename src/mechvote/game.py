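"""Deterministic engine for the repeated public-goods investment game.

Four players repeatedly split an integer endowment between a private account
and a public fund.  The fund is multiplied by a growth factor r = 1.6
(equivalently a marginal per capita return of r/k = 0.4 for k = 4) and paid
back according to a redistribution mechanism.  A full experimental session
is three 10-round blocks (no-referee tutorial, mechanism A, mechanism B), a
group vote, and a 4-round bonus block under the elected mechanism.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import voting
from ._rng import as_generator
from .mechanisms import Mechanism, equal_split

__all__ = [
    "GameConfig",
    "RoundRecord",
    "GameTrace",
    "SessionRecord",
    "MetricsSummary",
    "play_round",
    "play_block",
    "run_session",
    "gini",
    "surplus",
    "trace_to_dataframe",
    "session_to_dataframe",
    "trace_to_jsonl",
    "trace_from_jsonl",
]

SCHEMA_VERSION = 1
_CONSERVATION_TOL = 1e-9


@dataclass(frozen=True)
class GameConfig:
    """Parameters of one game: player count, growth factor, endowments.

    Endowments are listed head player first and stay constant across every
    round of a session.
    """

    k: int = 4
    r: float = 1.6
    n_rounds: int = 10
    endowments: tuple[int, ...] = (10, 2, 2, 2)
    bonus_rounds: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.r <= 0:
            raise ValueError("r must be positive")
        if len(self.endowments) != self.k:
            raise ValueError("endowments must have length k")
        for e in self.endowments:
            if int(e) != e or e < 1:
                raise ValueError("endowments must be integers >= 1")

    @property
    def mpcr(self) -> float:
        """Marginal per capita return r/k of a contributed coin under equal split."""
        return self.r / self.k

    @property
    def endowment_array(self) -> np.ndarray:
        return np.asarray(self.endowments, dtype=float)


@dataclass(frozen=True)
class RoundRecord:
    """One round's endowments, integer contributions, payouts and returns."""

    endowments: np.ndarray
    contributions: np.ndarray
    payouts: np.ndarray

    @property
    def returns(self) -> np.ndarray:
        """Per-player round return: payout plus endowment minus contribution."""
        return self.payouts + self.endowments - self.contributions

    @property
    def relative_contributions(self) -> np.ndarray:
        return self.contributions / self.endowments


@dataclass
class GameTrace:
    """An ordered block of rounds played under one mechanism."""

    config: GameConfig
    mechanism_id: str
    rounds: list[RoundRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rounds)

    @property
    def cumulative_returns(self) -> np.ndarray:
        total = np.zeros(self.config.k)
        for rec in self.rounds:
            total += rec.returns
        return total


@dataclass
class SessionRecord:
    """A full session: tutorial block, two mechanism blocks, vote, bonus block."""

    config: GameConfig
    block1: GameTrace
    block2: GameTrace
    block3: GameTrace
    vote: "voting.VoteRecord"
    block4: GameTrace
    order: str  # "AB" or "BA": which mechanism was experienced in block 2

    @property
    def elected_mechanism_id(self) -> str:
        return self.block4.mechanism_id


@dataclass(frozen=True)
class MetricsSummary:
    """Group welfare metrics: inequality (Gini) and productivity (surplus)."""

    gini: float
    surplus: float


def gini(values) -> float:
    """Gini coefficient: mean absolute pairwise difference over 2*n^2*mean.

    Zero for any constant positive vector; requires at least one positive
    entry (an all-zero vector has undefined inequality).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValueError("gini expects a nonempty 1-D vector")
    if np.any(x < 0):
        raise ValueError("gini expects nonnegative values")
    total = x.sum()
    if total == 0:
        raise ValueError("gini is undefined for an all-zero vector")
    n = x.size
    diff_sum = np.abs(x[:, None] - x[None, :]).sum()
    return float(diff_sum / (2.0 * n * total))


def surplus(trace: GameTrace) -> float:
    """Sum of returns over sum of initial endowments, across players and rounds.

    Equals 1 when nobody ever contributes and r when everyone always
    contributes fully under any conserving mechanism.
    """
    if len(trace.rounds) == 0:
        raise ValueError("surplus of an empty trace is undefined")
    total_returns = sum(float(rec.returns.sum()) for rec in trace.rounds)
    total_endow = sum(float(rec.endowments.sum()) for rec in trace.rounds)
    return total_returns / total_endow


def metrics(trace: GameTrace) -> MetricsSummary:
    return MetricsSummary(gini=gini(trace.cumulative_returns), surplus=surplus(trace))


def play_round(contributions, config: GameConfig, mechanism: Mechanism) -> RoundRecord:
    """Resolve one round: validate contributions, apply the mechanism.

    Payouts are ``weights * r * C``; the engine asserts fund conservation to
    1e-9 for every mechanism it is handed.
    """
    c = np.asarray(contributions)
    if c.shape != (config.k,):
        raise ValueError(f"expected {config.k} contributions, got shape {c.shape}")
    e = config.endowment_array
    for i, (ci, ei) in enumerate(zip(c, e)):
        if float(ci) != int(ci):
            raise ValueError(f"player {i}: contribution {ci} is not an integer")
        if not (0 <= ci <= ei):
            raise ValueError(
                f"player {i}: contribution {ci} outside [0, {int(ei)}]")
    c = c.astype(float)
    total = float(c.sum())
    payouts = mechanism.weights(e, c).payouts(config.r, total)
    if abs(payouts.sum() - config.r * total) > _CONSERVATION_TOL:
        raise AssertionError(
            f"mechanism {mechanism.id!r} violates conservation: "
            f"sum(y)={payouts.sum()} != r*C={config.r * total}")
    return RoundRecord(endowments=e, contributions=c, payouts=payouts)


def play_block(config: GameConfig, mechanism: Mechanism, agents,
               rng, n_rounds: int | None = None) -> GameTrace:
    """Play one block of rounds with the given agents.

    Each agent implements ``reset(endowments, focal)`` and
    ``act(prev_round, rng) -> int``; on round 1 it observes ``None``
    (zeroed history).
    """
    rng = as_generator(rng)
    if len(agents) != config.k:
        raise ValueError(f"need {config.k} agents, got {len(agents)}")
    n = config.n_rounds if n_rounds is None else n_rounds
    e = config.endowment_array
    for focal, agent in enumerate(agents):
        agent.reset(e, focal)
    trace = GameTrace(config=config, mechanism_id=mechanism.id)
    prev: RoundRecord | None = None
    for _ in range(n):
        c = np.array([agent.act(prev, rng) for agent in agents])
        for i, (ci, ei) in enumerate(zip(c, e)):
            if not (0 <= ci <= ei):
                raise ValueError(
                    f"agent {i} emitted contribution {ci} > endowment {int(ei)} "
                    "(mask violation)")
        prev = play_round(c, config, mechanism)
        trace.rounds.append(prev)
    return trace


def run_session(config: GameConfig, mechanism_a: Mechanism, mechanism_b: Mechanism,
                agents, order: str, voting_params: "voting.VotingModelParams",
                rng) -> SessionRecord:
    """Run a full session: tutorial, two mechanism blocks, vote, bonus block.

    Block 1 always uses the no-referee equal-split default.  Votes are
    sampled per player from the relative-payout voting model; the block-4
    mechanism is drawn with probability equal to the vote fraction for A
    (deterministic under a unanimous vote).
    """
    if order not in ("AB", "BA"):
        raise ValueError("order must be 'AB' or 'BA'")
    rng = as_generator(rng)
    block1 = play_block(config, equal_split(config.k, config.r), agents, rng)
    first, second = ((mechanism_a, mechanism_b) if order == "AB"
                     else (mechanism_b, mechanism_a))
    block_first = play_block(config, first, agents, rng)
    block_second = play_block(config, second, agents, rng)
    trace_a, trace_b = ((block_first, block_second) if order == "AB"
                        else (block_second, block_first))
    vote = voting.sample_group_votes(trace_a, trace_b, voting_params, rng)
    p_a = vote.votes.mean()
    elected = mechanism_a if rng.random() < p_a or p_a == 1.0 else mechanism_b
    block4 = play_block(config, elected, agents, rng, n_rounds=config.bonus_rounds)
    return SessionRecord(config=config, block1=block1,
                         block2=block_first, block3=block_second,
                         vote=vote, block4=block4, order=order)


# -- serialization ------------------------------------------------------------


def trace_to_dataframe(trace: GameTrace, session: int = 0, block: int = 1) -> pd.DataFrame:
    """Flatten a trace to one row per player-round."""
    rows = []
    for t, rec in enumerate(trace.rounds, start=1):
        for i in range(trace.config.k):
            rows.append({
                "session": session,
                "block": block,
                "round": t,
                "player": i,
                "endowment": rec.endowments[i],
                "contribution": rec.contributions[i],
                "payout": rec.payouts[i],
                "return": rec.returns[i],
                "mechanism": trace.mechanism_id,
            })
    return pd.DataFrame(rows)


def session_to_dataframe(record: SessionRecord, session: int = 0) -> pd.DataFrame:
    frames = [
        trace_to_dataframe(record.block1, session, block=1),
        trace_to_dataframe(record.block2, session, block=2),
        trace_to_dataframe(record.block3, session, block=3),
        trace_to_dataframe(record.block4, session, block=4),
    ]
    df = pd.concat(frames, ignore_index=True)
    df["order"] = record.order
    return df


def trace_to_jsonl(trace: GameTrace, path) -> None:
    """Write a trace as JSON lines: a header line then one line per round."""
    with open(path, "w") as fh:
        header = {
            "schema_version": SCHEMA_VERSION,
            "mechanism": trace.mechanism_id,
            "k": trace.config.k,
            "r": trace.config.r,
            "endowments": [int(e) for e in trace.config.endowments],
        }
        fh.write(json.dumps(header) + "\n")
        for t, rec in enumerate(trace.rounds, start=1):
            fh.write(json.dumps({
                "round": t,
                "contributions": rec.contributions.tolist(),
                "payouts": rec.payouts.tolist(),
            }) + "\n")


def trace_from_jsonl(path) -> GameTrace:
    with open(path) as fh:
        header = json.loads(fh.readline())
        if header.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported schema version {header.get('schema_version')}")
        config = GameConfig(k=header["k"], r=header["r"],
                            endowments=tuple(header["endowments"]))
        trace = GameTrace(config=config, mechanism_id=header["mechanism"])
        e = config.endowment_array
        for line in fh:
            rec = json.loads(line)
            trace.rounds.append(RoundRecord(
                endowments=e,
                contributions=np.asarray(rec["contributions"], dtype=float),
                payouts=np.asarray(rec["payouts"], dtype=float)))
    return trace
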