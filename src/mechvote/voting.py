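"""The relative-payout logistic voting model.

After experiencing two mechanisms for a block each, every player votes for
the one they prefer.  A player's vote is modelled on the sum of relative
payouts rpay^M = sum_t y_i^t / e_i obtained under each mechanism: the
probability of voting for A is a logistic function of rpay^A - rpay^B with
slope s (default 1.4).  Votes are sampled independently across the k players
given the traces; correlation between group members enters only through
their shared experience of the mechanisms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from ._rng import as_generator

if TYPE_CHECKING:  # pragma: no cover
    from .game import GameTrace

__all__ = [
    "VotingModelParams",
    "VoteRecord",
    "relative_payout_sum",
    "vote_probability",
    "sample_group_votes",
]


@dataclass(frozen=True)
class VotingModelParams:
    """Logistic slope s > 0 of the vote-probability curve."""

    s: float = 1.4

    def __post_init__(self):
        if self.s <= 0:
            raise ValueError("slope s must be positive")


@dataclass(frozen=True)
class VoteRecord:
    """One group election: binary votes for A and the rpay sums behind them."""

    votes: np.ndarray        # 1 = vote for mechanism A, 0 = for B
    rpay_a: np.ndarray
    rpay_b: np.ndarray
    mechanism_a: str = "A"
    mechanism_b: str = "B"
    group: int = 0

    @property
    def votes_for_a(self) -> int:
        return int(self.votes.sum())


def relative_payout_sum(trace: "GameTrace", player: int) -> float:
    """Sum over the block's rounds of the player's payout over endowment."""
    total = 0.0
    for rec in trace.rounds:
        e = rec.endowments[player]
        if e <= 0:
            raise ValueError("relative payout undefined for zero endowment")
        total += rec.payouts[player] / e
    return float(total)


def vote_probability(rpay_a, rpay_b, params: VotingModelParams = VotingModelParams()):
    """P(vote A) = 1 / (1 + exp(-s * (rpay_A - rpay_B))).

    Antisymmetric by construction: p(A, B) + p(B, A) = 1.
    """
    diff = np.asarray(rpay_a, dtype=float) - np.asarray(rpay_b, dtype=float)
    if not np.all(np.isfinite(diff)):
        raise ValueError("rpay values must be finite")
    p = 1.0 / (1.0 + np.exp(-params.s * diff))
    return float(p) if p.ndim == 0 else p


def sample_group_votes(trace_a: "GameTrace", trace_b: "GameTrace",
                       params: VotingModelParams, rng, group: int = 0) -> VoteRecord:
    """Sample one independent binary vote per player from the voting model."""
    rng = as_generator(rng)
    k = trace_a.config.k
    if len(trace_a.rounds) == 0 or len(trace_b.rounds) == 0:
        raise ValueError("both block traces must be complete")
    rpay_a = np.array([relative_payout_sum(trace_a, i) for i in range(k)])
    rpay_b = np.array([relative_payout_sum(trace_b, i) for i in range(k)])
    p = vote_probability(rpay_a, rpay_b, params)
    votes = (rng.random(k) < p).astype(int)
    return VoteRecord(votes=votes, rpay_a=rpay_a, rpay_b=rpay_b,
                      mechanism_a=trace_a.mechanism_id,
                      mechanism_b=trace_b.mechanism_id, group=group)
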