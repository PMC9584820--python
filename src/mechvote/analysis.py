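"""Statistical analyses and mechanism visual summaries.

* Beach grids: the fraction of the public fund a memoryless mechanism
  allocates to the head player as a function of the head and (common) tail
  relative contributions — the surface that makes a learned mechanism
  interpretable.
* Group-level permutation test for election outcomes: votes within a group
  are correlated through shared experience, so significance is assessed by
  jointly flipping whole groups' votes rather than individual ballots.
* Binomial standard errors for vote-share bars.
* A schema-validated loader for the deposited human dataset (never
  downloaded automatically) and vote-share summaries over it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._rng import substream
from .mechanisms import Mechanism

__all__ = [
    "BeachGrid",
    "PermutationResult",
    "beach_grid",
    "group_permutation_test",
    "binomial_se",
    "load_deposited_dataset",
    "vote_share_summary",
    "DEPOSITED_COLUMNS",
]


@dataclass
class BeachGrid:
    """Head player's fund share over a grid of relative contributions."""

    mechanism_id: str
    endowments: np.ndarray
    head_ratios: np.ndarray
    tail_ratios: np.ndarray
    head_share: np.ndarray  # [len(head_ratios), len(tail_ratios)]

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, hr in enumerate(self.head_ratios):
            for j, tr in enumerate(self.tail_ratios):
                rows.append({"head_ratio": hr, "tail_ratio": tr,
                             "head_share": self.head_share[i, j]})
        return pd.DataFrame(rows)


def beach_grid(mechanism: Mechanism, endowments, resolution: int = 21) -> BeachGrid:
    """Evaluate a memoryless mechanism on a head-vs-tail contribution grid.

    For each cell, the head player contributes ``round(ratio_h * e_head)``
    and every tail player ``round(ratio_t * e_tail)``; the cell records the
    head player's redistribution weight for that single round.  Cells with
    an empty fund take the uniform split 1/k.
    """
    if not getattr(mechanism, "memoryless", False):
        raise ValueError("beach grids require a memoryless mechanism "
                         "(history-dependent mechanisms need a rollout policy)")
    e = np.asarray(endowments, dtype=float)
    k = e.size
    ratios = np.linspace(0.0, 1.0, resolution)
    share = np.zeros((resolution, resolution))
    for i, hr in enumerate(ratios):
        for j, tr in enumerate(ratios):
            c = np.empty(k)
            c[0] = round(hr * e[0])
            c[1:] = [round(tr * ei) for ei in e[1:]]
            share[i, j] = mechanism.weights(e, c).weights[0]
    return BeachGrid(mechanism_id=mechanism.id, endowments=e,
                     head_ratios=ratios, tail_ratios=ratios, head_share=share)


@dataclass(frozen=True)
class PermutationResult:
    """Observed vote count, permutation p-value and shuffle count."""

    observed: int
    n_shuffles: int
    p_value: float
    seed: int


def group_permutation_test(votes_by_group, n_shuffles: int = 10_000,
                           seed: int = 0) -> PermutationResult:
    """One-tailed group-flip permutation test for votes for mechanism A.

    Each shuffle flips all votes of a group jointly with probability 0.5,
    preserving the within-group covariance of ballots.  The p-value is
    max(b, 1)/n_shuffles where b counts shuffled statistics at least as
    large as the observed total, so the smallest attainable p is
    1/n_shuffles.
    """
    groups = [np.asarray(g, dtype=int) for g in votes_by_group]
    if len(groups) == 0:
        raise ValueError("need at least one group of votes")
    for g in groups:
        if g.ndim != 1 or not np.all((g == 0) | (g == 1)):
            raise ValueError("votes must be binary (1 = vote for A)")
    observed = int(sum(g.sum() for g in groups))
    sums = np.array([g.sum() for g in groups])
    sizes = np.array([g.size for g in groups])
    rng = substream(seed, "permutation")
    # flipped group contributes size - sum votes for A
    flips = rng.random((n_shuffles, len(groups))) < 0.5
    stats = np.where(flips, (sizes - sums)[None, :], sums[None, :]).sum(axis=1)
    b = int((stats >= observed).sum())
    p = max(b, 1) / n_shuffles
    return PermutationResult(observed=observed, n_shuffles=n_shuffles,
                             p_value=p, seed=seed)


def binomial_se(successes: int, n: int) -> float:
    """Binomial standard error sqrt(p(1-p)/n) of an observed proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= successes <= n):
        raise ValueError("successes must be between 0 and n")
    p = successes / n
    return float(np.sqrt(p * (1.0 - p) / n))


# -- deposited human dataset ---------------------------------------------------

DEPOSITED_COLUMNS = ["session", "block", "round", "player", "endowment",
                     "contribution", "payout", "vote", "condition",
                     "mechanism_pair"]


def load_deposited_dataset(path) -> pd.DataFrame:
    """Load and validate a locally available copy of the released dataset.

    The file is never downloaded automatically.  Column names are checked
    against the expected schema and votes must be binary; offending rows are
    listed in the error.
    """
    df = pd.read_csv(path)
    missing = [c for c in DEPOSITED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"dataset at {path} is missing columns {missing}; expected schema: "
            f"{DEPOSITED_COLUMNS}")
    votes = df["vote"].dropna()
    bad = votes[~votes.isin([0, 1])]
    if len(bad):
        raise ValueError(f"non-binary votes at rows {bad.index.tolist()[:10]}")
    return df


def vote_share_summary(records: pd.DataFrame, comparison: str) -> dict:
    """Vote counts and percentage for one mechanism comparison.

    Counts one ballot per (session, player) among rows matching
    ``comparison`` in the ``mechanism_pair`` column; ``vote`` = 1 means a
    vote for the first mechanism of the pair.
    """
    subset = records[records["mechanism_pair"] == comparison]
    if len(subset) == 0:
        return {"comparison": comparison, "votes_for": 0, "total": 0,
                "percent": float("nan"), "empty": True}
    ballots = subset.groupby(["session", "player"])["vote"].first()
    votes_for = int(ballots.sum())
    total = int(ballots.size)
    return {"comparison": comparison, "votes_for": votes_for, "total": total,
            "percent": 100.0 * votes_for / total, "empty": False}
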