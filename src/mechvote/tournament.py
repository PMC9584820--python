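"""The metagame: exhaustive pairwise elections over the mechanism manifold.

Mechanisms sampled from the (v, w) manifold are pitted against one another
in head-to-head elections simulated with a fixed population of player
policies.  Cell (a, b) of the tournament matrix is the expected vote share
of mechanism a against b; the matrix defines a symmetric two-player game
whose pure-strategy symmetric Nash equilibria identify the strongest
mechanisms in the space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from .mechanisms import ManifoldParams, Mechanism
from .voting import VotingModelParams

__all__ = [
    "TournamentMatrix",
    "NashResult",
    "grid_sample_manifold",
    "pairwise_election_matrix",
    "find_symmetric_nash",
]


@dataclass
class TournamentMatrix:
    """Expected pairwise vote shares M[a, b] over a list of mechanisms."""

    mechanisms: list[str]
    matrix: np.ndarray
    n_per_cell: int
    seed: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.mechanisms,
                            columns=self.mechanisms)

    @property
    def standard_error(self) -> np.ndarray:
        """Binomial standard error of each cell estimate (k votes/session)."""
        p = self.matrix
        n_votes = 4 * self.n_per_cell
        se = np.sqrt(np.clip(p * (1 - p), 0, None) / max(n_votes, 1))
        return se


@dataclass
class NashResult:
    """Pure symmetric equilibria of the metagame, with certificates."""

    equilibria: list[int]
    best_response_values: np.ndarray  # max_j M[j, i] for each candidate i
    tolerance: float
    certificates: list[dict] = field(default_factory=list)


def grid_sample_manifold(n_v: int = 10, n_w: int = 10) -> list[ManifoldParams]:
    """Evenly spaced (v, w) grid on [0, 1]^2, corners included.

    The default 10x10 grid mirrors the manifold's ten w-bins; any grid with
    both endpoints contains the libertarian (0, 1) and liberal-egalitarian
    (1, 1) corners, and admits strict egalitarian whenever 1/k is a grid
    value of w.
    """
    if n_v < 2 or n_w < 2:
        raise ValueError("need at least a 2x2 grid")
    vs = np.linspace(0.0, 1.0, n_v)
    ws = np.linspace(0.0, 1.0, n_w)
    return [ManifoldParams(v=float(v), w=float(w)) for v in vs for w in ws]


def _election(mech_a: Mechanism, mech_b: Mechanism, make_agents, config,
              voting_params: VotingModelParams, n_sessions: int,
              rng: np.random.Generator) -> float:
    """Fraction of sampled votes for A over independent paired blocks."""
    from .game import play_block
    from .voting import sample_group_votes

    votes = 0
    total = 0
    for _ in range(n_sessions):
        agents = make_agents()
        trace_a = play_block(config, mech_a, agents, rng)
        agents = make_agents()
        trace_b = play_block(config, mech_b, agents, rng)
        record = sample_group_votes(trace_a, trace_b, voting_params, rng)
        votes += record.votes_for_a
        total += config.k
    return votes / total


def pairwise_election_matrix(mechanisms: list[Mechanism], make_agents,
                             config, n_per_cell: int, seed: int,
                             voting_params: VotingModelParams = VotingModelParams()
                             ) -> TournamentMatrix:
    """Estimate the full pairwise expected-vote-share matrix.

    ``make_agents`` is a zero-argument factory returning fresh agents for
    one block (so recurrent state never leaks between blocks).  Each
    unordered pair is simulated once and the mirror cell filled as the
    complement, making antisymmetry exact; diagonal cells are 0.5
    analytically (a mechanism against itself is a coin flip per player in
    expectation).
    """
    if len(mechanisms) < 2:
        raise ValueError("need at least 2 mechanisms")
    if n_per_cell <= 0:
        raise ValueError("n_per_cell must be positive")
    n = len(mechanisms)
    matrix = np.full((n, n), 0.5)
    rng = substream(seed, "tournament")
    for a in range(n):
        for b in range(a + 1, n):
            share = _election(mechanisms[a], mechanisms[b], make_agents,
                              config, voting_params, n_per_cell, rng)
            matrix[a, b] = share
            matrix[b, a] = 1.0 - share
    return TournamentMatrix(mechanisms=[m.id for m in mechanisms],
                            matrix=matrix, n_per_cell=n_per_cell, seed=seed)


def find_symmetric_nash(matrix, tolerance: float | None = None,
                        n_per_cell: int | None = None) -> NashResult:
    """Pure-strategy symmetric equilibria by exhaustive best-response checks.

    Strategy i is an equilibrium when no deviation j earns more than
    M[i, i] + tolerance against i.  With Monte-Carlo matrices the tolerance
    defaults to two binomial standard errors of a cell estimate; exact
    matrices use 0.
    """
    if isinstance(matrix, TournamentMatrix):
        if n_per_cell is None:
            n_per_cell = matrix.n_per_cell
        M = matrix.matrix
    else:
        M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("payoff matrix must be square")
    if tolerance is None:
        if n_per_cell:
            tolerance = 2.0 * np.sqrt(0.25 / (4 * n_per_cell))
        else:
            tolerance = 0.0
    n = M.shape[0]
    equilibria = []
    certificates = []
    best = np.zeros(n)
    for i in range(n):
        column = M[:, i]  # payoff of each deviation against incumbent i
        best[i] = column.max()
        if best[i] <= M[i, i] + tolerance:
            equilibria.append(i)
            certificates.append({
                "strategy": i,
                "incumbent_payoff": float(M[i, i]),
                "best_deviation": int(column.argmax()),
                "best_deviation_payoff": float(best[i]),
            })
    return NashResult(equilibria=equilibria, best_response_values=best,
                      tolerance=float(tolerance), certificates=certificates)
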