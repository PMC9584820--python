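"""The mechanism designer: a graph-network policy trained to win elections.

The designer is a memoryless, permutation-equivariant policy mapping one
round's observation (each player's endowment, contribution and relative
contribution — 12 scalars arranged on a fully connected directed graph with
one vertex per player) to redistribution weights via a softmax over per-
vertex outputs.  Two graph-network blocks run in sequence: the first updates
edges, vertices and a global attribute with distinct linear+tanh maps of 32
units; the second updates edges (linear 32 + tanh) and vertices (linear with
a single output).  Weight sharing across edges and vertices makes the policy
slot equivariant; the absence of recurrence makes it memoryless.

Training maximizes the expected number of votes the designed mechanism wins
in elections against a fixed opponent mechanism, using a stochastic-
computation-graph surrogate: the payout arithmetic and the voting
probabilities are differentiated exactly, while the players' discrete
contributions are handled by a score-function term over the virtual
players' log-probabilities (round-1 contributions excluded, since they
cannot depend on the mechanism).  The per-episode objective J is
mean-centred within each batch to reduce estimator variance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor, stop_grad
from ._nn import RMSProp, glorot
from ._rng import as_generator, substream
from .mechanisms import Mechanism, RedistributionWeights, mechanism_from_id
from .players import (ContributionPolicy, endowment_mask, observation_batch,
                      sample_categorical)
from .voting import VotingModelParams

__all__ = [
    "DesignerPolicy",
    "DesignerMechanism",
    "DesignerTrainConfig",
    "designer_rollout",
    "opponent_rollout",
    "surrogate_loss",
    "train_designer",
    "export_mechanism",
    "load_frozen",
    "expected_vote_share",
]

K = 4  # the policy graph is fixed at four player vertices
_N_VERTEX_FEATURES = 3
# directed edges of the fully connected graph on 4 vertices (12 edges)
_SENDERS, _RECEIVERS = map(np.array, zip(*[(s, r) for s in range(K)
                                           for r in range(K) if s != r]))
_S_HOT = np.zeros((len(_SENDERS), K))
_S_HOT[np.arange(len(_SENDERS)), _SENDERS] = 1.0
_R_HOT = np.zeros((len(_RECEIVERS), K))
_R_HOT[np.arange(len(_RECEIVERS)), _RECEIVERS] = 1.0
_ONES_E = np.ones((len(_SENDERS), 1))  # tiles the global attribute per edge
_ONES_V = np.ones((K, 1))


class DesignerPolicy:
    """Two-stage graph-network policy producing redistribution weights."""

    n_units = 32

    def __init__(self, rng=0):
        rng = as_generator(rng)
        n = self.n_units
        f = _N_VERTEX_FEATURES
        self.params: dict[str, Tensor] = {
            "e1_w": Tensor(glorot(rng, 2 * f, n), requires_grad=True),
            "e1_b": Tensor(np.zeros(n), requires_grad=True),
            "v1_w": Tensor(glorot(rng, n + f, n), requires_grad=True),
            "v1_b": Tensor(np.zeros(n), requires_grad=True),
            "u1_w": Tensor(glorot(rng, 2 * n, n), requires_grad=True),
            "u1_b": Tensor(np.zeros(n), requires_grad=True),
            "e2_w": Tensor(glorot(rng, 4 * n, n), requires_grad=True),
            "e2_b": Tensor(np.zeros(n), requires_grad=True),
            # near-zero output layer: the initial policy is near-uniform,
            # which keeps early score-function gradients well behaved
            "v2_w": Tensor(glorot(rng, 3 * n, 1) * 0.01, requires_grad=True),
            "v2_b": Tensor(np.zeros(1), requires_grad=True),
        }

    def forward(self, endowments, contributions) -> Tensor:
        """Redistribution weights [B, 4] for a batch of rounds.

        ``endowments`` and ``contributions`` are [B, 4] arrays or Tensors
        (contributions may carry gradients during training).  Endowments and
        contributions are scaled by 1/10, matching the player networks.
        """
        e = endowments if isinstance(endowments, Tensor) else Tensor(np.asarray(endowments, float))
        c = contributions if isinstance(contributions, Tensor) else Tensor(np.asarray(contributions, float))
        if e.data.ndim == 1:
            e = e.reshape(1, -1)
        if c.data.ndim == 1:
            c = c.reshape(1, -1)
        if e.data.shape[-1] != K or c.data.shape[-1] != K:
            raise ValueError(f"designer graph requires exactly {K} player vertices")
        B = c.data.shape[0]
        if e.data.shape[0] == 1 and B > 1:
            e = e * Tensor(np.ones((B, 1)))
        rho = c / e
        # vertex features [B, 4, 3]
        v = ad.concat([(e * 0.1).reshape(B, K, 1), (c * 0.1).reshape(B, K, 1),
                       rho.reshape(B, K, 1)], axis=2)
        p = self.params
        # stage 1: edges -> vertices -> global
        v_s = Tensor(_S_HOT) @ v
        v_r = Tensor(_R_HOT) @ v
        e1 = ad.tanh(ad.concat([v_s, v_r], axis=2) @ p["e1_w"] + p["e1_b"])
        agg1 = Tensor(_R_HOT.T) @ e1
        v1 = ad.tanh(ad.concat([agg1, v], axis=2) @ p["v1_w"] + p["v1_b"])
        u1 = ad.tanh(ad.concat([e1.sum(axis=1), v1.sum(axis=1)], axis=1)
                     @ p["u1_w"] + p["u1_b"])
        # stage 2: edges -> vertices (no global update)
        u_e = Tensor(_ONES_E) @ u1.reshape(B, 1, self.n_units)
        u_v = Tensor(_ONES_V) @ u1.reshape(B, 1, self.n_units)
        v1_s = Tensor(_S_HOT) @ v1
        v1_r = Tensor(_R_HOT) @ v1
        e2 = ad.tanh(ad.concat([e1, v1_s, v1_r, u_e], axis=2) @ p["e2_w"] + p["e2_b"])
        agg2 = Tensor(_R_HOT.T) @ e2
        logits = (ad.concat([agg2, v1, u_v], axis=2) @ p["v2_w"] + p["v2_b"]).reshape(B, K)
        return ad.softmax(logits, axis=-1)

    def to_container(self) -> dict:
        return {
            "kind": "designer_mechanism",
            "arch": {"k": K, "n_units": self.n_units,
                     "vertex_features": _N_VERTEX_FEATURES},
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_container(cls, container: dict) -> "DesignerPolicy":
        if container.get("kind") != "designer_mechanism":
            raise ValueError("container is not a designer mechanism checkpoint; "
                             f"got kind={container.get('kind')!r}")
        policy = cls(rng=0)
        expected = set(policy.params)
        got = set(container.get("params", {}))
        if expected != got:
            raise ValueError(f"checkpoint parameter mismatch: missing "
                             f"{expected - got}, unexpected {got - expected}")
        for k, v in container["params"].items():
            arr = np.asarray(v, float)
            if arr.shape != policy.params[k].data.shape:
                raise ValueError(f"parameter {k!r} has shape {arr.shape}, "
                                 f"expected {policy.params[k].data.shape}")
            policy.params[k] = Tensor(arr, requires_grad=True)
        return policy


class DesignerMechanism(Mechanism):
    """A (frozen) designer policy under the common mechanism contract."""

    def __init__(self, policy: DesignerPolicy, r: float = 1.6,
                 name: str = "designer"):
        self.policy = policy
        self.r = r
        self.id = name
        self.memoryless = True

    def weights(self, endowments, contributions) -> RedistributionWeights:
        w = self.policy.forward(np.asarray(endowments, float).reshape(1, -1),
                                np.asarray(contributions, float).reshape(1, -1))
        return RedistributionWeights(w.data[0])

    def payouts_batch(self, endowments: np.ndarray, contributions: np.ndarray) -> np.ndarray:
        c = np.asarray(contributions, float)
        w = self.policy.forward(np.asarray(endowments, float), c)
        return w.data * (self.r * c.sum(axis=1, keepdims=True))


def export_mechanism(policy: DesignerPolicy, path) -> None:
    """Write a portable JSON container (float64 repr round-trips exactly)."""
    with open(path, "w") as fh:
        json.dump(policy.to_container(), fh)


def load_frozen(path, r: float = 1.6) -> DesignerMechanism:
    with open(path) as fh:
        container = json.load(fh)
    return DesignerMechanism(DesignerPolicy.from_container(container), r=r,
                             name=f"frozen:{path}")


# -- training ------------------------------------------------------------------


@dataclass(frozen=True)
class DesignerTrainConfig:
    """Vote-maximization training schedule.

    Per update, two batches of ``batch_size`` 10-round games are simulated —
    one under the designer, one under the fixed opponent — partitioned into
    equal groups over the eight endowment conditions (head player 10 coins,
    tail players 2, 3, 4, 5, 6, 7, 8 or 10).  Paired episodes yield one
    logistic vote probability per player; the objective is the expected
    number of votes per episode.  RMSProp (lr 4e-4, eps 1e-5, decay 0.99,
    no momentum) optimizes the SCG surrogate.
    """

    n_updates: int = 10_000
    batch_size: int = 512
    lr: float = 4e-4
    eps: float = 1e-5
    decay: float = 0.99
    opponent: str = "canonical:liberal_egalitarian"
    head_endowment: int = 10
    tail_endowments: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8, 10)
    r: float = 1.6
    n_rounds: int = 10
    slope: float = 1.4
    log_every: int = 50
    seed: int = 0

    def endowment_batch(self) -> np.ndarray:
        """[batch_size, 4] endowments in contiguous equal-sized groups."""
        n_cond = len(self.tail_endowments)
        if self.batch_size % n_cond:
            raise ValueError(
                f"batch_size must be divisible by the {n_cond} endowment conditions")
        group = self.batch_size // n_cond
        rows = []
        for tail in self.tail_endowments:
            rows.append(np.tile([self.head_endowment, tail, tail, tail], (group, 1)))
        return np.concatenate(rows, axis=0).astype(float)


def designer_rollout(policy: DesignerPolicy, player_policy: ContributionPolicy,
                     endowments: np.ndarray, n_rounds: int, r: float, rng):
    """Roll a batch of games under the designer, building the gradient graph.

    Returns (rpay Tensor [B, 4], logp_sum Tensor [B]) where ``logp_sum`` is
    the summed log-probability of the players' sampled contributions for
    rounds 2..n (round 1 excluded: it cannot depend on the mechanism).
    """
    rng = as_generator(rng)
    e = np.asarray(endowments, float)
    B = e.shape[0]
    masks = [endowment_mask(e[:, j]) for j in range(K)]
    states = [player_policy.init_state(B) for _ in range(K)]
    c_prev = Tensor(np.zeros((B, K)))
    y_prev = Tensor(np.zeros((B, K)))
    rpay = Tensor(np.zeros((B, K)))
    logp_sum = Tensor(np.zeros(B))
    rows = np.arange(B)
    for t in range(n_rounds):
        c_t = np.zeros((B, K))
        logp_round = []
        for j in range(K):
            obs = observation_batch(Tensor(e), c_prev, y_prev, j)
            logits, states[j] = player_policy.step(obs, states[j], masks[j])
            logp = ad.log_softmax(logits)
            probs = np.exp(logp.data)
            a = sample_categorical(probs, rng)
            c_t[:, j] = a
            logp_round.append(logp[rows, a])
        if t >= 1:
            for lp in logp_round:
                logp_sum = logp_sum + lp
        weights = policy.forward(e, c_t)
        y_t = weights * Tensor((r * c_t.sum(axis=1, keepdims=True)))
        rpay = rpay + y_t / Tensor(e)
        c_prev, y_prev = Tensor(c_t), y_t
    return rpay, logp_sum


def opponent_rollout(mechanism: Mechanism, player_policy: ContributionPolicy,
                     endowments: np.ndarray, n_rounds: int, rng) -> np.ndarray:
    """Gradient-free batch rollout under a fixed mechanism; returns rpay [B, 4]."""
    rng = as_generator(rng)
    e = np.asarray(endowments, float)
    B = e.shape[0]
    masks = [endowment_mask(e[:, j]) for j in range(K)]
    states = [player_policy.init_state(B) for _ in range(K)]
    c_prev = np.zeros((B, K))
    y_prev = np.zeros((B, K))
    rpay = np.zeros((B, K))
    for _ in range(n_rounds):
        c_t = np.zeros((B, K))
        for j in range(K):
            obs = observation_batch(e, c_prev, y_prev, j).data
            probs, states[j] = player_policy.step_probs(obs, states[j], masks[j])
            c_t[:, j] = sample_categorical(probs, rng)
        if hasattr(mechanism, "payouts_batch"):
            y_t = mechanism.payouts_batch(e, c_t)
        else:
            y_t = np.stack([mechanism.payouts(e[b], c_t[b], 1.6) for b in range(B)])
        rpay += y_t / e
        c_prev, y_prev = c_t, y_t
    return rpay


def surrogate_loss(rpay_designer: Tensor, rpay_opponent: np.ndarray,
                   logp_sum: Tensor,
                   voting_params: VotingModelParams = VotingModelParams()
                   ) -> tuple[Tensor, Tensor]:
    """SCG surrogate S = mean[ J + stop_grad(J - mean J) * sum log p ].

    ``J`` is the expected number of votes for the designer per paired
    episode: the sum over players of the logistic vote probability.  J is
    mean-centred within the batch before weighting the score-function term.
    Returns (S, J).
    """
    if rpay_designer.data.shape != np.asarray(rpay_opponent).shape:
        raise ValueError("designer and opponent episodes must be paired "
                         f"(shapes {rpay_designer.data.shape} vs "
                         f"{np.asarray(rpay_opponent).shape})")
    diff = (rpay_designer - Tensor(rpay_opponent)) * voting_params.s
    p = ad.sigmoid(diff)
    J = p.sum(axis=1)
    J_centred = stop_grad(J - J.mean())
    S = (J + J_centred * logp_sum).mean()
    return S, J


def train_designer(config: DesignerTrainConfig,
                   player_policy: ContributionPolicy,
                   opponent: Mechanism | None = None
                   ) -> tuple[DesignerMechanism, pd.DataFrame]:
    """Train the mechanism designer against a fixed opponent mechanism.

    Returns the frozen mechanism and a curve of the expected vote share of
    the designer (mean over players and episodes of the vote probability).
    """
    if player_policy is None:
        raise ValueError("trained player policies are required")
    if opponent is None:
        opponent = mechanism_from_id(config.opponent, r=config.r)
    policy = DesignerPolicy(rng=substream(config.seed, "designer-init"))
    opt = RMSProp(policy.params, lr=config.lr, decay=config.decay, eps=config.eps)
    rng_a = substream(config.seed, "designer-rollout")
    rng_b = substream(config.seed, "opponent-rollout")
    e = config.endowment_batch()
    voting_params = VotingModelParams(s=config.slope)
    curves = []
    for update in range(1, config.n_updates + 1):
        rpay_a, logp_sum = designer_rollout(policy, player_policy, e,
                                            config.n_rounds, config.r, rng_a)
        rpay_b = opponent_rollout(opponent, player_policy, e,
                                  config.n_rounds, rng_b)
        S, J = surrogate_loss(rpay_a, rpay_b, logp_sum, voting_params)
        loss = S * -1.0
        opt.zero_grad()
        loss.backward()
        opt.step()
        for p in player_policy.params.values():
            p.grad = None  # players are frozen; drop their accumulated grads
        if update % config.log_every == 0 or update == config.n_updates:
            curves.append({"update": update,
                           "expected_vote_share": float(J.data.mean()) / K})
    mechanism = DesignerMechanism(policy, r=config.r)
    return mechanism, pd.DataFrame(curves)


def expected_vote_share(mechanism_a: Mechanism, mechanism_b: Mechanism,
                        player_policy: ContributionPolicy,
                        endowments: np.ndarray, n_rounds: int = 10,
                        voting_params: VotingModelParams = VotingModelParams(),
                        rng=0, sampled: bool = False) -> float:
    """Vote share of mechanism A over paired fresh rollouts.

    With ``sampled=True``, draws binary votes; otherwise averages the
    logistic vote probabilities.
    """
    rng = as_generator(rng)
    rpay_a = opponent_rollout(mechanism_a, player_policy, endowments, n_rounds, rng)
    rpay_b = opponent_rollout(mechanism_b, player_policy, endowments, n_rounds, rng)
    p = 1.0 / (1.0 + np.exp(-voting_params.s * (rpay_a - rpay_b)))
    if sampled:
        return float((rng.random(p.shape) < p).mean())
    return float(p.mean())
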