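"""Contribution-generating models.

Three kinds of players produce contributions in the investment game:

* **Virtual players** — recurrent networks (linear 16->64 + tanh, LSTM with
  hidden size 16, linear head over the 11 contribution levels 0..10) trained
  by behavioural cloning to predict a focal player's next contribution from
  the public state of the previous round.
* **Rational players** — the same architecture trained by score-function
  policy gradient to maximize their own per-episode return under a given
  mechanism.
* **Scripted synthetic agents** — parametric archetypes from the
  public-goods literature (full contributors, free riders, conditional
  cooperators, noisy uniform players) used to generate training corpora
  without any human data.

Observations are 16 features per step: every player's endowment, previous
contribution, previous relative contribution and previous payout, ordered
focal player first.  Endowments, contributions and payouts are divided by 10
so all features lie in roughly [0, 1]; round-1 previous-step features are
zero.  Action probabilities for contributions above the focal endowment are
masked to zero, so emitted contributions always respect the budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _autodiff as ad
from ._autodiff import Tensor
from ._nn import Adam, linear_params, lstm_params, lstm_step
from ._rng import as_generator, substream
from .game import GameConfig, GameTrace, RoundRecord, play_block
from .mechanisms import Mechanism, ManifoldMechanism, canonical

__all__ = [
    "N_ACTIONS",
    "MAX_ENDOWMENT",
    "build_observation",
    "observation_batch",
    "endowment_mask",
    "ContributionPolicy",
    "NeuralAgent",
    "ScriptedAgent",
    "FullContributor",
    "FreeRider",
    "ConditionalCooperator",
    "NoisyUniform",
    "ScriptedAgentSpec",
    "ImitationCorpus",
    "ImitationTrainConfig",
    "generate_synthetic_corpus",
    "imitation_train",
    "top1_agreement",
    "constant_baseline_cross_entropy",
    "RationalTrainConfig",
    "train_rational_players",
    "mean_relative_contribution",
]

N_ACTIONS = 11          # contribution levels 0..10 coins
MAX_ENDOWMENT = 10      # fixed by the 11-way output head
N_FEATURES = 16


def _focal_order(k: int, focal: int) -> list[int]:
    return [focal] + [j for j in range(k) if j != focal]


def observation_batch(endowments, c_prev, y_prev, focal: int) -> Tensor:
    """Batched focal-view observation [B, 16].

    Accepts arrays or Tensors (payouts carry gradients during designer
    training).  ``endowments`` may be [k] or [B, k]; ``c_prev``/``y_prev``
    are [B, k] in natural player order.
    """
    e = endowments if isinstance(endowments, Tensor) else Tensor(np.asarray(endowments, float))
    c = c_prev if isinstance(c_prev, Tensor) else Tensor(np.asarray(c_prev, float))
    y = y_prev if isinstance(y_prev, Tensor) else Tensor(np.asarray(y_prev, float))
    if e.data.ndim == 1:
        e = e.reshape(1, -1)
    k = e.data.shape[-1]
    order = _focal_order(k, focal)
    perm = np.zeros((k, k))
    perm[np.arange(k), order] = 1.0  # row i selects player order[i]
    pt = Tensor(perm.T)
    e_o, c_o, y_o = e @ pt, c @ pt, y @ pt
    rho_o = c_o / e_o
    if c.data.ndim == 2 and e.data.shape[0] == 1 and c.data.shape[0] > 1:
        e_o = e_o * Tensor(np.ones((c.data.shape[0], 1)))
    return ad.concat([e_o * 0.1, c_o * 0.1, rho_o, y_o * 0.1], axis=1)


def build_observation(endowments, prev: RoundRecord | None, focal: int) -> np.ndarray:
    """Single-step observation vector [16] for one focal player."""
    e = np.asarray(endowments, float)
    k = e.size
    if prev is None:
        c = np.zeros((1, k))
        y = np.zeros((1, k))
    else:
        c = prev.contributions.reshape(1, -1)
        y = prev.payouts.reshape(1, -1)
    return observation_batch(e, c, y, focal).data[0]


def endowment_mask(endowments) -> np.ndarray:
    """Additive logit mask [B, 11]: -inf (approx) above the focal endowment."""
    e = np.asarray(endowments)
    if np.any(e > MAX_ENDOWMENT):
        raise ValueError(
            f"endowment above {MAX_ENDOWMENT} is outside the {N_ACTIONS}-way "
            "contribution head")
    if np.any(e != np.round(e)) or np.any(e < 1):
        raise ValueError("endowments must be integers >= 1")
    mask = np.zeros((e.size, N_ACTIONS))
    actions = np.arange(N_ACTIONS)
    mask[actions[None, :] > e.reshape(-1, 1)] = -1e9
    return mask


def sample_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Vectorized sampling from rows of a probability matrix."""
    u = rng.random((probs.shape[0], 1))
    return np.minimum((u > probs.cumsum(axis=1)).sum(axis=1), probs.shape[1] - 1)


class ContributionPolicy:
    """Recurrent categorical policy over integer contributions 0..10.

    Architecture: linear(16 -> 64) + tanh, LSTM(hidden 16), linear(16 -> 11)
    producing unnormalized log-probabilities.  Used for imitation-trained
    virtual players and for rational players.
    """

    n_inputs = N_FEATURES
    n_embed = 64
    n_hidden = 16

    def __init__(self, rng=0):
        rng = as_generator(rng)
        self.params: dict[str, Tensor] = {}
        self.params.update(linear_params(rng, self.n_inputs, self.n_embed, "in"))
        self.params.update(lstm_params(rng, self.n_embed, self.n_hidden))
        self.params.update(linear_params(rng, self.n_hidden, N_ACTIONS, "out"))

    # -- forward --------------------------------------------------------------

    def init_state(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.n_hidden))
        return Tensor(z.copy()), Tensor(z.copy())

    def step(self, obs: Tensor, state: tuple[Tensor, Tensor],
             mask: np.ndarray) -> tuple[Tensor, tuple[Tensor, Tensor]]:
        """One recurrent step; returns masked logits [B, 11] and new state."""
        x = ad.tanh(obs @ self.params["in_w"] + self.params["in_b"])
        h, c = lstm_step(self.params, x, *state)
        logits = h @ self.params["out_w"] + self.params["out_b"]
        return logits + Tensor(mask), (h, c)

    def step_probs(self, obs: np.ndarray, state, mask: np.ndarray):
        """Gradient-free step returning probabilities as a plain array."""
        with ad.no_grad():
            logits, state = self.step(Tensor(obs), state, mask)
            return ad.softmax(logits).data, state

    # -- persistence ----------------------------------------------------------

    def to_container(self) -> dict:
        return {
            "kind": "contribution_policy",
            "arch": {"n_inputs": self.n_inputs, "n_embed": self.n_embed,
                     "n_hidden": self.n_hidden, "n_actions": N_ACTIONS},
            "params": {k: v.data.tolist() for k, v in self.params.items()},
        }

    @classmethod
    def from_container(cls, container: dict) -> "ContributionPolicy":
        if container.get("kind") != "contribution_policy":
            raise ValueError("container is not a contribution policy checkpoint")
        policy = cls(rng=0)
        for k, v in container["params"].items():
            if k not in policy.params:
                raise ValueError(f"unexpected parameter {k!r} in checkpoint")
            policy.params[k] = Tensor(np.asarray(v, float), requires_grad=True)
        return policy


class NeuralAgent:
    """Game-protocol adapter around a :class:`ContributionPolicy`."""

    def __init__(self, policy: ContributionPolicy, greedy: bool = False):
        self.policy = policy
        self.greedy = greedy
        self._state = None
        self._mask = None
        self._endowments = None
        self._focal = None

    def reset(self, endowments, focal: int) -> None:
        self._endowments = np.asarray(endowments, float)
        self._focal = focal
        self._state = self.policy.init_state(1)
        self._mask = endowment_mask(self._endowments[focal:focal + 1])

    def act(self, prev: RoundRecord | None, rng) -> int:
        obs = build_observation(self._endowments, prev, self._focal).reshape(1, -1)
        probs, self._state = self.policy.step_probs(obs, self._state, self._mask)
        if self.greedy:
            return int(probs[0].argmax())
        return int(sample_categorical(probs, as_generator(rng))[0])


# -- scripted synthetic agents -------------------------------------------------


class ScriptedAgent:
    """Base for parametric agents; subclasses implement ``_ratio``."""

    archetype = "scripted"

    def reset(self, endowments, focal: int) -> None:
        self.endowments = np.asarray(endowments, float)
        self.focal = focal
        self.t = 0

    def act(self, prev: RoundRecord | None, rng) -> int:
        e = self.endowments[self.focal]
        ratio = float(np.clip(self._ratio(prev, as_generator(rng)), 0.0, 1.0))
        self.t += 1
        return int(np.clip(round(ratio * e), 0, e))

    def _ratio(self, prev, rng) -> float:  # pragma: no cover - abstract
        raise NotImplementedError


class FullContributor(ScriptedAgent):
    """Always contributes the full endowment."""

    archetype = "full_contributor"

    def _ratio(self, prev, rng):
        return 1.0


class FreeRider(ScriptedAgent):
    """Contributes at most 20% of endowment (default around 10%)."""

    archetype = "free_rider"

    def __init__(self, frac: float = 0.1, noise: float = 0.05):
        if not (0.0 <= frac <= 0.2):
            raise ValueError("free-rider fraction must be in [0, 0.2]")
        self.frac, self.noise = frac, noise

    def _ratio(self, prev, rng):
        f = self.frac + (self.noise * rng.normal() if self.noise else 0.0)
        return float(np.clip(f, 0.0, 0.2))


class ConditionalCooperator(ScriptedAgent):
    """Reciprocates the other players' previous mean relative contribution.

    Round 1 contributes ``init_ratio`` of endowment; thereafter the target
    ratio is ``slope`` times the mean relative contribution of the other
    players in the previous round, plus Gaussian noise.
    """

    archetype = "conditional_cooperator"

    def __init__(self, init_ratio: float = 0.5, slope: float = 1.0,
                 noise: float = 0.1):
        self.init_ratio, self.slope, self.noise = init_ratio, slope, noise

    def _ratio(self, prev, rng):
        if prev is None:
            ratio = self.init_ratio
        else:
            rho = prev.relative_contributions
            others = np.delete(rho, self.focal)
            ratio = self.slope * float(others.mean())
        if self.noise:
            ratio += self.noise * rng.normal()
        return ratio


class NoisyUniform(ScriptedAgent):
    """Contributes a uniformly random integer in [0, e]."""

    archetype = "noisy_uniform"

    def _ratio(self, prev, rng):
        e = self.endowments[self.focal]
        return rng.integers(0, int(e) + 1) / e


_ARCHETYPES = {
    "full_contributor": FullContributor,
    "free_rider": FreeRider,
    "conditional_cooperator": ConditionalCooperator,
    "noisy_uniform": NoisyUniform,
}


@dataclass(frozen=True)
class ScriptedAgentSpec:
    """Mixture of archetypes used to generate a synthetic behaviour corpus.

    ``mixture`` maps archetype name to sampling weight (must sum to 1);
    ``archetype_kwargs`` optionally overrides archetype parameters.
    """

    mixture: dict[str, float] = field(default_factory=lambda: {
        "conditional_cooperator": 0.5,
        "free_rider": 0.25,
        "full_contributor": 0.15,
        "noisy_uniform": 0.1,
    })
    archetype_kwargs: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(self.mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {total}")
        for name in self.mixture:
            if name not in _ARCHETYPES:
                raise ValueError(f"unknown archetype {name!r}")

    def make_agent(self, name: str) -> ScriptedAgent:
        return _ARCHETYPES[name](**self.archetype_kwargs.get(name, {}))

    def sample_archetypes(self, k: int, rng: np.random.Generator) -> list[str]:
        names = sorted(self.mixture)
        weights = np.array([self.mixture[n] for n in names])
        return [names[i] for i in rng.choice(len(names), size=k, p=weights)]


@dataclass
class ImitationCorpus:
    """Behavioural-cloning corpus: focal-view observations and targets.

    One sample per (game, focal seat): ``obs`` is [N, T, 16], ``targets``
    [N, T] integer contributions, ``focal_endowments`` [N].  Train and
    validation games are disjoint.
    """

    obs: np.ndarray
    targets: np.ndarray
    focal_endowments: np.ndarray
    archetypes: list[str]
    traces: list[GameTrace]
    train_idx: np.ndarray
    val_idx: np.ndarray

    def __len__(self) -> int:
        return self.obs.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        """Game CSV schema plus a focal-player column (rows are focal samples)."""
        from .game import trace_to_dataframe

        frames = []
        for g, trace in enumerate(self.traces):
            df = trace_to_dataframe(trace, session=g)
            df["focal"] = df["player"]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)


def _trace_to_samples(trace: GameTrace) -> tuple[np.ndarray, np.ndarray]:
    """Focal-view observation/target arrays ([k, T, 16], [k, T]) of a trace."""
    k = trace.config.k
    T = len(trace.rounds)
    obs = np.zeros((k, T, N_FEATURES))
    targets = np.zeros((k, T), dtype=int)
    for focal in range(k):
        prev = None
        for t, rec in enumerate(trace.rounds):
            obs[focal, t] = build_observation(trace.config.endowment_array, prev, focal)
            targets[focal, t] = int(rec.contributions[focal])
            prev = rec
    return obs, targets


def generate_synthetic_corpus(spec: ScriptedAgentSpec, config: GameConfig,
                              n_games: int, seed: int,
                              mechanisms: list[Mechanism] | None = None,
                              tail_endowments: tuple[int, ...] | None = None,
                              holdout_fraction: float = 0.1) -> ImitationCorpus:
    """Play ``n_games`` scripted games and collect focal targets.

    Games cycle through the supplied mechanisms (default: the three
    canonical mechanisms) and, when ``tail_endowments`` is given, through
    endowment conditions (head player keeps ``config`` endowments[0], tail
    players take the cycled value) — emulating a corpus gathered under
    varied rules and wealth conditions.  Every seat of every game yields
    one focal sample.
    """
    if n_games <= 0:
        raise ValueError("n_games must be positive")
    if mechanisms is None:
        mechanisms = [ManifoldMechanism(canonical(name, config.k), r=config.r,
                                        name=f"canonical:{name}")
                      for name in ("strict_egalitarian", "libertarian",
                                   "liberal_egalitarian")]
    rng_assign = substream(seed, "corpus-archetypes")
    rng_play = substream(seed, "corpus-play")
    obs_all, targets_all, endow_all, arch_all, traces = [], [], [], [], []
    for g in range(n_games):
        if tail_endowments is not None:
            tail = tail_endowments[g % len(tail_endowments)]
            game_config = GameConfig(
                k=config.k, r=config.r, n_rounds=config.n_rounds,
                endowments=(config.endowments[0],) + (tail,) * (config.k - 1),
                bonus_rounds=config.bonus_rounds, seed=config.seed)
        else:
            game_config = config
        names = spec.sample_archetypes(config.k, rng_assign)
        agents = [spec.make_agent(n) for n in names]
        trace = play_block(game_config, mechanisms[g % len(mechanisms)],
                           agents, rng_play)
        obs, targets = _trace_to_samples(trace)
        obs_all.append(obs)
        targets_all.append(targets)
        endow_all.append(game_config.endowment_array)
        arch_all.extend(names)
        traces.append(trace)
    obs = np.concatenate(obs_all, axis=0)
    targets = np.concatenate(targets_all, axis=0)
    endow = np.concatenate(endow_all, axis=0).astype(int)
    # split by game so held-out games are fully unseen
    rng_split = substream(seed, "corpus-split")
    games = rng_split.permutation(n_games)
    n_val = max(1, int(round(holdout_fraction * n_games)))
    val_games = set(games[:n_val].tolist())
    sample_game = np.repeat(np.arange(n_games), config.k)
    val_mask = np.isin(sample_game, list(val_games))
    return ImitationCorpus(obs=obs, targets=targets, focal_endowments=endow,
                           archetypes=arch_all, traces=traces,
                           train_idx=np.where(~val_mask)[0],
                           val_idx=np.where(val_mask)[0])


# -- imitation training --------------------------------------------------------


@dataclass(frozen=True)
class ImitationTrainConfig:
    """Behavioural-cloning hyperparameters.

    Loss is cross-entropy minus an entropy bonus (weight 0.1) plus an L2
    penalty on parameters (weight 1e-5), optimized with Adam
    (lr 4e-4, beta1 0.9, beta2 0.999, eps 1e-8) over full-game
    backpropagation through time.
    """

    n_updates: int = 30_000
    batch_size: int = 512
    lr: float = 4e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    entropy_weight: float = 0.1
    l2_weight: float = 1e-5
    log_every: int = 500
    seed: int = 0

    def __post_init__(self):
        if self.n_updates < 1:
            raise ValueError("n_updates must be >= 1")
        if self.entropy_weight < 0 or self.l2_weight < 0:
            raise ValueError("regularizer weights must be nonnegative")


def _sequence_log_probs(policy: ContributionPolicy, obs: np.ndarray,
                        targets: np.ndarray, mask: np.ndarray):
    """Log-probabilities of targets and mean prediction entropy over a batch.

    ``obs`` is [B, T, 16]; unrolls the policy through time with gradients.
    Returns (logp [list of [B] Tensors], mean entropy Tensor).
    """
    B, T, _ = obs.shape
    state = policy.init_state(B)
    logps = []
    entropies = []
    rows = np.arange(B)
    for t in range(T):
        logits, state = policy.step(Tensor(obs[:, t, :]), state, mask)
        logp = ad.log_softmax(logits)
        logps.append(logp[rows, targets[:, t]])
        p = ad.exp(logp)
        # entropy of the masked categorical; masked cells contribute ~0
        entropies.append((p * logp * -1.0).sum(axis=1))
    ent = sum(e.sum() for e in entropies) * (1.0 / (B * T))
    return logps, ent


def _cross_entropy(policy: ContributionPolicy, obs, targets, endowments) -> float:
    """Mean per-decision cross-entropy (nats) without gradient tracking."""
    mask = endowment_mask(endowments)
    B, T, _ = obs.shape
    rows = np.arange(B)
    total = 0.0
    with ad.no_grad():
        state = policy.init_state(B)
        for t in range(T):
            logits, state = policy.step(Tensor(obs[:, t, :]), state, mask)
            logp = ad.log_softmax(logits).data
            total += -logp[rows, targets[:, t]].sum()
    return total / (B * T)


def imitation_train(corpus: ImitationCorpus,
                    config: ImitationTrainConfig = ImitationTrainConfig()
                    ) -> tuple[ContributionPolicy, pd.DataFrame]:
    """Train a virtual player by behavioural cloning on a corpus.

    Returns the trained policy and a curve of train/held-out cross-entropy.
    """
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    if np.any(corpus.focal_endowments > MAX_ENDOWMENT):
        raise ValueError(f"corpus contains endowments above {MAX_ENDOWMENT}")
    rng = substream(config.seed, "imitation")
    policy = ContributionPolicy(rng=substream(config.seed, "imitation-init"))
    opt = Adam(policy.params, lr=config.lr, beta1=config.beta1,
               beta2=config.beta2, eps=config.eps)
    n_train = corpus.train_idx.size
    curves = []
    for update in range(1, config.n_updates + 1):
        idx = corpus.train_idx[rng.integers(0, n_train, size=min(config.batch_size, n_train))]
        obs = corpus.obs[idx]
        targets = corpus.targets[idx]
        mask = endowment_mask(corpus.focal_endowments[idx])
        logps, entropy = _sequence_log_probs(policy, obs, targets, mask)
        B, T = targets.shape
        ce = sum((lp.sum() * -1.0) for lp in logps) * (1.0 / (B * T))
        l2 = sum((p * p).sum() for p in policy.params.values())
        loss = ce - config.entropy_weight * entropy + config.l2_weight * l2
        opt.zero_grad()
        loss.backward()
        opt.step()
        if update % config.log_every == 0 or update == config.n_updates:
            val_idx = corpus.val_idx[:512]
            val_ce = _cross_entropy(policy, corpus.obs[val_idx],
                                    corpus.targets[val_idx],
                                    corpus.focal_endowments[val_idx])
            curves.append({"update": update, "train_ce": float(ce.data),
                           "val_ce": val_ce})
    return policy, pd.DataFrame(curves)


def top1_agreement(policy: ContributionPolicy, corpus: ImitationCorpus,
                   idx: np.ndarray | None = None) -> float:
    """Fraction of decisions where the policy's argmax matches the target."""
    if idx is None:
        idx = corpus.val_idx
    obs = corpus.obs[idx]
    targets = corpus.targets[idx]
    mask = endowment_mask(corpus.focal_endowments[idx])
    B, T, _ = obs.shape
    hits = 0
    with ad.no_grad():
        state = policy.init_state(B)
        for t in range(T):
            logits, state = policy.step(Tensor(obs[:, t, :]), state, mask)
            hits += int((logits.data.argmax(axis=1) == targets[:, t]).sum())
    return hits / (B * T)


def constant_baseline_cross_entropy(corpus: ImitationCorpus,
                                    idx: np.ndarray | None = None) -> float:
    """Cross-entropy (nats) of the best constant categorical on the targets."""
    if idx is None:
        idx = corpus.val_idx
    targets = corpus.targets[idx].ravel()
    counts = np.bincount(targets, minlength=N_ACTIONS).astype(float)
    p = counts / counts.sum()
    nz = counts > 0
    return float(-(counts[nz] * np.log(p[nz])).sum() / counts.sum())


# -- rational players ----------------------------------------------------------


@dataclass(frozen=True)
class RationalTrainConfig:
    """Score-function (REINFORCE) training of self-interested players.

    Each seat's policy maximizes its own per-episode cumulative return with
    a batch-mean baseline; the estimator is the plain score-function
    gradient over the 10-round episode.
    """

    n_updates: int = 500
    batch_size: int = 128
    lr: float = 3e-3
    entropy_weight: float = 0.0
    log_every: int = 50
    seed: int = 0


def _rollout_batch(policies: list[ContributionPolicy], config: GameConfig,
                   mechanism: Mechanism, batch: int, rng):
    """Sample a batch of episodes; returns obs [k][B,T,16], actions [k][B,T],
    per-seat returns [k][B], and the contribution tensor [B,T,k]."""
    k = config.k
    e = config.endowment_array
    e_b = np.broadcast_to(e, (batch, k))
    masks = [endowment_mask(np.full(batch, e[j])) for j in range(k)]
    states = [p.init_state(batch) for p in policies]
    c_prev = np.zeros((batch, k))
    y_prev = np.zeros((batch, k))
    obs_hist = [np.zeros((batch, config.n_rounds, N_FEATURES)) for _ in range(k)]
    act_hist = [np.zeros((batch, config.n_rounds), dtype=int) for _ in range(k)]
    returns = np.zeros((batch, k))
    contribs = np.zeros((batch, config.n_rounds, k))
    for t in range(config.n_rounds):
        c_t = np.zeros((batch, k))
        for j in range(k):
            obs = observation_batch(e, c_prev, y_prev, j).data
            obs_hist[j][:, t, :] = obs
            probs, states[j] = policies[j].step_probs(obs, states[j], masks[j])
            a = sample_categorical(probs, rng)
            act_hist[j][:, t] = a
            c_t[:, j] = a
        if hasattr(mechanism, "payouts_batch"):
            y_t = mechanism.payouts_batch(e_b, c_t)
        else:
            y_t = np.stack([
                mechanism.payouts(e, c_t[b], config.r) for b in range(batch)])
        returns += y_t + e_b - c_t
        contribs[:, t, :] = c_t
        c_prev, y_prev = c_t, y_t
    return obs_hist, act_hist, [returns[:, j] for j in range(k)], contribs


def train_rational_players(config: GameConfig, mechanism: Mechanism,
                           train_config: RationalTrainConfig = RationalTrainConfig(),
                           seed: int | None = None
                           ) -> tuple[list[ContributionPolicy], pd.DataFrame]:
    """Train one self-interested policy per seat under a fixed mechanism.

    All seats learn simultaneously in self-play; each seat's objective is
    its own expected cumulative return.  Returns the per-seat policies and
    a training curve (mean relative contribution and mean return).
    """
    if seed is None:
        seed = train_config.seed
    rng = substream(seed, "rational")
    policies = [ContributionPolicy(rng=substream(seed, f"rational-init-{j}"))
                for j in range(config.k)]
    opts = [Adam(p.params, lr=train_config.lr) for p in policies]
    e = config.endowment_array
    curves = []
    for update in range(1, train_config.n_updates + 1):
        obs_hist, act_hist, returns, contribs = _rollout_batch(
            policies, config, mechanism, train_config.batch_size, rng)
        for j in range(config.k):
            mask = endowment_mask(np.full(train_config.batch_size, e[j]))
            logps, entropy = _sequence_log_probs(
                policies[j], obs_hist[j], act_hist[j], mask)
            adv = returns[j] - returns[j].mean()
            logp_sum = sum(logps[1:], start=logps[0])
            loss = (logp_sum * Tensor(adv)).mean() * -1.0
            if train_config.entropy_weight:
                loss = loss - train_config.entropy_weight * entropy
            opts[j].zero_grad()
            loss.backward()
            opts[j].step()
        if update % train_config.log_every == 0 or update == train_config.n_updates:
            rel = (contribs / e).mean()
            curves.append({
                "update": update,
                "mean_relative_contribution": float(rel),
                "mean_return": float(np.mean([r.mean() for r in returns])),
            })
    return policies, pd.DataFrame(curves)


def mean_relative_contribution(policies: list[ContributionPolicy],
                               config: GameConfig, mechanism: Mechanism,
                               n_episodes: int = 256, seed: int = 0) -> float:
    """Monte-Carlo mean of c/e across seats, rounds and episodes."""
    rng = substream(seed, "rational-eval")
    _, _, _, contribs = _rollout_batch(policies, config, mechanism, n_episodes, rng)
    return float((contribs / config.endowment_array).mean())
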