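"""Shared fixtures.

The heavy fixtures (trained policies) are session-scoped so that the
scaled-down training runs they require execute at most once per session.
"""

from __future__ import annotations

import numpy as np
import pytest

from mechvote.game import GameConfig
from mechvote.mechanisms import ManifoldMechanism, canonical
from mechvote.players import (ImitationTrainConfig, RationalTrainConfig,
                              ScriptedAgentSpec, generate_synthetic_corpus,
                              imitation_train, train_rational_players)

TAIL_ENDOWMENTS = (2, 4, 6, 8, 10)


@pytest.fixture(scope="session")
def default_config() -> GameConfig:
    return GameConfig()


@pytest.fixture(scope="session")
def cc_corpus():
    """Corpus from deterministic conditional cooperators, varied endowments."""
    spec = ScriptedAgentSpec(
        mixture={"conditional_cooperator": 1.0},
        archetype_kwargs={"conditional_cooperator": {"noise": 0.0}})
    return generate_synthetic_corpus(spec, GameConfig(), n_games=200, seed=11,
                                     tail_endowments=TAIL_ENDOWMENTS)


@pytest.fixture(scope="session")
def recovered_policy(cc_corpus):
    """Behaviour-recovery run: 2,000 imitation updates on the deterministic corpus."""
    return imitation_train(cc_corpus, ImitationTrainConfig(
        n_updates=2000, batch_size=256, seed=0, log_every=1000))


@pytest.fixture(scope="session")
def freerider_policy():
    """Virtual player imitating a free-riding-prone synthetic population."""
    spec = ScriptedAgentSpec(mixture={"free_rider": 0.6,
                                      "conditional_cooperator": 0.3,
                                      "noisy_uniform": 0.1})
    corpus = generate_synthetic_corpus(spec, GameConfig(), n_games=200, seed=7,
                                       tail_endowments=TAIL_ENDOWMENTS)
    policy, _ = imitation_train(corpus, ImitationTrainConfig(
        n_updates=400, batch_size=128, seed=7, log_every=200))
    return policy


@pytest.fixture(scope="session")
def rational_policies():
    """Self-interested players trained under libertarian and strict egalitarian."""
    config = GameConfig()
    out = {}
    for name in ("libertarian", "strict_egalitarian"):
        mech = ManifoldMechanism(canonical(name), name=f"canonical:{name}")
        policies, curves = train_rational_players(
            config, mech, RationalTrainConfig(n_updates=500, batch_size=128,
                                              lr=3e-3, seed=0))
        out[name] = (mech, policies, curves)
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
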