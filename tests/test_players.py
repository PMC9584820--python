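"""Players: observations, masking, scripted agents, corpora, training."""

import numpy as np
import pytest

from mechvote.game import GameConfig, RoundRecord, play_block
from mechvote.mechanisms import equal_split
from mechvote.players import (ConditionalCooperator, ContributionPolicy,
                              FreeRider, FullContributor, ImitationTrainConfig,
                              NeuralAgent, NoisyUniform, ScriptedAgentSpec,
                              build_observation, constant_baseline_cross_entropy,
                              endowment_mask, generate_synthetic_corpus,
                              imitation_train, top1_agreement)
from mechvote._rng import substream


class TestObservation:
    def test_round_one_history_is_zero(self):
        obs = build_observation([10, 2, 2, 2], None, focal=0)
        assert np.allclose(obs[:4], [1.0, 0.2, 0.2, 0.2])  # endowments / 10
        assert np.allclose(obs[4:], 0.0)

    def test_focal_first_ordering_and_scaling(self):
        e = np.array([10.0, 2, 2, 2])
        rec = RoundRecord(endowments=e, contributions=np.array([5.0, 2, 0, 1]),
                          payouts=np.array([4.0, 3, 2, 1]))
        obs = build_observation(e, rec, focal=2)
        assert np.allclose(obs[:4], [0.2, 1.0, 0.2, 0.2])       # e, focal first
        assert np.allclose(obs[4:8], [0.0, 0.5, 0.2, 0.1])      # c / 10
        assert np.allclose(obs[8:12], [0.0, 0.5, 1.0, 0.5])     # rho unscaled
        assert np.allclose(obs[12:16], [0.2, 0.4, 0.3, 0.1])    # y / 10


class TestMasking:
    def test_probabilities_above_endowment_are_zero(self):
        policy = ContributionPolicy(rng=0)
        mask = endowment_mask(np.array([4]))
        probs, _ = policy.step_probs(np.zeros((1, 16)), policy.init_state(1), mask)
        assert np.allclose(probs[0, 5:], 0.0)
        assert probs[0, :5].sum() == pytest.approx(1.0)

    def test_uniform_logits_give_uniform_distribution(self):
        policy = ContributionPolicy(rng=0)
        for key in ("out_w", "out_b"):
            policy.params[key].data[:] = 0.0
        mask = endowment_mask(np.array([10]))
        probs, _ = policy.step_probs(np.zeros((1, 16)), policy.init_state(1), mask)
        assert np.allclose(probs, 1.0 / 11)

    def test_oversized_endowment_rejected(self):
        with pytest.raises(ValueError, match="11-way"):
            endowment_mask(np.array([12]))

    def test_sampled_contributions_respect_mask(self):
        policy = ContributionPolicy(rng=1)
        agent = NeuralAgent(policy)
        config = GameConfig(endowments=(10, 2, 2, 2))
        trace = play_block(config, equal_split(),
                           [NeuralAgent(policy) for _ in range(4)], rng=5)
        for rec in trace.rounds:
            assert np.all(rec.contributions <= rec.endowments)
        assert agent is not None


class TestScriptedAgents:
    def _play(self, agent, e=(10, 2, 2, 2), focal=0, prev=None, seed=0):
        agent.reset(np.asarray(e, float), focal)
        return agent.act(prev, np.random.default_rng(seed))

    def test_full_contributor_gives_everything(self):
        assert self._play(FullContributor()) == 10
        assert self._play(FullContributor(), focal=1) == 2

    def test_free_rider_caps_at_twenty_percent(self):
        for seed in range(20):
            c = self._play(FreeRider(), seed=seed)
            assert c <= 2  # 0.2 * 10
        with pytest.raises(ValueError):
            FreeRider(frac=0.5)

    def test_conditional_cooperator_reciprocates(self):
        e = np.array([10.0, 10, 10, 10])
        rec = RoundRecord(endowments=e, contributions=np.array([0.0, 8, 8, 8]),
                          payouts=np.zeros(4))
        agent = ConditionalCooperator(noise=0.0)
        agent.reset(e, 0)
        assert agent.act(rec, np.random.default_rng(0)) == 8  # mean others rho = 0.8
        agent.reset(e, 0)
        assert agent.act(None, np.random.default_rng(0)) == 5  # init ratio 0.5

    def test_noisy_uniform_in_range(self):
        for seed in range(20):
            assert 0 <= self._play(NoisyUniform(), seed=seed) <= 10

    def test_mixture_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            ScriptedAgentSpec(mixture={"free_rider": 0.5})
        with pytest.raises(ValueError, match="unknown archetype"):
            ScriptedAgentSpec(mixture={"altruist": 1.0})


class TestCorpus:
    def test_full_contributor_targets_equal_endowments(self):
        spec = ScriptedAgentSpec(mixture={"full_contributor": 1.0})
        corpus = generate_synthetic_corpus(spec, GameConfig(), 10, seed=0)
        assert np.array_equal(corpus.targets,
                              np.tile(corpus.focal_endowments[:, None], (1, 10)))

    def test_mixture_mean_relative_contribution(self):
        # 50/50 free riders (~0.1 of endowment) and full contributors (1.0)
        spec = ScriptedAgentSpec(mixture={"free_rider": 0.5,
                                          "full_contributor": 0.5})
        corpus = generate_synthetic_corpus(spec, GameConfig(endowments=(10,) * 4),
                                           200, seed=1)
        rel = corpus.targets / corpus.focal_endowments[:, None]
        assert rel.mean() == pytest.approx(0.55, abs=0.04)

    def test_same_seed_identical_corpora(self):
        spec = ScriptedAgentSpec()
        c1 = generate_synthetic_corpus(spec, GameConfig(), 15, seed=3)
        c2 = generate_synthetic_corpus(spec, GameConfig(), 15, seed=3)
        assert np.array_equal(c1.targets, c2.targets)
        assert np.array_equal(c1.obs, c2.obs)
        assert c1.archetypes == c2.archetypes

    def test_invalid_game_count(self):
        with pytest.raises(ValueError, match="positive"):
            generate_synthetic_corpus(ScriptedAgentSpec(), GameConfig(), 0, seed=0)

    def test_split_is_disjoint_and_by_game(self):
        corpus = generate_synthetic_corpus(ScriptedAgentSpec(), GameConfig(),
                                           30, seed=2)
        assert set(corpus.train_idx).isdisjoint(corpus.val_idx)
        assert len(corpus.train_idx) + len(corpus.val_idx) == len(corpus)
        # all four seats of a game land on the same side of the split
        games_val = set(i // 4 for i in corpus.val_idx)
        games_train = set(i // 4 for i in corpus.train_idx)
        assert games_val.isdisjoint(games_train)

    def test_dataframe_has_focal_column(self):
        corpus = generate_synthetic_corpus(ScriptedAgentSpec(), GameConfig(),
                                           5, seed=4)
        df = corpus.to_dataframe()
        assert "focal" in df.columns
        assert len(df) == 5 * 10 * 4


class TestImitation:
    def test_recovers_full_contributor_rule(self):
        spec = ScriptedAgentSpec(mixture={"full_contributor": 1.0})
        corpus = generate_synthetic_corpus(spec, GameConfig(), 60, seed=5,
                                           tail_endowments=(2, 6, 10))
        policy, curves = imitation_train(corpus, ImitationTrainConfig(
            n_updates=250, batch_size=64, seed=0, log_every=250))
        assert top1_agreement(policy, corpus) == pytest.approx(1.0)
        assert curves["val_ce"].iloc[-1] < constant_baseline_cross_entropy(corpus)

    def test_entropy_bonus_keeps_distribution_soft(self):
        # single-state single-action corpus: without the bonus the policy
        # would collapse to a point mass; the entropy term keeps a floor
        spec = ScriptedAgentSpec(mixture={"full_contributor": 1.0})
        corpus = generate_synthetic_corpus(spec, GameConfig(endowments=(10,) * 4),
                                           20, seed=6)
        policy, _ = imitation_train(corpus, ImitationTrainConfig(
            n_updates=400, batch_size=32, seed=0, log_every=400))
        mask = endowment_mask(np.array([10]))
        probs, _ = policy.step_probs(corpus.obs[0, :1, :], policy.init_state(1),
                                     mask)
        assert probs.max() < 1.0 - 1e-6

    def test_same_seed_identical_parameters(self):
        spec = ScriptedAgentSpec(mixture={"free_rider": 1.0})
        corpus = generate_synthetic_corpus(spec, GameConfig(), 20, seed=7)
        cfg = ImitationTrainConfig(n_updates=30, batch_size=16, seed=9,
                                   log_every=30)
        p1, _ = imitation_train(corpus, cfg)
        p2, _ = imitation_train(corpus, cfg)
        for key in p1.params:
            assert np.array_equal(p1.params[key].data, p2.params[key].data)

    def test_empty_corpus_rejected(self, cc_corpus):
        import dataclasses

        empty = dataclasses.replace(cc_corpus, obs=cc_corpus.obs[:0],
                                    targets=cc_corpus.targets[:0],
                                    focal_endowments=cc_corpus.focal_endowments[:0])
        with pytest.raises(ValueError, match="empty"):
            imitation_train(empty, ImitationTrainConfig(n_updates=1))


class TestPolicyPersistence:
    def test_container_round_trip_preserves_forward(self):
        policy = ContributionPolicy(rng=substream(0, "persist"))
        container = policy.to_container()
        restored = ContributionPolicy.from_container(container)
        obs = np.random.default_rng(0).random((3, 16))
        mask = endowment_mask(np.array([10, 4, 7]))
        p1, _ = policy.step_probs(obs, policy.init_state(3), mask)
        p2, _ = restored.step_probs(obs, restored.init_state(3), mask)
        assert np.array_equal(p1, p2)

    def test_bad_container_rejected(self):
        with pytest.raises(ValueError, match="not a contribution policy"):
            ContributionPolicy.from_container({"kind": "other"})
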