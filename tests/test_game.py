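"""Game engine: round resolution, blocks, sessions, welfare metrics, I/O."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mechvote.game import (GameConfig, gini, play_block, play_round,
                           run_session, session_to_dataframe, surplus,
                           trace_from_jsonl, trace_to_dataframe,
                           trace_to_jsonl)
from mechvote.mechanisms import (ManifoldMechanism, ManifoldParams, canonical,
                                 equal_split)
from mechvote.players import ConditionalCooperator, FullContributor
from mechvote.voting import VotingModelParams


def _mech(name):
    return ManifoldMechanism(canonical(name), name=f"canonical:{name}")


class _Never:
    def reset(self, endowments, focal):
        pass

    def act(self, prev, rng):
        return 0


class TestPlayRound:
    def test_equal_split_payouts(self):
        config = GameConfig(endowments=(10, 10, 10, 10))
        rec = play_round([4, 4, 4, 4], config, equal_split())
        assert np.allclose(rec.payouts, 6.4)          # r*C = 25.6 split 4 ways
        assert np.allclose(rec.returns, 12.4)         # y + e - c

    def test_empty_fund(self):
        rec = play_round([0, 0, 0, 0], GameConfig(), equal_split())
        assert np.allclose(rec.payouts, 0.0)
        assert np.allclose(rec.returns, GameConfig().endowment_array)

    def test_return_is_payout_plus_endowment_minus_contribution(self):
        config = GameConfig(endowments=(10, 10, 10, 10))
        rec = play_round([4, 0, 0, 0], config, _mech("liberal_egalitarian"))
        # focal player receives the whole fund back: y = 1.6*4 = 6.4
        assert rec.returns[0] == pytest.approx(rec.payouts[0] + 10 - 4)

    @pytest.mark.parametrize("contributions,msg", [
        ([4.5, 0, 0, 0], "player 0"),
        ([0, 3, 0, 0], "player 1"),       # above tail endowment of 2
        ([0, -1, 0, 0], "player 1"),
    ])
    def test_invalid_contribution_names_offender(self, contributions, msg):
        with pytest.raises(ValueError, match=msg):
            play_round(contributions, GameConfig(), equal_split())

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            play_round([1, 1, 1], GameConfig(), equal_split())

    def test_conservation_asserted(self):
        # a synthetic broken mechanism that silently destroys half the fund
        mech = ManifoldMechanism(ManifoldParams(0, 1))
        original = mech.weights

        def halved(e, c):
            w = original(e, c)
            object.__setattr__(w, "weights", w.weights * 0.5)
            return w

        mech.weights = halved
        with pytest.raises(AssertionError, match="conservation"):
            play_round([2, 2, 2, 2], GameConfig(), mech)


class TestPlayBlock:
    def test_full_contribution_under_libertarian(self):
        config = GameConfig()
        agents = [FullContributor() for _ in range(4)]
        trace = play_block(config, _mech("libertarian"), agents, rng=0)
        for rec in trace.rounds:
            assert np.allclose(rec.payouts, 1.6 * config.endowment_array)
        assert surplus(trace) == pytest.approx(1.6)

    def test_no_contribution_surplus_one(self):
        trace = play_block(GameConfig(), equal_split(), [_Never()] * 4, rng=0)
        assert all(np.all(r.contributions == 0) for r in trace.rounds)
        assert surplus(trace) == pytest.approx(1.0)

    def test_fixed_seed_reproducible(self):
        def run():
            agents = [ConditionalCooperator() for _ in range(4)]
            return play_block(GameConfig(), _mech("liberal_egalitarian"),
                              agents, rng=42)

        t1, t2 = run(), run()
        for r1, r2 in zip(t1.rounds, t2.rounds):
            assert np.array_equal(r1.contributions, r2.contributions)
            assert np.array_equal(r1.payouts, r2.payouts)

    def test_mask_violation_rejected(self):
        class Cheater(_Never):
            def act(self, prev, rng):
                return 5  # above the tail endowment of 2

        agents = [_Never(), Cheater(), _Never(), _Never()]
        with pytest.raises(ValueError, match="agent 1"):
            play_block(GameConfig(), equal_split(), agents, rng=0)


class TestSession:
    def _session(self, order="AB", seed=0):
        agents = [ConditionalCooperator() for _ in range(4)]
        return run_session(GameConfig(), _mech("libertarian"),
                           _mech("liberal_egalitarian"), agents, order,
                           VotingModelParams(), rng=seed)

    def test_structure(self):
        s = self._session()
        assert len(s.block1) == 10 and len(s.block2) == 10 and len(s.block3) == 10
        assert len(s.block4) == 4
        assert s.block1.mechanism_id == "canonical:strict_egalitarian"
        assert s.elected_mechanism_id in ("canonical:libertarian",
                                          "canonical:liberal_egalitarian")

    def test_counterbalance_swaps_blocks(self):
        ab = self._session("AB")
        ba = self._session("BA")
        assert ab.block2.mechanism_id == "canonical:libertarian"
        assert ba.block2.mechanism_id == "canonical:liberal_egalitarian"

    def test_unanimous_vote_is_deterministic(self):
        # full contributors under libertarian earn strictly more relative
        # payout than under strict egalitarian with unequal endowments, so
        # a lopsided rpay gap makes all four sampled votes agree
        agents = [FullContributor() for _ in range(4)]
        for seed in range(5):
            s = run_session(GameConfig(endowments=(10, 10, 10, 10)),
                            _mech("libertarian"), _mech("liberal_egalitarian"),
                            agents, "AB", VotingModelParams(s=100.0), rng=seed)
            if s.vote.votes_for_a == 4:
                assert s.elected_mechanism_id == "canonical:libertarian"
            elif s.vote.votes_for_a == 0:
                assert s.elected_mechanism_id == "canonical:liberal_egalitarian"

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            self._session("XY")


class TestGini:
    @pytest.mark.parametrize("values,expected", [
        ((10, 2, 2, 2), 0.375),
        ((5, 5, 5, 5), 0.0),
        ((1, 0, 0, 0), 0.75),
    ])
    def test_known_values(self, values, expected):
        assert gini(values) == pytest.approx(expected)

    def test_most_unequal_condition_rounds_to_038(self):
        assert round(gini((10, 2, 2, 2)), 2) == 0.38

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            gini([0, 0, 0])

    @given(st.lists(st.integers(min_value=0, max_value=50), min_size=2,
                    max_size=8).filter(lambda v: sum(v) > 0))
    @settings(max_examples=50, deadline=None)
    def test_matches_pairwise_oracle(self, values):
        x = np.asarray(values, dtype=float)
        n = x.size
        brute = sum(abs(a - b) for a in x for b in x) / (2 * n * n * x.mean())
        assert gini(x) == pytest.approx(brute)
        assert 0 <= gini(x) < 1


class TestSurplusBounds:
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=20, deadline=None)
    def test_surplus_within_bounds_for_conserving_mechanisms(self, seed):
        rng = np.random.default_rng(seed)
        params = ManifoldParams(v=float(rng.random()), w=float(rng.random()))
        agents = [ConditionalCooperator() for _ in range(4)]
        trace = play_block(GameConfig(), ManifoldMechanism(params), agents,
                           rng=rng)
        assert 1.0 - 1e-9 <= surplus(trace) <= 1.6 + 1e-9


class TestSerialization:
    def test_jsonl_round_trip(self, tmp_path):
        agents = [ConditionalCooperator() for _ in range(4)]
        trace = play_block(GameConfig(), equal_split(), agents, rng=3)
        path = tmp_path / "trace.jsonl"
        trace_to_jsonl(trace, path)
        loaded = trace_from_jsonl(path)
        assert loaded.mechanism_id == trace.mechanism_id
        for r1, r2 in zip(trace.rounds, loaded.rounds):
            assert np.array_equal(r1.contributions, r2.contributions)
            assert np.allclose(r1.payouts, r2.payouts)

    def test_session_csv_is_34_rounds_per_player(self):
        agents = [ConditionalCooperator() for _ in range(4)]
        s = run_session(GameConfig(), _mech("libertarian"),
                        _mech("liberal_egalitarian"), agents, "AB",
                        VotingModelParams(), rng=0)
        df = session_to_dataframe(s)
        assert len(df) == 4 * 34
        assert set(df.columns) >= {"session", "block", "round", "player",
                                   "endowment", "contribution", "payout",
                                   "return"}
        per_player = df.groupby("player")["round"].count()
        assert (per_player == 34).all()

    def test_trace_dataframe_conserves_fund(self):
        agents = [ConditionalCooperator() for _ in range(4)]
        trace = play_block(GameConfig(), equal_split(), agents, rng=5)
        df = trace_to_dataframe(trace)
        by_round = df.groupby("round").agg({"payout": "sum", "contribution": "sum"})
        assert np.allclose(by_round["payout"], 1.6 * by_round["contribution"])


class TestConfigValidation:
    def test_mpcr(self):
        assert GameConfig().mpcr == pytest.approx(0.4)

    @pytest.mark.parametrize("kwargs", [
        {"k": 1},
        {"r": 0.0},
        {"endowments": (10, 2, 2)},
        {"endowments": (10, 2, 2, 0)},
        {"endowments": (10, 2.5, 2, 2)},
    ])
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GameConfig(**kwargs)
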