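import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plebeian.corpus import Corpus, Post, Thread
from plebeian.moderation import (
    FlagConfig,
    FlagResult,
    JuryConfig,
    ThreadByte,
    dequantize,
    encode_thread_byte,
    flag_phase,
    interval_sweep,
    panel_size_for,
    quantize_mean,
    run_jury,
    select_jury,
    update_thread_byte,
)
from plebeian.sentiment import PolarityScore
from plebeian.synthetic import SyntheticConfig, generate_corpus, user_population


def _score(c):
    return PolarityScore(compound=c)


def _thread(root_compound, comment_compounds, views=1000):
    root = Post(post_id="r", text="t", views=views)
    comments = [
        Post(post_id=f"c{i}", text="t", parent_id="r")
        for i in range(len(comment_compounds))
    ]
    scores = {"r": _score(root_compound)}
    scores.update({f"c{i}": _score(c) for i, c in enumerate(comment_compounds)})
    return Thread(root=root, comments=comments), scores


class TestFlagPhase:
    def test_below_threshold_not_eligible(self, rng):
        thread, scores = _thread(-0.6, [-0.5, -0.4], views=10)
        res = flag_phase(thread, scores, FlagConfig(v_thres=100), rng)
        assert not res.eligible and not res.flagged
        assert res.sampled_comment_ids == []

    def test_negative_thread_flagged(self, rng):
        thread, scores = _thread(-0.6, [-0.5, -0.7, -0.4])
        res = flag_phase(thread, scores, FlagConfig(v_thres=100), rng)
        assert res.eligible and res.flagged
        assert res.mean_compound < 0

    def test_positive_thread_not_flagged(self, rng):
        thread, scores = _thread(0.3, [0.3, 0.3, 0.3])
        res = flag_phase(thread, scores, FlagConfig(v_thres=100), rng)
        assert res.eligible and not res.flagged

    def test_unscorable_root_raises(self, rng):
        thread, scores = _thread(-0.6, [-0.5])
        scores["r"] = PolarityScore(compound=0.0, inconclusive=True)
        with pytest.raises(ValueError, match="unscorable root"):
            flag_phase(thread, scores, FlagConfig(v_thres=100), rng)

    def test_sample_capped_and_without_replacement(self, rng):
        thread, scores = _thread(-0.1, [-0.2] * 50)
        res = flag_phase(
            thread, scores, FlagConfig(v_thres=100, comment_sample_size=10), rng
        )
        assert len(res.sampled_comment_ids) == 10
        assert len(set(res.sampled_comment_ids)) == 10

    def test_same_seed_same_sample(self):
        thread, scores = _thread(-0.1, [-0.2] * 50)
        config = FlagConfig(v_thres=100, comment_sample_size=5)
        r1 = flag_phase(thread, scores, config, np.random.default_rng(9))
        r2 = flag_phase(thread, scores, config, np.random.default_rng(9))
        assert r1.sampled_comment_ids == r2.sampled_comment_ids

    def test_mean_is_unweighted_root_plus_sample(self, rng):
        thread, scores = _thread(-0.6, [0.2, 0.2])
        res = flag_phase(
            thread, scores, FlagConfig(v_thres=100, comment_sample_size=100), rng
        )
        assert res.mean_compound == pytest.approx((-0.6 + 0.2 + 0.2) / 3)

    def test_flagged_implies_eligible_invariant(self):
        with pytest.raises(ValueError):
            FlagResult(
                thread_id="x", eligible=False, sampled_comment_ids=[],
                mean_compound=-1.0, flagged=True,
            )


class TestSelectJury:
    @pytest.mark.parametrize(
        "viewers,expected", [(1, 1), (9, 1), (10, 1), (95, 10), (1000, 100)]
    )
    def test_panel_size_law(self, viewers, expected):
        assert panel_size_for(viewers) == expected

    def test_selection_without_replacement(self, rng):
        pool = user_population(200)
        panel = select_jury(1000, pool, rng)
        assert len(panel) == 100
        assert len(set(panel)) == 100
        assert set(panel) <= set(pool)

    def test_population_too_small(self, rng):
        with pytest.raises(ValueError, match="too small"):
            select_jury(1000, user_population(50), rng)

    def test_reproducible(self):
        pool = user_population(500)
        p1 = select_jury(200, pool, np.random.default_rng(3))
        p2 = select_jury(200, pool, np.random.default_rng(3))
        assert p1 == p2

    def test_approximately_uniform(self):
        pool = user_population(20)
        counts = {u: 0 for u in pool}
        rng = np.random.default_rng(0)
        for _ in range(2000):
            for u in select_jury(95, pool, rng):  # panels of 10 from 20
                counts[u] += 1
        freqs = np.array(list(counts.values())) / (2000 * 10)
        assert np.all(np.abs(freqs - 1 / 20) < 0.01)


class TestRunJury:
    def _flag(self):
        return FlagResult(
            thread_id="x", eligible=True, sampled_comment_ids=[],
            mean_compound=-0.5, flagged=True,
        )

    def test_strict_majority_removes(self):
        panel = [f"j{i}" for i in range(10)]
        votes = {f"j{i}": "remove" for i in range(7)}
        votes.update({f"j{i}": "keep" for i in range(7, 10)})
        v = run_jury(self._flag(), panel, votes, JuryConfig(quorum=10))
        assert v.removed and v.terminated_by == "quorum"
        assert (v.votes_remove, v.votes_keep) == (7, 3)

    def test_tie_keeps(self):
        panel = [f"j{i}" for i in range(10)]
        votes = {f"j{i}": "remove" for i in range(4)}
        votes.update({f"j{i}": "keep" for i in range(4, 8)})
        v = run_jury(self._flag(), panel, votes, JuryConfig(quorum=100))
        assert not v.removed
        assert v.terminated_by == "deadline"

    def test_no_votes_at_deadline_keeps(self):
        panel = [f"j{i}" for i in range(5)]
        v = run_jury(self._flag(), panel, {}, JuryConfig(quorum=3))
        assert not v.removed and v.terminated_by == "deadline"

    def test_abstentions_ignored(self):
        panel = ["a", "b", "c"]
        votes = {"a": "remove", "b": None, "c": "remove"}
        v = run_jury(self._flag(), panel, votes, JuryConfig(quorum=2))
        assert v.removed and v.votes_remove == 2 and v.votes_keep == 0

    def test_non_juror_vote_rejected(self):
        with pytest.raises(ValueError, match="non-juror"):
            run_jury(self._flag(), ["a"], {"zz": "remove"}, JuryConfig())

    def test_unflagged_thread_rejected(self):
        flag = FlagResult(
            thread_id="x", eligible=True, sampled_comment_ids=[],
            mean_compound=0.5, flagged=False,
        )
        with pytest.raises(ValueError):
            run_jury(flag, ["a"], {}, JuryConfig())

    def test_jury_fraction_fixed(self):
        with pytest.raises(ValueError):
            JuryConfig(fraction=0.2)


class TestThreadByte:
    @pytest.mark.parametrize("mean,beta", [(0.0, 64), (1.0, 127), (-1.0, 0)])
    def test_quantize_endpoints(self, mean, beta):
        assert quantize_mean(mean) == beta

    def test_byte_packing(self):
        tb = ThreadByte(phi_d=1, beta=100, shadow_mean=0.57, n_seen=3)
        assert tb.to_byte() == (1 << 7) | 100
        back = ThreadByte.from_byte(tb.to_byte(), shadow_mean=0.57, n_seen=3)
        assert (back.phi_d, back.beta) == (1, 100)
        assert 0 <= tb.to_byte() <= 255

    @given(st.floats(min_value=-1.0, max_value=1.0))
    @settings(max_examples=300, deadline=None)
    def test_quantization_error_bound(self, mean):
        beta = quantize_mean(mean)
        assert 0 <= beta <= 127
        assert abs(dequantize(beta) - mean) <= 1.0 / 127.0 + 1e-12

    def test_invalid_bits_rejected(self):
        with pytest.raises(ValueError):
            ThreadByte(phi_d=2)
        with pytest.raises(ValueError):
            ThreadByte(beta=128)


class TestEncodeThreadByte:
    def test_popular_nothing_new_skips(self):
        thread, scores = _thread(-0.2, [0.1, 0.3], views=1000)
        first = encode_thread_byte(thread, scores, v_thres=100)
        assert first.phi_d == 0  # all posts new
        again = encode_thread_byte(thread, scores, v_thres=100, prior=first)
        assert again.phi_d == 1  # nothing new -> n_d = 0 -> skip

    def test_popular_one_new_comment_analyzes(self):
        thread, scores = _thread(-0.2, [0.1], views=1000)
        prior = encode_thread_byte(thread, scores, v_thres=100)
        thread.comments.append(Post(post_id="c_new", text="t", parent_id="r"))
        scores["c_new"] = _score(0.5)
        nxt = encode_thread_byte(thread, scores, v_thres=100, prior=prior)
        assert nxt.phi_d == 0
        assert nxt.n_seen == prior.n_seen + 1

    def test_unpopular_thread_skips(self):
        thread, scores = _thread(-0.2, [0.1, 0.3], views=10)
        tb = encode_thread_byte(thread, scores, v_thres=100)
        assert tb.phi_d == 1  # sgn negative -> n_d < 0

    def test_shadow_mean_is_batch_mean(self):
        thread, scores = _thread(-0.6, [0.0, 0.3], views=10)
        tb = encode_thread_byte(thread, scores, v_thres=100)
        assert tb.shadow_mean == pytest.approx((-0.6 + 0.0 + 0.3) / 3)
        assert tb.beta == quantize_mean(tb.shadow_mean)


class TestUpdateThreadByte:
    def test_fixed_point(self):
        state = ThreadByte(phi_d=0, beta=quantize_mean(0.5), shadow_mean=0.5, n_seen=4)
        nxt = update_thread_byte(state, [0.5])
        assert nxt.shadow_mean == pytest.approx(0.5)
        assert nxt.beta == state.beta
        assert nxt.n_seen == 5

    @pytest.mark.parametrize("seed", range(10))
    def test_recursive_equals_batch_over_shuffles(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.uniform(-1, 1, 200)
        batch_mean = scores.mean()  # independent batch oracle
        shuffled = scores.copy()
        rng.shuffle(shuffled)
        state = ThreadByte(phi_d=0, beta=64, shadow_mean=0.0, n_seen=0)
        state = update_thread_byte(state, shuffled)
        assert abs(state.shadow_mean - batch_mean) < 1e-12

    def test_chunked_equals_single_pass(self, rng):
        scores = rng.uniform(-1, 1, 100)
        one = update_thread_byte(ThreadByte(), list(scores))
        two = update_thread_byte(
            update_thread_byte(ThreadByte(), list(scores[:37])), list(scores[37:])
        )
        assert two.shadow_mean == pytest.approx(one.shadow_mean, abs=1e-14)
        assert two.n_seen == one.n_seen == 100


class TestIntervalSweep:
    @pytest.fixture
    def swept(self, demo_corpus, demo_scores):
        corpus, _ = demo_corpus
        config = FlagConfig(v_thres=300, seed=0)
        state = {}
        first = interval_sweep(corpus, state, demo_scores, config)
        return corpus, state, config, first

    def test_second_sweep_analyzes_nothing(self, swept, demo_scores):
        corpus, state, config, first = swept
        assert first.n_analyzed > 0
        second = interval_sweep(corpus, state, demo_scores, config)
        assert second.n_analyzed == 0
        assert second.flags == []
        assert second.n_skipped == len(corpus)

    def test_new_comment_triggers_exactly_one(self, swept, demo_scores):
        corpus, state, config, _ = swept
        scores = dict(demo_scores)
        target = next(t for t in corpus.threads if t.v_act >= config.v_thres)
        new_post = Post(
            post_id="brand_new", text="t", parent_id=target.root.post_id
        )
        target.comments.append(new_post)
        scores["brand_new"] = _score(-0.4)
        result = interval_sweep(corpus, state, scores, config)
        assert result.n_analyzed == 1
        assert result.flags[0].thread_id == target.thread_id
        target.comments.pop()  # restore shared fixture

    def test_state_bytes_valid(self, swept):
        _, state, _, _ = swept
        for tb in state.values():
            assert 0 <= tb.to_byte() <= 255
            assert abs(dequantize(tb.beta) - tb.shadow_mean) <= 1 / 127 + 1e-12


class TestEnrichment:
    def test_flagged_precision_beats_base_rate(self):
        """Flagging enriches for misinformation on negativity-coupled corpora."""
        ratios = []
        for seed in range(20):
            corpus, _ = generate_corpus(
                SyntheticConfig(n_threads=150, seed=seed)
            )
            from plebeian.sentiment import score_corpus

            scores = dict(score_corpus(corpus))
            config = FlagConfig(v_thres=200, seed=seed)
            result = interval_sweep(corpus, {}, scores, config)
            flagged_roots = [
                f.thread_id for f in result.flags if f.flagged
            ]
            if not flagged_roots:
                continue
            labels = {t.root.post_id: t.root.misinfo_label for t in corpus.threads}
            precision = np.mean([labels[r] for r in flagged_roots])
            base = np.mean(list(labels.values()))
            ratios.append(precision / max(base, 1e-9))
        assert len(ratios) >= 15
        assert np.median(ratios) > 1.0
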