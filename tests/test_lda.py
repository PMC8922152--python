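import numpy as np
import pytest

from revtopics import (TopicModelParams, align_topics, build_dtm, fit_lda,
                       log_likelihood, primary_topics, select_num_topics,
                       top_words, topic_density)

FAST = dict(n_iterations=120, burn_in=40, sample_lag=4)


def block_corpus(seed=0, n_docs=100, doc_len=12):
    """Two disjoint 10-word vocabulary blocks; each doc drawn purely from one."""
    rng = np.random.default_rng(seed)
    block_a = [f"a{i:02d}" for i in range(10)]
    block_b = [f"b{i:02d}" for i in range(10)]
    docs = []
    for d in range(2 * n_docs):
        block = block_a if d % 2 == 0 else block_b
        docs.append(list(rng.choice(block, size=doc_len)))
    return build_dtm(docs), set(block_a), set(block_b)


class TestFitLda:
    def test_single_topic_closed_form(self):
        dtm = build_dtm([["a", "b", "a"], ["c", "b"]])
        m = fit_lda(dtm, TopicModelParams(n_topics=1, seed=3, **FAST))
        assert np.all(m.theta == 1.0)
        counts = np.asarray(dtm.counts.sum(axis=0)).ravel()
        expected = (counts + m.params.beta) / (dtm.total_tokens
                                               + dtm.n_terms * m.params.beta)
        assert np.allclose(m.phi[0], expected)

    def test_symmetric_single_token_theta(self):
        dtm = build_dtm([["aa"]])
        with pytest.warns(UserWarning, match="degenerate"):
            m = fit_lda(dtm, TopicModelParams(
                n_topics=2, alpha=1.0, beta=1.0, n_iterations=20000,
                burn_in=100, sample_lag=10, seed=1))
        assert np.allclose(m.theta[0], [0.5, 0.5], atol=0.02)

    def test_disjoint_blocks_recovered(self):
        dtm, block_a, block_b = block_corpus()
        m = fit_lda(dtm, TopicModelParams(n_topics=2, seed=7,
                                          n_iterations=300, burn_in=100,
                                          sample_lag=5))
        tops = [set(top_words(m, k, 10)) for k in range(2)]
        assert {frozenset(t) for t in tops} == {frozenset(block_a),
                                                frozenset(block_b)}

    def test_seeded_determinism(self):
        dtm, _, _ = block_corpus(n_docs=20)
        params = TopicModelParams(n_topics=2, seed=9, **FAST)
        a, b = fit_lda(dtm, params), fit_lda(dtm, params)
        assert np.array_equal(a.z, b.z)
        assert np.array_equal(a.phi, b.phi)
        assert np.array_equal(a.log_likelihood_trace, b.log_likelihood_trace)

    def test_count_cache_consistency_and_token_conservation(self):
        dtm, _, _ = block_corpus(n_docs=15)
        m = fit_lda(dtm, TopicModelParams(n_topics=3, seed=2, **FAST))
        m.check_consistency()
        assert m.n_k.sum() == dtm.total_tokens
        assert np.allclose(m.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(m.theta.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(m.phi > 0) and np.all(m.theta > 0)

    def test_empty_dtm_rejected(self):
        dtm = build_dtm([["a"]])
        dtm.counts = dtm.counts[:0]
        with pytest.raises(ValueError):
            fit_lda(dtm, TopicModelParams(n_topics=2, **FAST))


class TestLogLikelihood:
    def test_single_topic_reduction(self):
        dtm = build_dtm([["a", "b", "a"], ["c", "b"]])
        m = fit_lda(dtm, TopicModelParams(n_topics=1, seed=0, **FAST))
        manual = 0.0
        dense = dtm.counts.toarray()
        for d in range(dtm.n_docs):
            for v in range(dtm.n_terms):
                manual += dense[d, v] * np.log(m.phi[0, v])
        assert log_likelihood(m, dtm) == pytest.approx(manual)

    def test_uniform_model_closed_form(self):
        dtm = build_dtm([["a", "b"], ["c", "d"]])
        m = fit_lda(dtm, TopicModelParams(n_topics=2, seed=0, **FAST))
        m.phi = np.full_like(m.phi, 1.0 / dtm.n_terms)
        m.theta = np.full_like(m.theta, 0.5)
        assert log_likelihood(m, dtm) == pytest.approx(
            dtm.total_tokens * np.log(1.0 / dtm.n_terms))

    def test_structured_model_beats_single_topic(self):
        dtm, _, _ = block_corpus()
        m2 = fit_lda(dtm, TopicModelParams(n_topics=2, seed=1,
                                           n_iterations=300, burn_in=100,
                                           sample_lag=5))
        m1 = fit_lda(dtm, TopicModelParams(n_topics=1, seed=1, **FAST))
        assert log_likelihood(m2, dtm) > log_likelihood(m1, dtm)

    def test_vocabulary_mismatch_rejected(self):
        dtm = build_dtm([["a", "b"]])
        other = build_dtm([["a", "b", "c"]])
        m = fit_lda(dtm, TopicModelParams(n_topics=2, seed=0, **FAST))
        with pytest.raises(ValueError):
            log_likelihood(m, other)


class TestTopicDensity:
    def test_identical_rows(self):
        phi = np.array([[0.5, 0.5], [0.5, 0.5]])
        assert topic_density(phi) == pytest.approx(1.0)

    def test_disjoint_support(self):
        phi = np.array([[1.0, 0.0], [0.0, 1.0]])
        assert topic_density(phi) == pytest.approx(0.0)

    def test_hand_computed_cosine(self):
        phi = np.array([[1.0, 0.0], [0.5, 0.5]])
        assert topic_density(phi) == pytest.approx(1 / np.sqrt(2), abs=1e-4)

    def test_requires_two_topics(self):
        with pytest.raises(ValueError):
            topic_density(np.array([[1.0, 0.0]]))

    def test_mean_over_all_pairs(self):
        phi = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        expected = (0 + 1 / np.sqrt(2) + 1 / np.sqrt(2)) / 3
        assert topic_density(phi) == pytest.approx(expected)


class TestSelectNumTopics:
    def test_single_candidate_chosen(self):
        dtm, _, _ = block_corpus(n_docs=15)
        sel = select_num_topics(dtm, [4], TopicModelParams(seed=1, **FAST))
        assert sel.chosen_k == 4 and set(sel.scores) == {4}

    def test_scores_bounded(self):
        dtm, _, _ = block_corpus(n_docs=15)
        sel = select_num_topics(dtm, [2, 3], TopicModelParams(seed=1, **FAST))
        assert all(0.0 <= s <= 1.0 for s in sel.scores.values())

    def test_empty_and_invalid_candidates(self):
        dtm, _, _ = block_corpus(n_docs=5)
        with pytest.raises(ValueError):
            select_num_topics(dtm, [])
        with pytest.raises(ValueError):
            select_num_topics(dtm, [1, 2])


class TestPrimaryTopics:
    def test_argmax_and_tie_break(self):
        dtm, _, _ = block_corpus(n_docs=10)
        m = fit_lda(dtm, TopicModelParams(n_topics=2, seed=0, **FAST))
        m.n_dk = np.array([[5, 2], [3, 3]] * 10)
        out = primary_topics(m)
        assert [a.topic for a in out[:2]] == [0, 0]  # (3,3) tie -> topic 0

    def test_partition_property(self):
        dtm, _, _ = block_corpus(n_docs=10)
        dtm.dropped_doc_ids = ["gone"]
        m = fit_lda(dtm, TopicModelParams(n_topics=2, seed=0, **FAST))
        out = primary_topics(m)
        assigned = [a for a in out if a.topic is not None]
        missing = [a for a in out if a.topic is None]
        assert len(assigned) == dtm.n_docs
        assert [a.doc_id for a in missing] == ["gone"]


class TestTopWords:
    def test_requested_count_and_argmax(self):
        dtm, _, _ = block_corpus(n_docs=10)
        m = fit_lda(dtm, TopicModelParams(n_topics=2, seed=0, **FAST))
        assert len(top_words(m, 0, 30)) == 20  # min(n, V)
        assert len(top_words(m, 0, 5)) == 5
        assert top_words(m, 0, 1)[0] == m.terms[np.argmax(m.phi[0])]

    def test_tie_break_by_vocabulary_order(self):
        dtm = build_dtm([["a", "b", "c", "d"]])
        m = fit_lda(dtm, TopicModelParams(n_topics=2, seed=0, **FAST))
        m.phi = np.full_like(m.phi, 0.25)
        assert top_words(m, 0, 4) == m.terms

    def test_bad_topic_index(self):
        dtm, _, _ = block_corpus(n_docs=5)
        m = fit_lda(dtm, TopicModelParams(n_topics=2, seed=0, **FAST))
        with pytest.raises(IndexError):
            top_words(m, 5)


def test_align_topics_permutation():
    phi = np.array([[0.8, 0.1, 0.1], [0.1, 0.8, 0.1], [0.1, 0.1, 0.8]])
    shuffled = phi[[2, 0, 1]]
    perm, cos = align_topics(shuffled, phi)
    assert np.allclose(cos, 1.0)
    assert np.array_equal(perm, [1, 2, 0])
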