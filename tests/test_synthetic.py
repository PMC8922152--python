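import numpy as np
import pytest

from revtopics import generate_ground_truth, render_corpus
from revtopics.corpus_io import SPAM_MARKERS
from revtopics.synthetic import SyntheticConfig, make_vocabulary
from revtopics.stemming import porter_stem

from conftest import NO_CONTAMINATION


def small_config(**kw):
    base = dict(n_docs_per_drug={"a": 50}, n_topics=3, n_terms=30,
                doc_length_mean=20, seed=4,
                contamination_rates=dict(NO_CONTAMINATION))
    base.update(kw)
    return SyntheticConfig(**base)


class TestConfigValidation:
    @pytest.mark.parametrize("kw", [
        dict(n_docs_per_drug={"a": 0}),
        dict(doc_length_mean=0),
        dict(beta_gen=-1.0),
        dict(rating_noise_sd=-0.5),
        dict(contamination_rates={"spam": 0.6, "empty_comment": 0.5,
                                  "underage_or_missing_age": 0.0}),
        dict(rating_effects={0: 1.0}),  # does not cover all topics
    ])
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            small_config(**kw)


class TestGroundTruth:
    def test_single_topic_mixtures_degenerate(self):
        gt = generate_ground_truth(small_config(n_topics=1,
                                                rating_effects={0: 0.0}))
        assert np.all(gt.theta == 1.0)

    def test_seeded_determinism(self):
        c = small_config()
        a, b = generate_ground_truth(c), generate_ground_truth(c)
        assert np.array_equal(a.phi, b.phi)
        assert all(np.array_equal(x.words, y.words) and
                   np.array_equal(x.z, y.z) and x.rating_mean == y.rating_mean
                   for x, y in zip(a.docs, b.docs))

    def test_rows_are_stochastic_and_labels_in_range(self):
        gt = generate_ground_truth(small_config())
        assert np.allclose(gt.phi.sum(axis=1), 1.0, atol=1e-9)
        assert np.allclose(gt.theta.sum(axis=1), 1.0, atol=1e-9)
        for d in gt.docs:
            assert d.z.min() >= 0 and d.z.max() < 3
            assert len(d.z) == len(d.words) >= 1

    def test_topic_token_shares_match_mixing_weights(self):
        """Corpus-wide topic shares of z lie within 3 standard errors of the
        length-weighted mean of the document mixtures (Monte-Carlo tally)."""
        cfg = small_config(n_docs_per_drug={"a": 400}, doc_length_mean=100,
                           seed=13)
        gt = generate_ground_truth(cfg)
        lengths = np.array([len(d.z) for d in gt.docs])
        T = lengths.sum()
        for k in range(cfg.n_topics):
            observed = sum((d.z == k).sum() for d in gt.docs) / T
            theta_k = np.array([d.theta[k] for d in gt.docs])
            expected = float((lengths * theta_k).sum() / T)
            se = float(np.sqrt((lengths * theta_k * (1 - theta_k)).sum()) / T)
            assert abs(observed - expected) <= 3 * se


class TestRenderCorpus:
    def test_no_contamination_record_count(self):
        cfg = small_config(n_docs_per_drug={"a": 30, "b": 20})
        records, log = render_corpus(generate_ground_truth(cfg), cfg)
        assert len(records) == 50
        assert log.injected_totals() == {"spam": 0, "empty_comment": 0,
                                         "underage_or_missing_age": 0}

    def test_zero_noise_ratings_equal_configured_means(self):
        cfg = small_config(rating_noise_sd=0.0,
                           rating_effects={0: 1.2, 1: -0.6, 2: 0.0},
                           age_rating_shift={}, time_rating_shift={})
        gt = generate_ground_truth(cfg)
        records, _ = render_corpus(gt, cfg)
        expected = {0: 4, 1: 2, 2: 3}  # round-half-up of 3 + effect
        for doc, rec in zip(gt.docs, records):
            assert rec.rating == expected[doc.primary_topic]

    def test_all_zero_effects_give_constant_rating(self):
        cfg = small_config(rating_noise_sd=0.0,
                           rating_effects={0: 0.0, 1: 0.0, 2: 0.0},
                           age_rating_shift={}, time_rating_shift={})
        records, _ = render_corpus(generate_ground_truth(cfg), cfg)
        assert {r.rating for r in records} == {3}

    def test_spam_count_matches_rescan(self):
        cfg = small_config(n_docs_per_drug={"a": 200},
                           contamination_rates={"spam": 0.1,
                                                "empty_comment": 0.0,
                                                "underage_or_missing_age": 0.0})
        records, log = render_corpus(generate_ground_truth(cfg), cfg)
        rescan = sum(1 for r in records
                     if any(m in (r.comment or "").lower()
                            for m in SPAM_MARKERS))
        assert rescan == log.injected_totals()["spam"] > 0

    def test_byte_identical_rendering(self):
        cfg = small_config(contamination_rates={"spam": 0.05,
                                                "empty_comment": 0.05,
                                                "underage_or_missing_age": 0.05})
        gt = generate_ground_truth(cfg)
        a, _ = render_corpus(gt, cfg)
        b, _ = render_corpus(gt, cfg)
        assert a == b

    def test_token_conservation_through_cleaning(self):
        from revtopics import clean_and_tokenize
        cfg = small_config()
        gt = generate_ground_truth(cfg)
        records, _ = render_corpus(gt, cfg)
        for doc, rec in zip(gt.docs, records):
            assert len(clean_and_tokenize(rec.comment)) == len(doc.z)


def test_vocabulary_codes_are_porter_stable():
    terms = make_vocabulary(500)
    assert len(set(terms)) == 500
    assert all(porter_stem(t) == t for t in terms)
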