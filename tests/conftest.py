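import itertools
import math

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from revtopics import (TopicModelParams, fit_lda, generate_ground_truth,
                       preprocess_corpus, render_corpus)
from revtopics.synthetic import SyntheticConfig

settings.register_profile(
    "default", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow], deadline=None)
settings.load_profile("default")

NO_CONTAMINATION = {"spam": 0.0, "empty_comment": 0.0,
                    "underage_or_missing_age": 0.0}


def block_beta(n_topics: int, n_terms: int, high: float = 5.0,
               low: float = 0.01) -> np.ndarray:
    """Near-orthogonal topic-word Dirichlet concentrations: each topic owns
    a disjoint block of the vocabulary."""
    beta = np.full((n_topics, n_terms), low)
    width = n_terms // n_topics
    for k in range(n_topics):
        beta[k, k * width:(k + 1) * width] = high
    return beta


def separated_config(n_docs=400, n_topics=3, n_terms=50, doc_length=100,
                     seed=11) -> SyntheticConfig:
    return SyntheticConfig(
        n_docs_per_drug={"drug": n_docs}, n_topics=n_topics, n_terms=n_terms,
        beta_gen=block_beta(n_topics, n_terms), doc_length_mean=doc_length,
        contamination_rates=dict(NO_CONTAMINATION), seed=seed)


@pytest.fixture(scope="session")
def separated_corpus():
    """Well-separated synthetic corpus at recovery-test scale:
    K=3, V=50, 400 docs of ~100 tokens, no contaminants."""
    config = separated_config()
    gt = generate_ground_truth(config)
    records, _ = render_corpus(gt, config)
    dtm = preprocess_corpus([r.comment for r in records],
                            [r.record_id for r in records])
    return config, gt, dtm


@pytest.fixture(scope="session")
def separated_fit(separated_corpus):
    _, gt, dtm = separated_corpus
    params = TopicModelParams(n_topics=3, n_iterations=800, burn_in=300,
                              sample_lag=10, seed=2)
    return gt, dtm, fit_lda(dtm, params)


def exact_z_marginals(token_doc, token_word, n_docs, n_terms, n_topics,
                      alpha, beta) -> np.ndarray:
    """Token-level topic marginals by brute-force enumeration of the
    collapsed LDA joint p(z, w) over all K^T assignment vectors."""
    T = len(token_doc)
    marg = np.zeros((T, n_topics))
    for z in itertools.product(range(n_topics), repeat=T):
        z = np.asarray(z)
        n_dk = np.zeros((n_docs, n_topics))
        n_kv = np.zeros((n_topics, n_terms))
        for t in range(T):
            n_dk[token_doc[t], z[t]] += 1
            n_kv[z[t], token_word[t]] += 1
        logw = 0.0
        for d in range(n_docs):
            logw += sum(math.lgamma(n_dk[d, k] + alpha) for k in range(n_topics))
        for k in range(n_topics):
            logw += sum(math.lgamma(n_kv[k, v] + beta) for v in range(n_terms))
            logw -= math.lgamma(n_kv[k].sum() + n_terms * beta)
        w = math.exp(logw)
        for t in range(T):
            marg[t, z[t]] += w
    return marg / marg.sum(axis=1, keepdims=True)
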