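"""Latent Dirichlet allocation fitted by collapsed Gibbs sampling.

Each review is modeled as a mixture of K topics and each topic as a
distribution over vocabulary terms. The sampler integrates out the topic
mixtures (theta) and topic-word distributions (phi) and resamples every
token's topic from its full conditional

    p(z = k) ∝ (n_dk + alpha) * (n_kv + beta) / (n_k + V*beta)

with the current token excluded from all counts. phi and theta are
posterior-mean estimates averaged over post-burn-in thinned samples.

The number of topics is selected by a density criterion: mean pairwise
cosine similarity among the topic-word rows, minimized over candidate K
so that topics are distinct and independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from numba import njit
from scipy.optimize import linear_sum_assignment

from .preprocess import DocumentTermMatrix


@dataclass
class TopicModelParams:
    """Sampler configuration.

    ``alpha`` defaults to 50/K and ``beta`` to 0.1 (the usual collapsed
    Gibbs convention) when left as None.
    """

    n_topics: int = 5
    alpha: Optional[float] = None
    beta: float = 0.1
    n_iterations: int = 2000
    burn_in: int = 500
    sample_lag: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_topics < 1:
            raise ValueError("n_topics must be >= 1")
        if self.alpha is None:
            self.alpha = 50.0 / self.n_topics
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if not (0 <= self.burn_in < self.n_iterations):
            raise ValueError("need 0 <= burn_in < n_iterations")
        if self.sample_lag < 1:
            raise ValueError("sample_lag must be >= 1")


@njit(cache=False)
def _gibbs_kernel(token_doc, token_word, doc_len, K, V, D,
                  alpha, beta, n_iterations, burn_in, sample_lag, seed):
    np.random.seed(seed)
    T = token_doc.shape[0]
    z = np.empty(T, np.int64)
    n_dk = np.zeros((D, K), np.int64)
    n_kv = np.zeros((K, V), np.int64)
    n_k = np.zeros(K, np.int64)

    for t in range(T):
        k = np.random.randint(0, K)
        z[t] = k
        n_dk[token_doc[t], k] += 1
        n_kv[k, token_word[t]] += 1
        n_k[k] += 1

    phi_sum = np.zeros((K, V))
    theta_sum = np.zeros((D, K))
    z_tally = np.zeros((T, K), np.int64)
    ll_trace = np.empty(n_iterations)
    probs = np.empty(K)
    vbeta = V * beta
    n_samples = 0

    for sweep in range(n_iterations):
        for t in range(T):
            d = token_doc[t]
            w = token_word[t]
            k = z[t]
            n_dk[d, k] -= 1
            n_kv[k, w] -= 1
            n_k[k] -= 1

            total = 0.0
            for j in range(K):
                p = (n_dk[d, j] + alpha) * (n_kv[j, w] + beta) / (n_k[j] + vbeta)
                total += p
                probs[j] = total
            u = np.random.random() * total
            k_new = 0
            while k_new < K - 1 and probs[k_new] < u:
                k_new += 1

            z[t] = k_new
            n_dk[d, k_new] += 1
            n_kv[k_new, w] += 1
            n_k[k_new] += 1

        # collapsed log p(w | z) up to the additive prior constant
        ll = 0.0
        for j in range(K):
            for v in range(V):
                ll += math.lgamma(n_kv[j, v] + beta)
            ll -= math.lgamma(n_k[j] + vbeta)
        ll += K * math.lgamma(vbeta) - K * V * math.lgamma(beta)
        ll_trace[sweep] = ll

        if sweep >= burn_in and (sweep - burn_in) % sample_lag == 0:
            n_samples += 1
            for j in range(K):
                denom = n_k[j] + vbeta
                for v in range(V):
                    phi_sum[j, v] += (n_kv[j, v] + beta) / denom
            for d in range(D):
                denom = doc_len[d] + K * alpha
                for j in range(K):
                    theta_sum[d, j] += (n_dk[d, j] + alpha) / denom
            for t in range(T):
                z_tally[t, z[t]] += 1

    return z, n_dk, n_kv, n_k, phi_sum, theta_sum, z_tally, ll_trace, n_samples


@dataclass
class TopicModel:
    """Fitted LDA state: final-sample assignments, count caches, and
    posterior-mean phi (topics x terms) and theta (docs x topics)."""

    params: TopicModelParams
    z: np.ndarray                 # final-sample topic of every token
    token_doc: np.ndarray
    token_word: np.ndarray
    n_dk: np.ndarray
    n_kv: np.ndarray
    n_k: np.ndarray
    phi: np.ndarray
    theta: np.ndarray
    z_marginals: np.ndarray       # tokens x K: marginal assignment frequencies
    log_likelihood_trace: np.ndarray
    n_samples_averaged: int
    doc_ids: list[str]
    dropped_doc_ids: list[str]
    terms: list[str]

    @property
    def n_topics(self) -> int:
        return self.phi.shape[0]

    def check_consistency(self) -> None:
        """Audit that the count caches agree with the retained z sample."""
        K, V = self.n_kv.shape
        n_dk = np.zeros_like(self.n_dk)
        n_kv = np.zeros_like(self.n_kv)
        np.add.at(n_dk, (self.token_doc, self.z), 1)
        np.add.at(n_kv, (self.z, self.token_word), 1)
        if not (np.array_equal(n_dk, self.n_dk) and np.array_equal(n_kv, self.n_kv)
                and np.array_equal(n_kv.sum(axis=1), self.n_k)):
            raise AssertionError("count caches inconsistent with z")


def _tokens_from_dtm(dtm: DocumentTermMatrix) -> tuple[np.ndarray, np.ndarray]:
    coo = dtm.counts.tocoo()
    order = np.lexsort((coo.col, coo.row))  # row-major token stream
    reps = coo.data[order].astype(np.int64)
    token_doc = np.repeat(coo.row[order].astype(np.int64), reps)
    token_word = np.repeat(coo.col[order].astype(np.int64), reps)
    return token_doc, token_word


def fit_lda(dtm: DocumentTermMatrix, params: TopicModelParams) -> TopicModel:
    """Fit LDA on a DTM by collapsed Gibbs sampling.

    Deterministic given (dtm, params): the seed drives initialization and
    every sweep. Raises on an empty DTM; warns when K exceeds the token
    count (legal but degenerate).
    """
    if dtm.n_docs == 0 or dtm.total_tokens == 0:
        raise ValueError("cannot fit LDA on an empty document-term matrix")
    if np.any(dtm.doc_lengths == 0):
        raise ValueError("DTM contains empty documents")
    if params.n_topics > dtm.total_tokens:
        warnings.warn("more topics than tokens: model is degenerate", stacklevel=2)

    token_doc, token_word = _tokens_from_dtm(dtm)
    doc_len = dtm.doc_lengths
    K, V, D = params.n_topics, dtm.n_terms, dtm.n_docs

    (z, n_dk, n_kv, n_k, phi_sum, theta_sum, z_tally, ll_trace,
     n_samples) = _gibbs_kernel(
        token_doc, token_word, doc_len, K, V, D,
        float(params.alpha), float(params.beta),
        params.n_iterations, params.burn_in, params.sample_lag,
        int(params.seed) % (2 ** 31),
    )

    phi = phi_sum / n_samples
    theta = theta_sum / n_samples
    return TopicModel(
        params=params, z=z, token_doc=token_doc, token_word=token_word,
        n_dk=n_dk, n_kv=n_kv, n_k=n_k, phi=phi, theta=theta,
        z_marginals=z_tally / n_samples, log_likelihood_trace=ll_trace,
        n_samples_averaged=int(n_samples),
        doc_ids=list(dtm.doc_ids), dropped_doc_ids=list(dtm.dropped_doc_ids),
        terms=list(dtm.vocabulary.terms),
    )


def log_likelihood(model: TopicModel, dtm: DocumentTermMatrix) -> float:
    """Held-in log predictive likelihood: sum over tokens of
    log(sum_k theta[d,k] phi[k,w])."""
    if dtm.n_terms != model.phi.shape[1]:
        raise ValueError("vocabulary size mismatch between model and DTM")
    if dtm.n_docs != model.theta.shape[0]:
        raise ValueError("document count mismatch between model and DTM")
    csr = dtm.counts.tocsr()
    ll = 0.0
    for d in range(dtm.n_docs):
        cols = csr.indices[csr.indptr[d]:csr.indptr[d + 1]]
        cnts = csr.data[csr.indptr[d]:csr.indptr[d + 1]]
        probs = model.theta[d] @ model.phi[:, cols]
        ll += float(np.dot(cnts, np.log(probs)))
    return ll


def topic_density(phi: np.ndarray) -> float:
    """Mean cosine similarity over all unordered pairs of topic-word rows.

    Lies in [0, 1] for non-negative rows; lower means more distinct topics.
    Undefined for fewer than two topics.
    """
    phi = np.asarray(phi, dtype=float)
    K = phi.shape[0]
    if K < 2:
        raise ValueError("topic density requires at least 2 topics")
    norms = np.linalg.norm(phi, axis=1)
    sims = (phi @ phi.T) / np.outer(norms, norms)
    iu = np.triu_indices(K, k=1)
    return float(np.mean(sims[iu]))


@dataclass
class TopicNumberSelection:
    scores: dict[int, float]      # candidate K -> density
    chosen_k: int


def select_num_topics(dtm: DocumentTermMatrix, candidates: Sequence[int],
                      params_template: TopicModelParams | None = None
                      ) -> TopicNumberSelection:
    """Fit one model per candidate K and choose the K minimizing density.

    All candidate fits use the template's seed, sweeps and priors (alpha
    rescaled as 50/K when the template leaves it at its default). The full
    per-K score table is returned for plotting. Ties go to the smaller K.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("empty candidate list")
    if any(k < 2 for k in candidates):
        raise ValueError("topic-number candidates must all be >= 2")
    template = params_template or TopicModelParams()
    rescale_alpha = template.alpha == 50.0 / template.n_topics
    scores: dict[int, float] = {}
    for k in sorted(set(candidates)):
        params = TopicModelParams(
            n_topics=k,
            alpha=(None if rescale_alpha else template.alpha),
            beta=template.beta, n_iterations=template.n_iterations,
            burn_in=template.burn_in, sample_lag=template.sample_lag,
            seed=template.seed,
        )
        scores[k] = topic_density(fit_lda(dtm, params).phi)
    chosen = min(scores, key=lambda k: (scores[k], k))
    return TopicNumberSelection(scores=scores, chosen_k=chosen)


@dataclass
class PrimaryTopicAssignment:
    """Per-document primary topic: the topic holding the largest number of
    the document's token assignments in the final retained sample; None for
    documents dropped before modeling."""

    doc_id: str
    topic: Optional[int]


def primary_topics(model: TopicModel) -> list[PrimaryTopicAssignment]:
    """Assign each document the topic with the largest token count
    (ties -> lowest topic index); dropped documents get a missing topic."""
    winners = np.argmax(model.n_dk, axis=1)  # argmax takes the lowest index on ties
    out = [PrimaryTopicAssignment(doc_id, int(k))
           for doc_id, k in zip(model.doc_ids, winners)]
    out.extend(PrimaryTopicAssignment(doc_id, None)
               for doc_id in model.dropped_doc_ids)
    return out


def top_words(model: TopicModel, topic: int, n: int = 30) -> list[str]:
    """The n terms with largest phi[topic, .], descending; ties broken by
    vocabulary order. Returns min(n, V) terms."""
    if not (0 <= topic < model.n_topics):
        raise IndexError(f"topic index {topic} out of range")
    phi_row = model.phi[topic]
    order = np.argsort(-phi_row, kind="stable")
    return [model.terms[i] for i in order[: min(n, len(phi_row))]]


def align_topics(phi_fit: np.ndarray, phi_ref: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of fitted topics to reference topics by cosine
    similarity. Returns (permutation, per-pair cosine) where
    ``phi_fit[permutation[j]]`` corresponds to ``phi_ref[j]``."""
    a = phi_fit / np.linalg.norm(phi_fit, axis=1, keepdims=True)
    b = phi_ref / np.linalg.norm(phi_ref, axis=1, keepdims=True)
    sim = a @ b.T
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(len(cols), dtype=int)
    perm[cols] = rows
    return perm, sim[rows, cols][np.argsort(cols)]
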