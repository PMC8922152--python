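"""Text preprocessing: from raw review comments to a document-term matrix.

The chain is: case-fold and strip punctuation/digits -> tokenize on
whitespace -> drop short tokens -> fix known typos -> merge listed bigrams
into single ``a_b`` tokens -> remove stopwords -> stem (Porter) and
complete each stem to its most frequent surface form -> tally counts.

Every step is a pure function of (input, config), so the emitted matrix is
bit-reproducible.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import scipy.io
import scipy.sparse as sp
from sklearn.feature_extraction.text import ENGLISH_STOP_WORDS

from .stemming import porter_stem

#: default bigram inventory merged before stemming
DEFAULT_BIGRAMS = (("erectile", "dysfunction"), ("side", "effect"))

_STRIP_RE = re.compile(r"[^a-z\s]+")


@dataclass
class PreprocessConfig:
    """Configuration of the preprocessing chain.

    ``stopwords=None`` selects the packaged standard English list;
    pass an explicit set (possibly empty) to override. ``typo_map``
    rewrites whole tokens after cleaning, before bigram merging.
    """

    stopwords: Optional[frozenset] = None
    bigrams: Sequence[tuple[str, str]] = DEFAULT_BIGRAMS
    typo_map: Mapping[str, str] = field(default_factory=dict)
    min_token_len: int = 2
    case_fold: bool = True

    def __post_init__(self) -> None:
        for pair in self.bigrams:
            if len(pair) != 2 or any(w != w.lower() for w in pair):
                raise ValueError(f"bigram pairs must be lowercase word pairs: {pair!r}")
        if len(set(self.bigrams)) != len(tuple(self.bigrams)):
            raise ValueError("duplicate bigram pairs")

    def stopword_set(self) -> frozenset:
        if self.stopwords is None:
            return frozenset(ENGLISH_STOP_WORDS)
        return frozenset(self.stopwords)


@dataclass
class Vocabulary:
    """Ordered vocabulary with term -> index and term -> corpus frequency maps."""

    terms: list[str]
    index: dict[str, int]
    frequency: dict[str, int]

    def __len__(self) -> int:
        return len(self.terms)


@dataclass
class DocumentTermMatrix:
    """Sparse document x term count matrix aligned to surviving documents.

    ``doc_ids`` names the rows; ``dropped_doc_ids`` lists documents emptied
    by preprocessing (they carry no row and downstream get a missing
    primary topic).
    """

    counts: sp.csr_matrix
    vocabulary: Vocabulary
    doc_ids: list[str]
    dropped_doc_ids: list[str] = field(default_factory=list)

    @property
    def n_docs(self) -> int:
        return self.counts.shape[0]

    @property
    def n_terms(self) -> int:
        return self.counts.shape[1]

    @property
    def doc_lengths(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(np.int64)

    @property
    def total_tokens(self) -> int:
        return int(self.counts.sum())


def clean_and_tokenize(text: str, config: PreprocessConfig | None = None) -> list[str]:
    """Case-fold, delete punctuation/digit characters, split on whitespace.

    Tokens shorter than ``min_token_len`` are dropped; the typo map is then
    applied to whole tokens. Empty text yields an empty list.
    """
    config = config or PreprocessConfig()
    if config.case_fold:
        text = text.lower()
    text = _STRIP_RE.sub("", text)
    tokens = [t for t in text.split() if len(t) >= config.min_token_len]
    if config.typo_map:
        tokens = [config.typo_map.get(t, t) for t in tokens]
    return tokens


def merge_bigrams(tokens: Sequence[str],
                  bigrams: Iterable[tuple[str, str]]) -> list[str]:
    """Single left-to-right pass joining listed adjacent pairs with ``_``.

    A merged token is consumed and never re-merged with its successor.
    """
    pairs = set(tuple(p) for p in bigrams)
    if not pairs:
        return list(tokens)
    out: list[str] = []
    i = 0
    while i < len(tokens):
        if i + 1 < len(tokens) and (tokens[i], tokens[i + 1]) in pairs:
            out.append(tokens[i] + "_" + tokens[i + 1])
            i += 2
        else:
            out.append(tokens[i])
            i += 1
    return out


def remove_stopwords(tokens: Sequence[str], stopwords: Iterable[str]) -> list[str]:
    """Drop tokens that are members of the stopword set (whole-token match).

    Bigram-joined tokens contain ``_`` and never match single stopwords.
    """
    stop = set(stopwords)
    return [t for t in tokens if t not in stop]


def _stem_token(token: str) -> str:
    # bigram-joined tokens are stemmed component-wise
    if "_" in token:
        return "_".join(porter_stem(part) for part in token.split("_"))
    return porter_stem(token)


def stem_and_complete(documents: Sequence[Sequence[str]]
                      ) -> tuple[list[list[str]], dict[str, str]]:
    """Stem every token, then replace each stem by its dominant surface form.

    The completion of a stem is the surface form with the highest corpus
    frequency among all surface forms sharing that stem; ties go to the
    lexicographically smallest form. Returns the rewritten documents and
    the stem -> completion map.
    """
    if not documents:
        raise ValueError("corpus is empty")
    surface_freq: Counter = Counter()
    for doc in documents:
        surface_freq.update(doc)

    stem_of = {surface: _stem_token(surface) for surface in surface_freq}
    best: dict[str, str] = {}
    for surface in sorted(surface_freq):  # lexicographic order fixes ties
        stem = stem_of[surface]
        if stem not in best or surface_freq[surface] > surface_freq[best[stem]]:
            best[stem] = surface

    completed = [[best[stem_of[t]] for t in doc] for doc in documents]
    return completed, best


def build_dtm(documents: Sequence[Sequence[str]],
              doc_ids: Sequence[str] | None = None) -> DocumentTermMatrix:
    """Tally token counts into a sparse DTM.

    Vocabulary is ordered by descending corpus frequency, ties broken
    lexicographically. Documents emptied by preprocessing are dropped and
    reported via ``dropped_doc_ids``; an all-empty corpus is an error.
    """
    if doc_ids is None:
        doc_ids = [f"doc{i}" for i in range(len(documents))]
    if len(doc_ids) != len(documents):
        raise ValueError("doc_ids and documents length mismatch")

    freq: Counter = Counter()
    for doc in documents:
        freq.update(doc)
    if not freq:
        raise ValueError("all documents are empty after preprocessing")

    terms = sorted(freq, key=lambda t: (-freq[t], t))
    index = {t: i for i, t in enumerate(terms)}
    vocab = Vocabulary(terms=terms, index=index, frequency={t: freq[t] for t in terms})

    kept_rows: list[Counter] = []
    kept_ids: list[str] = []
    dropped: list[str] = []
    for doc_id, doc in zip(doc_ids, documents):
        if doc:
            kept_rows.append(Counter(doc))
            kept_ids.append(str(doc_id))
        else:
            dropped.append(str(doc_id))

    indptr = [0]
    indices: list[int] = []
    data: list[int] = []
    for row in kept_rows:
        for term in sorted(row, key=index.__getitem__):
            indices.append(index[term])
            data.append(row[term])
        indptr.append(len(indices))
    counts = sp.csr_matrix(
        (np.array(data, dtype=np.int64),
         np.array(indices, dtype=np.int64),
         np.array(indptr, dtype=np.int64)),
        shape=(len(kept_rows), len(terms)),
    )
    return DocumentTermMatrix(counts=counts, vocabulary=vocab,
                              doc_ids=kept_ids, dropped_doc_ids=dropped)


def preprocess_corpus(texts: Sequence[str], doc_ids: Sequence[str] | None = None,
                      config: PreprocessConfig | None = None) -> DocumentTermMatrix:
    """Run the full chain on raw comment texts and return the DTM."""
    config = config or PreprocessConfig()
    stop = config.stopword_set()
    docs = []
    for text in texts:
        tokens = clean_and_tokenize(text, config)
        tokens = merge_bigrams(tokens, config.bigrams)
        tokens = remove_stopwords(tokens, stop)
        docs.append(tokens)
    completed, _ = stem_and_complete(docs)
    return build_dtm(completed, doc_ids)


def save_dtm(dtm: DocumentTermMatrix, prefix: str | Path) -> None:
    """Serialize as MatrixMarket counts + vocabulary and doc-id text files."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix.with_suffix(".mtx")), dtm.counts)
    prefix.with_suffix(".vocab.txt").write_text(
        "\n".join(dtm.vocabulary.terms) + "\n", encoding="utf-8")
    meta = {"doc_ids": dtm.doc_ids, "dropped_doc_ids": dtm.dropped_doc_ids}
    prefix.with_suffix(".docs.json").write_text(
        json.dumps(meta, indent=2) + "\n", encoding="utf-8")


def load_dtm(prefix: str | Path) -> DocumentTermMatrix:
    prefix = Path(prefix)
    counts = sp.csr_matrix(scipy.io.mmread(str(prefix.with_suffix(".mtx"))))
    terms = prefix.with_suffix(".vocab.txt").read_text(encoding="utf-8").split()
    meta = json.loads(prefix.with_suffix(".docs.json").read_text(encoding="utf-8"))
    freq = np.asarray(counts.sum(axis=0)).ravel().astype(int)
    vocab = Vocabulary(terms=terms, index={t: i for i, t in enumerate(terms)},
                       frequency={t: int(f) for t, f in zip(terms, freq)})
    return DocumentTermMatrix(counts=counts, vocabulary=vocab,
                              doc_ids=list(meta["doc_ids"]),
                              dropped_doc_ids=list(meta["dropped_doc_ids"]))
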