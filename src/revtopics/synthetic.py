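"""Synthetic patient-review corpora with known topic structure.

Emulates the shape of scraped drug-review data: two drug cohorts of
unequal size, a handful of latent topics per drug, age and
time-on-medication strata whose topic prevalence differs, 1-5 satisfaction
ratings that depend on the review's primary topic, and a controlled dose
of ineligible records (spam URLs, empty comments, under-19 or missing
ages) to exercise the filters. Documents are token sequences over a
nonsense vocabulary — no attempt at English prose.

The generating process is exactly the model the analysis assumes: each
topic is a Dirichlet draw over the vocabulary, each document mixes topics
according to its stratum's Dirichlet concentration, and tokens are drawn
topic-first. Because the ground truth (phi, theta, z) is returned, every
downstream stage can be tested for recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .records import AGE_GROUPS, TIME_GROUPS, ReviewRecord

_AGE_RANGES = {"19-44": (19, 44), "45-64": (45, 64), "65+": (65, 88)}

#: Porter-stable consonant alphabet for synthetic vocabulary codes: no
#: vowels, so no stemming rule fires and the preprocessing chain is the
#: identity on clean tokens.
_CODE_ALPHABET = "bcfkmnprtv"


def make_vocabulary(size: int) -> list[str]:
    """Deterministic nonsense terms ("bbbb", "bbbc", ...) that survive
    cleaning, stopword removal and stemming unchanged."""
    n = len(_CODE_ALPHABET)
    if size > n ** 4:
        raise ValueError(f"vocabulary size {size} exceeds code space")
    terms = []
    for i in range(size):
        code = ""
        x = i
        for _ in range(4):
            code = _CODE_ALPHABET[x % n] + code
            x //= n
        terms.append(code)
    return terms


def _default_age_alphas(K: int, base: float = 0.4, boost: float = 1.2
                        ) -> dict[str, np.ndarray]:
    """Stratum-dependent mixing: each age group leans toward different topics."""
    alphas = {}
    for g, group in enumerate(AGE_GROUPS):
        v = np.full(K, base)
        v[g % K] += boost
        v[(g + 1) % K] += boost / 2
        alphas[group] = v
    return alphas


def _default_time_tilts(K: int, strength: float = 0.6) -> dict[str, np.ndarray]:
    tilts = {}
    for t, group in enumerate(TIME_GROUPS):
        v = np.ones(K)
        v[(K - 1 - t) % K] += strength
        tilts[group] = v
    return tilts


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults mirror the study conditions: two
    cohorts of 463 and 919 eligible reviews, 5 latent topics, and modest
    contamination by each filter target."""

    n_docs_per_drug: Mapping[str, int] = field(
        default_factory=lambda: {"drug_a": 463, "drug_b": 919})
    n_topics: int = 5
    n_terms: int = 300
    alpha_gen: Union[Sequence[float], Mapping[str, Sequence[float]], None] = None
    time_tilt: Optional[Mapping[str, Sequence[float]]] = None
    beta_gen: Union[float, np.ndarray] = 0.1
    doc_length_mean: float = 100.0
    rating_effects: Optional[Mapping[int, float]] = None
    rating_noise_sd: float = 1.0
    age_rating_shift: Mapping[str, float] = field(
        default_factory=lambda: {"19-44": 0.1, "45-64": 0.0, "65+": -0.2})
    time_rating_shift: Mapping[str, float] = field(
        default_factory=lambda: {"lt_1_month": -0.4, "m1_to_lt_1_year": 0.1,
                                 "ge_1_year": 0.4})
    age_group_probs: Sequence[float] = (0.26, 0.57, 0.17)
    time_group_probs: Sequence[float] = (0.42, 0.28, 0.30)
    contamination_rates: Mapping[str, float] = field(
        default_factory=lambda: {"spam": 0.03, "empty_comment": 0.05,
                                 "underage_or_missing_age": 0.06})
    decorate_frac: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.n_docs_per_drug.values()):
            raise ValueError("n_docs_per_drug entries must be positive")
        if self.n_topics < 1 or self.n_terms < 2:
            raise ValueError("need n_topics >= 1 and n_terms >= 2")
        if self.doc_length_mean <= 0:
            raise ValueError("doc_length_mean must be positive")
        if self.rating_noise_sd < 0:
            raise ValueError("rating_noise_sd must be non-negative")
        rates = self.contamination_rates
        if any(not (0 <= r < 1) for r in rates.values()) or sum(rates.values()) >= 1:
            raise ValueError("contamination rates must lie in [0,1) and sum < 1")
        if self.rating_effects is None:
            # alternate favorable / unfavorable topics around the midpoint
            self.rating_effects = {k: (0.9 if k % 2 == 0 else -0.9)
                                   for k in range(self.n_topics)}
        if set(self.rating_effects) != set(range(self.n_topics)):
            raise ValueError("rating_effects must cover every topic index")
        beta = np.asarray(self.beta_gen, dtype=float)
        if np.any(beta <= 0):
            raise ValueError("beta_gen concentrations must be strictly positive")

    def age_alpha(self, group: str) -> np.ndarray:
        if self.alpha_gen is None:
            table = _default_age_alphas(self.n_topics)
            v = table[group]
        elif isinstance(self.alpha_gen, Mapping):
            v = np.asarray(self.alpha_gen[group], dtype=float)
        else:
            v = np.asarray(self.alpha_gen, dtype=float)
        if v.shape != (self.n_topics,) or np.any(v <= 0):
            raise ValueError("alpha_gen vectors must be positive, length n_topics")
        return v

    def tilt(self, time_group: str) -> np.ndarray:
        if self.time_tilt is None:
            return _default_time_tilts(self.n_topics)[time_group]
        v = np.asarray(self.time_tilt[time_group], dtype=float)
        if v.shape != (self.n_topics,) or np.any(v <= 0):
            raise ValueError("time_tilt vectors must be positive, length n_topics")
        return v

    def beta_rows(self) -> np.ndarray:
        beta = np.asarray(self.beta_gen, dtype=float)
        if beta.ndim == 0:
            return np.full((self.n_topics, self.n_terms), float(beta))
        if beta.ndim == 1:
            if beta.shape != (self.n_terms,):
                raise ValueError("1-D beta_gen must have length n_terms")
            return np.tile(beta, (self.n_topics, 1))
        if beta.shape != (self.n_topics, self.n_terms):
            raise ValueError("2-D beta_gen must be n_topics x n_terms")
        return beta


@dataclass
class SyntheticDoc:
    doc_id: str
    drug: str
    age_group: str
    age_years: int
    time_group: str
    theta: np.ndarray
    z: np.ndarray
    words: np.ndarray
    primary_topic: int
    rating_mean: float         # configured mean before noise and clipping


@dataclass
class SyntheticGroundTruth:
    """Generating parameters and latent state for recovery tests."""

    config: SyntheticConfig
    terms: list[str]
    phi: np.ndarray            # n_topics x n_terms, rows sum to 1
    docs: list[SyntheticDoc]

    @property
    def theta(self) -> np.ndarray:
        return np.stack([d.theta for d in self.docs])

    def docs_for(self, drug: str) -> list[SyntheticDoc]:
        return [d for d in self.docs if d.drug == drug]

    def phi_for_vocabulary(self, terms: Sequence[str]) -> np.ndarray:
        """Generating topic-word matrix with columns reordered to a fitted
        vocabulary (e.g. a DTM's), rows renormalized over the kept terms.
        Unknown terms raise KeyError."""
        index = {t: i for i, t in enumerate(self.terms)}
        cols = [index[t] for t in terms]
        phi = self.phi[:, cols]
        return phi / phi.sum(axis=1, keepdims=True)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "terms": self.terms,
            "phi": self.phi.tolist(),
            "docs": [
                {
                    "doc_id": d.doc_id, "drug": d.drug,
                    "age_group": d.age_group, "age_years": d.age_years,
                    "time_group": d.time_group,
                    "theta": d.theta.tolist(), "z": d.z.tolist(),
                    "words": d.words.tolist(),
                    "primary_topic": d.primary_topic,
                    "rating_mean": d.rating_mean,
                }
                for d in self.docs
            ],
        }
        Path(path).write_text(json.dumps(payload) + "\n", encoding="utf-8")


def _clipped_rating_mean(x: float) -> float:
    """Expected reported rating with zero noise: round half up, clip to 1..5."""
    return float(min(5, max(1, math.floor(x + 0.5))))


def generate_ground_truth(config: SyntheticConfig) -> SyntheticGroundTruth:
    """Draw topics, stratified document mixtures and token-level topic labels.

    Deterministic given ``config.seed``. Document lengths are Poisson with
    mean ``doc_length_mean``, truncated at >= 1.
    """
    rng = np.random.default_rng([int(config.seed) % (2 ** 31), 0])
    K, V = config.n_topics, config.n_terms
    terms = make_vocabulary(V)
    phi = np.vstack([rng.dirichlet(row) for row in config.beta_rows()])

    docs: list[SyntheticDoc] = []
    for drug in sorted(config.n_docs_per_drug):
        n_docs = config.n_docs_per_drug[drug]
        for i in range(n_docs):
            age_group = AGE_GROUPS[rng.choice(len(AGE_GROUPS),
                                              p=np.asarray(config.age_group_probs))]
            lo, hi = _AGE_RANGES[age_group]
            age_years = int(rng.integers(lo, hi + 1))
            time_group = TIME_GROUPS[rng.choice(len(TIME_GROUPS),
                                                p=np.asarray(config.time_group_probs))]
            alpha = config.age_alpha(age_group) * config.tilt(time_group)
            theta = rng.dirichlet(alpha)
            if K == 1:
                theta = np.ones(1)
            length = 0
            while length < 1:
                length = int(rng.poisson(config.doc_length_mean))
            z = rng.choice(K, size=length, p=theta)
            words = np.empty(length, dtype=np.int64)
            for k in range(K):
                mask = z == k
                if mask.any():
                    words[mask] = rng.choice(V, size=int(mask.sum()), p=phi[k])
            primary = int(np.argmax(np.bincount(z, minlength=K)))
            mean = (3.0 + config.rating_effects[primary]
                    + config.age_rating_shift.get(age_group, 0.0)
                    + config.time_rating_shift.get(time_group, 0.0))
            docs.append(SyntheticDoc(
                doc_id=f"{drug}-{i:05d}", drug=drug, age_group=age_group,
                age_years=age_years, time_group=time_group, theta=theta,
                z=z, words=words, primary_topic=primary, rating_mean=mean))
    return SyntheticGroundTruth(config=config, terms=terms, phi=phi, docs=docs)


_DECORATIONS = ("bang", "period", "comma", "caps", "title", "digits")


def _decorate(token: str, style: str) -> str:
    if style == "bang":
        return token + "!!"
    if style == "period":
        return token + "."
    if style == "comma":
        return token + ","
    if style == "caps":
        return token.upper()
    if style == "title":
        return token.title()
    return token + "42"


_SPAM_TEMPLATES = (
    "visit www.cheappills.biz for deals",
    "order now at pillstore.com cheap",
    "go to http://pills.example today",
)


@dataclass
class GeneratorLog:
    """Counts of eligible and injected-contaminant records, per drug."""

    n_eligible: Mapping[str, int]
    injected: Mapping[str, Mapping[str, int]]  # drug -> rule -> count

    def injected_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for per_rule in self.injected.values():
            for rule, n in per_rule.items():
                totals[rule] = totals.get(rule, 0) + n
        return totals

    def to_dict(self) -> dict:
        return {"n_eligible": dict(self.n_eligible),
                "injected": {d: dict(r) for d, r in self.injected.items()}}


def render_corpus(gt: SyntheticGroundTruth, config: SyntheticConfig | None = None
                  ) -> tuple[list[ReviewRecord], GeneratorLog]:
    """Materialize ground-truth documents as review records.

    Tokens are joined into comment text with a configurable fraction
    decorated by punctuation/digits/case to exercise cleaning; ratings are
    round-half-up-then-clip of (configured mean + Gaussian noise).
    Contaminant records (spam, empty comment, underage/missing age) are
    appended after the eligible records of each drug, with counts drawn
    binomially from ``contamination_rates`` and recorded in the log.
    """
    config = config or gt.config
    rng = np.random.default_rng([int(config.seed) % (2 ** 31), 1])
    records: list[ReviewRecord] = []
    n_eligible: dict[str, int] = {}
    injected: dict[str, dict[str, int]] = {}

    drugs = sorted({d.drug for d in gt.docs})
    for drug in drugs:
        docs = gt.docs_for(drug)
        n_eligible[drug] = len(docs)
        for doc in docs:
            toks = []
            for w in doc.words:
                tok = gt.terms[w]
                if rng.random() < config.decorate_frac:
                    tok = _decorate(tok, _DECORATIONS[rng.integers(len(_DECORATIONS))])
                toks.append(tok)
            rating = _apply_noise(doc.rating_mean, config.rating_noise_sd, rng)
            gender = ("male", "female", "missing")[
                rng.choice(3, p=[0.95, 0.02, 0.03])]
            records.append(ReviewRecord(
                record_id=doc.doc_id, drug=drug, source="synthetic",
                comment=" ".join(toks), age_years=doc.age_years,
                gender=gender, time_on_med=doc.time_group, rating=rating,
                post_date=f"{rng.integers(2005, 2020)}-06-15",
                reviewer_type="patient"))

        n = len(docs)
        rates = config.contamination_rates
        per_rule = {
            "spam": int(rng.binomial(n, rates.get("spam", 0.0))),
            "empty_comment": int(rng.binomial(n, rates.get("empty_comment", 0.0))),
            "underage_or_missing_age":
                int(rng.binomial(n, rates.get("underage_or_missing_age", 0.0))),
        }
        injected[drug] = per_rule
        for i in range(per_rule["spam"]):
            filler = " ".join(gt.terms[w] for w in rng.integers(0, len(gt.terms), 5))
            records.append(ReviewRecord(
                record_id=f"{drug}-spam-{i:04d}", drug=drug, source="synthetic",
                comment=filler + " " + _SPAM_TEMPLATES[i % len(_SPAM_TEMPLATES)],
                age_years=int(rng.integers(25, 70)),
                rating=int(rng.integers(1, 6))))
        for i in range(per_rule["empty_comment"]):
            records.append(ReviewRecord(
                record_id=f"{drug}-empty-{i:04d}", drug=drug, source="synthetic",
                comment="", age_years=int(rng.integers(25, 70)),
                rating=int(rng.integers(1, 6))))
        for i in range(per_rule["underage_or_missing_age"]):
            filler = " ".join(gt.terms[w] for w in rng.integers(0, len(gt.terms), 8))
            records.append(ReviewRecord(
                record_id=f"{drug}-under-{i:04d}", drug=drug, source="synthetic",
                comment=filler,
                age_years=(18 if i % 2 == 0 else None),
                rating=int(rng.integers(1, 6))))

    return records, GeneratorLog(n_eligible=n_eligible, injected=injected)


def _apply_noise(mean: float, sd: float, rng: np.random.Generator) -> int:
    return int(min(5, max(1, math.floor(mean + rng.normal(0.0, sd) + 0.5)))) \
        if sd > 0 else int(_clipped_rating_mean(mean))
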