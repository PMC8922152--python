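"""Human-readable report pieces: topic listings and demographics tables."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .lda import PrimaryTopicAssignment, TopicModel, top_words
from .records import AGE_GROUPS, TIME_GROUPS, ReviewRecord
from .stats import percent


@dataclass
class TopicReport:
    """Per-topic top words with primary-topic document counts and shares,
    in the style of a published topic box: ``Topic k (n=.., ..%)``."""

    drug: str
    n_assigned: int
    topics: list[dict]        # {"topic", "top_words", "n_docs", "share_pct"}
    primary: list[PrimaryTopicAssignment]

    def to_dict(self) -> dict:
        return {
            "drug": self.drug,
            "n_assigned": self.n_assigned,
            "topics": self.topics,
            "primary_topics": {a.doc_id: a.topic for a in self.primary},
        }

    def to_markdown(self) -> str:
        lines = [f"**{self.drug} (N={self.n_assigned})**", ""]
        for t in self.topics:
            lines.append(
                f"- **Topic {t['topic']} (n={t['n_docs']}, {t['share_pct']:.1f}%)**")
            lines.append("  Words: " + ", ".join(t["top_words"]))
        return "\n".join(lines) + "\n"


def topic_report(model: TopicModel, assignments: Sequence[PrimaryTopicAssignment],
                 drug: str = "", n_words: int = 30) -> TopicReport:
    """Assemble the top-``n_words`` listing per topic plus (n, %) of
    documents holding each topic as primary."""
    assigned = [a for a in assignments if a.topic is not None]
    n_assigned = len(assigned)
    topics = []
    for k in range(model.n_topics):
        n_docs = sum(1 for a in assigned if a.topic == k)
        topics.append({
            "topic": k,
            "top_words": top_words(model, k, n_words),
            "n_docs": n_docs,
            "share_pct": percent(n_docs, n_assigned) if n_assigned else float("nan"),
        })
    return TopicReport(drug=drug, n_assigned=n_assigned, topics=topics,
                       primary=list(assignments))


def demographics_table(records: Sequence[ReviewRecord]) -> pd.DataFrame:
    """Characteristics of reviews per drug: n (%) by gender, age group and
    time on medication."""
    drugs = sorted({r.drug for r in records})
    rows = []
    for block, labels, getter in (
        ("gender", ("male", "female", "missing"), lambda r: r.gender),
        ("age_group", AGE_GROUPS, lambda r: r.age_group),
        ("time_on_med", TIME_GROUPS + ("missing",), lambda r: r.time_on_med),
    ):
        for label in labels:
            row = {"variable": block, "category": label}
            for drug in drugs:
                sub = [r for r in records if r.drug == drug]
                n = sum(1 for r in sub if getter(r) == label)
                row[f"{drug}_n"] = n
                row[f"{drug}_pct"] = percent(n, len(sub)) if sub else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)
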