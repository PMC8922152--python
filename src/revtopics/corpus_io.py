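"""Reading, writing and eligibility filtering of review records.

Filters mirror the study's inclusion rules: posts without any comment are
dropped, then spam (comments carrying "http", ".com" or "www."), then
reviews with missing age or age under 19. Female-authored reviews are
retained — they may come from caregivers or partners reporting the
patient's experience.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Sequence

from .records import FIELD_NAMES, FilterLog, ReviewRecord

SPAM_MARKERS = ("http", ".com", "www.")

#: filter rules in precedence order; a record is logged under the first match
RULE_EMPTY = "empty_comment"
RULE_SPAM = "spam"
RULE_AGE = "underage_or_missing_age"
FILTER_RULES = (RULE_EMPTY, RULE_SPAM, RULE_AGE)

_INT_FIELDS = {"age_years", "rating"}


def _coerce_row(row: dict, where: str) -> ReviewRecord:
    kwargs = {}
    for name in FIELD_NAMES:
        value = row.get(name)
        if value in (None, ""):
            value = None
        if value is not None and name in _INT_FIELDS:
            try:
                value = int(value)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"{where}: field {name!r} not an integer: {value!r}") from exc
        if value is None and name in ("source", "gender", "time_on_med", "reviewer_type"):
            value = "missing"
        if value is not None:
            kwargs[name] = value
    if "record_id" not in kwargs or "drug" not in kwargs:
        raise ValueError(f"{where}: record_id and drug are required")
    try:
        return ReviewRecord(**kwargs)
    except ValueError as exc:
        raise ValueError(f"{where}: {exc}") from exc


def read_reviews(path: str | Path, format: str | None = None) -> list[ReviewRecord]:
    """Read review records from a CSV (RFC-4180, header row) or JSON-lines file.

    ``format`` is ``"csv"`` or ``"jsonl"``; inferred from the suffix when
    omitted. Empty cells map to the missing sentinel. Malformed rows raise
    ``ValueError`` naming the line.
    """
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"
    if format not in ("csv", "jsonl"):
        raise ValueError(f"unknown format {format!r}")

    records: list[ReviewRecord] = []
    if format == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            for lineno, row in enumerate(reader, start=2):
                records.append(_coerce_row(row, f"{path.name}:{lineno}"))
    else:
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    row = json.loads(line)
                except json.JSONDecodeError as exc:
                    raise ValueError(f"{path.name}:{lineno}: invalid JSON") from exc
                records.append(_coerce_row(row, f"{path.name}:{lineno}"))
    return records


def write_reviews(records: Iterable[ReviewRecord], path: str | Path,
                  format: str | None = None) -> None:
    """Write records as CSV or JSON-lines (schema-complete, missing -> empty/null)."""
    path = Path(path)
    if format is None:
        format = "jsonl" if path.suffix in (".jsonl", ".ndjson", ".json") else "csv"
    records = list(records)
    if format == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=FIELD_NAMES)
            writer.writeheader()
            for rec in records:
                row = {k: ("" if v is None else v) for k, v in rec.to_dict().items()}
                writer.writerow(row)
    elif format == "jsonl":
        with path.open("w", encoding="utf-8") as fh:
            for rec in records:
                fh.write(json.dumps(rec.to_dict(), sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _first_matching_rule(rec: ReviewRecord,
                         side_effect_rescues: bool = False) -> str | None:
    comment = (rec.comment or "").strip()
    if not comment:
        if not (side_effect_rescues and (rec.side_effect_comment or "").strip()):
            return RULE_EMPTY
    low = comment.lower()
    if any(marker in low for marker in SPAM_MARKERS):
        return RULE_SPAM
    if rec.age_years is None or rec.age_years < 19:
        return RULE_AGE
    return None


def filter_reviews(records: Sequence[ReviewRecord],
                   side_effect_rescues: bool = False
                   ) -> tuple[list[ReviewRecord], FilterLog]:
    """Apply the eligibility filters; return survivors (input order) and a log.

    Rule precedence: empty comment, then spam markers, then age missing or
    under 19 (age exactly 19 is eligible). ``side_effect_rescues`` lets a
    non-empty side-effects field stand in for an empty main comment; off by
    default.
    """
    log = FilterLog(n_input=len(records),
                    removed_counts={rule: 0 for rule in FILTER_RULES})
    survivors: list[ReviewRecord] = []
    for rec in records:
        rule = _first_matching_rule(rec, side_effect_rescues)
        if rule is None:
            survivors.append(rec)
        else:
            log.removed_counts[rule] += 1
            log.removal_reasons[rec.record_id] = rule
    log.n_output = len(survivors)
    log.check()
    return survivors, log


def write_filter_log(log: FilterLog, path: str | Path) -> None:
    Path(path).write_text(json.dumps(log.to_dict(), indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
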