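"""Core record and result types shared across the pipeline."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

#: closed category sets mirroring the review-site field layouts
SOURCES = ("webmd", "askapatient", "synthetic", "missing")
GENDERS = ("male", "female", "missing")
TIME_ON_MED = ("lt_1_month", "m1_to_lt_1_year", "ge_1_year", "missing")
REVIEWER_TYPES = ("patient", "caregiver", "missing")

#: age strata used throughout the stratified analyses (years)
AGE_GROUPS = ("19-44", "45-64", "65+")
TIME_GROUPS = ("lt_1_month", "m1_to_lt_1_year", "ge_1_year")


@dataclass
class ReviewRecord:
    """One patient medication review.

    ``comment`` is the free-text field mined for topics;
    ``side_effect_comment`` is the separate side-effects field some sites
    provide. ``rating`` is overall satisfaction on a 1-5 Likert scale
    (1 least satisfied, 5 most satisfied). Missing values are ``None``
    (or ``"missing"`` for the enumerated fields).
    """

    record_id: str
    drug: str
    source: str = "synthetic"
    comment: Optional[str] = None
    side_effect_comment: Optional[str] = None
    age_years: Optional[int] = None
    gender: str = "missing"
    time_on_med: str = "missing"
    rating: Optional[int] = None
    post_date: Optional[str] = None
    reviewer_type: str = "missing"

    def __post_init__(self) -> None:
        if self.rating is not None and self.rating not in (1, 2, 3, 4, 5):
            raise ValueError(
                f"record {self.record_id!r}: rating must be an integer in 1..5 "
                f"or missing, got {self.rating!r}"
            )
        if self.source not in SOURCES:
            raise ValueError(f"record {self.record_id!r}: unknown source {self.source!r}")
        if self.gender not in GENDERS:
            raise ValueError(f"record {self.record_id!r}: unknown gender {self.gender!r}")
        if self.time_on_med not in TIME_ON_MED:
            raise ValueError(
                f"record {self.record_id!r}: unknown time_on_med {self.time_on_med!r}"
            )
        if self.reviewer_type not in REVIEWER_TYPES:
            raise ValueError(
                f"record {self.record_id!r}: unknown reviewer_type {self.reviewer_type!r}"
            )

    @property
    def age_group(self) -> Optional[str]:
        """Age stratum label, or None when age is missing or below 19."""
        if self.age_years is None or self.age_years < 19:
            return None
        if self.age_years <= 44:
            return "19-44"
        if self.age_years <= 64:
            return "45-64"
        return "65+"

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


FIELD_NAMES = [f.name for f in dataclasses.fields(ReviewRecord)]


@dataclass
class FilterLog:
    """Audit trail of eligibility filtering.

    Each removed record is attributed to exactly one rule (the first that
    matched); ``n_input == n_output + sum(removed_counts.values())``.
    """

    n_input: int = 0
    n_output: int = 0
    removed_counts: dict = field(default_factory=dict)
    removal_reasons: dict = field(default_factory=dict)  # record_id -> rule

    def check(self) -> None:
        total_removed = sum(self.removed_counts.values())
        if self.n_input != self.n_output + total_removed:
            raise AssertionError(
                f"filter log does not reconcile: {self.n_input} != "
                f"{self.n_output} + {total_removed}"
            )

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_output": self.n_output,
            "removed_counts": dict(self.removed_counts),
            "removal_reasons": dict(self.removal_reasons),
        }
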