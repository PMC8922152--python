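"""Stratified topic-share tables, rating summaries and significance tests.

The downstream analysis works on one categorical outcome per review (its
primary topic) and one ordinal outcome (the 1-5 satisfaction rating):
topic-share contingency tables by age / time-on-medication / drug with a
Fisher exact test, and rating means by topic and stratum with Welch t
tests and one-way ANOVA. Alpha is .05 throughout and no multiple-testing
correction is applied; every emitted table notes this.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import gammaln

from .lda import PrimaryTopicAssignment

ALPHA = 0.05


def percent(n: int, total: int) -> float:
    """Percentage share rounded half-up to one decimal (the printed style)."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = (Decimal(100 * n) / Decimal(total)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP)
    return float(q)


@dataclass
class StatTestResult:
    """Outcome of one significance test at alpha .05."""

    method: str                      # fisher_exact | welch_t | one_way_anova
    statistic: Optional[float]
    df: Optional[tuple]              # e.g. (welch df,) or (df1, df2); None for Fisher
    p_value: float
    n_per_group: tuple
    mc_se: Optional[float] = None    # Monte-Carlo standard error, when sampled
    seed: Optional[int] = None

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "statistic": self.statistic,
            "df": list(self.df) if self.df is not None else None,
            "p_value": self.p_value,
            "n_per_group": list(self.n_per_group),
            "significant": self.significant,
            "mc_se": self.mc_se,
            "seed": self.seed,
        }


@dataclass
class StratifiedShareTable:
    """Primary-topic counts and one-decimal percentage shares by stratum.

    Percentages are computed over the column (stratum) totals; the
    ``total`` column covers all documents with a defined primary topic and
    stratum.
    """

    counts: pd.DataFrame     # rows: topic index; columns: strata + "total"
    percents: pd.DataFrame   # same shape, one-decimal shares

    def to_csv(self, path) -> None:
        merged = self.counts.astype(str) + " (" + self.percents.map(
            lambda p: f"{p:.1f}") + "%)"
        merged.to_csv(path)


def share_table(assignments: Sequence[PrimaryTopicAssignment],
                stratum_of: Mapping[str, Optional[str]],
                strata_order: Sequence[str] | None = None,
                n_topics: int | None = None) -> StratifiedShareTable:
    """Tabulate primary topics by stratum with counts and rounded shares.

    ``stratum_of`` maps doc_id to a stratum label; documents with a
    missing primary topic or missing stratum are excluded from the
    relevant denominator.
    """
    rows = [(a.topic, stratum_of.get(a.doc_id))
            for a in assignments if a.topic is not None]
    if not rows:
        raise ValueError("no documents with a defined primary topic")
    K = n_topics if n_topics is not None else max(t for t, _ in rows) + 1
    strata = (list(strata_order) if strata_order is not None
              else sorted({s for _, s in rows if s is not None}))

    counts = pd.DataFrame(0, index=range(K), columns=strata + ["total"])
    for topic, stratum in rows:
        counts.loc[topic, "total"] += 1
        if stratum in strata:
            counts.loc[topic, stratum] += 1
    margins = counts.sum(axis=0)
    percents = counts.copy().astype(float)
    for col in counts.columns:
        denom = int(margins[col])
        percents[col] = [percent(int(c), denom) if denom else float("nan")
                         for c in counts[col]]
    counts.index.name = "topic"
    percents.index.name = "topic"
    return StratifiedShareTable(counts=counts, percents=percents)


def _validate_table(table: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if np.any(table < 0):
        raise ValueError("table cells must be non-negative")
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    if np.any(rows == 0):
        raise ValueError(f"zero margin in row {int(np.argmin(rows != 0))}")
    if np.any(cols == 0):
        raise ValueError(f"zero margin in column {int(np.argmin(cols != 0))}")
    return rows, cols


def _log_table_prob(table: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> float:
    """Multiple hypergeometric log-probability of a table given its margins."""
    n = rows.sum()
    return float(gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                 - gammaln(n + 1) - gammaln(table + 1).sum())


def _fisher_2x2_exact(table: np.ndarray) -> float:
    """Two-sided p: total probability of 2x2 tables (fixed margins) whose
    probability does not exceed the observed table's."""
    rows, cols = table.sum(axis=1), table.sum(axis=0)
    n = int(rows.sum())
    rv = scipy.stats.hypergeom(n, int(rows[0]), int(cols[0]))
    lo = max(0, int(cols[0] - rows[1]))
    hi = min(int(rows[0]), int(cols[0]))
    support = np.arange(lo, hi + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(int(table[0, 0]))
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-7)].sum()))


def enumerate_fisher_p(table: np.ndarray) -> float:
    """Exact two-sided Fisher p for a small r x c table by brute-force
    enumeration of every table with the observed margins.

    Reference routine for small-margin instances; cost grows combinatorially,
    so keep margins tiny.
    """
    table = np.asarray(table, dtype=np.int64)
    rows, cols = _validate_table(table)
    log_p_obs = _log_table_prob(table, rows, cols)

    r, c = table.shape
    total_p = 0.0

    def fill_row(i: int, remaining_cols: np.ndarray, acc: list[np.ndarray]):
        nonlocal total_p
        if i == r - 1:
            if np.any(remaining_cols < 0):
                return
            cand = np.vstack(acc + [remaining_cols])
            if np.all(cand[-1] >= 0):
                lp = _log_table_prob(cand, rows, cols)
                if lp <= log_p_obs + 1e-7:
                    total_p += np.exp(lp)
            return
        target = int(rows[i])

        def compose(j: int, left: int, row: list[int]):
            if j == c - 1:
                if 0 <= left <= remaining_cols[j]:
                    fill_row(i + 1,
                             remaining_cols - np.array(row + [left]),
                             acc + [np.array(row + [left])])
                return
            for v in range(min(left, int(remaining_cols[j])) + 1):
                compose(j + 1, left - v, row + [v])

        compose(0, target, [])

    fill_row(0, cols.astype(np.int64), [])
    return float(min(1.0, total_p))


def fisher_exact(table, mc_reps: int = 100_000, seed: int = 0) -> StatTestResult:
    """Fisher exact test of independence on an r x c contingency table.

    2x2 tables get the exact two-sided p by hypergeometric enumeration
    (with the odds ratio as the statistic). Larger tables get a
    Monte-Carlo p over ``mc_reps`` tables drawn with fixed margins
    (sequential multivariate-hypergeometric rows), reported with its
    standard error; p = (1 + hits) / (reps + 1).
    """
    table = np.asarray(table, dtype=np.int64)
    rows, cols = _validate_table(table)
    n_per_group = tuple(int(x) for x in rows)

    if table.shape == (2, 2):
        p = _fisher_2x2_exact(table)
        a, b, c, d = table.ravel().astype(float)
        odds = (a * d) / (b * c) if b * c > 0 else float("inf")
        return StatTestResult(method="fisher_exact", statistic=odds, df=None,
                              p_value=p, n_per_group=n_per_group)

    rng = np.random.default_rng(int(seed) % (2 ** 31))
    log_p_obs = _log_table_prob(table, rows, cols)
    const = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
             - gammaln(rows.sum() + 1))
    hits = 0
    for _ in range(mc_reps):
        remaining = cols.copy()
        lg = 0.0
        for i in range(table.shape[0] - 1):
            row = rng.multivariate_hypergeometric(remaining, int(rows[i]))
            lg += gammaln(row + 1).sum()
            remaining = remaining - row
        lg += gammaln(remaining + 1).sum()
        if const - lg <= log_p_obs + 1e-7:
            hits += 1
    p = (1 + hits) / (mc_reps + 1)
    mc_se = float(np.sqrt(p * (1 - p) / mc_reps))
    return StatTestResult(method="fisher_exact", statistic=None, df=None,
                          p_value=float(p), n_per_group=n_per_group,
                          mc_se=mc_se, seed=seed)


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> StatTestResult:
    """Two-sided Welch two-sample t test (unequal variances)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return StatTestResult(method="welch_t", statistic=0.0,
                                  df=(float(len(a) + len(b) - 2),), p_value=1.0,
                                  n_per_group=(len(a), len(b)))
        raise ValueError("both groups have zero variance with unequal means")
    res = scipy.stats.ttest_ind(a, b, equal_var=False)
    return StatTestResult(method="welch_t", statistic=float(res.statistic),
                          df=(float(res.df),), p_value=float(res.pvalue),
                          n_per_group=(len(a), len(b)))


def one_way_anova(groups: Sequence[Sequence[float]]) -> StatTestResult:
    """One-way ANOVA F test with (g-1, N-g) degrees of freedom."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("ANOVA groups must all be non-empty")
    N = sum(len(g) for g in groups)
    g = len(groups)
    if N <= g:
        raise ValueError("total n must exceed the number of groups")
    means = [x.mean() for x in groups]
    if np.allclose(means, means[0]) and all(
            np.allclose(x, x.mean()) for x in groups):
        return StatTestResult(method="one_way_anova", statistic=0.0,
                              df=(float(g - 1), float(N - g)), p_value=1.0,
                              n_per_group=tuple(len(x) for x in groups))
    with np.errstate(divide="ignore"):
        f, p = scipy.stats.f_oneway(*groups)
    return StatTestResult(method="one_way_anova", statistic=float(f),
                          df=(float(g - 1), float(N - g)), p_value=float(p),
                          n_per_group=tuple(len(x) for x in groups))


@dataclass
class RatingSummary:
    """Rating grid: n / mean / SD per (primary topic x stratum) with an
    ANOVA p per topic row, in the layout of the printed rating tables."""

    table: pd.DataFrame          # MultiIndex columns: (stratum, {n, mean, sd})
    anova_p: pd.Series           # per topic row (NaN where undefined)
    n_missing_rating: int

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out[("tests", "anova_p")] = self.anova_p
        out.to_csv(path)


def rating_summary(assignments: Sequence[PrimaryTopicAssignment],
                   ratings: Mapping[str, Optional[int]],
                   stratum_of: Mapping[str, Optional[str]],
                   strata_order: Sequence[str] | None = None,
                   n_topics: int | None = None) -> RatingSummary:
    """Mean (SD) satisfaction rating per primary topic and stratum.

    Records with a missing rating are excluded and counted. SD is the
    sample standard deviation, reported missing for n < 2. Each topic row
    carries the one-way ANOVA p across strata (NaN when fewer than two
    strata have >= 2 ratings); an overall ``total`` row closes the grid.
    """
    recs = []
    n_missing = 0
    for a in assignments:
        if a.topic is None:
            continue
        r = ratings.get(a.doc_id)
        if r is None:
            n_missing += 1
            continue
        recs.append((a.topic, stratum_of.get(a.doc_id), float(r)))
    if not recs:
        raise ValueError("no rated documents with a defined primary topic")
    df = pd.DataFrame(recs, columns=["topic", "stratum", "rating"])
    K = n_topics if n_topics is not None else int(df["topic"].max()) + 1
    strata = (list(strata_order) if strata_order is not None
              else sorted(s for s in df["stratum"].dropna().unique()))

    index = list(range(K)) + ["total"]
    cols = pd.MultiIndex.from_product([["overall"] + strata, ["n", "mean", "sd"]])
    table = pd.DataFrame(index=index, columns=cols, dtype=float)
    anova_p = pd.Series(index=index, dtype=float)

    def fill(row_key, sub: pd.DataFrame) -> None:
        table.loc[row_key, ("overall", "n")] = len(sub)
        if len(sub):
            table.loc[row_key, ("overall", "mean")] = sub["rating"].mean()
        table.loc[row_key, ("overall", "sd")] = (
            sub["rating"].std(ddof=1) if len(sub) >= 2 else np.nan)
        groups = []
        for s in strata:
            vals = sub.loc[sub["stratum"] == s, "rating"]
            table.loc[row_key, (s, "n")] = len(vals)
            table.loc[row_key, (s, "mean")] = vals.mean() if len(vals) else np.nan
            table.loc[row_key, (s, "sd")] = (
                vals.std(ddof=1) if len(vals) >= 2 else np.nan)
            if len(vals) >= 2:
                groups.append(vals.to_numpy())
        if len(groups) >= 2:
            try:
                anova_p[row_key] = one_way_anova(groups).p_value
            except ValueError:
                anova_p[row_key] = np.nan
        else:
            anova_p[row_key] = np.nan

    for k in range(K):
        fill(k, df[df["topic"] == k])
    fill("total", df)
    table[("overall", "n")] = table[("overall", "n")].astype(float)
    return RatingSummary(table=table, anova_p=anova_p,
                         n_missing_rating=n_missing)
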