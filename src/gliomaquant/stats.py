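"""Contingency-table association tests and condition comparisons.

Conventions (chosen to reproduce published TMA association tables from
their printed counts, and footnoted in every report):

* Pearson chi-squared is computed **without** Yates continuity correction.
* ``unknown`` categories are excluded from tumor-type and grade tests.
* The r×c Fisher exact test is the Freeman–Halton generalization: the
  p-value sums the conditional (multivariate hypergeometric) probabilities
  of every margin-fixed table as or less probable than the observed one,
  with a relative tie tolerance of 1e-7.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import lgamma, log1p
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ContingencyTable",
    "AssociationResult",
    "ConditionComparison",
    "build_table",
    "pearson_chi2",
    "fisher_exact_rxc",
    "compare_conditions",
]

#: Preferred display order for the covariates this pipeline knows about.
CATEGORY_ORDERS: dict[str, list[str]] = {
    "age_group": ["<=25", "26-60", ">60"],
    "sex": ["M", "F"],
    "location": ["cerebrum", "cerebellum"],
    "tumor_type": ["benign", "malignant", "unknown"],
    "grade": ["1", "2", "3", "4", "unknown"],
    "localization": ["membranous", "cytoplasmic", "negative"],
    "expression_class": ["low", "high"],
}


@dataclass(frozen=True)
class ContingencyTable:
    """Labeled r×c count matrix."""

    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # (r, c) non-negative ints
    excluded_categories: tuple[str, ...] = ()
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape must match labels")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if counts.shape[0] < 2 or counts.shape[1] < 2:
            raise ValueError("need at least a 2x2 table after exclusions")
        object.__setattr__(self, "counts", counts.astype(np.int64))

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def column_percentages(self) -> np.ndarray:
        """Column-normalized shares ×100, as printed next to table counts."""
        col_tot = self.counts.sum(axis=0, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return 100.0 * self.counts / col_tot


@dataclass(frozen=True)
class AssociationResult:
    method: str  # pearson_chi2 | fisher_exact
    p_value: float
    statistic: float | None = None  # chi-squared only
    df: int | None = None  # chi-squared only


@dataclass(frozen=True)
class ConditionComparison:
    statistic: float
    df: float
    p_value: float
    mean_difference: float  # mean(a) - mean(b)


def build_table(
    cohort: pd.DataFrame,
    row_covariate: str,
    col_variable: str,
    exclude: Sequence[str] = (),
    name: str = "",
) -> ContingencyTable:
    """Cross-tabulate a cohort into a labeled contingency table.

    Records whose row or column category is listed in ``exclude`` are
    dropped; record conservation (kept + excluded = cohort size) is an
    invariant the tests rely on.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    for var in (row_covariate, col_variable):
        if var not in cohort.columns:
            raise ValueError(f"unknown covariate {var!r}; cohort has {list(cohort.columns)}")
    keep = ~(
        cohort[row_covariate].astype(str).isin(exclude)
        | cohort[col_variable].astype(str).isin(exclude)
    )
    sub = cohort[keep]
    ct = pd.crosstab(sub[row_covariate].astype(str), sub[col_variable].astype(str))

    def _order(var: str, present: list[str]) -> list[str]:
        pref = [c for c in CATEGORY_ORDERS.get(var, []) if c in present]
        return pref + [c for c in present if c not in pref]

    rows = _order(row_covariate, list(ct.index))
    cols = _order(col_variable, list(ct.columns))
    ct = ct.reindex(index=rows, columns=cols, fill_value=0)
    if ct.shape[0] < 2 or ct.shape[1] < 2:
        raise ValueError(
            f"table {name or row_covariate!r} collapses below 2x2 after "
            f"excluding {list(exclude)}"
        )
    return ContingencyTable(
        row_labels=tuple(rows),
        col_labels=tuple(cols),
        counts=ct.to_numpy(),
        excluded_categories=tuple(exclude),
        name=name or f"{row_covariate} x {col_variable}",
    )


def pearson_chi2(table: ContingencyTable) -> AssociationResult:
    """Uncorrected Pearson chi-squared test of independence."""
    counts = table.counts
    if np.any(counts.sum(axis=0) == 0) or np.any(counts.sum(axis=1) == 0):
        raise ValueError(
            f"table {table.name!r} has a zero row/column total; "
            "chi-squared expected counts are undefined"
        )
    stat, p, df, _ = sps.chi2_contingency(counts, correction=False)
    return AssociationResult(
        method="pearson_chi2", statistic=float(stat), df=int(df), p_value=float(p)
    )


# --------------------------------------------------------------------------
# Freeman–Halton r x c Fisher exact test
# --------------------------------------------------------------------------

def _log_table_prob(counts: np.ndarray, lgf: np.ndarray) -> float:
    """log P(table | margins) under the multivariate hypergeometric null:
    (Π rows! Π cols!) / (N! Π cells!)."""
    rows = counts.sum(axis=1)
    cols = counts.sum(axis=0)
    n = counts.sum()
    return (
        lgf[rows].sum()
        + lgf[cols].sum()
        - lgf[n]
        - lgf[counts].sum()
    )


def _enumerate_tables(row_tot: np.ndarray, col_tot: np.ndarray):
    """Yield every non-negative integer matrix with the given margins.

    Depth-first over rows; each row is a bounded composition of its total
    over the remaining column capacity, pruned as soon as a partial fill
    becomes infeasible.
    """
    r = len(row_tot)

    def fill(i: int, remaining_cols: np.ndarray, acc: list[np.ndarray]):
        if i == r - 1:
            yield acc + [remaining_cols.copy()]
            return
        for row in _compositions(int(row_tot[i]), remaining_cols):
            yield from fill(i + 1, remaining_cols - row, acc + [row])

    def _compositions(total: int, caps: np.ndarray):
        c = len(caps)

        def rec(j: int, left: int, cur: list[int]):
            if j == c - 1:
                if left <= caps[j]:
                    yield np.array(cur + [left], dtype=np.int64)
                return
            # leave enough for the remaining columns' capacity
            min_here = max(0, left - int(caps[j + 1 :].sum()))
            for v in range(min_here, min(left, int(caps[j])) + 1):
                yield from rec(j + 1, left - v, cur + [v])

        yield from rec(0, total, [])

    yield from fill(0, col_tot.astype(np.int64).copy(), [])


def fisher_exact_rxc(
    table: ContingencyTable,
    *,
    max_n: int = 500,
    rel_tol: float = 1e-7,
) -> AssociationResult:
    """Freeman–Halton exact test by exhaustive enumeration.

    Sums the null probability of every table with the observed margins
    whose probability is at most that of the observed table (with relative
    tie tolerance ``rel_tol``). Guarded at ``max_n`` total observations;
    larger tables should use :func:`pearson_chi2`.
    """
    counts = table.counts
    n = int(counts.sum())
    if n == 0:
        raise ValueError("empty table")
    if n > max_n:
        raise ValueError(
            f"N={n} exceeds the enumeration guard ({max_n}); "
            "use pearson_chi2 for large tables"
        )
    lgf = np.array([lgamma(k + 1) for k in range(n + 1)])
    log_p_obs = _log_table_prob(counts, lgf)
    cutoff = log_p_obs + log1p(rel_tol)

    row_tot = counts.sum(axis=1)
    col_tot = counts.sum(axis=0)
    p = 0.0
    for rows in _enumerate_tables(row_tot, col_tot):
        t = np.stack(rows)
        lp = _log_table_prob(t, lgf)
        if lp <= cutoff:
            p += float(np.exp(lp))
    return AssociationResult(method="fisher_exact", p_value=min(p, 1.0))


def compare_conditions(
    sample_a: Iterable[float],
    sample_b: Iterable[float],
    *,
    equal_var: bool = True,
) -> ConditionComparison:
    """Two-sample unpaired t-test (pooled-variance by default, Welch via
    ``equal_var=False``) with the difference of means.

    Degenerate zero-variance inputs are resolved by the obvious limits:
    identical means give p = 1, separated means p = 0.
    """
    a = np.asarray(list(sample_a), dtype=float)
    b = np.asarray(list(sample_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    diff = float(a.mean() - b.mean())
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        df = float(a.size + b.size - 2)
        return ConditionComparison(
            statistic=0.0 if diff == 0 else float("inf"),
            df=df,
            p_value=1.0 if diff == 0 else 0.0,
            mean_difference=diff,
        )
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return ConditionComparison(
        statistic=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_difference=diff,
    )
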