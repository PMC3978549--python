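"""Contingency tabulation, Pearson chi-square, and logistic regression.

The analyses are simple by design: every comparison in the study is a
crosstab of coded variables tested with an uncorrected Pearson
chi-square, plus single-factor logistic regressions for the grouped
nontraditional-symptom outcomes.  No continuity correction is applied
anywhere — the printed p-values only reproduce without it — and no
multiple-testing adjustment is made, matching the source analyses.
Small expected cell counts trigger a warning rather than a silent
switch to an exact test.

P-values are rendered both to two and to three decimals with the
leading zero dropped (".056", ".01"), because the source mixes both
precisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .coding import (
    AGE_BANDS,
    CodedStory,
    RELATIONS,
    SYMPTOMS,
    derive_flags,
)

__all__ = [
    "ContingencyTable",
    "TestResult",
    "LogisticFit",
    "crosstab",
    "pearson_chi2",
    "chi2_sf",
    "fit_logistic",
    "logistic_from_2x2",
    "format_p",
    "percent_cell",
    "SmallExpectedCountWarning",
]

DERIVED_FLAGS = (
    "any_traditional", "any_nontraditional", "any_nontraditional_excl_msc",
)

_SCHEMA_ORDERS: dict[str, tuple] = {
    "patient_sex": ("female", "male"),
    "narrator": ("first", "third"),
    "stroke_type": ("ischemic", "hemorrhagic", "unknown"),
    "relation": RELATIONS,
    "age_band": AGE_BANDS,
    "hemiparesis_subtype": ("body", "face", "both"),
}
_BOOL_ORDER = (True, False)   # "yes" row first, as the tables print


class SmallExpectedCountWarning(UserWarning):
    """Expected cell count below 5: the chi-square approximation is thin."""


@dataclass
class ContingencyTable:
    """Labeled count matrix with margins; the unit of every test here."""

    row_labels: list
    col_labels: list
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("count matrix shape does not match labels")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.row_labels,
                            columns=self.col_labels)


def _value_of(record: CodedStory, var: str):
    if var in SYMPTOMS:
        return bool(record.symptoms.get(var, False))
    if var in DERIVED_FLAGS:
        return derive_flags(record)[var]
    if not hasattr(record, var):
        raise KeyError(f"unknown variable {var!r}")
    return getattr(record, var)


def _label_order(var: str, observed: set) -> list:
    if var in _SCHEMA_ORDERS:
        return [v for v in _SCHEMA_ORDERS[var] if v in observed]
    if observed <= {True, False}:
        return [v for v in _BOOL_ORDER if v in observed]
    return sorted(observed)


def crosstab(records: Sequence[CodedStory], row_var: str, col_var: str,
             where: Optional[Callable[[CodedStory], bool]] = None,
             ) -> ContingencyTable:
    """Cross-tabulate two coded variables over non-missing pairs.

    Records where either variable is missing (None) drop out of N, as
    do records failing the optional ``where`` predicate.  Label order is
    the schema's, not the data's, so tables are deterministic.
    """
    pairs = []
    for rec in records:
        if where is not None and not where(rec):
            continue
        r, c = _value_of(rec, row_var), _value_of(rec, col_var)
        if r is None or c is None:
            continue
        pairs.append((r, c))
    if not pairs:
        name = getattr(where, "__name__", repr(where)) if where else "no filter"
        raise ValueError(
            f"empty selection for crosstab({row_var}, {col_var}) [{name}]"
        )
    rows = _label_order(row_var, {r for r, _ in pairs})
    cols = _label_order(col_var, {c for _, c in pairs})
    counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
    ri = {v: i for i, v in enumerate(rows)}
    ci = {v: i for i, v in enumerate(cols)}
    for r, c in pairs:
        counts[ri[r], ci[c]] += 1
    return ContingencyTable(row_labels=rows, col_labels=cols, counts=counts)


def chi2_sf(x: float, df: int) -> float:
    """Chi-square survival function P(X >= x)."""
    if x < 0:
        raise ValueError("statistic must be non-negative")
    if df < 1:
        raise ValueError("df must be >= 1")
    return float(scipy.stats.chi2.sf(x, df))


def round_half_up(x: float, ndigits: int) -> str:
    """Fixed-point rendering with ties away from zero — the rounding
    convention summary tables use — rather than banker's rounding."""
    q = Decimal(1).scaleb(-ndigits)
    return str(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def format_p(p: float) -> tuple[str, str]:
    """Render a p-value to (2dp, 3dp) strings with leading zero dropped."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p out of [0,1]: {p}")
    out = []
    for nd in (2, 3):
        s = round_half_up(p, nd)
        if s.startswith("0."):
            s = s[1:]
        out.append(s)
    return out[0], out[1]


@dataclass
class TestResult:
    statistic: float
    df: int
    p: float
    min_expected: float = float("nan")

    @property
    def p_printed_2dp(self) -> str:
        return format_p(self.p)[0]

    @property
    def p_printed_3dp(self) -> str:
        return format_p(self.p)[1]

    def __str__(self) -> str:
        return (f"chi2({self.df}) = {self.statistic:.4f}, "
                f"P = {self.p_printed_3dp}")


def pearson_chi2(table: ContingencyTable) -> TestResult:
    """Pearson chi-square test of independence, no continuity correction.

    Expected counts are the usual margin products E = row*col/N; a zero
    row or column margin is a hard error (the test is undefined), and
    any expected count below 5 raises :class:`SmallExpectedCountWarning`.
    """
    if (table.row_margins == 0).any() or (table.col_margins == 0).any():
        raise ValueError("zero margin: chi-square test undefined")
    stat, p, dof, expected = scipy.stats.chi2_contingency(
        table.counts, correction=False
    )
    min_e = float(expected.min())
    if min_e < 5.0:
        warnings.warn(
            f"minimum expected cell count {min_e:.2f} < 5; chi-square "
            "approximation may be poor", SmallExpectedCountWarning,
            stacklevel=2,
        )
    return TestResult(statistic=float(stat), df=int(dof), p=float(p),
                      min_expected=min_e)


@dataclass
class LogisticFit:
    """Results of one logistic regression: estimates, their uncertainty,
    and all three classical tests of the non-intercept terms (Wald,
    likelihood ratio, score).  On a 2x2 problem the score test is
    algebraically the Pearson chi-square."""

    names: list[str]
    params: np.ndarray
    bse: np.ndarray
    wald_z: np.ndarray
    wald_p: np.ndarray
    llf: float
    llf_null: float
    lrt_stat: float
    lrt_df: int
    lrt_p: float
    score_stat: float
    score_df: int
    score_p: float
    converged: bool
    iterations: int

    @property
    def odds_ratios(self) -> np.ndarray:
        return np.exp(self.params)

    def summary(self) -> str:
        lines = [
            "Logistic regression (IRLS maximum likelihood)",
            f"  log-likelihood {self.llf:.4f}  (null {self.llf_null:.4f})",
            f"  converged: {self.converged}  iterations: {self.iterations}",
            f"  {'term':<24}{'coef':>10}{'se':>10}{'z':>8}{'P(Wald)':>10}{'OR':>8}",
        ]
        for i, name in enumerate(self.names):
            lines.append(
                f"  {name:<24}{self.params[i]:>10.4f}{self.bse[i]:>10.4f}"
                f"{self.wald_z[i]:>8.2f}{format_p(self.wald_p[i])[1]:>10}"
                f"{np.exp(self.params[i]):>8.3f}"
            )
        lines.append(
            f"  LRT chi2({self.lrt_df}) = {self.lrt_stat:.4f}, "
            f"P = {format_p(self.lrt_p)[1]}"
        )
        lines.append(
            f"  Score chi2({self.score_df}) = {self.score_stat:.4f}, "
            f"P = {format_p(self.score_p)[1]}"
        )
        return "\n".join(lines)


def _score_test(y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    # Score (Rao) test of all non-intercept terms at the intercept-only MLE.
    p0 = y.mean()
    if p0 <= 0.0 or p0 >= 1.0:
        raise ValueError("degenerate outcome: all responses identical")
    u = X.T @ (y - p0)
    info = (p0 * (1 - p0)) * (X.T @ X)
    stat = float(u @ np.linalg.pinv(info) @ u)
    df = int(np.linalg.matrix_rank(X)) - 1
    return stat, df


def fit_logistic(y: Sequence[float], X: np.ndarray,
                 names: Optional[list[str]] = None) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least
    squares (tolerance 1e-10 on the deviance, at most 50 iterations).

    ``X`` must carry the intercept as its first column.  Complete or
    quasi-complete separation is flagged (any |coefficient| > 15 marks
    the fit non-converged) rather than silently returned.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("design matrix and outcome sizes disagree")
    if not np.allclose(X[:, 0], 1.0):
        raise ValueError("first design column must be the intercept")
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate outcome: all responses identical")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if names is None:
        names = ["intercept"] + [f"x{i}" for i in range(1, X.shape[1])]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        res = model.fit(maxiter=50, tol=1e-10)  # IRLS; tol is on deviance change
        null = sm.GLM(y, X[:, :1], family=sm.families.Binomial()).fit(
            maxiter=50, tol=1e-10
        )

    params = np.asarray(res.params)
    separated = bool(np.any(np.abs(params) > 15.0))
    converged = bool(getattr(res, "converged", True)) and not separated
    iterations = len(res.fit_history.get("deviance", [])) - 1

    lrt_stat = float(2.0 * (res.llf - null.llf))
    lrt_df = X.shape[1] - 1
    score_stat, score_df = _score_test(y, X)
    wald_z = params / np.asarray(res.bse)
    return LogisticFit(
        names=names,
        params=params,
        bse=np.asarray(res.bse),
        wald_z=wald_z,
        wald_p=2.0 * scipy.stats.norm.sf(np.abs(wald_z)),
        llf=float(res.llf),
        llf_null=float(null.llf),
        lrt_stat=max(lrt_stat, 0.0),
        lrt_df=lrt_df,
        lrt_p=chi2_sf(max(lrt_stat, 0.0), lrt_df) if lrt_df else 1.0,
        score_stat=score_stat,
        score_df=score_df,
        score_p=chi2_sf(score_stat, score_df) if score_df else 1.0,
        converged=converged,
        iterations=max(iterations, 0),
    )


def logistic_from_2x2(table: ContingencyTable,
                      names: Optional[list[str]] = None) -> LogisticFit:
    """Fit outcome ~ row-factor from a 2x2 table (column 0 = event).

    The row factor is coded 1 for the first row, 0 for the second, so
    the slope is the log odds ratio of the first row against the second.
    """
    if table.counts.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    y, x = [], []
    for i in range(2):
        for j in range(2):
            c = int(table.counts[i, j])
            y.extend([1.0 - j] * c)      # col 0 = event
            x.extend([1.0 - i] * c)      # row 0 = exposed
    X = np.column_stack([np.ones(len(x)), x])
    if names is None:
        names = ["intercept", str(table.row_labels[0])]
    return fit_logistic(y, X, names=names)


def percent_cell(numerator: int, denominator: int) -> str:
    """Render "n/d = p%" with one decimal, the tables' percentage style."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    pct = round_half_up(100.0 * numerator / denominator, 1)
    return f"{numerator}/{denominator} = {pct}%"
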