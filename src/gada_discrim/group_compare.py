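"""Between-group inferential statistics for the baseline comparison table.

Continuous variables are compared with a pooled-variance two-sample t-test
(callable from group summaries or raw samples), common categorical variables
with a Pearson chi-square test without continuity correction, and sparse
categorical variables with a two-sided Fisher exact test using the
point-probability rule.  A Kolmogorov-Smirnov normality screen (Lilliefors
corrected for estimated parameters) flags non-normal variables.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .cohort_model import Cohort, Gender, Group
from .errors import DomainError

ALPHA = 0.05


class TestKind(str, enum.Enum):
    STUDENT_T = "STUDENT_T"
    CHI2 = "CHI2"
    FISHER_EXACT = "FISHER_EXACT"


@dataclass
class ComparisonRow:
    variable: str
    test: TestKind
    statistic: Optional[float]
    df: Optional[float]
    p_value: float
    #: per-group summary: (mean, sd) for continuous, (count, percent) for categorical
    group_summaries: dict


@dataclass
class NormalityResult:
    variable: str
    ks_statistic: float
    p_value: float

    @property
    def normal(self) -> bool:
        return self.p_value >= ALPHA


def pooled_t_test(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, int, float]:
    """Pooled-variance Student's t from group summaries.

    Returns (t, df, two-sided p) with df = n1 + n2 - 2.
    """
    if n1 < 2 or n2 < 2:
        raise DomainError(f"each group needs n >= 2, got ({n1}, {n2})")
    if sd1 < 0 or sd2 < 0:
        raise DomainError("standard deviations must be nonnegative")
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if pooled_var == 0:
        if mean1 == mean2:
            return 0.0, df, 1.0
        raise DomainError("degenerate samples: both SDs are zero with unequal means")
    t = (mean1 - mean2) / np.sqrt(pooled_var * (1.0 / n1 + 1.0 / n2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


def pooled_t_test_raw(sample1: Sequence[float], sample2: Sequence[float]) -> tuple[float, int, float]:
    """Pooled t from raw samples; agrees exactly with the summary form."""
    x1 = np.asarray(sample1, dtype=float)
    x2 = np.asarray(sample2, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise DomainError(f"each group needs n >= 2, got ({x1.size}, {x2.size})")
    return pooled_t_test(
        float(x1.mean()), float(x1.std(ddof=1)), x1.size,
        float(x2.mean()), float(x2.std(ddof=1)), x2.size,
    )


def pearson_chi2(table) -> tuple[float, int, float]:
    """Pearson chi-square on a 2x2 table, no continuity correction.

    Returns (X^2, df=1, two-sided p from chi-square with 1 df).
    """
    obs = np.asarray(table, dtype=float)
    if obs.shape != (2, 2) or np.any(obs < 0):
        raise DomainError("table must be 2x2 with nonnegative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        raise DomainError("all row and column margins must be positive")
    expected = np.outer(rows, cols) / obs.sum()
    x2 = float(((obs - expected) ** 2 / expected).sum())
    return x2, 1, float(stats.chi2.sf(x2, 1))


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p on a 2x2 table (point-probability rule).

    Sums hypergeometric probabilities of every table with point probability
    at most that of the observed table.  Degenerate tables (a zero margin)
    return p = 1.
    """
    obs = np.asarray(table)
    if obs.shape != (2, 2) or np.any(obs < 0) or not np.issubdtype(obs.dtype, np.integer):
        obs = np.asarray(table, dtype=float)
        if obs.shape != (2, 2) or np.any(obs < 0) or np.any(obs != np.round(obs)):
            raise DomainError("table must be 2x2 with nonnegative integer counts")
        obs = obs.astype(int)
    a = int(obs[0, 0])
    r1, r2 = int(obs[0].sum()), int(obs[1].sum())
    c1 = int(obs[:, 0].sum())
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return 1.0
    lo, hi = max(0, c1 - r2), min(c1, r1)
    support = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(support, n, r1, c1)
    p_obs = pmf[a - lo]
    # relative tolerance guards against float noise at ties
    return float(min(1.0, pmf[pmf <= p_obs * (1.0 + 1e-7)].sum()))


def ks_normality(sample: Sequence[float], lilliefors: bool = True) -> NormalityResult:
    """One-sample KS test against a normal with sample-estimated mean/SD.

    With ``lilliefors`` (default) the p-value is corrected for parameter
    estimation; otherwise the naive (anticonservative) KS p is returned.
    """
    x = np.asarray(sample, dtype=float)
    if x.size < 5:
        raise DomainError(f"need at least 5 observations, got {x.size}")
    sd = x.std(ddof=1)
    if sd == 0:
        raise DomainError("constant sample has no defined normality test")
    if lilliefors:
        d, p = _lilliefors(x, dist="norm")
    else:
        d, p = stats.kstest(x, "norm", args=(x.mean(), sd))[:2]
    return NormalityResult(variable="", ks_statistic=float(d), p_value=float(p))


# ---------------------------------------------------------------------------
# Whole-table comparison
# ---------------------------------------------------------------------------

#: (variable, test) in the report's row order.
TABLE_ROWS = (
    ("gender", TestKind.CHI2),
    ("age_onset", TestKind.STUDENT_T),
    ("bmi", TestKind.STUDENT_T),
    ("total_chol", TestKind.STUDENT_T),
    ("tg", TestKind.STUDENT_T),
    ("hdl", TestKind.STUDENT_T),
    ("hba1c", TestKind.STUDENT_T),
    ("gpt", TestKind.STUDENT_T),
    ("creatinine", TestKind.STUDENT_T),
    ("smoking", TestKind.CHI2),
    ("statin", TestKind.FISHER_EXACT),
    ("fibrate", TestKind.FISHER_EXACT),
)


def _binary_counts(records, variable) -> tuple[int, int]:
    """(positive count, total with data) for a binary variable."""
    pos = tot = 0
    for rec in records:
        if variable == "gender":
            value = None if rec.gender is None else rec.gender is Gender.M
        else:
            value = getattr(rec, variable)
        if value is None:
            continue
        tot += 1
        pos += int(value)
    return pos, tot


def compare_table(cohort: Cohort) -> list[ComparisonRow]:
    """Row-per-variable between-group comparison (complete case per row)."""
    cohort.require_two_groups()
    cases, refs = cohort.split()

    out: list[ComparisonRow] = []
    for variable, kind in TABLE_ROWS:
        if kind is TestKind.STUDENT_T:
            x1 = np.array([getattr(r, variable) for r in cases if getattr(r, variable) is not None])
            x2 = np.array([getattr(r, variable) for r in refs if getattr(r, variable) is not None])
            t, df, p = pooled_t_test_raw(x1, x2)
            summaries = {
                Group.GADA_POS: (float(x1.mean()), float(x1.std(ddof=1))),
                Group.T2DM: (float(x2.mean()), float(x2.std(ddof=1))),
            }
            out.append(ComparisonRow(variable, kind, t, float(df), p, summaries))
        else:
            pos1, tot1 = _binary_counts(cases, variable)
            pos2, tot2 = _binary_counts(refs, variable)
            table = [[pos1, tot1 - pos1], [pos2, tot2 - pos2]]
            summaries = {
                Group.GADA_POS: (pos1, 100.0 * pos1 / tot1 if tot1 else float("nan")),
                Group.T2DM: (pos2, 100.0 * pos2 / tot2 if tot2 else float("nan")),
            }
            if kind is TestKind.CHI2:
                x2stat, df, p = pearson_chi2(table)
                out.append(ComparisonRow(variable, kind, x2stat, float(df), p, summaries))
            else:
                p = fisher_exact(table)
                out.append(ComparisonRow(variable, kind, None, None, p, summaries))
    return out
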