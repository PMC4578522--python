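"""Cohort descriptive table: group comparisons of binary traits and
continuous variables between controlled and uncontrolled asthma.

Binary traits are compared with the Pearson chi-square test without
continuity correction (Fisher's exact test when any expected cell count
falls below 1, or on request); continuous variables with the two-sided
rank-sum test. Printed percentages can be converted back to integer counts
for re-analysis of published tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CohortRow:
    variable: str
    group0_summary: float
    group1_summary: float
    test: str  # "chi2" | "fisher" | "ranksum"
    p: float


def percent_to_counts(percent: float, group_n: int) -> int:
    """Nearest-integer count implied by a printed percentage.

    Exact .5 cases round half to even (Python round), e.g. 87.5% of 8 -> 7.
    """
    if not 0 <= percent <= 100:
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    if group_n < 1:
        raise ValueError("group_n must be >= 1")
    return int(round(percent / 100.0 * group_n))


def _as_table(table) -> np.ndarray:
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("table entries must be non-negative integers")
    return t


def chi2_test(table) -> tuple[float, float]:
    """Pearson chi-square on a 2x2 table, 1 df, no continuity correction."""
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("zero margin: use fisher_exact instead")
    stat, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p: sum of hypergeometric probabilities of
    all tables (margins fixed) no more probable than the observed one."""
    t = _as_table(table)
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t.astype(int), alternative="two-sided")[1])


def expected_counts(table) -> np.ndarray:
    t = _as_table(table)
    return np.outer(t.sum(axis=1), t.sum(axis=0)) / t.sum()


def binary_trait_test(table, force: str | None = None) -> CohortRow | tuple:
    """Pick chi-square unless an expected cell is below 1 (then Fisher)."""
    t = _as_table(table)
    use_fisher = force == "fisher" or (
        force is None and (expected_counts(t) < 1).any())
    if use_fisher:
        return "fisher", fisher_exact(t)
    return "chi2", chi2_test(t)[1]


def reconstruct_table(percent0: float, n0: int, percent1: float,
                      n1: int) -> np.ndarray:
    """2x2 counts [[yes0, no0], [yes1, no1]] from printed percentages."""
    a = percent_to_counts(percent0, n0)
    b = percent_to_counts(percent1, n1)
    return np.array([[a, n0 - a], [b, n1 - b]])


def build_cohort_table(
    phenotype: pd.Series,
    binary_traits: pd.DataFrame | None = None,
    continuous_vars: pd.DataFrame | None = None,
    force_test: str | None = None,
) -> pd.DataFrame:
    """Group summaries and tests for every requested variable.

    ``binary_traits``: subject x trait 0/1 indicators (summary = percent
    positive per group); ``continuous_vars``: subject x variable values
    (summary = group mean, rank-sum p).
    """
    y = phenotype.astype(int)
    rows: list[CohortRow] = []
    if binary_traits is not None:
        for var in binary_traits.columns:
            x = binary_traits[var].astype(int)
            table = np.array([
                [(x[y == 0] == 1).sum(), (x[y == 0] == 0).sum()],
                [(x[y == 1] == 1).sum(), (x[y == 1] == 0).sum()],
            ])
            test, p = binary_trait_test(table, force=force_test)
            rows.append(CohortRow(
                var,
                100.0 * x[y == 0].mean(),
                100.0 * x[y == 1].mean(),
                test, p,
            ))
    if continuous_vars is not None:
        for var in continuous_vars.columns:
            x = continuous_vars[var].astype(float)
            g0 = x[y == 0].dropna()
            g1 = x[y == 1].dropna()
            if np.ptp(np.concatenate([g0, g1])) == 0:
                p = 1.0
            else:
                p = float(stats.mannwhitneyu(
                    g0, g1, alternative="two-sided").pvalue)
            rows.append(CohortRow(var, float(g0.mean()), float(g1.mean()),
                                  "ranksum", p))
    return pd.DataFrame(
        [{"variable": r.variable, "group0": r.group0_summary,
          "group1": r.group1_summary, "test": r.test, "p": r.p}
         for r in rows]
    )
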