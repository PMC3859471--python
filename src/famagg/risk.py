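"""Cohort-standardised relative risks in relatives and prevalence tables.

The population of phenotyped individuals is partitioned into cohorts by
birth year (5-year bins), sex, and birthplace.  Cohort-specific rates
(cases / phenotyped per cohort) give the expected number of cases in any
subset of phenotyped individuals; the relative risk in d-th-degree
relatives of case probands is observed / expected with relatives counted
once at their minimal degree.  Confidence intervals for the RR use a
log-scale Poisson interval ``exp(ln RR +/- z * sqrt(1/observed))``;
two-sided p-values are exact Poisson doubled smaller tails.  Prevalence
confidence intervals are exact Clopper-Pearson.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import Genealogy

__all__ = [
    "clopper_pearson",
    "prevalence_by_age",
    "CohortModel",
    "assign_cohorts",
    "expected_cases",
    "agresti_ci",
    "poisson_two_sided_p",
    "relative_risk_table",
]

logger = logging.getLogger(__name__)


# ----------------------------------------------------------------------
# prevalence
# ----------------------------------------------------------------------

def clopper_pearson(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Exact (beta-quantile) binomial confidence interval for k/n."""
    if not (0 <= k <= n) or n < 1:
        raise ValueError(f"invalid counts k={k}, n={n}")
    alpha = 1.0 - level
    low = 0.0 if k == 0 else float(stats.beta.ppf(alpha / 2, k, n - k + 1))
    high = 1.0 if k == n else float(stats.beta.ppf(1 - alpha / 2, k + 1, n - k))
    return low, high


def prevalence_by_age(
    phenotype: pd.DataFrame,
    age_bins: Sequence[tuple[int, int]],
    case_col: str = "case",
    age_col: str = "age",
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-age-bin case counts, prevalence, and Clopper-Pearson CI.

    ``phenotype`` needs one row per individual with a boolean ``case``
    column and an integer ``age`` column (age at the most recent record).
    Bins are inclusive on both ends.  Empty bins get NaN prevalence and
    are flagged in the ``empty`` column.
    """
    rows = []
    for lo, hi in age_bins:
        sub = phenotype[(phenotype[age_col] >= lo) & (phenotype[age_col] <= hi)]
        n = len(sub)
        k = int(sub[case_col].sum())
        if n > 0:
            prev = k / n
            ci_low, ci_high = clopper_pearson(k, n, level)
        else:
            prev = ci_low = ci_high = float("nan")
        rows.append(
            {
                "age_low": lo,
                "age_high": hi,
                "cases": k,
                "n": n,
                "prevalence": prev,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "empty": n == 0,
            }
        )
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# cohorts
# ----------------------------------------------------------------------

@dataclass
class CohortModel:
    """Cohort assignment and rates for a phenotyped population.

    ``assignments`` maps individual id -> cohort key
    ``(birth_year_bin, sex, birthplace)``; ``table`` holds per-cohort
    ``n_phenotyped``, ``n_cases`` and ``rate``; ``n_excluded`` counts
    individuals dropped for missing attributes.
    """

    assignments: dict[str, tuple[int, str, str]]
    table: pd.DataFrame
    bin_width: int
    n_excluded: int = 0

    @property
    def rates(self) -> Mapping[tuple[int, str, str], float]:
        return self.table["rate"].to_dict()


def assign_cohorts(
    g: Genealogy,
    phenotyped: Iterable[str],
    cases: Iterable[str],
    bin_width: int = 5,
) -> CohortModel:
    """Partition the phenotyped population into birth-year x sex x
    birthplace cohorts and compute cohort-specific case rates."""
    cases = set(cases)
    assignments: dict[str, tuple[int, str, str]] = {}
    n_excluded = 0
    for iid in sorted(set(phenotyped)):
        ind = g.individual(iid)
        if ind.birth_year is None or ind.sex is None or ind.birthplace is None:
            n_excluded += 1
            continue
        assignments[iid] = (ind.birth_year // bin_width, ind.sex, ind.birthplace)
    if n_excluded:
        logger.warning(
            "%d phenotyped individuals excluded from cohorts (missing "
            "birth year, sex, or birthplace)", n_excluded,
        )
    df = pd.DataFrame(
        {
            "cohort": list(assignments.values()),
            "case": [iid in cases for iid in assignments],
        }
    )
    table = (
        df.groupby("cohort")
        .agg(n_phenotyped=("case", "size"), n_cases=("case", "sum"))
        .sort_index()
    )
    table["rate"] = table["n_cases"] / table["n_phenotyped"]
    return CohortModel(assignments=assignments, table=table,
                       bin_width=bin_width, n_excluded=n_excluded)


def expected_cases(relatives: Iterable[str], cohorts: CohortModel) -> float:
    """Expected case count in a deduplicated, phenotyped relative set:
    sum over cohorts of (#relatives in cohort) x cohort rate."""
    rates = cohorts.rates
    total = 0.0
    for iid in set(relatives):
        key = cohorts.assignments.get(iid)
        if key is not None:
            total += rates[key]
    return total


# ----------------------------------------------------------------------
# relative risk
# ----------------------------------------------------------------------

def agresti_ci(
    observed: int,
    expected: float,
    level: float = 0.95,
    method: str = "log",
) -> tuple[float, float]:
    """Confidence interval for RR = observed/expected, observed treated
    as Poisson with the expected count fixed.

    ``method="log"`` (default) is the positivity-preserving log-scale
    interval ``exp(ln RR +/- z sqrt(1/observed))``; ``method="wald"`` is
    the ratio-scale alternative ``RR +/- z sqrt(observed)/expected``.
    With observed 0 the lower limit is 0 and the upper limit is the
    one-sided Poisson bound ``-ln(1 - level)/expected``.
    """
    if observed < 0 or expected <= 0:
        raise ValueError("observed must be >= 0 and expected > 0")
    z = stats.norm.ppf(1 - (1 - level) / 2)
    if observed == 0:
        return 0.0, float(-math.log(1 - level) / expected)
    rr = observed / expected
    if method == "log":
        half = z * math.sqrt(1.0 / observed)
        return rr * math.exp(-half), rr * math.exp(half)
    if method == "wald":
        half = z * math.sqrt(observed) / expected
        return max(0.0, rr - half), rr + half
    raise ValueError(f"unknown CI method {method!r}")


def poisson_two_sided_p(observed: int, expected: float) -> float:
    """Exact two-sided Poisson tail probability at the observed count:
    twice the smaller of P(X <= obs) and P(X >= obs), capped at 1."""
    if observed < 0 or expected <= 0:
        raise ValueError("observed must be >= 0 and expected > 0")
    lower = stats.poisson.cdf(observed, expected)
    upper = stats.poisson.sf(observed - 1, expected)
    return float(min(1.0, 2.0 * min(lower, upper)))


def relative_risk_table(
    g: Genealogy,
    probands: Iterable[str],
    cases: Iterable[str],
    cohorts: CohortModel,
    max_degree: int = 7,
    level: float = 0.95,
    ci_method: str = "log",
) -> pd.DataFrame:
    """Observed/expected relative risks in 1st..max_degree-degree
    relatives of the probands.

    Each degree is counted independently: row d spans every phenotyped
    individual having some proband at degree exactly d (rows overlap; a
    case that is a relative of another case contributes to the observed
    count of every row where it appears; within a row each individual
    counts once).  Rows with zero expected and positive observed are
    flagged undefined.
    """
    probands = set(probands)
    cases = set(cases)
    phenotyped = set(cohorts.assignments)
    degree_rows = g.relatives_at_degrees(probands, max_degree)
    rows = []
    for degree in range(1, max_degree + 1):
        rel = degree_rows.get(degree, set()) & phenotyped
        n_rel = len(rel)
        obs = len(rel & cases)
        exp = expected_cases(rel, cohorts)
        if exp > 0:
            rr = obs / exp
            ci_low, ci_high = agresti_ci(obs, exp, level, ci_method)
            p = poisson_two_sided_p(obs, exp)
            undefined = False
        else:
            rr = ci_low = ci_high = p = float("nan")
            undefined = obs > 0
        rows.append(
            {
                "degree": degree,
                "n_relatives": n_rel,
                "observed": obs,
                "expected": exp,
                "rr": rr,
                "ci_low": ci_low,
                "ci_high": ci_high,
                "p_two_sided": p,
                "undefined": undefined,
            }
        )
    return pd.DataFrame(rows)
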