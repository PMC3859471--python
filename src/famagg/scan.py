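"""High-risk pedigree discovery.

Every founding anchor (a founder couple when both spouses are recorded,
a single founder otherwise) defines a pedigree: the union of the
anchor's descendants.  Case clusters are the case subsets of those
pedigrees (size >= 2), with clusters that are subsets of another
retained cluster removed — individuals may still belong to several
retained clusters.  Each anchor's descendancy is then tested for an
excess of cases against the expectation under cohort-specific rates,
using a one-sided Poisson upper tail; pedigrees passing a significance
and minimum-case filter are reported as high-risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy import stats

from .pedigree import Genealogy
from .risk import CohortModel, expected_cases

__all__ = [
    "CaseCluster",
    "HighRiskPedigree",
    "founding_anchors",
    "find_case_clusters",
    "descendant_excess_test",
    "select_high_risk",
    "scan_high_risk",
]


@dataclass(frozen=True)
class CaseCluster:
    """Case descendants of one founding anchor (size >= 2)."""

    founder: tuple[str, ...]  # one or two founder ids, sorted
    members: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class HighRiskPedigree:
    """Observed-vs-expected case excess in one anchor's descendancy."""

    founder: tuple[str, ...]
    n_descendants_phenotyped: int
    observed: int
    expected: float
    p_excess: float
    case_ids: frozenset[str] = field(default_factory=frozenset)


def founding_anchors(g: Genealogy) -> list[tuple[str, ...]]:
    """Founding couples (both co-parents founders) plus single founders
    whose co-parent is unrecorded or not a founder, sorted for stable
    output."""
    founders = g.founders()
    couples: set[tuple[str, ...]] = set()
    singles: set[str] = set()
    for f in sorted(founders):
        for child in g.children(f):
            fa, mo = g.parents(child)
            other = mo if fa == f else fa
            if other is not None and other in founders:
                couples.add(tuple(sorted((f, other))))
            else:
                singles.add(f)
    # a founder already anchored by a couple needs no separate single anchor
    in_couples = {m for c in couples for m in c}
    anchors: list[tuple[str, ...]] = sorted(couples) + sorted(
        (s,) for s in singles - in_couples
    )
    return anchors


def _anchor_descendants(g: Genealogy, anchor: tuple[str, ...]) -> set[str]:
    desc: set[str] = set()
    for a in anchor:
        desc |= g.descendants(a)
    return desc


def find_case_clusters(
    g: Genealogy,
    cases: Iterable[str],
    anchors: Iterable[tuple[str, ...]] | None = None,
) -> list[CaseCluster]:
    """All maximal founder-anchored clusters of related cases.

    For every anchor, the cluster is its case descendants when at least
    two exist; clusters whose member set is contained in another
    retained cluster are dropped (ties broken by anchor id, keeping the
    first in sorted order)."""
    cases = set(cases)
    if anchors is None:
        anchors = founding_anchors(g)
    raw: list[CaseCluster] = []
    for anchor in anchors:
        members = frozenset(_anchor_descendants(g, anchor) & cases)
        if len(members) >= 2:
            raw.append(CaseCluster(founder=tuple(anchor), members=members))
    # maximality filter: drop subset (or duplicate) clusters
    raw.sort(key=lambda c: (-c.size, c.founder))
    kept: list[CaseCluster] = []
    for cl in raw:
        if not any(cl.members <= other.members for other in kept):
            kept.append(cl)
    kept.sort(key=lambda c: c.founder)
    return kept


def descendant_excess_test(
    g: Genealogy,
    anchor: tuple[str, ...] | str,
    cases: Iterable[str],
    cohorts: CohortModel,
) -> HighRiskPedigree:
    """One-sided Poisson test for an excess of cases among the
    phenotyped descendants of an anchor.

    Expected = sum of cohort rates over phenotyped descendants;
    p = P(X >= observed | X ~ Poisson(expected)).  Raises if the anchor
    has no phenotyped descendant.
    """
    if isinstance(anchor, str):
        anchor = (anchor,)
    anchor = tuple(sorted(anchor))
    cases = set(cases)
    desc = _anchor_descendants(g, anchor)
    phen = desc & set(cohorts.assignments)
    if not phen:
        raise ValueError(f"anchor {anchor} has no phenotyped descendant")
    case_ids = frozenset(phen & cases)
    observed = len(case_ids)
    expected = expected_cases(phen, cohorts)
    p = float(stats.poisson.sf(observed - 1, expected)) if expected > 0 else float("nan")
    return HighRiskPedigree(
        founder=anchor,
        n_descendants_phenotyped=len(phen),
        observed=observed,
        expected=expected,
        p_excess=p,
        case_ids=case_ids,
    )


def select_high_risk(
    pedigrees: Iterable[HighRiskPedigree],
    alpha: float = 1e-4,
    min_cases: int = 10,
) -> list[HighRiskPedigree]:
    """Pedigrees with p_excess < alpha and at least ``min_cases``
    observed cases, sorted by ascending p."""
    out = [p for p in pedigrees
           if p.p_excess < alpha and p.observed >= min_cases]
    out.sort(key=lambda p: (p.p_excess, p.founder))
    return out


def scan_high_risk(
    g: Genealogy,
    cases: Iterable[str],
    cohorts: CohortModel,
    alpha: float = 1e-4,
    min_cases: int = 10,
) -> tuple[list[CaseCluster], list[HighRiskPedigree]]:
    """Full scan: enumerate clusters, test each cluster's anchor, filter.

    Returns (retained clusters, selected high-risk pedigrees)."""
    cases = set(cases)
    clusters = find_case_clusters(g, cases)
    tested = [descendant_excess_test(g, cl.founder, cases, cohorts)
              for cl in clusters]
    return clusters, select_high_risk(tested, alpha, min_cases)


def high_risk_table(pedigrees: Iterable[HighRiskPedigree]) -> pd.DataFrame:
    """Tabular view of excess-test results."""
    return pd.DataFrame(
        {
            "founder": ["+".join(p.founder) for p in pedigrees],
            "n_descendants_phenotyped": [p.n_descendants_phenotyped for p in pedigrees],
            "observed": [p.observed for p in pedigrees],
            "expected": [p.expected for p in pedigrees],
            "p_excess": [p.p_excess for p in pedigrees],
        }
    )
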