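"""Shared pedigree fixtures.

All fixtures are built programmatically; the simulator provides larger
random populations.
"""

from __future__ import annotations

import pytest

from famagg.pedigree import Genealogy, Individual
from famagg.simulate import SimConfig, simulate_population


def ind(iid, father=None, mother=None, sex=None, year=None, place=None):
    return Individual(id=iid, father_id=father, mother_id=mother,
                      sex=sex, birth_year=year, birthplace=place)


@pytest.fixture
def nuclear():
    """Founder couple with two children (full sibs)."""
    return Genealogy([
        ind("f", sex="M", year=1900, place="in"),
        ind("m", sex="F", year=1902, place="in"),
        ind("c1", "f", "m", "M", 1925, "in"),
        ind("c2", "f", "m", "F", 1927, "in"),
    ])


@pytest.fixture
def three_gen():
    """Founder couple, two sibling offspring married to unrelated
    spouses, one child each: the two grandchildren are first cousins."""
    return Genealogy([
        ind("gf", sex="M", year=1900), ind("gm", sex="F", year=1900),
        ind("p1", "gf", "gm", "M", 1925), ind("p2", "gf", "gm", "F", 1927),
        ind("s1", sex="F", year=1926), ind("s2", sex="M", year=1926),
        ind("c1", "p1", "s1", "M", 1950), ind("c2", "s2", "p2", "F", 1952),
    ])


@pytest.fixture
def half_sib_pedigree():
    """One shared father, two mothers -> half siblings."""
    return Genealogy([
        ind("dad", sex="M"), ind("mom1", sex="F"), ind("mom2", sex="F"),
        ind("h1", "dad", "mom1", "M"), ind("h2", "dad", "mom2", "F"),
    ])


def complete_pedigree(n_great_grandparents: int) -> tuple[Genealogy, str]:
    """Four-generation pedigree where the focal individual has 2 parents,
    4 grandparents, and a configurable number of recorded
    great-grandparents (0..8).  Returns (genealogy, focal id)."""
    assert 0 <= n_great_grandparents <= 8
    inds = []
    ggp_ids: list[str | None] = []
    for i in range(8):
        if i < n_great_grandparents:
            sex = "M" if i % 2 == 0 else "F"
            inds.append(ind(f"ggp{i}", sex=sex))
            ggp_ids.append(f"ggp{i}")
        else:
            ggp_ids.append(None)
    for j in range(4):  # grandparents, each couple of great-grandparents
        sex = "M" if j % 2 == 0 else "F"
        father, mother = ggp_ids[2 * j], ggp_ids[2 * j + 1]
        inds.append(ind(f"gp{j}", father, mother, sex))
    inds.append(ind("pa", "gp0", "gp1", "M"))
    inds.append(ind("ma", "gp2", "gp3", "F"))
    inds.append(ind("focal", "pa", "ma", "M"))
    return Genealogy(inds), "focal"


@pytest.fixture(params=[0, 1, 2, 3, 4, 5])
def random_pedigree(request):
    """Small random multi-generation pedigree (a few dozen individuals)
    for oracle-equivalence property tests."""
    cfg = SimConfig(n_founder_couples=3, n_generations=4, mean_children=2.2,
                    immigrant_spouse_fraction=0.3, phenotype_coverage=1.0)
    pop = simulate_population(cfg, seed=request.param)
    return pop.genealogy


@pytest.fixture(scope="session")
def medium_population():
    """One moderately sized heritable population shared across tests."""
    cfg = SimConfig(n_founder_couples=120, h2=0.5, c2=0.1,
                    prevalence_by_age={(0, 200): 0.06},
                    phenotype_coverage=0.8)
    return simulate_population(cfg, seed=42)
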