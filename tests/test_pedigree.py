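"""Genealogy model: distances, coefficients, degrees, filters — with
independent graph-algorithm oracles on random pedigrees."""

from __future__ import annotations

import math

import networkx as nx
import pytest

from famagg.pedigree import (
    CycleError,
    Genealogy,
    Individual,
    PedigreeError,
    UnknownIndividualError,
)

from conftest import complete_pedigree, ind


# ----------------------------------------------------------------------
# construction and validation
# ----------------------------------------------------------------------

def test_duplicate_id_rejected():
    with pytest.raises(PedigreeError, match="duplicate"):
        Genealogy([ind("a"), ind("a")])


def test_unknown_parent_rejected():
    with pytest.raises(PedigreeError, match="unknown father"):
        Genealogy([ind("kid", father="ghost")])


def test_parent_sex_mismatch_rejected():
    with pytest.raises(PedigreeError, match="recorded female"):
        Genealogy([ind("p", sex="F"), ind("kid", father="p")])


def test_cycle_rejected():
    with pytest.raises(CycleError, match="a"):
        Genealogy([
            Individual("a", father_id="b"),
            Individual("b", father_id="a"),
        ])


# ----------------------------------------------------------------------
# completeness filter
# ----------------------------------------------------------------------

@pytest.mark.parametrize(
    "n_ggp,included", [(8, True), (7, True), (6, True), (5, False), (0, False)]
)
def test_completeness_threshold(n_ggp, included):
    """Both parents + 4 grandparents + >=6 of 8 great-grandparents."""
    g, focal = complete_pedigree(n_ggp)
    assert (focal in g.completeness_filter()) is included


def test_completeness_excludes_founders_and_shallow(nuclear):
    # founders have no parents; children lack grandparents
    assert nuclear.completeness_filter() == set()


# ----------------------------------------------------------------------
# genetic distance and relatedness coefficient
# ----------------------------------------------------------------------

def test_distance_examples(nuclear, three_gen):
    assert nuclear.genetic_distance("f", "c1") == 1      # parent/offspring
    assert nuclear.genetic_distance("c1", "c2") == 2     # full sibs
    assert three_gen.genetic_distance("p1", "c2") == 3   # avuncular
    assert three_gen.genetic_distance("c1", "c2") == 4   # first cousins
    assert math.isinf(three_gen.genetic_distance("s1", "s2"))  # disjoint founders


def test_coefficient_printed_values(nuclear, three_gen):
    """The published convention: 0.50 PO, 0.25 sibs, 0.125 avuncular,
    0.0625 first cousins, 0 unrelated."""
    assert nuclear.relatedness_coefficient("f", "c1") == 0.5
    assert nuclear.relatedness_coefficient("c1", "c2") == 0.25
    assert three_gen.relatedness_coefficient("p1", "c2") == 0.125
    assert three_gen.relatedness_coefficient("c1", "c2") == 0.0625
    assert three_gen.relatedness_coefficient("s1", "s2") == 0.0


def test_distance_errors(nuclear):
    with pytest.raises(UnknownIndividualError):
        nuclear.genetic_distance("f", "nobody")
    with pytest.raises(PedigreeError):
        nuclear.genetic_distance("f", "f")


# ----------------------------------------------------------------------
# degree of relationship
# ----------------------------------------------------------------------

def test_degree_examples(three_gen, half_sib_pedigree):
    assert three_gen.degree_of_relationship("gm", "c1") == 2   # grandmother
    assert three_gen.degree_of_relationship("p1", "c2") == 2   # uncle
    assert three_gen.degree_of_relationship("c1", "c2") == 3   # first cousin
    # half-sibs share one parent only: no sib edge, path via the parent
    assert half_sib_pedigree.degree_of_relationship("h1", "h2") == 2


def test_degree_follows_relation_graph_through_marriages(three_gen):
    """The relation graph links spouses through their shared offspring,
    so affinal pairs get a finite degree even at infinite genetic
    distance (s1-c1-p1-p2-c2-s2)."""
    assert three_gen.degree_of_relationship("s1", "s2") == 5
    assert math.isinf(three_gen.genetic_distance("s1", "s2"))


def test_degree_disconnected():
    g = Genealogy([
        ind("a", sex="M"), ind("b", sex="F"), ind("kid", "a", "b", "M"),
        ind("z", sex="M"),
    ])
    assert math.isinf(g.degree_of_relationship("kid", "z"))


# ----------------------------------------------------------------------
# relatives by degree
# ----------------------------------------------------------------------

def test_relatives_by_degree_nuclear(three_gen):
    # proband c1: parents p1, s1 and no sibs/offspring -> 2 at degree 1
    buckets = three_gen.relatives_by_degree({"c1"}, 3)
    assert buckets[1] == {"p1", "s1"}
    assert buckets[2] == {"gf", "gm", "p2"}
    assert buckets[3] == {"c2"}


def test_relatives_minimal_degree_rule():
    """A sibling of one proband who is also a cousin of another lands
    only in the degree-1 bucket."""
    g = Genealogy([
        ind("gf", sex="M"), ind("gm", sex="F"),
        ind("p1", "gf", "gm", "M"), ind("p2", "gf", "gm", "F"),
        ind("s1", sex="F"), ind("s2", sex="M"),
        ind("a", "p1", "s1", "M"), ind("b", "p1", "s1", "F"),
        ind("c", "s2", "p2", "M"),
    ])
    buckets = g.relatives_by_degree({"a", "c"}, 3)
    assert "b" in buckets[1] and all("b" not in buckets[d] for d in (2, 3))


def test_relatives_exclude_probands(three_gen):
    buckets = three_gen.relatives_by_degree({"c1", "c2"}, 3)
    assert all("c1" not in s and "c2" not in s for s in buckets.values())


def test_relatives_at_degrees_rows_overlap():
    """Per-degree rows: an individual appears in every row where some
    proband sits at exactly that degree."""
    g = Genealogy([
        ind("gf", sex="M"), ind("gm", sex="F"),
        ind("p1", "gf", "gm", "M"), ind("p2", "gf", "gm", "F"),
        ind("s1", sex="F"), ind("s2", sex="M"),
        ind("a", "p1", "s1", "M"), ind("b", "p1", "s1", "F"),
        ind("c", "s2", "p2", "M"),
    ])
    rows = g.relatives_at_degrees({"a", "c"}, 3)
    assert "b" in rows[1]   # sibling of proband a
    assert "b" in rows[3]   # first cousin of proband c
    assert "a" in rows[3] and "c" in rows[3]  # probands are mutual cousins


# ----------------------------------------------------------------------
# founders and descendants
# ----------------------------------------------------------------------

def test_founders_and_descendants():
    g = Genealogy([
        ind("f", sex="M"), ind("m", sex="F"),
        ind("c0", "f", "m", "M"), ind("c1", "f", "m", "F"), ind("c2", "f", "m", "M"),
        ind("s0", sex="F"), ind("s1", sex="M"), ind("s2", sex="F"),
        *[ind(f"g{i}{j}", ["c0", "s1", "c2"][i], ["s0", "c1", "s2"][i], "M")
          for i in range(3) for j in range(3)],
    ])
    assert g.founders() == {"f", "m", "s0", "s1", "s2"}
    # 3 children + 9 grandchildren descend from the founder
    assert len(g.descendants("f")) == 12
    assert g.descendants("g00") == set()


def test_descendants_chain():
    n = 7
    inds = [ind("x0", sex="M")]
    for i in range(1, n + 1):
        inds.append(ind(f"x{i}", father=f"x{i-1}", sex="M"))
    g = Genealogy(inds)
    assert len(g.descendants("x0")) == n


# ----------------------------------------------------------------------
# oracle equivalence and invariants on random pedigrees
# ----------------------------------------------------------------------

def _oracle_genetic_distance(g: Genealogy, a: str, b: str) -> float:
    """Independent oracle: min over common ancestors of the sum of
    shortest paths in the child->parent digraph (networkx BFS)."""
    dg = nx.DiGraph()
    dg.add_nodes_from(i.id for i in g)
    for i in g:
        for p in i.parent_ids:
            if p is not None:
                dg.add_edge(i.id, p)
    da = nx.single_source_shortest_path_length(dg, a)
    db = nx.single_source_shortest_path_length(dg, b)
    common = set(da) & set(db)
    return min((da[c] + db[c] for c in common), default=math.inf)


def _oracle_relation_graph(g: Genealogy) -> nx.Graph:
    ug = nx.Graph()
    ug.add_nodes_from(i.id for i in g)
    members = list(g)
    for i in members:
        for p in i.parent_ids:
            if p is not None:
                ug.add_edge(i.id, p)
    for i in members:
        for j in members:
            if i.id < j.id and i.father_id is not None and i.mother_id is not None:
                if (i.father_id, i.mother_id) == (j.father_id, j.mother_id):
                    ug.add_edge(i.id, j.id)
    return ug


def test_distance_and_degree_match_oracle(random_pedigree):
    g = random_pedigree
    ids = sorted(g.ids)[:60]
    ug = _oracle_relation_graph(g)
    deg_oracle = dict(nx.all_pairs_shortest_path_length(ug))
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            d = g.genetic_distance(a, b)
            assert d == _oracle_genetic_distance(g, a, b)
            expected_deg = deg_oracle.get(a, {}).get(b, math.inf)
            assert g.degree_of_relationship(a, b) == expected_deg
            # symmetry and coefficient law
            assert g.genetic_distance(b, a) == d
            coef = g.relatedness_coefficient(a, b)
            assert coef == (0.0 if math.isinf(d) else 2.0 ** (-d))
            # each meiotic step is a relation-graph edge
            if not math.isinf(d):
                assert g.degree_of_relationship(a, b) <= d


def test_halving_law(three_gen):
    """Coefficient halves per unit of genetic distance."""
    pairs = [("gf", "p1"), ("p1", "p2"), ("p1", "c2"), ("c1", "c2")]
    coefs = [three_gen.relatedness_coefficient(a, b) for a, b in pairs]
    dists = [three_gen.genetic_distance(a, b) for a, b in pairs]
    assert dists == [1, 2, 3, 4]
    for lo, hi in zip(coefs[1:], coefs):
        assert lo == hi / 2


def test_relatives_by_degree_matches_bruteforce(random_pedigree):
    """Buckets equal exhaustive per-pair minimal degree enumeration."""
    g = random_pedigree
    ids = sorted(g.ids)
    probands = set(ids[:: max(1, len(ids) // 7)][:5])
    max_degree = 5
    buckets = g.relatives_by_degree(probands, max_degree)
    rows = g.relatives_at_degrees(probands, max_degree)
    for x in ids:
        if x in probands:
            degs = [g.degree_of_relationship(x, p) for p in probands if p != x]
            mind = min(degs, default=math.inf)
            assert all(x not in buckets[d] for d in buckets)
        else:
            degs = [g.degree_of_relationship(x, p) for p in probands]
            mind = min(degs, default=math.inf)
            for d in range(1, max_degree + 1):
                assert (x in buckets[d]) == (mind == d)
        # per-degree rows: membership wherever some other proband sits
        degs_other = {g.degree_of_relationship(x, p) for p in probands if p != x}
        for d in range(1, max_degree + 1):
            assert (x in rows[d]) == (d in degs_other)


def test_pairwise_distance_matrix_consistent(random_pedigree):
    g = random_pedigree
    ids = sorted(g.ids)[:30]
    order, dist = g.pairwise_genetic_distance(ids)
    for i, a in enumerate(order):
        for j, b in enumerate(order):
            if i < j:
                assert dist[i, j] == g.genetic_distance(a, b)
                assert dist[i, j] == dist[j, i]
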