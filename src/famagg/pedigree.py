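"""Genealogy data model and pairwise relatedness measures.

A :class:`Genealogy` is a directed acyclic parent-child graph over
individuals carrying demographic attributes (sex, birth year, birthplace).
On top of it this module provides the quantities familial-aggregation
statistics are built from:

* **genetic distance** — the minimal number of meioses connecting two
  individuals through a common ancestor (1 = parent/offspring,
  2 = siblings, 3 = avuncular, 4 = first cousins, ...);
* **relatedness coefficient** — ``2**(-genetic_distance)``, the convention
  used by the Genealogical Index of Familiality: 0.50 for parent/offspring,
  0.25 for a sibling pair, 0.0625 for first cousins.  A single shortest
  path is used; inbreeding loops and multiple common ancestors do not
  accumulate;
* **degree of relationship** — shortest path in the relation graph whose
  edges join each individual to parents, offspring and full siblings
  (1st degree = parent/sib/child, 2nd = grandparent/uncle/half-sib,
  3rd = first cousin/great-grandchild), the epidemiological convention
  used for relative-risk tables;
* a **genealogy-completeness filter** (both parents, all four
  grandparents, and at least six of eight great-grandparents known)
  used to restrict analyses to well-recorded individuals.
"""

from __future__ import annotations

import math
from collections import defaultdict, deque
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping

import numpy as np

__all__ = [
    "Individual",
    "Genealogy",
    "PedigreeError",
    "CycleError",
    "UnknownIndividualError",
    "MALE",
    "FEMALE",
]

MALE = "M"
FEMALE = "F"


class PedigreeError(ValueError):
    """Structural problem in a genealogy (bad parent reference, bad sex)."""


class CycleError(PedigreeError):
    """An individual is its own ancestor."""


class UnknownIndividualError(KeyError):
    """An identifier not present in the genealogy."""


@dataclass(frozen=True)
class Individual:
    """One genealogy row.

    ``father_id``/``mother_id`` are ``None`` when the parent is not
    recorded.  ``sex`` is ``"M"``/``"F"`` (or ``None`` if unknown);
    ``birthplace`` is an opaque label ("in-state or not" in practice).
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str | None = None
    birth_year: int | None = None
    birthplace: str | None = None

    @property
    def parent_ids(self) -> tuple[str | None, str | None]:
        return (self.father_id, self.mother_id)


class Genealogy:
    """Immutable parent-child DAG with relatedness queries.

    Parameters
    ----------
    individuals
        Iterable of :class:`Individual`.  Ids must be unique; every
        referenced parent must itself be present; the graph must be
        acyclic; a referenced father must not be recorded female nor a
        mother male.
    validate
        Skip validation only when the input is known-good (e.g. output
        of the bundled simulator).
    """

    def __init__(self, individuals: Iterable[Individual], validate: bool = True):
        self._ind: dict[str, Individual] = {}
        for ind in individuals:
            if ind.id in self._ind:
                raise PedigreeError(f"duplicate individual id {ind.id!r}")
            self._ind[ind.id] = ind
        self._children: dict[str, set[str]] = defaultdict(set)
        for ind in self._ind.values():
            for pid in ind.parent_ids:
                if pid is not None:
                    self._children[pid].add(ind.id)
        # lazy caches; the genealogy is treated as immutable after construction
        self._anc_cache: dict[str, dict[str, int]] = {}
        self._relation_adj: dict[str, set[str]] | None = None
        if validate:
            self._validate()

    # ------------------------------------------------------------------
    # basic container behaviour
    # ------------------------------------------------------------------
    def __len__(self) -> int:
        return len(self._ind)

    def __contains__(self, iid: str) -> bool:
        return iid in self._ind

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._ind.values())

    @property
    def ids(self) -> set[str]:
        return set(self._ind)

    def individual(self, iid: str) -> Individual:
        try:
            return self._ind[iid]
        except KeyError:
            raise UnknownIndividualError(iid) from None

    def parents(self, iid: str) -> tuple[str | None, str | None]:
        return self.individual(iid).parent_ids

    def children(self, iid: str) -> set[str]:
        self.individual(iid)
        return set(self._children.get(iid, ()))

    # ------------------------------------------------------------------
    # validation
    # ------------------------------------------------------------------
    def _validate(self) -> None:
        for ind in self._ind.values():
            f, m = ind.parent_ids
            if f is not None:
                if f not in self._ind:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown father {f!r}"
                    )
                if self._ind[f].sex == FEMALE:
                    raise PedigreeError(f"father {f!r} of {ind.id!r} is recorded female")
            if m is not None:
                if m not in self._ind:
                    raise PedigreeError(
                        f"individual {ind.id!r} references unknown mother {m!r}"
                    )
                if self._ind[m].sex == MALE:
                    raise PedigreeError(f"mother {m!r} of {ind.id!r} is recorded male")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        # iterative three-colour DFS on child -> parent edges
        state: dict[str, int] = {}  # 1 = in progress, 2 = done
        for start in self._ind:
            if state.get(start):
                continue
            stack: list[tuple[str, Iterator[str]]] = [
                (start, iter([p for p in self._ind[start].parent_ids if p]))
            ]
            state[start] = 1
            while stack:
                node, it = stack[-1]
                nxt = next(it, None)
                if nxt is None:
                    state[node] = 2
                    stack.pop()
                elif state.get(nxt) == 1:
                    cycle = [n for n, _ in stack[stack.index(next(
                        s for s in stack if s[0] == nxt)):]] + [nxt]
                    raise CycleError(
                        "parentage cycle involving ids: " + " -> ".join(cycle)
                    )
                elif state.get(nxt) is None:
                    state[nxt] = 1
                    stack.append(
                        (nxt, iter([p for p in self._ind[nxt].parent_ids if p]))
                    )

    # ------------------------------------------------------------------
    # founders / descendants
    # ------------------------------------------------------------------
    def founders(self) -> set[str]:
        """Individuals with both parents unrecorded."""
        return {i for i, ind in self._ind.items()
                if ind.father_id is None and ind.mother_id is None}

    def descendants(self, iid: str) -> set[str]:
        """Transitive closure of child links, excluding ``iid`` itself."""
        self.individual(iid)
        out: set[str] = set()
        stack = [iid]
        while stack:
            for c in self._children.get(stack.pop(), ()):
                if c not in out:
                    out.add(c)
                    stack.append(c)
        return out

    # ------------------------------------------------------------------
    # genealogy completeness
    # ------------------------------------------------------------------
    def completeness_filter(self) -> set[str]:
        """Ids with both parents, all 4 grandparents, and >=6 of 8
        great-grandparents recorded."""
        out: set[str] = set()
        for iid, ind in self._ind.items():
            parents = [p for p in ind.parent_ids if p is not None]
            if len(parents) != 2:
                continue
            gps: list[str] = []
            for p in parents:
                gps.extend(q for q in self._ind[p].parent_ids if q is not None)
            if len(gps) != 4:
                continue
            n_ggp = sum(
                1 for gp in gps for q in self._ind[gp].parent_ids if q is not None
            )
            if n_ggp >= 6:
                out.add(iid)
        return out

    # ------------------------------------------------------------------
    # genetic distance / relatedness coefficient
    # ------------------------------------------------------------------
    def ancestor_depths(self, iid: str) -> Mapping[str, int]:
        """Minimal meiosis count from ``iid`` to each ancestor.

        ``iid`` itself is included at depth 0, so a parent-offspring pair
        meets at the parent with total distance 1.
        """
        cached = self._anc_cache.get(iid)
        if cached is not None:
            return cached
        self.individual(iid)
        depths: dict[str, int] = {iid: 0}
        frontier = deque([(iid, 0)])
        while frontier:
            node, d = frontier.popleft()
            for p in self._ind[node].parent_ids:
                if p is not None and (p not in depths or depths[p] > d + 1):
                    depths[p] = d + 1
                    frontier.append((p, d + 1))
        self._anc_cache[iid] = depths
        return depths

    def genetic_distance(self, a: str, b: str) -> float:
        """Minimal total meioses through any common ancestor; ``inf`` when
        the pair shares no recorded ancestor."""
        if a == b:
            raise PedigreeError("genetic distance is undefined for a self-pair")
        da = self.ancestor_depths(a)
        db = self.ancestor_depths(b)
        if len(db) < len(da):
            da, db = db, da
        best = math.inf
        for anc, d1 in da.items():
            d2 = db.get(anc)
            if d2 is not None and d1 + d2 < best:
                best = d1 + d2
        return best

    def relatedness_coefficient(self, a: str, b: str) -> float:
        """``2**(-genetic_distance)``; 0 for unrelated pairs."""
        d = self.genetic_distance(a, b)
        return 0.0 if math.isinf(d) else 2.0 ** (-d)

    def pairwise_genetic_distance(self, members: Iterable[str]) -> tuple[list[str], np.ndarray]:
        """Dense matrix of genetic distances among ``members``.

        Returns the sorted id list and a symmetric float matrix with
        ``inf`` for unrelated pairs and 0 on the diagonal.  Computed by
        inverting ancestor maps (ancestor -> member depths) so each common
        ancestor updates its descendant block vectorised.
        """
        ids = sorted(members)
        n = len(ids)
        dist = np.full((n, n), np.inf)
        by_anc: dict[str, list[tuple[int, int]]] = defaultdict(list)
        for i, iid in enumerate(ids):
            for anc, d in self.ancestor_depths(iid).items():
                by_anc[anc].append((i, d))
        for entries in by_anc.values():
            if len(entries) < 2:
                continue
            idx = np.fromiter((e[0] for e in entries), dtype=np.intp, count=len(entries))
            dep = np.fromiter((e[1] for e in entries), dtype=np.float64, count=len(entries))
            cand = dep[:, None] + dep[None, :]
            block = dist[np.ix_(idx, idx)]
            np.minimum(block, cand, out=block)
            dist[np.ix_(idx, idx)] = block
        np.fill_diagonal(dist, 0.0)
        return ids, dist

    # ------------------------------------------------------------------
    # degree of relationship
    # ------------------------------------------------------------------
    def _relation_graph(self) -> dict[str, set[str]]:
        """Adjacency of the first-degree relation graph: parent-child and
        full-sibling edges (both parents shared and recorded).  Half-sibs
        are linked only through the shared parent and thus come out as
        second degree."""
        if self._relation_adj is None:
            adj: dict[str, set[str]] = defaultdict(set)
            for iid, ind in self._ind.items():
                for p in ind.parent_ids:
                    if p is not None:
                        adj[iid].add(p)
                        adj[p].add(iid)
            sibships: dict[tuple[str, str], list[str]] = defaultdict(list)
            for iid, ind in self._ind.items():
                f, m = ind.parent_ids
                if f is not None and m is not None:
                    sibships[(f, m)].append(iid)
            for sibs in sibships.values():
                for i, a in enumerate(sibs):
                    for b in sibs[i + 1:]:
                        adj[a].add(b)
                        adj[b].add(a)
            self._relation_adj = adj
        return self._relation_adj

    def degree_of_relationship(self, a: str, b: str) -> float:
        """Shortest path between ``a`` and ``b`` in the relation graph;
        ``inf`` when disconnected."""
        if a == b:
            raise PedigreeError("degree of relationship undefined for a self-pair")
        self.individual(a)
        self.individual(b)
        adj = self._relation_graph()
        seen = {a}
        frontier = deque([(a, 0)])
        while frontier:
            node, d = frontier.popleft()
            for nb in adj.get(node, ()):
                if nb == b:
                    return d + 1
                if nb not in seen:
                    seen.add(nb)
                    frontier.append((nb, d + 1))
        return math.inf

    def relatives_by_degree(
        self, probands: Iterable[str], max_degree: int,
        include_probands: bool = False,
    ) -> dict[int, set[str]]:
        """Bucket every individual related to >=1 proband by its minimal
        degree to any proband (no duplication across buckets).

        By default probands themselves are excluded.  With
        ``include_probands=True`` a proband also appears as a relative,
        at its minimal degree to any *other* proband — the counting the
        observed/expected relative-risk tables need, where every case is
        a proband yet case relatives of other cases must still be
        counted."""
        if max_degree < 1:
            raise PedigreeError("max_degree must be >= 1")
        probands = set(probands)
        for p in probands:
            self.individual(p)
        adj = self._relation_graph()
        buckets: dict[int, set[str]] = {d: set() for d in range(1, max_degree + 1)}
        seen = set(probands)
        frontier = deque((p, 0) for p in probands)
        while frontier:
            node, d = frontier.popleft()
            if d == max_degree:
                continue
            for nb in adj.get(node, ()):
                if nb not in seen:
                    seen.add(nb)
                    buckets[d + 1].add(nb)
                    frontier.append((nb, d + 1))
        if include_probands:
            # per-proband BFS, stopping at the first *other* proband
            for p in probands:
                found = None
                seen_p = {p}
                frontier_p = deque([(p, 0)])
                while frontier_p and found is None:
                    node, d = frontier_p.popleft()
                    if d == max_degree:
                        continue
                    for nb in adj.get(node, ()):
                        if nb in seen_p:
                            continue
                        if nb in probands:
                            found = d + 1
                            break
                        seen_p.add(nb)
                        frontier_p.append((nb, d + 1))
                if found is not None:
                    buckets[found].add(p)
        return buckets

    def relatives_at_degrees(
        self, probands: Iterable[str], max_degree: int
    ) -> dict[int, set[str]]:
        """Per-degree relative rows: row d holds every individual having
        *some* proband at degree exactly d (its shortest-path degree to
        that proband), deduplicated within the row only.

        Rows overlap — a sibling of one proband who is also a cousin of
        another appears in both row 1 and row 3 — and a proband appears
        in any row where another proband sits at that degree.  This is
        the counting observed/expected relative-risk tables use: the
        d-th-degree row spans the d-th-degree relatives of *each* case.
        """
        if max_degree < 1:
            raise PedigreeError("max_degree must be >= 1")
        probands = set(probands)
        for p in probands:
            self.individual(p)
        adj = self._relation_graph()
        rows: dict[int, set[str]] = {d: set() for d in range(1, max_degree + 1)}
        for p in probands:
            seen = {p}
            frontier = deque([(p, 0)])
            while frontier:
                node, d = frontier.popleft()
                if d == max_degree:
                    continue
                for nb in adj.get(node, ()):
                    if nb not in seen:
                        seen.add(nb)
                        rows[d + 1].add(nb)
                        frontier.append((nb, d + 1))
        return rows
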