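"""Genealogical Index of Familiality (GIF) statistics.

The GIF of a set of individuals is the scaled average pairwise
relatedness coefficient over all unordered pairs in the set:

    GIF = scale * sum_pairs 2**(-d(a, b)) / n_pairs

with d the genetic distance (``inf`` contributing 0) and
``scale = 100_000`` by convention, so typical population values land in
single digits.  Excess familial clustering of a phenotype is tested by
comparing the case-set GIF with the GIFs of many control sets matched to
the cases on birth year, sex, and birthplace; the empirical p-value is
the fraction of control GIFs at least as large as the case GIF.  The
*distant* GIF (dGIF) repeats the test counting only distantly related
pairs (genetic distance >= 4 by default), separating a genetic signal
from shared-household environment, which close relatives alone cannot
distinguish.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .pedigree import Genealogy

__all__ = [
    "GIF_SCALE",
    "MatchStratum",
    "GifResult",
    "gif",
    "contribution_curve",
    "sample_matched_controls",
    "empirical_p",
    "run_gif_analysis",
]

GIF_SCALE = 100_000.0


class MatchStratum(NamedTuple):
    """Matching stratum: birth-year bin x sex x birthplace."""

    year_bin: int
    sex: str | None
    birthplace: str | None


class StratumExhaustedError(RuntimeError):
    """No eligible controls remain in a matching stratum, even after
    widening the birth-year bin by one on each side."""


def _pair_distances(g: Genealogy, members: Iterable[str]) -> np.ndarray:
    ids, dist = g.pairwise_genetic_distance(members)
    iu = np.triu_indices(len(ids), k=1)
    return dist[iu]


def _gif_from_distances(d: np.ndarray, min_distance: int, scale: float) -> float:
    mask = np.isfinite(d) & (d >= min_distance)
    return float(scale * np.sum(2.0 ** (-d[mask])) / d.size)


def gif(
    g: Genealogy,
    members: Iterable[str],
    min_distance: int = 1,
    scale: float = GIF_SCALE,
) -> float:
    """GIF of ``members``; ``min_distance=4`` gives the distant GIF."""
    members = set(members)
    if len(members) < 2:
        raise ValueError("GIF requires at least 2 members")
    return _gif_from_distances(_pair_distances(g, members), min_distance, scale)


def contribution_curve(
    g: Genealogy,
    members: Iterable[str],
    scale: float = GIF_SCALE,
) -> dict[int, float]:
    """Per-genetic-distance contribution to the GIF.

    Entry at distance d is ``scale * n_pairs(d) * 2**(-d) / n_all_pairs``;
    entries sum to the GIF of the set.  Unrelated pairs contribute no
    entry.
    """
    members = set(members)
    if len(members) < 2:
        raise ValueError("contribution curve requires at least 2 members")
    d = _pair_distances(g, members)
    n_pairs = d.size
    curve: dict[int, float] = {}
    finite = d[np.isfinite(d)].astype(int)
    for dist, count in zip(*np.unique(finite, return_counts=True)):
        curve[int(dist)] = float(scale * count * 2.0 ** (-float(dist)) / n_pairs)
    return curve


# ----------------------------------------------------------------------
# matched-control resampling
# ----------------------------------------------------------------------

def _stratum_of(g: Genealogy, iid: str, bin_width: int) -> MatchStratum:
    ind = g.individual(iid)
    if ind.birth_year is None:
        raise ValueError(f"individual {iid!r} has no birth year; cannot match")
    return MatchStratum(ind.birth_year // bin_width, ind.sex, ind.birthplace)


def sample_matched_controls(
    g: Genealogy,
    candidates: Iterable[str],
    cases: Iterable[str],
    n_sets: int,
    seed: int,
    bin_width: int = 5,
) -> list[list[str]]:
    """Draw ``n_sets`` control sets matched to the cases on birth-year
    bin, sex, and birthplace.

    Within a set, controls are drawn without replacement from the
    non-case candidates of each case's stratum; sets are drawn
    independently of each other, so an individual may serve in many sets.
    If a stratum cannot supply enough controls, the birth-year bin is
    widened by one bin on each side; if it still cannot, a
    :class:`StratumExhaustedError` names the stratum.
    """
    candidates = set(candidates)
    cases = set(cases)
    if not cases <= candidates:
        raise ValueError("cases must be a subset of the candidate pool")
    noncase = candidates - cases

    pools: dict[MatchStratum, list[str]] = defaultdict(list)
    for iid in sorted(noncase):
        pools[_stratum_of(g, iid, bin_width)].append(iid)

    demand: dict[MatchStratum, int] = defaultdict(int)
    for iid in cases:
        demand[_stratum_of(g, iid, bin_width)] += 1

    # resolve each stratum's sampling pool once (exact, then +/- one bin)
    resolved: list[tuple[MatchStratum, int, list[str]]] = []
    for stratum in sorted(demand):
        k = demand[stratum]
        pool = pools.get(stratum, [])
        if len(pool) < k:
            widened = list(pool)
            for nb in (stratum.year_bin - 1, stratum.year_bin + 1):
                widened += pools.get(MatchStratum(nb, stratum.sex, stratum.birthplace), [])
            pool = sorted(widened)
            if len(pool) < k:
                raise StratumExhaustedError(
                    f"stratum {stratum} needs {k} controls but only "
                    f"{len(pool)} candidates remain after widening the "
                    "birth-year bin by one on each side"
                )
        resolved.append((stratum, k, pool))

    rng = np.random.default_rng(seed)
    sets: list[list[str]] = []
    for _ in range(n_sets):
        members: list[str] = []
        for _stratum, k, pool in resolved:
            pick = rng.choice(len(pool), size=k, replace=False)
            members.extend(pool[i] for i in pick)
        sets.append(sorted(members))
    return sets


def empirical_p(case_stat: float, control_stats: Sequence[float]) -> tuple[float, str]:
    """Empirical tail probability of ``case_stat`` within the control
    distribution (ties count toward the tail) and its display string
    ("<1/N" when no control reaches the case value)."""
    controls = np.asarray(control_stats, dtype=float)
    if controls.size == 0:
        raise ValueError("control_stats must be nonempty")
    n_ge = int(np.sum(controls >= case_stat))
    p = n_ge / controls.size
    display = f"<{1.0 / controls.size:g}" if n_ge == 0 else f"{p:g}"
    return p, display


# ----------------------------------------------------------------------
# full analysis
# ----------------------------------------------------------------------

@dataclass
class GifResult:
    """Case GIF and dGIF with their matched-control null distributions."""

    n_cases: int
    case_gif: float
    control_gifs: np.ndarray
    gif_p: float
    gif_p_display: str
    case_dgif: float
    control_dgifs: np.ndarray
    dgif_p: float
    dgif_p_display: str
    contribution_curve: dict[int, float]
    control_curve_mean: dict[int, float] = field(default_factory=dict)
    dgif_min_distance: int = 4
    seed: int | None = None

    def summary(self) -> dict:
        """JSON-friendly summary (control distributions reduced to means)."""
        return {
            "n_cases": self.n_cases,
            "case_gif": self.case_gif,
            "mean_control_gif": float(np.mean(self.control_gifs)),
            "gif_p": self.gif_p,
            "gif_p_display": self.gif_p_display,
            "case_dgif": self.case_dgif,
            "mean_control_dgif": float(np.mean(self.control_dgifs)),
            "dgif_p": self.dgif_p,
            "dgif_p_display": self.dgif_p_display,
            "dgif_min_distance": self.dgif_min_distance,
            "n_control_sets": int(len(self.control_gifs)),
        }


def run_gif_analysis(
    g: Genealogy,
    cases: Iterable[str],
    candidates: Iterable[str],
    n_sets: int = 1000,
    seed: int = 0,
    dgif_min_distance: int = 4,
    scale: float = GIF_SCALE,
    bin_width: int = 5,
) -> GifResult:
    """GIF and dGIF test of excess relatedness for a case set.

    ``candidates`` is the phenotype-eligible pool the controls are drawn
    from (it must contain the cases).  GIF and dGIF p-values are computed
    against the same ``n_sets`` matched control sets.
    """
    cases = set(cases)
    if len(cases) < 2:
        raise ValueError("GIF analysis requires at least 2 cases")
    case_d = _pair_distances(g, cases)
    case_gif = _gif_from_distances(case_d, 1, scale)
    case_dgif = _gif_from_distances(case_d, dgif_min_distance, scale)
    curve = contribution_curve(g, cases, scale)

    control_sets = sample_matched_controls(g, candidates, cases, n_sets, seed, bin_width)
    control_gifs = np.empty(n_sets)
    control_dgifs = np.empty(n_sets)
    curve_acc: dict[int, float] = defaultdict(float)
    for i, members in enumerate(control_sets):
        d = _pair_distances(g, members)
        control_gifs[i] = _gif_from_distances(d, 1, scale)
        control_dgifs[i] = _gif_from_distances(d, dgif_min_distance, scale)
        finite = d[np.isfinite(d)].astype(int)
        for dist, count in zip(*np.unique(finite, return_counts=True)):
            curve_acc[int(dist)] += scale * count * 2.0 ** (-float(dist)) / d.size
    control_curve = {k: v / n_sets for k, v in sorted(curve_acc.items())}

    gif_p, gif_disp = empirical_p(case_gif, control_gifs)
    dgif_p, dgif_disp = empirical_p(case_dgif, control_dgifs)
    return GifResult(
        n_cases=len(cases),
        case_gif=case_gif,
        control_gifs=control_gifs,
        gif_p=gif_p,
        gif_p_display=gif_disp,
        case_dgif=case_dgif,
        control_dgifs=control_dgifs,
        dgif_p=dgif_p,
        dgif_p_display=dgif_disp,
        contribution_curve=curve,
        control_curve_mean=control_curve,
        dgif_min_distance=dgif_min_distance,
        seed=seed,
    )
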