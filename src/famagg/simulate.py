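"""Synthetic genealogy + phenotype generator.

Emulates the structure the analysis needs from a founder-descendant
population genealogy linked to modern measurement records:

* a multi-generation genealogy started from founder couples, with
  within-generation mating, immigrant spouses (founders-by-marriage with
  no recorded parents), and Poisson-distributed sibship sizes;
* a binary low-BMI phenotype generated under a liability-threshold
  model: liability L = A + C + E with additive-genetic variance h²
  (midparent transmission), shared-sibship environment c², and residual
  1 − h² − c²; the case threshold is set per age bin so the marginal
  prevalence matches a target map (U-shaped in age by default, echoing
  driver's-license prevalence patterns);
* ascertainment: phenotype records exist only for the most recent
  generations, while earlier generations contribute relatedness paths
  only.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .pedigree import FEMALE, MALE, Genealogy, Individual

__all__ = [
    "DEFAULT_PREVALENCE_BY_AGE",
    "SimConfig",
    "SimPopulation",
    "simulate_genealogy",
    "simulate_phenotypes",
    "apply_ascertainment",
    "simulate_population",
]

# Age-bin -> target prevalence of the low-BMI phenotype, U-shaped in age:
# high in adolescence, minimal in late middle age, rising again in old
# age (range ~0.4%–11%).
DEFAULT_PREVALENCE_BY_AGE: dict[tuple[int, int], float] = {
    (0, 19): 0.110,
    (20, 24): 0.046,
    (25, 29): 0.025,
    (30, 34): 0.019,
    (35, 39): 0.014,
    (40, 44): 0.011,
    (45, 49): 0.008,
    (50, 54): 0.006,
    (55, 59): 0.004,
    (60, 64): 0.005,
    (65, 69): 0.007,
    (70, 74): 0.010,
    (75, 200): 0.016,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic population.

    ``h2`` and ``c2`` are the additive-genetic and shared-sibship
    variance fractions of liability (h2 + c2 <= 1).  Phenotype records
    are emitted only for the last ``phenotyped_generations`` generations.
    """

    n_founder_couples: int = 60
    n_generations: int = 6
    mean_children: float = 2.6
    immigrant_spouse_fraction: float = 0.35
    generation_span: int = 25
    birth_year_jitter: int = 8
    founder_birth_year: int = 1850
    p_in_state: float = 0.8
    h2: float = 0.0
    c2: float = 0.0
    prevalence_by_age: Mapping[tuple[int, int], float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE_BY_AGE)
    )
    reference_year: int = 2005
    phenotyped_generations: int = 2
    # fraction of recent-generation individuals that actually carry a
    # record: measurement registries (e.g. driver's licenses) cover only
    # about half of the genealogically well-recorded population
    phenotype_coverage: float = 0.5
    bmi_scale: float = 3.0
    duplicate_record_fraction: float = 0.0
    max_extinction_retries: int = 5

    def __post_init__(self) -> None:
        for name in ("immigrant_spouse_fraction", "p_in_state", "h2", "c2",
                     "phenotype_coverage"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.h2 + self.c2 > 1.0:
            raise ValueError("h2 + c2 must not exceed 1")
        if self.n_generations < 3:
            raise ValueError("need >= 3 generations for completeness structure")
        if not 1 <= self.phenotyped_generations <= self.n_generations:
            raise ValueError("phenotyped_generations out of range")
        for (lo, hi), p in self.prevalence_by_age.items():
            if lo > hi or not 0.0 < p < 1.0:
                raise ValueError(f"bad prevalence bin ({lo},{hi})->{p}")


@dataclass
class SimPopulation:
    """Simulated genealogy, ascertained phenotype table, and per-
    individual truth (liability components, case flag, generation)."""

    genealogy: Genealogy
    phenotypes: pd.DataFrame
    truth: pd.DataFrame
    config: SimConfig
    seed: int

    @property
    def generations(self) -> dict[str, int]:
        t = self.truth.dropna(subset=["generation"])
        return {i: int(v) for i, v in zip(t["id"], t["generation"])}


class ExtinctionError(RuntimeError):
    """All lineages died out repeatedly during simulation."""


def _simulate_once(cfg: SimConfig, rng: np.random.Generator):
    inds: list[Individual] = []
    generation: dict[str, int] = {}
    counter = 0

    def new_id() -> str:
        nonlocal counter
        counter += 1
        return f"I{counter:06d}"

    def birthplace() -> str:
        return "in" if rng.random() < cfg.p_in_state else "out"

    def make_person(gen: int, sex: str, father=None, mother=None) -> Individual:
        base = cfg.founder_birth_year + gen * cfg.generation_span
        year = int(base + rng.integers(-cfg.birth_year_jitter, cfg.birth_year_jitter + 1))
        ind = Individual(
            id=new_id(), father_id=father, mother_id=mother,
            sex=sex, birth_year=year, birthplace=birthplace(),
        )
        inds.append(ind)
        generation[ind.id] = gen
        return ind

    couples: list[tuple[str, str]] = []
    for _ in range(cfg.n_founder_couples):
        f = make_person(0, MALE)
        m = make_person(0, FEMALE)
        couples.append((f.id, m.id))

    for gen in range(1, cfg.n_generations):
        kids: list[Individual] = []
        for father, mother in couples:
            for _ in range(rng.poisson(cfg.mean_children)):
                sex = MALE if rng.random() < 0.5 else FEMALE
                kids.append(make_person(gen, sex, father=father, mother=mother))
        if not kids:
            return None
        if gen == cfg.n_generations - 1:
            break  # last generation does not reproduce
        # mate: a fraction marry immigrants, the rest pair within the
        # generation avoiding full-sib unions; leftovers stay childless
        couples = []
        males, females = [], []
        for k in kids:
            if rng.random() < cfg.immigrant_spouse_fraction:
                spouse_sex = FEMALE if k.sex == MALE else MALE
                spouse = make_person(gen, spouse_sex)
                pair = (k.id, spouse.id) if k.sex == MALE else (spouse.id, k.id)
                couples.append(pair)
            elif k.sex == MALE:
                males.append(k)
            else:
                females.append(k)
        rng.shuffle(males)
        rng.shuffle(females)
        # pair off sequentially; swap ahead a bounded number of times to
        # avoid full-sib unions (leftovers stay unmarried)
        fi = 0
        for man in males:
            if fi >= len(females):
                break
            if (man.father_id, man.mother_id) == (
                females[fi].father_id, females[fi].mother_id
            ):
                for j in range(fi + 1, min(fi + 8, len(females))):
                    if (man.father_id, man.mother_id) != (
                        females[j].father_id, females[j].mother_id
                    ):
                        females[fi], females[j] = females[j], females[fi]
                        break
                else:
                    continue  # only sisters in reach; man stays unmarried
            couples.append((man.id, females[fi].id))
            fi += 1
        if not couples:
            return None
    return inds, generation


def simulate_genealogy(cfg: SimConfig, seed: int = 0) -> tuple[Genealogy, dict[str, int]]:
    """Generate a genealogy; returns it with the id -> generation map.

    Retries a bounded number of times if every lineage goes extinct."""
    for attempt in range(cfg.max_extinction_retries):
        rng = np.random.default_rng([seed, attempt])
        result = _simulate_once(cfg, rng)
        if result is not None:
            inds, generation = result
            return Genealogy(inds, validate=False), generation
    raise ExtinctionError(
        f"population went extinct in {cfg.max_extinction_retries} attempts"
    )


def _age_bin_threshold(cfg: SimConfig, age: int) -> float:
    """Liability threshold for an age: Phi^-1(1 - p) of the bin's target
    prevalence; out-of-range ages clamp to the nearest bin."""
    best, best_gap = None, math.inf
    for (lo, hi), p in cfg.prevalence_by_age.items():
        if lo <= age <= hi:
            return float(stats.norm.isf(p))
        gap = min(abs(age - lo), abs(age - hi))
        if gap < best_gap:
            best, best_gap = p, gap
    return float(stats.norm.isf(best))


def simulate_phenotypes(
    g: Genealogy,
    cfg: SimConfig,
    seed: int = 0,
    generation: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Liability-threshold phenotypes for every individual.

    Liability L = A + C + E: founders draw A ~ N(0, h2); children get
    midparent A plus N(0, h2/2) segregation noise (variance-preserving);
    C is one draw per full sibship ~ N(0, c2); E ~ N(0, 1-h2-c2).  The
    case threshold is age-bin-specific so marginal prevalence tracks the
    target map, and BMI is emitted as a decreasing affine transform of
    liability calibrated so BMI < 18.5 exactly at the threshold.

    Returns the full (unascertained) table with one row per individual:
    id, bmi, record_year, age, case, liability, A, C, E, generation.
    """
    rng = np.random.default_rng([seed, 7])
    sd_a = math.sqrt(cfg.h2)
    sd_seg = math.sqrt(cfg.h2 / 2.0)
    sd_c = math.sqrt(cfg.c2)
    sd_e = math.sqrt(max(0.0, 1.0 - cfg.h2 - cfg.c2))

    # parents before children: sort by generation when available, else
    # by ancestor depth
    if generation is not None:
        order = sorted(g.ids, key=lambda i: (generation[i], i))
    else:
        depth = {i: max(g.ancestor_depths(i).values()) for i in g.ids}
        order = sorted(g.ids, key=lambda i: (depth[i], i))

    A: dict[str, float] = {}
    C_sib: dict[tuple[str, str], float] = {}
    rows = []
    for iid in order:
        ind = g.individual(iid)
        f, m = ind.parent_ids
        if f is None or m is None:
            a = rng.normal(0.0, sd_a) if sd_a else 0.0
            c = rng.normal(0.0, sd_c) if sd_c else 0.0
        else:
            a = 0.5 * (A[f] + A[m]) + (rng.normal(0.0, sd_seg) if sd_seg else 0.0)
            key = (f, m)
            if key not in C_sib:
                C_sib[key] = rng.normal(0.0, sd_c) if sd_c else 0.0
            c = C_sib[key]
        A[iid] = a
        e = rng.normal(0.0, sd_e) if sd_e else 0.0
        liab = a + c + e
        age = cfg.reference_year - (ind.birth_year or cfg.reference_year)
        thr = _age_bin_threshold(cfg, age)
        case = liab > thr
        bmi = float(np.clip(18.5 - cfg.bmi_scale * (liab - thr), 12.0, 63.0))
        rows.append(
            {
                "id": iid,
                "bmi": bmi,
                "record_year": cfg.reference_year,
                "age": age,
                "case": bool(case),
                "liability": liab,
                "A": a,
                "C": c,
                "E": e,
                "generation": generation[iid] if generation is not None else None,
            }
        )
    df = pd.DataFrame(rows).sort_values("id", ignore_index=True)

    if cfg.duplicate_record_fraction > 0:
        # optional extra, older record per individual to exercise the
        # most-recent-record rule downstream
        pick = rng.random(len(df)) < cfg.duplicate_record_fraction
        dup = df.loc[pick, ["id", "bmi", "record_year"]].copy()
        dup["record_year"] = dup["record_year"] - 5
        dup["bmi"] = dup["bmi"] + rng.normal(0.0, 1.0, len(dup))
        df = pd.concat([df, dup], ignore_index=True)
    return df


def apply_ascertainment(
    phenotypes: pd.DataFrame,
    cfg: SimConfig,
    generation: Mapping[str, int],
    seed: int = 0,
) -> pd.DataFrame:
    """Restrict phenotype rows to the registry-covered population.

    Records survive only for the most recent ``phenotyped_generations``
    generations (driver's-license-style era coverage), and within those
    generations each individual carries a record independently with
    probability ``phenotype_coverage``; earlier or uncovered individuals
    stay in the genealogy unphenotyped."""
    cutoff = cfg.n_generations - cfg.phenotyped_generations
    keep = phenotypes["id"].map(lambda i: generation[i] >= cutoff).to_numpy()
    if cfg.phenotype_coverage < 1.0:
        rng = np.random.default_rng([seed, 13])
        covered_ids = {
            iid for iid in sorted({i for i, gen in generation.items() if gen >= cutoff})
            if rng.random() < cfg.phenotype_coverage
        }
        keep &= phenotypes["id"].isin(covered_ids).to_numpy()
    return phenotypes[keep].reset_index(drop=True)


def simulate_population(cfg: SimConfig, seed: int = 0) -> SimPopulation:
    """Genealogy + phenotypes + ascertainment in one call."""
    g, generation = simulate_genealogy(cfg, seed)
    truth = simulate_phenotypes(g, cfg, seed, generation)
    phen = apply_ascertainment(truth, cfg, generation, seed)
    phen = phen[["id", "bmi", "record_year"]].reset_index(drop=True)
    return SimPopulation(genealogy=g, phenotypes=phen, truth=truth,
                         config=cfg, seed=seed)
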