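# Methods

This note documents the statistical model behind `famagg`, the
conventions it adopts where the literature leaves choices open, what the
synthetic-data generator does and does not emulate, and the numerical
details a user auditing results will want.

## Relatedness on a genealogy

The genealogy is a directed acyclic parent-child graph.  Three pairwise
quantities are derived from it:

* **Genetic distance** `d(a,b)`: the minimum over common ancestors `c`
  of (meioses from `a` to `c`) + (meioses from `b` to `c`), with each
  individual counting as its own ancestor at depth 0.  Parent/offspring
  pairs are at distance 1, full siblings 2, avunculars 3, first cousins
  4; pairs with no recorded common ancestor are at infinite distance.
* **Relatedness coefficient** `2^-d`.  This is the convention used by
  the GIF literature — 0.50 for parent/offspring, 0.25 for a sibling
  pair, 0.125 avuncular, 0.0625 first cousins.  Deliberately, only the
  single shortest path contributes: full siblings count 0.25 (not the
  2-path 0.5), and inbreeding loops or multiple common ancestors do not
  accumulate.  This is *not* the textbook kinship coefficient (which is
  0.25 for parent/offspring) nor Wright's coefficient of relationship;
  it is the convention that matches the published values the package is
  validated against.  A missing parent simply contributes no paths.
* **Degree of relationship**: shortest-path length in the *relation
  graph*, whose edges connect each individual to parents, offspring,
  and full siblings.  Grandparents and uncles come out as 2nd degree,
  first cousins and great-grandchildren as 3rd.  A sibling edge
  requires both parents shared, so half-siblings classify as 2nd
  degree, matching epidemiological convention.  Because edges pass
  through shared offspring, affinal pairs (e.g. spouses) acquire a
  finite degree while remaining at infinite genetic distance; degree is
  a path-counting notion, relatedness a meiotic one.

A genealogy-completeness filter (both parents, all four grandparents,
at least six of eight great-grandparents recorded) restricts analyses to
individuals whose relatedness can be measured with comparable quality —
without it, apparent "unrelatedness" is mostly missing data.

## GIF and dGIF

For a member set `S`, `GIF(S) = scale · Σ_{pairs} 2^{-d} / n_pairs` over
all unordered pairs, `scale = 100 000` (configurable; the scale makes
population values land in convenient single digits).  The contribution
curve decomposes the GIF by genetic distance
(`scale · n_pairs(d) · 2^-d / n_pairs`) and sums back to the GIF
exactly; it is the standard diagnostic for where in the relationship
spectrum an excess lives.

Significance is empirical.  Control sets are matched to the cases on
birth-year bin (5 years), sex, and birthplace, sampled uniformly without
replacement within a set from the non-case phenotype-eligible pool, sets
independent of each other.  If a stratum cannot supply enough controls
the birth-year bin is widened by one bin on each side; if it still
cannot, the run fails loudly naming the stratum — silent mismatching
would bias the null.  The empirical p-value is the fraction of control
GIFs at least as large as the case GIF (ties count toward the tail,
conservative); with no control reaching the case value it is displayed
as `<1/N`.

The **dGIF** recomputes both case and control GIFs keeping only pairs at
genetic distance ≥ 4 (first cousins and beyond).  The threshold is by
genetic distance, not degree — the two readings differ for
great-grandchildren (distance 3, degree 3) — and is exposed as
`dgif_min_distance` so the degree-≤2-exclusion reading is one parameter
away.  Because the numerator can only lose pairs, dGIF ≤ GIF always; a
significant dGIF indicates distant excess relatedness, which shared
households cannot easily produce.

## Cohorts, expected counts, relative risks

All phenotype-eligible individuals are assigned to cohorts by birth-year
5-year bin × sex × birthplace; the cohort rate is cases/phenotyped
within the cohort.  The expected number of cases in any set of
phenotyped individuals is the sum of their cohort rates, which
standardises every observed/expected comparison for demography.

Relative risks in relatives are computed per degree, **each degree
counted independently**: row *d* contains every phenotyped individual
having *some* case proband at degree exactly *d*, deduplicated within
the row; rows overlap, and a case that is a relative of another case
contributes to the observed count of every row it appears in.  (An
alternative disjoint bucketing — each individual once, at its minimal
degree to any proband — is available as
`Genealogy.relatives_by_degree`; note that under strong familial
clustering minimal-degree bucketing systematically *depletes* distant
rows, because enriched cousins usually also have a close case relative
and get promoted, driving distant-row RRs below 1 even when true
cousin-level risk is elevated.  The per-degree counting is the one whose
published reference tables are internally consistent, and it is the
epidemiologically interpretable "risk in k-th-degree relatives".)

`RR = observed/expected` is treated as a Poisson intensity ratio with
the expectation fixed:

* CI (default): log-scale interval `exp(ln RR ± z·√(1/observed))`,
  positivity-preserving; a ratio-scale Wald variant
  (`RR ± z·√observed/expected`) is available as `method="wald"`.  With
  zero observed the lower limit is 0 and the upper limit the one-sided
  Poisson bound `-ln(1-level)/expected`.
* p-value: exact two-sided Poisson, twice the smaller tail at the
  observed count, capped at 1.  Published tables in this literature mix
  conventions (some entries match one-sided exact tails, some doubled
  normal tails); the exact doubled-tail form is used uniformly here and
  agrees with those values to the differences those conventions imply.

Prevalence tables use exact Clopper–Pearson (beta-quantile) binomial
intervals.

## High-risk pedigree scan

Founding anchors are couples where both co-parents are founders (their
descendancies are merged), or single founders whose co-parent is
unrecorded.  A case cluster is an anchor's set of case descendants
(size ≥ 2); clusters that are subsets of another retained cluster are
dropped, while individuals may belong to several retained clusters.
Each anchor is then tested for excess: observed cases among its
phenotyped descendants against the cohort-expected count, one-sided
Poisson upper tail `P(X ≥ obs | λ = exp)`.  High-risk pedigrees are
those with `p < α` (default 1e-4) and at least `min_cases` observed
(default 10), sorted by p.  The scan is a screening device — the
per-founder tests are correlated and not multiplicity-adjusted; the
default α is deliberately stringent.

## The synthetic-data generator

The generator emulates the features of a founder-descendant population
genealogy linked to a modern measurement registry that the analysis is
sensitive to:

* **Structure**: `n_founder_couples` couples found generation 0; each
  couple has Poisson(`mean_children`) children; children marry within
  their generation (full-sib unions excluded) or, with probability
  `immigrant_spouse_fraction` (default 0.35), an immigrant spouse with
  no recorded parents — these founders-by-marriage reproduce the
  genealogy-completeness mix real databases show.  Birth years are
  generation-based (25-year spacing from 1850) with ±8 years of jitter;
  sex is a fair coin; birthplace is in-state with probability 0.8.
  Defaults give six generations; lineage extinction triggers a bounded
  retry.
* **Phenotype**: liability `L = A + C + E`, all variances summing to 1.
  Founders draw `A ~ N(0, h²)`; a child's `A` is the midparent mean
  plus `N(0, h²/2)` segregation noise, which preserves additive
  variance and yields the standard correlations (sibs `h²/2 + c²` in
  liability, first cousins `h²/8`; both are verified by the test
  suite).  `C ~ N(0, c²)` is drawn once per full sibship,
  `E ~ N(0, 1-h²-c²)` independently.  The case threshold is set per age
  bin as `Φ⁻¹(1-p_bin)` against a target prevalence map — by default
  the U-shape observed for low BMI in license data (≈11% in late
  adolescence, 0.4–0.6% in late middle age, rising again in old age).
  A continuous BMI is emitted as a decreasing affine transform of
  liability anchored at the threshold (slope 3 BMI units per liability
  SD, clipped to [12, 63]), so `BMI < 18.5 ⇔ case` exactly.
* **Ascertainment**: phenotype records exist only for the most recent
  `phenotyped_generations` (default 2) generations, and within those
  only for a `phenotype_coverage` fraction (default 0.5) of
  individuals, mirroring registries that cover roughly half of the
  genealogically well-recorded population.  Earlier individuals stay in
  the genealogy and contribute relatedness paths.  Coverage matters
  scientifically: with full coverage of dense recent generations,
  nearly every cousin of a case also has a phenotyped close case
  relative, which is unlike sparse real registries.

Not modelled: realistic demography (mortality, migration waves),
assortative mating, secular phenotype trends across generations, age
structure within a generation beyond birth-year jitter, and
self-report measurement error.  Passing the calibration suites
therefore demonstrates the statistical machinery is correct under a
faithful liability-threshold world, not that real registry data are
free of reporting or linkage artefacts.

## Calibration suites and problem sizes

Two Monte-Carlo suites exercise the full chain end to end
(`tests/test_acceptance.py`), both on six-generation populations with
two phenotyped generations at 50% coverage and a flat 5% target
prevalence (flat removes age-structure confounding from the
calibration):

* **Null** (`h² = c² = 0`): 20 replicates of ~5,000 eligible phenotyped
  individuals (750 founder couples), 200 matched control sets each.
  The empirical GIF p-value must be consistent with Uniform(0,1)
  (Kolmogorov–Smirnov) and the degree-1..3 RR intervals must cover 1 at
  close to the nominal rate.
* **Signal** (`h² = 0.6`): 20 replicates at 1,200 founder couples
  (~8,000 phenotyped; the larger size stabilises the degree-3 row's
  expected count at ~55), 100 control sets.  At least 80% of replicates
  must give an empirical GIF p < 0.05 together with the RR gradient
  `RR₁ > RR₃ > 1`.

These sizes keep the whole suite around ten minutes on one CPU while
leaving the Monte-Carlo margins comfortable.

## Numerical and engineering notes

* Pairwise distances for a member set are computed by inverting
  ancestor-depth maps (ancestor → member depths) and updating a dense
  distance matrix per shared ancestor, vectorised; ancestor maps are
  cached on the genealogy, so resampling 200–1,000 control sets reuses
  them.  Genealogies are treated as immutable after construction.
* All randomness flows through `numpy.random.default_rng` seeded from
  explicit arguments; simulation, control sampling, and the pipeline
  are bit-reproducible given a seed.
* Degenerate inputs fail loudly rather than silently: GIF needs ≥ 2
  members, exhausted matching strata raise after one widening step,
  zero expected with positive observed flags the RR row undefined,
  parentage cycles and unknown parents are construction errors.
* Ages are `record_year − birth_year`; when an individual has several
  phenotype records the most recent wins.  The default analysis window
  is ages 25–64 inclusive (stable adult prevalence, outside adolescent
  and geriatric weight dynamics); the BMI threshold (18.5, strict `<`)
  and window are `RunConfig` parameters.
* Display rounding follows the field's tables (prevalence to 0.1%, RR
  and CI to 2 decimals), but all stored outputs keep full precision.
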