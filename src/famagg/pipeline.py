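"""End-to-end analysis pipeline.

Chains the eligibility filters (genealogy completeness -> phenotype
record -> age window -> BMI threshold) and runs the prevalence table,
the GIF/dGIF test, the degree-stratified relative-risk table, and the
high-risk pedigree scan, emitting a JSON report plus TSV side tables.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from .gif import GifResult, run_gif_analysis
from .pedigree import Genealogy
from .risk import assign_cohorts, prevalence_by_age, relative_risk_table
from .scan import high_risk_table, scan_high_risk

__all__ = ["RunConfig", "PipelineResult", "run_pipeline",
           "DEFAULT_AGE_BINS", "eligible_phenotyped"]

logger = logging.getLogger(__name__)

# Table-style age bins for prevalence reporting (inclusive ends)
DEFAULT_AGE_BINS: list[tuple[int, int]] = [
    (15, 19), (20, 24), (25, 29), (30, 34), (35, 39), (40, 44), (45, 49),
    (50, 54), (55, 59), (60, 64), (65, 69), (70, 74), (75, 79), (80, 200),
]


@dataclass
class RunConfig:
    """Parameters of a full analysis run."""

    bmi_threshold: float = 18.5  # cases are strictly below
    age_min: int = 25
    age_max: int = 64  # inclusive
    n_control_sets: int = 1000
    dgif_min_distance: int = 4
    max_degree: int = 7
    cohort_bin_width: int = 5
    scan_alpha: float = 1e-4
    scan_min_cases: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bmi_threshold <= 0:
            raise ValueError("bmi_threshold must be positive")
        if self.age_min > self.age_max:
            raise ValueError("age_min must be <= age_max")


@dataclass
class PipelineResult:
    config: RunConfig
    prevalence: pd.DataFrame
    gif: GifResult
    rr: pd.DataFrame
    high_risk: pd.DataFrame
    n_complete: int
    n_phenotyped: int
    n_cases: int

    def report(self) -> dict:
        def _clean(obj):
            # NaN is not valid JSON and breaks equality checks
            if isinstance(obj, dict):
                return {k: _clean(v) for k, v in obj.items()}
            if isinstance(obj, list):
                return [_clean(v) for v in obj]
            if isinstance(obj, float) and math.isnan(obj):
                return None
            return obj

        return _clean({
            "parameters": asdict(self.config),
            "counts": {
                "genealogy_complete": self.n_complete,
                "phenotyped_eligible": self.n_phenotyped,
                "cases": self.n_cases,
            },
            "prevalence": self.prevalence.to_dict(orient="records"),
            "gif": self.gif.summary(),
            "relative_risk": self.rr.drop(columns=["undefined"]).to_dict(orient="records"),
            "high_risk_pedigrees": self.high_risk.to_dict(orient="records"),
        })

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.report(), fh, indent=2)
        self.prevalence.to_csv(out / "prevalence.tsv", sep="\t", index=False)
        self.rr.to_csv(out / "relative_risk.tsv", sep="\t", index=False)
        self.high_risk.to_csv(out / "high_risk_pedigrees.tsv", sep="\t", index=False)
        curves = pd.DataFrame(
            {
                "genetic_distance": sorted(
                    set(self.gif.contribution_curve) | set(self.gif.control_curve_mean)
                ),
            }
        )
        curves["case_contribution"] = curves["genetic_distance"].map(
            self.gif.contribution_curve
        ).fillna(0.0)
        curves["control_contribution"] = curves["genetic_distance"].map(
            self.gif.control_curve_mean
        ).fillna(0.0)
        curves.to_csv(out / "gif_contribution_curve.tsv", sep="\t", index=False)


def eligible_phenotyped(
    g: Genealogy, phenotype: pd.DataFrame
) -> pd.DataFrame:
    """Phenotype rows for individuals passing the genealogy-completeness
    filter, with age at record attached."""
    complete = g.completeness_filter()
    df = phenotype[phenotype["id"].isin(complete)].copy()
    years = df["id"].map(lambda i: g.individual(i).birth_year)
    df["age"] = df["record_year"] - years
    df = df.dropna(subset=["age"])
    df["age"] = df["age"].astype(int)
    return df


def run_pipeline(
    g: Genealogy,
    phenotype: pd.DataFrame,
    cfg: RunConfig | None = None,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run prevalence, GIF, RR, and high-risk scan on one data set.

    ``phenotype`` must hold one row per individual (``id, bmi,
    record_year``; apply the most-recent-record rule upstream).  The
    eligibility chain is: completeness filter -> phenotype record ->
    age window -> BMI threshold; cohort rates come from all eligible
    phenotyped individuals regardless of the age window.
    """
    cfg = cfg or RunConfig()
    try:
        phen = eligible_phenotyped(g, phenotype)
    except Exception as err:  # pragma: no cover - defensive relabelling
        raise RuntimeError(f"eligibility stage failed: {err}") from err
    phen["case"] = phen["bmi"] < cfg.bmi_threshold

    prevalence = prevalence_by_age(phen, DEFAULT_AGE_BINS)

    in_window = phen[(phen["age"] >= cfg.age_min) & (phen["age"] <= cfg.age_max)]
    cases = set(in_window.loc[in_window["case"], "id"])
    candidates = set(phen["id"])
    all_cases = set(phen.loc[phen["case"], "id"])
    logger.info(
        "pipeline: %d complete+phenotyped, %d in age window, %d cases",
        len(candidates), len(in_window), len(cases),
    )
    if len(cases) < 2:
        raise RuntimeError(
            f"GIF stage needs >= 2 cases in the age window; found {len(cases)}"
        )

    gif_result = run_gif_analysis(
        g, cases, candidates,
        n_sets=cfg.n_control_sets, seed=cfg.seed,
        dgif_min_distance=cfg.dgif_min_distance,
        bin_width=cfg.cohort_bin_width,
    )

    cohorts = assign_cohorts(g, candidates, all_cases, cfg.cohort_bin_width)
    rr = relative_risk_table(g, cases, all_cases, cohorts, cfg.max_degree)
    _clusters, selected = scan_high_risk(
        g, cases, cohorts, cfg.scan_alpha, cfg.scan_min_cases
    )
    result = PipelineResult(
        config=cfg,
        prevalence=prevalence,
        gif=gif_result,
        rr=rr,
        high_risk=high_risk_table(selected),
        n_complete=len(g.completeness_filter()),
        n_phenotyped=len(candidates),
        n_cases=len(cases),
    )
    if out_dir is not None:
        result.write(out_dir)
    return result
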