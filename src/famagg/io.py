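"""Readers and writers for pedigree and phenotype tables.

Pedigree files are tab-separated with a header row and columns
``id  father_id  mother_id  sex  birth_year  birthplace``; a parent of
``0`` or empty means unrecorded (PLINK .fam-style parent encoding).
Phenotype files carry either a precomputed ``bmi`` column or raw
``weight``/``height`` columns (kg and m by default; lb/in conversion is
an explicit option), plus a ``record_year``; multiple records per
individual are resolved by keeping the most recent.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .pedigree import Genealogy, Individual, PedigreeError

__all__ = [
    "read_pedigree",
    "write_pedigree",
    "read_phenotype",
    "write_phenotype",
]

PEDIGREE_COLUMNS = ["id", "father_id", "mother_id", "sex", "birth_year", "birthplace"]

_SEX_CODES = {
    "m": "M", "male": "M", "1": "M",
    "f": "F", "female": "F", "2": "F",
}

_MISSING = {"", "0", "na", "nan", "none", "."}


def _parse_parent(value: str) -> str | None:
    return None if value.strip().lower() in _MISSING else value.strip()


def read_pedigree(path: str | Path) -> Genealogy:
    """Read and validate a pedigree TSV; errors cite the offending line."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing_cols = [c for c in PEDIGREE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise PedigreeError(f"{path}: missing pedigree columns {missing_cols}")
    individuals = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line = idx + 2  # header is line 1
        sex_raw = str(row.sex).strip().lower()
        sex = _SEX_CODES.get(sex_raw)
        if sex is None and sex_raw not in _MISSING:
            raise PedigreeError(f"{path}:{line}: unrecognised sex {row.sex!r}")
        year_raw = str(row.birth_year).strip()
        try:
            birth_year = None if year_raw.lower() in _MISSING else int(float(year_raw))
        except ValueError:
            raise PedigreeError(
                f"{path}:{line}: malformed birth_year {row.birth_year!r}"
            ) from None
        birthplace = str(row.birthplace).strip() or None
        individuals.append(
            Individual(
                id=str(row.id).strip(),
                father_id=_parse_parent(str(row.father_id)),
                mother_id=_parse_parent(str(row.mother_id)),
                sex=sex,
                birth_year=birth_year,
                birthplace=birthplace,
            )
        )
    return Genealogy(individuals)  # validates references, sexes, acyclicity


def write_pedigree(g: Genealogy, path: str | Path) -> None:
    rows = [
        {
            "id": ind.id,
            "father_id": ind.father_id or "0",
            "mother_id": ind.mother_id or "0",
            "sex": ind.sex or "0",
            "birth_year": "" if ind.birth_year is None else ind.birth_year,
            "birthplace": ind.birthplace or "",
        }
        for ind in sorted(g, key=lambda i: i.id)
    ]
    pd.DataFrame(rows, columns=PEDIGREE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_phenotype(
    path: str | Path,
    units: str = "metric",
) -> pd.DataFrame:
    """Read a phenotype TSV into columns ``id, bmi, record_year``.

    Accepts either a ``bmi`` column or ``weight``/``height`` raw columns
    (``units="metric"``: kg and m; ``units="imperial"``: lb and in).
    When an individual has several records, the most recent
    ``record_year`` wins (ties keep the last row in file order).
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "record_year" not in df.columns:
        raise ValueError(f"{path}: phenotype file needs a record_year column")
    if "bmi" in df.columns:
        out = df[["id", "bmi", "record_year"]].copy()
    elif {"weight", "height"} <= set(df.columns):
        w = df["weight"].astype(float)
        h = df["height"].astype(float)
        if units == "imperial":
            w = w * 0.45359237
            h = h * 0.0254
        elif units != "metric":
            raise ValueError(f"unknown units {units!r}")
        out = pd.DataFrame(
            {"id": df["id"], "bmi": w / h**2, "record_year": df["record_year"]}
        )
    else:
        raise ValueError(
            f"{path}: phenotype file needs either a bmi column or "
            "weight and height columns"
        )
    out["bmi"] = out["bmi"].astype(float)
    out["record_year"] = out["record_year"].astype(int)
    # most-recent-record rule; stable sort keeps file order within a year
    out = (
        out.sort_values("record_year", kind="stable")
        .drop_duplicates("id", keep="last")
        .sort_values("id", ignore_index=True)
    )
    return out


def write_phenotype(df: pd.DataFrame, path: str | Path) -> None:
    df[["id", "bmi", "record_year"]].to_csv(path, sep="\t", index=False)
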