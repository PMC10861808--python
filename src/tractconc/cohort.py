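"""Cohort characteristics table and its summary statistics."""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["CohortTable", "cohort_summary"]

COHORT_COLUMNS = [
    "subject_id",
    "age",
    "sex",
    "tumor_location",
    "hemisphere",
    "tumor_volume_cm3",
    "diagnosis",
]

_GRADE_RE = re.compile(r"WHO\s*Grade\s*(\d)", re.IGNORECASE)

# histological type keywords, checked in order (glioblastoma before astrocytoma
# since some diagnoses mention both lineages)
_TYPE_KEYWORDS = ["glioblastoma", "oligodendroglioma", "astrocytoma"]


@dataclass
class CohortTable:
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in COHORT_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"cohort table is missing columns: {missing}")
        if len(self.frame) < 1:
            raise ValueError("cohort table must have at least one row")
        if (self.frame["age"] <= 0).any():
            raise ValueError("ages must be positive")
        bad_hemi = set(self.frame["hemisphere"].astype(str).str.capitalize()) - {"Left", "Right"}
        if bad_hemi:
            raise ValueError(f"hemisphere must be Left or Right, got {bad_hemi}")

    @classmethod
    def from_csv(cls, path) -> "CohortTable":
        return cls(pd.read_csv(path))


def parse_who_grade(diagnosis: str) -> int | None:
    m = _GRADE_RE.search(str(diagnosis))
    return int(m.group(1)) if m else None


def parse_histological_type(diagnosis: str) -> str | None:
    text = str(diagnosis).lower()
    for kw in _TYPE_KEYWORDS:
        if kw in text:
            return kw
    return None


def cohort_summary(table: CohortTable) -> dict:
    """Summary record: n, sex counts, age stats, hemisphere / grade / type shares.

    Percentages are of n (full precision internally; round at
    serialization).  Rows whose diagnosis has no parseable WHO grade are
    flagged, warned about and excluded from the grade percentages only.
    """
    df = table.frame
    n = len(df)
    ages = df["age"].astype(float)
    hemis = df["hemisphere"].astype(str).str.capitalize()
    grades = df["diagnosis"].map(parse_who_grade)
    types = df["diagnosis"].map(parse_histological_type)
    unparseable = df.loc[grades.isna(), "subject_id"].tolist()
    if unparseable:
        logger.warning("no WHO grade parseable for subjects %s — excluded from grade shares", unparseable)
    sex = df["sex"].astype(str).str.upper()
    summary = {
        "n": n,
        "n_male": int((sex == "M").sum()),
        "n_female": int((sex == "F").sum()),
        "age_mean": float(ages.mean()),
        "age_min": float(ages.min()),
        "age_max": float(ages.max()),
        "hemisphere_pct": {h: 100.0 * (hemis == h).sum() / n for h in ("Left", "Right")},
        "who_grade_pct": {
            int(g): 100.0 * (grades == g).sum() / n for g in sorted(grades.dropna().unique())
        },
        "histological_type_pct": {
            t: 100.0 * (types == t).sum() / n for t in sorted(types.dropna().astype(str).unique())
        },
        "tumor_location_counts": df["tumor_location"].value_counts().to_dict(),
        "unparseable_grade_subjects": unparseable,
    }
    return summary
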