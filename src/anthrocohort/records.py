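"""Core record types: one child-visit, one child, one set of z-scores.

The workhorse container for whole cohorts is a pandas DataFrame in the
canonical visit schema (see :mod:`anthrocohort.io`); these dataclasses are the
per-record view used by the simulator and by scalar operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

SEXES = ("male", "female")
INDICATORS = ("HAZ", "WHZ", "WAZ")

#: WHO Anthro convention for converting an age in months to an age in days.
DAYS_PER_MONTH = 30.4375

#: Canonical column order for visit-level cohort files.
VISIT_COLUMNS = (
    "child_id",
    "visit_number",
    "sex",
    "age_months",
    "weight_kg",
    "length_cm",
    "muac_mm",
)


def age_months_to_days(age_months: float) -> float:
    """Convert an age in months to a whole-day reference key.

    Ages are keyed in completed days (WHO Anthro convention); rounding to the
    nearest day makes z-scores exactly reproducible across file round-trips.
    """
    return float(round(age_months * DAYS_PER_MONTH))


@dataclass
class VisitRecord:
    """One anthropometric observation of one child at one visit."""

    child_id: str
    visit_number: int
    sex: str | None
    age_months: float
    weight_kg: float = math.nan
    length_cm: float = math.nan
    muac_mm: float = math.nan


@dataclass
class ChildRecord:
    """A child with their ordered visit history."""

    child_id: str
    sex: str | None
    visits: list[VisitRecord]

    @property
    def enrollment_age_months(self) -> float:
        return self.visits[0].age_months


@dataclass
class ZScoreSet:
    """HAZ/WHZ/WAZ z-scores (restricted-adjusted) plus raw MUAC for one visit.

    ``flags`` holds the indicators whose value failed the biological
    plausibility screen; flags are only ever set for present values.
    """

    haz: float = math.nan
    whz: float = math.nan
    waz: float = math.nan
    muac_mm: float = math.nan
    flags: frozenset[str] = field(default_factory=frozenset)

    def get(self, indicator: str) -> float:
        return {"HAZ": self.haz, "WHZ": self.whz, "WAZ": self.waz}[indicator]


def cohort_to_frame(children: list[ChildRecord]) -> pd.DataFrame:
    """Flatten ChildRecords into the canonical visit DataFrame."""
    rows = []
    for child in children:
        for v in child.visits:
            rows.append(
                (v.child_id, v.visit_number, v.sex, v.age_months,
                 v.weight_kg, v.length_cm, v.muac_mm)
            )
    return pd.DataFrame(rows, columns=list(VISIT_COLUMNS))


def frame_to_cohort(visits: pd.DataFrame) -> list[ChildRecord]:
    """Group a canonical visit DataFrame back into ChildRecords."""
    children: list[ChildRecord] = []
    for child_id, grp in visits.groupby("child_id", sort=False):
        grp = grp.sort_values("visit_number")
        recs = [
            VisitRecord(
                child_id=str(child_id),
                visit_number=int(r.visit_number),
                sex=None if pd.isna(r.sex) else str(r.sex),
                age_months=float(r.age_months) if pd.notna(r.age_months) else math.nan,
                weight_kg=float(r.weight_kg) if pd.notna(r.weight_kg) else math.nan,
                length_cm=float(r.length_cm) if pd.notna(r.length_cm) else math.nan,
                muac_mm=float(r.muac_mm) if pd.notna(r.muac_mm) else math.nan,
            )
            for r in grp.itertuples()
        ]
        sex = recs[0].sex
        children.append(ChildRecord(child_id=str(child_id), sex=sex, visits=recs))
    return children
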