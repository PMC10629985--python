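"""Two-stage cohort cleaning.

Stage 1 (participant screening) drops whole children, in a fixed order so the
attribution of each child to a reason is deterministic:

1. sex or age not recorded,
2. fewer than three visits (the minimum follow-up in which intervention
   effects are considered observable),
3. severe acute malnutrition (SAM) at the first visit — such children are
   referred to therapeutic feeding and analysed elsewhere.

Stage 2 (visit-level plausibility) blanks individual indicator values that
are biologically implausible, using the conventional fixed bounds:
HAZ outside (-6, +6), WHZ outside (-6, +5), WAZ outside (-5, +5), with strict
inequalities (a value exactly at a bound is retained).  Blanking is
per-indicator: a wild length eliminates HAZ without touching WAZ, and visit
rows survive with their remaining indicators.  The stage produces an
elimination table cross-classified by visit number and indicator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError
from .growth_reference import LMSReference, compute_cohort_zscores
from .records import ZScoreSet

logger = logging.getLogger(__name__)

#: Strict (lower, upper) plausibility bounds per indicator, in z units.
PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "HAZ": (-6.0, 6.0),
    "WHZ": (-6.0, 5.0),
    "WAZ": (-5.0, 5.0),
}

_ZCOL = {"HAZ": "haz", "WHZ": "whz", "WAZ": "waz"}

STAGE_MISSING = "missing_sex_age"
STAGE_FEW_VISITS = "too_few_visits"
STAGE_SAM = "sam_first_visit"
STAGE_IMPLAUSIBLE = "implausible_value"


@dataclass(frozen=True)
class SAMRule:
    """Severe-acute-malnutrition triage rule (CMAM admission criteria)."""

    whz_below: float = -3.0
    muac_below_mm: float = 115.0


@dataclass
class ScreeningResult:
    kept: pd.DataFrame
    log: pd.DataFrame  # columns: stage, child_id, visit_number, indicator, detail


@dataclass
class CleaningResult:
    cleaned: pd.DataFrame          # visit frame with haz/whz/waz, blanked where flagged
    elimination_table: pd.DataFrame
    log: pd.DataFrame


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["stage", "child_id", "visit_number", "indicator", "detail"]
    )


def ensure_zscores(visits: pd.DataFrame, ref: LMSReference) -> pd.DataFrame:
    """Return a z-scored frame, computing haz/whz/waz only when absent.

    Existing z columns take precedence: on an already-cleaned frame the
    blanked values must stay blank (recomputing them from the raw
    measurements would resurrect the implausible records), which is what
    makes cleaning idempotent across file round-trips.
    """
    if {"haz", "whz", "waz"} <= set(visits.columns):
        return visits.copy()
    return compute_cohort_zscores(visits, ref)


def flag_implausible(zset: ZScoreSet,
                     bounds: dict[str, tuple[float, float]] | None = None) -> ZScoreSet:
    """Return a copy of ``zset`` with per-indicator plausibility flags set.

    Bounds are strict: values exactly at a bound are retained.  Flags are
    independent across indicators and only ever set for present values.
    """
    bounds = bounds or PLAUSIBILITY_BOUNDS
    flags = set()
    for indicator, (lo, hi) in bounds.items():
        z = zset.get(indicator)
        if math.isfinite(z) and (z < lo or z > hi):
            flags.add(indicator)
    return ZScoreSet(haz=zset.haz, whz=zset.whz, waz=zset.waz,
                     muac_mm=zset.muac_mm, flags=frozenset(flags))


def implausibility_mask(zframe: pd.DataFrame,
                        bounds: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
    """Boolean mask (columns HAZ/WHZ/WAZ) of implausible values in a z-frame."""
    bounds = bounds or PLAUSIBILITY_BOUNDS
    mask = {}
    for indicator, (lo, hi) in bounds.items():
        z = zframe[_ZCOL[indicator]].to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            mask[indicator] = np.isfinite(z) & ((z < lo) | (z > hi))
    return pd.DataFrame(mask, index=zframe.index)


def is_sam_at_first_visit(zset: ZScoreSet, sam_rule: SAMRule = SAMRule(),
                          bounds: dict[str, tuple[float, float]] | None = None) -> bool:
    """True iff the first-visit z-set meets the SAM rule.

    Only a biologically plausible WHZ is diagnostic: an implausible value is
    a recording error, not a diagnosis, and falls through to the MUAC arm.
    With both WHZ and MUAC unassessable the child is retained (returns False)
    and a warning is logged.
    """
    flagged = flag_implausible(zset, bounds).flags
    whz_ok = math.isfinite(zset.whz) and "WHZ" not in flagged
    muac_ok = math.isfinite(zset.muac_mm)
    if whz_ok and zset.whz < sam_rule.whz_below:
        return True
    if muac_ok and zset.muac_mm < sam_rule.muac_below_mm:
        return True
    if not whz_ok and not muac_ok:
        logger.warning("SAM unassessable (no usable WHZ or MUAC); child retained")
    return False


def screen_participants(visits: pd.DataFrame, ref: LMSReference,
                        sam_rule: SAMRule = SAMRule(),
                        min_visits: int = 3,
                        bounds: dict[str, tuple[float, float]] | None = None) -> ScreeningResult:
    """Apply the three participant screens in order; each dropped child is
    logged once, under the first rule that caught it.  Row order of the kept
    cohort is preserved."""
    log_rows: list[dict] = []
    df = visits

    # 1. missing sex or age
    per_child = df.groupby("child_id", sort=False).agg(
        sex_missing=("sex", lambda s: s.isna().any() | (~s.isin(("male", "female"))).any()),
        age_missing=("age_months", lambda a: a.isna().any()),
        n_visits=("visit_number", "size"),
    )
    drop1 = per_child.index[per_child.sex_missing | per_child.age_missing]
    for cid in drop1:
        which = []
        if per_child.loc[cid, "sex_missing"]:
            which.append("sex")
        if per_child.loc[cid, "age_missing"]:
            which.append("age")
        log_rows.append(dict(stage=STAGE_MISSING, child_id=cid, visit_number=np.nan,
                             indicator=None, detail=f"missing {'/'.join(which)}"))
    df = df[~df["child_id"].isin(set(drop1))]

    # 2. fewer than `min_visits` visits
    remaining = per_child.drop(index=drop1)
    drop2 = remaining.index[remaining.n_visits < min_visits]
    for cid in drop2:
        log_rows.append(dict(stage=STAGE_FEW_VISITS, child_id=cid, visit_number=np.nan,
                             indicator=None,
                             detail=f"{remaining.loc[cid, 'n_visits']} visit(s) < {min_visits}"))
    df = df[~df["child_id"].isin(set(drop2))]

    # 3. SAM at first visit
    if len(df):
        first = df.sort_values("visit_number").groupby("child_id", sort=False).head(1)
        zfirst = ensure_zscores(first, ref)
        mask = implausibility_mask(zfirst, bounds)
        whz = zfirst["whz"].to_numpy(dtype=float)
        muac = zfirst["muac_mm"].to_numpy(dtype=float)
        whz_ok = np.isfinite(whz) & ~mask["WHZ"].to_numpy()
        with np.errstate(invalid="ignore"):
            sam = (whz_ok & (whz < sam_rule.whz_below)) | (
                np.isfinite(muac) & (muac < sam_rule.muac_below_mm)
            )
        drop3 = zfirst.loc[sam, "child_id"].tolist()
        for cid, w, mu in zip(zfirst.loc[sam, "child_id"],
                              whz[sam], muac[sam]):
            log_rows.append(dict(stage=STAGE_SAM, child_id=cid, visit_number=1,
                                 indicator=None,
                                 detail=f"whz={w:.2f} muac={mu:.0f}mm"))
        df = df[~df["child_id"].isin(set(drop3))]

    log = pd.DataFrame(log_rows) if log_rows else _empty_log()
    n_in = visits["child_id"].nunique()
    n_kept = df["child_id"].nunique()
    logger.info("screening: %d children in, %d kept, %d dropped",
                n_in, n_kept, n_in - n_kept)
    return ScreeningResult(kept=df.copy(), log=log)


def apply_visit_filters(visits: pd.DataFrame, ref: LMSReference,
                        bounds: dict[str, tuple[float, float]] | None = None) -> CleaningResult:
    """Score every visit, blank implausible indicator values and account for
    the eliminations by visit number and indicator.

    The number of children never changes here — only individual data are
    removed.  Percentages are relative to the number of computed (non-missing)
    z-scores per indicator.
    """
    zframe = ensure_zscores(visits, ref)
    mask = implausibility_mask(zframe, bounds)

    log_rows: list[dict] = []
    for indicator in ("HAZ", "WHZ", "WAZ"):
        col = _ZCOL[indicator]
        hit = mask[indicator]
        for idx in zframe.index[hit]:
            log_rows.append(dict(
                stage=STAGE_IMPLAUSIBLE,
                child_id=zframe.at[idx, "child_id"],
                visit_number=int(zframe.at[idx, "visit_number"]),
                indicator=indicator,
                detail=f"{col}={zframe.at[idx, col]:.2f}",
            ))

    initial = {ind: int(zframe[_ZCOL[ind]].notna().sum()) for ind in ("HAZ", "WHZ", "WAZ")}

    cleaned = zframe.copy()
    for indicator in ("HAZ", "WHZ", "WAZ"):
        cleaned.loc[mask[indicator], _ZCOL[indicator]] = np.nan

    # elimination table: visit rows x indicator columns, totals, percentages
    max_visit = int(visits["visit_number"].max()) if len(visits) else 0
    visit_index = list(range(1, max_visit + 1))
    counts = pd.DataFrame(0, index=visit_index, columns=["HAZ", "WHZ", "WAZ"])
    if log_rows:
        logdf = pd.DataFrame(log_rows)
        tab = logdf.groupby(["visit_number", "indicator"]).size().unstack(fill_value=0)
        counts.loc[tab.index, tab.columns] = tab
    counts["Total"] = counts.sum(axis=1)
    table = counts.copy()
    table.index = [f"visit_{v}" for v in visit_index]
    table.loc["total_eliminated"] = counts.sum()
    init_row = {ind: initial[ind] for ind in ("HAZ", "WHZ", "WAZ")}
    init_row["Total"] = sum(initial.values())
    table.loc["initial_data"] = pd.Series(init_row)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = {
            c: (100.0 * table.loc["total_eliminated", c] / table.loc["initial_data", c]
                if table.loc["initial_data", c] else 0.0)
            for c in table.columns
        }
    table.loc["percent_eliminated"] = pd.Series(pct)
    table = table.reindex(["initial_data", *[f"visit_{v}" for v in visit_index],
                           "total_eliminated", "percent_eliminated"])

    log = pd.DataFrame(log_rows) if log_rows else _empty_log()
    logger.info("visit filters: %d implausible values blanked across %d visits",
                len(log_rows), visits["visit_number"].nunique() if len(visits) else 0)
    return CleaningResult(cleaned=cleaned, elimination_table=table, log=log)


def clean_cohort(visits: pd.DataFrame, ref: LMSReference,
                 sam_rule: SAMRule = SAMRule(), min_visits: int = 3,
                 bounds: dict[str, tuple[float, float]] | None = None
                 ) -> tuple[CleaningResult, ScreeningResult]:
    """Participant screening followed by visit-level plausibility filtering."""
    if visits.empty:
        raise DataError("empty cohort")
    screened = screen_participants(visits, ref, sam_rule=sam_rule,
                                   min_visits=min_visits, bounds=bounds)
    cleaned = apply_visit_filters(screened.kept, ref, bounds=bounds)
    return cleaned, screened
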