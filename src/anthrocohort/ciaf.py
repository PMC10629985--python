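"""Composite Index of Anthropometric Failure (CIAF).

Stunting (HAZ < -2), wasting (WHZ < -2) and underweight (WAZ < -2) are
distinct processes that can co-occur; the CIAF partitions children into
failure categories and aggregates them into a single figure:

    A  no anthropometric failure
    B  wasting only
    C  wasting + underweight
    D  wasting + stunting + underweight
    E  stunting + underweight
    F  stunting only
    Y  underweight only
    X  wasting + stunting without underweight (logically possible but absent
       from the classical scheme; kept explicit and logged as anomalous)

The aggregate CIAF is the total number of children minus those in category A.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DataError, UnclassifiableError
from .records import ZScoreSet

logger = logging.getLogger(__name__)

CATEGORY_ORDER = ("A", "B", "C", "D", "E", "F", "Y", "X")

CATEGORY_LABELS = {
    "A": "no anthropometric failure",
    "B": "wasting only",
    "C": "wasting + underweight",
    "D": "wasting + stunting + underweight",
    "E": "stunting + underweight",
    "F": "stunting only",
    "Y": "underweight only",
    "X": "wasting + stunting (anomalous)",
}

# (wasting, stunting, underweight) -> code
_TRUTH_TABLE = {
    (False, False, False): "A",
    (True, False, False): "B",
    (True, False, True): "C",
    (True, True, True): "D",
    (False, True, True): "E",
    (False, True, False): "F",
    (False, False, True): "Y",
    (True, True, False): "X",
}


@dataclass
class CIAFTable:
    """Category counts plus the aggregate CIAF for one set of child-visits."""

    counts: dict[str, int]
    n_total: int
    ciaf_count: int
    ciaf_proportion: float
    n_unclassifiable: int = 0

    def to_frame(self) -> pd.DataFrame:
        rows = [
            dict(category=c, label=CATEGORY_LABELS[c], count=self.counts[c],
                 proportion=self.counts[c] / self.n_total if self.n_total else math.nan)
            for c in CATEGORY_ORDER
        ]
        return pd.DataFrame(rows)


def classify_ciaf(zset: ZScoreSet | tuple[float, float, float],
                  threshold: float = -2.0) -> str:
    """Map one z-set to its failure category.

    The threshold is strict ("below -2"); any missing required z raises
    :class:`UnclassifiableError` so the caller decides about exclusion.
    """
    if isinstance(zset, ZScoreSet):
        haz, whz, waz = zset.haz, zset.whz, zset.waz
    else:
        haz, whz, waz = zset
    if not (math.isfinite(haz) and math.isfinite(whz) and math.isfinite(waz)):
        raise UnclassifiableError("HAZ, WHZ and WAZ must all be present")
    code = _TRUTH_TABLE[(whz < threshold, haz < threshold, waz < threshold)]
    if code == "X":
        logger.warning("anomalous combination wasting+stunting without underweight "
                       "(haz=%.2f whz=%.2f waz=%.2f)", haz, whz, waz)
    return code


def classify_frame(zframe: pd.DataFrame, threshold: float = -2.0) -> pd.Series:
    """Vectorised classification of a z-frame; unclassifiable rows get NaN."""
    haz = zframe["haz"].to_numpy(dtype=float)
    whz = zframe["whz"].to_numpy(dtype=float)
    waz = zframe["waz"].to_numpy(dtype=float)
    ok = np.isfinite(haz) & np.isfinite(whz) & np.isfinite(waz)
    codes = np.full(len(zframe), None, dtype=object)
    with np.errstate(invalid="ignore"):
        w = whz < threshold
        s = haz < threshold
        u = waz < threshold
    lut = np.array([_TRUTH_TABLE[(bool(a), bool(b), bool(c))]
                    for a in (0, 1) for b in (0, 1) for c in (0, 1)]).reshape(2, 2, 2)
    codes[ok] = lut[w[ok].astype(int), s[ok].astype(int), u[ok].astype(int)]
    return pd.Series(codes, index=zframe.index, name="ciaf")


def tabulate_ciaf(zframe: pd.DataFrame, threshold: float = -2.0) -> CIAFTable:
    """Tabulate categories over child-visits; every category is reported even
    when zero.  Unclassifiable entries are removed and their count reported."""
    codes = classify_frame(zframe, threshold)
    n_bad = int(codes.isna().sum())
    codes = codes.dropna()
    if codes.empty:
        raise DataError("no classifiable entries (all z-sets incomplete)")
    counts = {c: int((codes == c).sum()) for c in CATEGORY_ORDER}
    n_total = int(len(codes))
    ciaf_count = n_total - counts["A"]
    return CIAFTable(counts=counts, n_total=n_total, ciaf_count=ciaf_count,
                     ciaf_proportion=ciaf_count / n_total,
                     n_unclassifiable=n_bad)


def ciaf_transition(start: pd.DataFrame, end: pd.DataFrame,
                    threshold: float = -2.0) -> pd.DataFrame:
    """Start-to-end category transition counts, paired by child.

    ``start`` and ``end`` are z-frames with a ``child_id`` column (one row per
    child).  Children missing from either side, or unclassifiable at either
    timepoint, are excluded with a log entry.  The marginals of the returned
    8x8 matrix equal the per-timepoint tabulations of the included children.
    """
    s = start.set_index("child_id")
    e = end.set_index("child_id")
    common = s.index.intersection(e.index)
    n_unpaired = len(s.index.symmetric_difference(e.index))
    if n_unpaired:
        logger.info("ciaf_transition: %d unpaired child(ren) excluded", n_unpaired)
    cs = classify_frame(s.loc[common], threshold)
    ce = classify_frame(e.loc[common], threshold)
    ok = cs.notna() & ce.notna()
    n_uncls = int((~ok).sum())
    if n_uncls:
        logger.info("ciaf_transition: %d child(ren) unclassifiable at a timepoint", n_uncls)
    matrix = pd.DataFrame(0, index=list(CATEGORY_ORDER), columns=list(CATEGORY_ORDER))
    pairs = pd.crosstab(cs[ok], ce[ok])
    matrix.loc[pairs.index, pairs.columns] = pairs
    return matrix
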