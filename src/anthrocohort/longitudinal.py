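"""Start-vs-end change analysis for a cleaned, z-scored cohort.

For each child and indicator the first and last visits with a usable value
form a pair; paired change within a cohort is tested with the Wilcoxon
signed-rank test and summarised as median [IQR], while between-cohort
contrasts of per-child deltas (end minus start) use the Mann-Whitney
rank-sum test.  Strata mirror the usual reporting structure of growth
monitoring programmes: whole sample, programme compliance, length-of-stay
quartiles and CIAF category at inclusion.

Small samples get exact p-values (full null enumeration, implemented via the
rank generating function); larger samples use the normal approximation with
continuity and tie corrections.  Quartiles and IQRs use the linear
interpolation convention throughout.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ciaf import CATEGORY_ORDER, classify_frame
from .errors import DataError

logger = logging.getLogger(__name__)

#: Reported indicators and their column names in a cleaned z-frame.
INDICATOR_COLUMNS = {"HAZ": "haz", "WHZ": "whz", "WAZ": "waz", "MUAC": "muac_mm"}

#: Largest number of non-zero differences for which the signed-rank p-value
#: is computed exactly.
WILCOXON_EXACT_MAX = 25

#: Largest combined sample size for which the rank-sum p-value is exact.
MANNWHITNEY_EXACT_MAX = 16


@dataclass
class PairedSeries:
    """Per-child (start, end) values for one indicator."""

    indicator: str
    pairs: pd.DataFrame  # columns: child_id, start, end
    n_excluded: int = 0

    @property
    def n(self) -> int:
        return len(self.pairs)

    @property
    def deltas(self) -> np.ndarray:
        return (self.pairs["end"] - self.pairs["start"]).to_numpy(dtype=float)


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int
    n_zero: int = 0
    degenerate: bool = False


def first_last_pairs(clean: pd.DataFrame, indicator: str) -> PairedSeries:
    """First and last usable value per child for ``indicator``.

    "First usable" means the earliest visit at which the value survived
    cleaning, not the first scheduled visit.  Children with fewer than two
    usable values are excluded and counted.
    """
    col = INDICATOR_COLUMNS[indicator]
    df = clean[["child_id", "visit_number", col]].dropna(subset=[col])
    df = df.sort_values(["child_id", "visit_number"], kind="stable")
    grp = df.groupby("child_id", sort=False)[col]
    firsts = grp.first()
    lasts = grp.last()
    sizes = grp.size()
    usable = sizes >= 2
    pairs = pd.DataFrame({
        "child_id": firsts.index[usable],
        "start": firsts[usable].to_numpy(),
        "end": lasts[usable].to_numpy(),
    }).reset_index(drop=True)
    n_excluded = int(clean["child_id"].nunique() - usable.sum())
    return PairedSeries(indicator=indicator, pairs=pairs, n_excluded=n_excluded)


def median_iqr(values) -> tuple[float, float, float]:
    """(median, q1, q3) with the linear-interpolation quantile convention."""
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size == 0:
        raise DataError("median_iqr of empty collection")
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


# ---------------------------------------------------------------------------
# exact signed-rank distribution via its generating function


def _signed_rank_exact_p(d: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p for non-zero differences ``d`` (midranks allowed).

    Enumerates the null distribution of W+ (sum of ranks of positive
    differences) over all 2^n sign assignments through the generating
    function on doubled ranks, which is exact for any tie pattern.
    Returns (W+, p).
    """
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    r2 = np.rint(2.0 * ranks).astype(np.int64)  # midranks doubled -> integers
    w2 = int(r2[d > 0].sum())
    total = int(r2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: total + 1 - r]
        counts += shifted
    denom = 2.0 ** n
    p_le = counts[: w2 + 1].sum() / denom
    p_ge = counts[w2:].sum() / denom
    p = min(1.0, 2.0 * min(p_le, p_ge))
    return float(w2 / 2.0), p


def wilcoxon_signed_rank(start, end=None, *, zero_method: str = "wilcox",
                         method: str = "auto", zero_tol: float = 1e-6) -> TestResult:
    """Paired signed-rank test on (start, end) values or on differences.

    Zero differences are dropped by default (classical Wilcoxon convention;
    ``zero_method='pratt'`` keeps them in the ranking via scipy).  Paired
    float values that agree to within ``zero_tol`` are treated as ties:
    values that went through a compute/store/recompute cycle differ by
    accumulated rounding even when nothing changed, and counting that noise
    as signed differences would manufacture significance out of nothing.
    The exact two-sided p is used when the number of non-zero differences is
    at most ``WILCOXON_EXACT_MAX``; otherwise the normal approximation with
    continuity and tie corrections.  ``method`` may force 'exact' or
    'approx'.  With every difference zero the result is degenerate: p = 1.
    """
    if end is not None:
        d = np.asarray(end, dtype=float) - np.asarray(start, dtype=float)
    else:
        d = np.asarray(start, dtype=float)
    d = d[np.isfinite(d)]
    d = np.where(np.abs(d) <= zero_tol, 0.0, d)
    n_zero = int((d == 0).sum())
    nz = d[d != 0]
    n = len(nz)
    if n == 0:
        return TestResult(statistic=0.0, p_value=1.0, method="degenerate",
                          n=0, n_zero=n_zero, degenerate=True)
    use_exact = method == "exact" or (
        method == "auto" and n <= WILCOXON_EXACT_MAX and zero_method == "wilcox"
    )
    if use_exact and zero_method == "wilcox":
        stat, p = _signed_rank_exact_p(nz)
        return TestResult(statistic=stat, p_value=p, method="wilcoxon-exact",
                          n=n, n_zero=n_zero)
    res = sps.wilcoxon(d if zero_method == "pratt" else nz,
                       zero_method=zero_method, correction=True,
                       alternative="two-sided", method="approx")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="wilcoxon-approx", n=n, n_zero=n_zero)


# ---------------------------------------------------------------------------
# Mann-Whitney


def _mann_whitney_exact_p(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Exact two-sided p by enumerating every split of the combined ranks."""
    m, k = len(a), len(b)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u_obs = float(ranks[:m].sum() - m * (m + 1) / 2.0)
    n_total = m + k
    us = np.array([
        ranks[list(idx)].sum() - m * (m + 1) / 2.0
        for idx in itertools.combinations(range(n_total), m)
    ])
    n_comb = len(us)
    p_le = (us <= u_obs + 1e-12).sum() / n_comb
    p_ge = (us >= u_obs - 1e-12).sum() / n_comb
    return u_obs, min(1.0, 2.0 * min(p_le, p_ge))


def mann_whitney_u(a, b, *, method: str = "auto") -> TestResult:
    """Two-sided rank-sum test between independent samples ``a`` and ``b``.

    Exact by combination enumeration when the combined size is at most
    ``MANNWHITNEY_EXACT_MAX``; the normal approximation with tie and
    continuity corrections otherwise.  The statistic is U for the first
    sample.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) == 0 or len(b) == 0:
        raise DataError("both groups must be nonempty")
    if method == "exact" or (method == "auto" and len(a) + len(b) <= MANNWHITNEY_EXACT_MAX):
        stat, p = _mann_whitney_exact_p(a, b)
        return TestResult(statistic=stat, p_value=p, method="mannwhitney-exact",
                          n=len(a) + len(b))
    res = sps.mannwhitneyu(a, b, use_continuity=True, alternative="two-sided",
                           method="asymptotic")
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      method="mannwhitney-approx", n=len(a) + len(b))


# ---------------------------------------------------------------------------
# strata


def child_stays(clean: pd.DataFrame) -> pd.Series:
    """Length of stay per child, in months: last visit age minus first."""
    grp = clean.groupby("child_id")["age_months"]
    return (grp.max() - grp.min()).rename("stay_months")


def stay_quartiles(clean: pd.DataFrame) -> tuple[pd.Series, tuple[float, float, float]]:
    """Assign each child to a length-of-stay quartile stratum (1..4).

    Boundaries are the empirical quartiles (linear interpolation); a stay
    exactly at a boundary goes to the lower stratum.  Raises when fewer than
    four distinct stays exist.
    """
    stays = child_stays(clean)
    if stays.nunique() < 4:
        raise DataError(
            f"only {stays.nunique()} distinct stay value(s); "
            "use fewer strata than quartiles"
        )
    q1, q2, q3 = np.percentile(stays.to_numpy(), [25, 50, 75], method="linear")
    strata = (1 + (stays > q1).astype(int) + (stays > q2).astype(int)
              + (stays > q3).astype(int)).rename("stay_stratum")
    logger.info("stay quartile boundaries: %.2f / %.2f / %.2f months", q1, q2, q3)
    return strata, (float(q1), float(q2), float(q3))


def compliance_subgroup(clean: pd.DataFrame, enroll_max_months: float = 1.0,
                        exit_min_months: float = 23.0) -> pd.DataFrame:
    """Children who effectively completed the whole 0-24-month programme:
    enrolled by ``enroll_max_months`` and still followed at ``exit_min_months``."""
    grp = clean.groupby("child_id")["age_months"]
    ok = (grp.min() <= enroll_max_months) & (grp.max() >= exit_min_months)
    keep = set(ok.index[ok])
    return clean[clean["child_id"].isin(keep)].copy()


def first_last_zframes(clean: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-child z-frames at the first and last fully classifiable visit
    (all three z present), for CIAF tabulation and transitions."""
    full = clean.dropna(subset=["haz", "whz", "waz"])
    full = full.sort_values(["child_id", "visit_number"], kind="stable")
    start = full.groupby("child_id", as_index=False).head(1)
    end = full.groupby("child_id", as_index=False).tail(1)
    cols = ["child_id", "haz", "whz", "waz"]
    return start[cols].reset_index(drop=True), end[cols].reset_index(drop=True)


# ---------------------------------------------------------------------------
# reporting


def _stratum_rows(clean: pd.DataFrame, label: str,
                  indicators=tuple(INDICATOR_COLUMNS)) -> list[dict]:
    rows = []
    for indicator in indicators:
        series = first_last_pairs(clean, indicator)
        if series.n == 0:
            rows.append(dict(stratum=label, indicator=indicator, n=0,
                             start_median=np.nan, start_q1=np.nan, start_q3=np.nan,
                             end_median=np.nan, end_q1=np.nan, end_q3=np.nan,
                             p_value=np.nan, test="none"))
            continue
        sm, sq1, sq3 = median_iqr(series.pairs["start"])
        em, eq1, eq3 = median_iqr(series.pairs["end"])
        res = wilcoxon_signed_rank(series.pairs["start"], series.pairs["end"])
        rows.append(dict(stratum=label, indicator=indicator, n=series.n,
                         start_median=sm, start_q1=sq1, start_q3=sq3,
                         end_median=em, end_q1=eq1, end_q3=eq3,
                         p_value=res.p_value, test=res.method))
    return rows


def change_report(clean: pd.DataFrame,
                  strata: str = "whole",
                  ciaf_threshold: float = -2.0,
                  enroll_max_months: float = 1.0,
                  exit_min_months: float = 23.0) -> pd.DataFrame:
    """One summary row per stratum and indicator.

    ``strata`` is one of 'whole', 'compliance', 'stay_quartiles',
    'ciaf_at_inclusion'.  Empty strata produce n = 0 rows, never a crash.
    """
    if strata == "whole":
        rows = _stratum_rows(clean, "all")
    elif strata == "compliance":
        sub = compliance_subgroup(clean, enroll_max_months, exit_min_months)
        rows = _stratum_rows(sub, "completed_program")
    elif strata == "stay_quartiles":
        assignment, bounds = stay_quartiles(clean)
        rows = []
        for q in (1, 2, 3, 4):
            ids = set(assignment.index[assignment == q])
            sub = clean[clean["child_id"].isin(ids)]
            rows.extend(_stratum_rows(sub, f"stay_q{q}"))
    elif strata == "ciaf_at_inclusion":
        start, _ = first_last_zframes(clean)
        codes = classify_frame(start, ciaf_threshold)
        start = start.assign(ciaf=codes.to_numpy())
        rows = []
        for code in CATEGORY_ORDER:
            ids = set(start.loc[start["ciaf"] == code, "child_id"])
            if not ids:
                continue
            sub = clean[clean["child_id"].isin(ids)]
            rows.extend(_stratum_rows(sub, f"ciaf_{code}"))
    else:
        raise DataError(f"unknown strata spec {strata!r}")
    return pd.DataFrame(rows)


def delta_contrast(clean_a: pd.DataFrame, clean_b: pd.DataFrame,
                   labels: tuple[str, str] = ("cohort_a", "cohort_b"),
                   indicators=("HAZ", "WHZ", "WAZ")) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Between-cohort contrast of per-child first-to-last deltas.

    Returns (summary, tidy): per-indicator medians and the rank-sum p, plus a
    tidy (cohort, indicator, delta) table suitable for violin plots.
    """
    summary_rows = []
    tidy_rows = []
    for indicator in indicators:
        da = first_last_pairs(clean_a, indicator).deltas
        db = first_last_pairs(clean_b, indicator).deltas
        res = mann_whitney_u(da, db)
        summary_rows.append(dict(
            indicator=indicator,
            **{f"median_{labels[0]}": float(np.median(da)) if len(da) else np.nan,
               f"median_{labels[1]}": float(np.median(db)) if len(db) else np.nan},
            n_a=len(da), n_b=len(db),
            p_value=res.p_value, test=res.method,
        ))
        for label, deltas in ((labels[0], da), (labels[1], db)):
            tidy_rows.extend(dict(cohort=label, indicator=indicator, delta=float(x))
                             for x in deltas)
    return pd.DataFrame(summary_rows), pd.DataFrame(tidy_rows)
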