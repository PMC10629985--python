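"""Paired change analysis: pairing, quantiles, the exact nonparametric tests
against full brute-force enumeration, strata and the two-cohort contrast."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from anthrocohort import (
    SimulationParams,
    change_report,
    compliance_subgroup,
    delta_contrast,
    first_last_pairs,
    mann_whitney_u,
    median_iqr,
    simulate_cohort,
    stay_quartiles,
    wilcoxon_signed_rank,
)
from anthrocohort.cleaning import clean_cohort
from anthrocohort.errors import DataError
from scipy import stats as sps


def _frame(rows):
    return pd.DataFrame(rows, columns=["child_id", "visit_number", "age_months",
                                       "haz", "whz", "waz", "muac_mm"])


# ---------------------------------------------------------------------------
# pairing


def test_first_last_pair_uses_first_and_last_usable():
    df = _frame([
        ("a", 1, 1.0, -1.0, 0, 0, 130),
        ("a", 2, 2.0, -1.2, 0, 0, 130),
        ("a", 3, 3.0, -1.4, 0, 0, 130),
        ("b", 1, 1.0, np.nan, 0, 0, 130),   # blanked at visit 1
        ("b", 2, 2.0, -0.5, 0, 0, 130),
        ("b", 5, 5.0, -0.9, 0, 0, 130),
    ])
    series = first_last_pairs(df, "HAZ")
    pairs = series.pairs.set_index("child_id")
    assert pairs.loc["a", "start"] == -1.0 and pairs.loc["a", "end"] == -1.4
    assert pairs.loc["b", "start"] == -0.5 and pairs.loc["b", "end"] == -0.9


def test_children_with_fewer_than_two_usable_values_excluded():
    rows = []
    for i in range(20):
        usable = 1 if i < 3 else 3   # 3 children have a single usable HAZ
        for v in range(1, 4):
            rows.append((f"c{i:02d}", v, float(v),
                         -1.0 if v <= usable else np.nan, 0, 0, 130))
    series = first_last_pairs(_frame(rows), "HAZ")
    assert series.n == 17
    assert series.n_excluded == 3


# ---------------------------------------------------------------------------
# quantiles


def test_median_iqr_worked_examples():
    assert median_iqr([1, 2, 3, 4, 5]) == (3.0, 2.0, 4.0)
    assert median_iqr([7.5]) == (7.5, 7.5, 7.5)
    with pytest.raises(DataError):
        median_iqr([])


def test_median_iqr_against_sorted_oracle():
    """Linear-interpolation quantiles recomputed from the order statistics."""
    rng = np.random.default_rng(23)
    values = rng.normal(size=1000)
    med, q1, q3 = median_iqr(values)

    def quantile(sorted_v, q):
        h = (len(sorted_v) - 1) * q
        lo = int(math.floor(h))
        hi = min(lo + 1, len(sorted_v) - 1)
        return sorted_v[lo] + (h - lo) * (sorted_v[hi] - sorted_v[lo])

    s = np.sort(values)
    assert med == pytest.approx(quantile(s, 0.5), rel=1e-12)
    assert q1 == pytest.approx(quantile(s, 0.25), rel=1e-12)
    assert q3 == pytest.approx(quantile(s, 0.75), rel=1e-12)
    assert q1 <= med <= q3


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank


def _brute_force_signed_rank_p(d):
    """Full 2^n enumeration of sign assignments (midranks for ties)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n_le = n_ge = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for s, r in zip(signs, ranks) if s)
        n_le += w <= w_obs + 1e-9
        n_ge += w >= w_obs - 1e-9
    total = 2 ** n
    return min(1.0, 2.0 * min(n_le / total, n_ge / total))


def test_wilcoxon_all_zero_differences_degenerate():
    res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
    assert res.p_value == 1.0 and res.degenerate


def test_wilcoxon_five_positive_differences():
    res = wilcoxon_signed_rank([0.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])
    assert res.p_value == pytest.approx(2 / 32)
    assert res.method == "wilcoxon-exact"


def test_wilcoxon_exact_equals_full_enumeration():
    """Exact p equals brute-force 2^n enumeration for n <= 12, ties included."""
    rng = np.random.default_rng(41)
    for n in range(4, 13):
        for trial in range(3):
            d = np.round(rng.normal(scale=2.0, size=n), 0)  # integer ties likely
            d = np.where(d == 0, 1.0, d)
            res = wilcoxon_signed_rank(d, method="exact")
            assert res.p_value == pytest.approx(
                _brute_force_signed_rank_p(d), abs=1e-12), (n, trial, d)


def test_wilcoxon_exact_and_approx_agree_at_n100():
    rng = np.random.default_rng(47)
    start = rng.normal(size=100)
    end = start + 0.15 + rng.normal(scale=0.8, size=100)
    exact = wilcoxon_signed_rank(start, end, method="exact")
    approx = wilcoxon_signed_rank(start, end, method="approx")
    assert abs(exact.p_value - approx.p_value) < 0.01


def test_wilcoxon_zero_handling_reported():
    res = wilcoxon_signed_rank([0, 0, 1, 2], [0, 0, 2, 4])
    assert res.n_zero == 2 and res.n == 2


def test_wilcoxon_pratt_mode_runs():
    res = wilcoxon_signed_rank([0, 0, 1, 2, 3, 1, 2, 4, 1, 1],
                               [0, 0, 2, 4, 5, 3, 1, 6, 3, 2],
                               zero_method="pratt")
    assert 0 <= res.p_value <= 1


# ---------------------------------------------------------------------------
# Mann-Whitney


def _brute_force_rank_sum_p(a, b):
    """Full C(m+n, m) enumeration of group assignments."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = len(a)
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    u_obs = ranks[:m].sum() - m * (m + 1) / 2
    us = [sum(ranks[i] for i in idx) - m * (m + 1) / 2
          for idx in itertools.combinations(range(len(combined)), m)]
    n_le = sum(u <= u_obs + 1e-9 for u in us)
    n_ge = sum(u >= u_obs - 1e-9 for u in us)
    return min(1.0, 2.0 * min(n_le / len(us), n_ge / len(us)))


def test_mann_whitney_worked_example():
    res = mann_whitney_u([1, 2, 3], [10, 11, 12])
    assert res.statistic == 0.0
    assert res.p_value == pytest.approx(0.1)  # 2 * (1/20)


def test_mann_whitney_identical_groups():
    res = mann_whitney_u([1, 2, 3], [1, 2, 3])
    assert res.p_value == 1.0


def test_mann_whitney_exact_equals_full_enumeration():
    rng = np.random.default_rng(53)
    for m, k in [(3, 3), (4, 4), (5, 5), (4, 6), (2, 7)]:
        for trial in range(3):
            a = np.round(rng.normal(size=m), 0)
            b = np.round(rng.normal(loc=0.5, size=k), 0)
            res = mann_whitney_u(a, b, method="exact")
            assert res.p_value == pytest.approx(
                _brute_force_rank_sum_p(a, b), abs=1e-12), (m, k, trial)


def test_mann_whitney_p_decreases_with_shift():
    rng = np.random.default_rng(59)
    a = rng.normal(size=60)
    base = rng.normal(size=60)
    pvals = [mann_whitney_u(a, base + shift).p_value
             for shift in (0.25, 0.5, 0.75, 1.0, 1.5)]
    assert all(p1 > p2 for p1, p2 in zip(pvals, pvals[1:]))


def test_mann_whitney_empty_group_errors():
    with pytest.raises(DataError):
        mann_whitney_u([], [1.0])


# ---------------------------------------------------------------------------
# strata


def _stay_frame(stays):
    rows = []
    for i, stay in enumerate(stays):
        rows.append((f"c{i:03d}", 1, 1.0, -1.0, 0, 0, 130))
        rows.append((f"c{i:03d}", 2, 1.0 + stay, -1.5, 0, 0, 130))
    return _frame(rows)


def test_stay_quartiles_even_split():
    df = _stay_frame(list(range(1, 9)))
    strata, bounds = stay_quartiles(df)
    assert strata.value_counts().sort_index().tolist() == [2, 2, 2, 2]


def test_stay_quartile_boundary_ties_go_low():
    df = _stay_frame([1, 2, 2, 2, 3, 4, 5, 6])
    strata, (q1, _, _) = stay_quartiles(df)
    tied = strata[[f"c{i:03d}" for i in (1, 2, 3)]]
    assert (tied <= 2).all()


def test_stay_quartiles_all_tied_errors():
    with pytest.raises(DataError, match="strata"):
        stay_quartiles(_stay_frame([5, 5, 5, 5]))


def test_stay_quartiles_partition(default_cleaned):
    cleaning, _ = default_cleaned
    strata, _ = stay_quartiles(cleaning.cleaned)
    assert len(strata) == cleaning.cleaned["child_id"].nunique()
    assert set(strata.unique()) == {1, 2, 3, 4}


def test_first_stay_quartile_boundary_matches_programme(default_cleaned):
    """With stay 14.5 +/- 6.6 and exit at 24 months, the first length-of-stay
    quartile boundary falls in the 8-10 month range."""
    cleaning, _ = default_cleaned
    _, (q1, _, _) = stay_quartiles(cleaning.cleaned)
    assert 8.0 <= q1 <= 10.0


def test_compliance_subgroup_rules():
    rows = [
        ("in", 1, 0.5, -1, 0, 0, 130), ("in", 2, 23.5, -1, 0, 0, 130),
        ("late", 1, 4.0, -1, 0, 0, 130), ("late", 2, 23.5, -1, 0, 0, 130),
        ("early_exit", 1, 0.5, -1, 0, 0, 130), ("early_exit", 2, 20.0, -1, 0, 0, 130),
    ]
    sub = compliance_subgroup(_frame(rows))
    assert set(sub["child_id"]) == {"in"}


def test_compliance_count_matches_manifest():
    rows = []
    for i in range(30):
        qualifies = i < 12
        age0 = 0.5 if qualifies else 3.0
        age_end = 23.5 if qualifies else 20.0
        rows += [(f"c{i}", 1, age0, -1, 0, 0, 130),
                 (f"c{i}", 2, age_end, -1, 0, 0, 130)]
    sub = compliance_subgroup(_frame(rows))
    assert sub["child_id"].nunique() == 12


# ---------------------------------------------------------------------------
# change report and contrast


def test_change_report_whole_sample_shape(default_cleaned):
    cleaning, _ = default_cleaned
    table = change_report(cleaning.cleaned)
    assert list(table["indicator"]) == ["HAZ", "WHZ", "WAZ", "MUAC"]
    assert (table["n"] > 0).all()
    assert ((0 <= table["p_value"]) & (table["p_value"] <= 1)).all()
    assert (table["start_q1"] <= table["start_median"]).all()
    assert (table["start_median"] <= table["start_q3"]).all()


def test_change_report_ciaf_strata_blocks(default_cleaned):
    cleaning, _ = default_cleaned
    table = change_report(cleaning.cleaned, strata="ciaf_at_inclusion")
    assert table["stratum"].str.startswith("ciaf_").all()
    assert len(table) % 4 == 0  # one block of 4 indicators per category present


def test_change_report_empty_stratum_yields_n0_rows():
    rows = [("a", v, 3.0 + v, -1.0, 0, 0, 130) for v in range(1, 4)]
    table = change_report(_frame(rows), strata="compliance")
    assert (table["n"] == 0).all()
    assert table["p_value"].isna().all()


def test_change_report_identical_start_end_gives_p_one():
    rows = []
    for i in range(12):
        for v in range(1, 4):
            rows.append((f"c{i}", v, float(v), -1.0 - 0.1 * i, 0.2, -0.5, 130.0))
    table = change_report(_frame(rows))
    assert (table["p_value"] == 1.0).all()
    assert (table["start_median"] == table["end_median"]).all()


def test_delta_contrast_self_is_null():
    rng = np.random.default_rng(61)
    rows = []
    for i in range(40):
        for v in range(1, 4):
            rows.append((f"c{i}", v, float(v), rng.normal(), rng.normal(),
                         rng.normal(), 130.0))
    df = _frame(rows)
    summary, tidy = delta_contrast(df, df.copy())
    assert (summary["median_cohort_a"] == summary["median_cohort_b"]).all()
    assert (summary["p_value"] > 0.9).all()
    # tidy export row count = sum of usable pairs per cohort
    n_pairs = first_last_pairs(df, "HAZ").n
    assert len(tidy) == 2 * 3 * n_pairs


def test_two_slopes_contrast_detects_difference():
    """Cohorts faltering at -0.03 vs -0.10 z/month separate clearly."""
    pa = SimulationParams(n_children=150, seed=71, haz_slope_per_month=-0.03)
    pb = SimulationParams(n_children=150, seed=72, haz_slope_per_month=-0.10)
    ca, _ = clean_cohort(simulate_cohort(pa).visits, simulate_cohort(pa).reference)
    cb, _ = clean_cohort(simulate_cohort(pb).visits, simulate_cohort(pb).reference)
    summary, _ = delta_contrast(ca.cleaned, cb.cleaned, labels=("mild", "steep"))
    row = summary.set_index("indicator").loc["HAZ"]
    assert row["median_steep"] < row["median_mild"]
    assert row["p_value"] < 0.01
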