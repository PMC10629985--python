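"""Synthetic longitudinal cohort generator with a ground-truth manifest.

The generator emulates the statistical structure of a preventive
growth-monitoring cohort of under-two-year-olds in the Sahel: an
enrollment-age mixture concentrated in early infancy, monthly visits, a
length of stay truncated by programme exit at 24 months of age, progressive
height-for-age faltering of about -0.10 z/month, a mean-reverting
weight-for-height process, anthropometric measurement error including the
field habit of rounding heights up, and a small rate of biologically
implausible records injected per indicator.

Everything is deterministic under a fixed seed, and every generated child,
trajectory and injected corruption is recorded in a manifest so downstream
cleaning and analysis stages can be tested against exact ground truth.

Internal-coherence design: weight-for-age is never simulated independently.
The true length comes from the HAZ trajectory, the true weight from the WHZ
process applied at that length, and the weight-for-age median curve of the
synthetic reference is the exact composition of the other two median curves
— so the three indicators are mutually consistent the way real anthropometry
is, and a zero-noise cohort has exactly constant z-scores.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri
from scipy.optimize import brentq

from .errors import DataError
from .growth_reference import (
    LMSReference,
    _Group,
    _inv_arrays,
    _z_arrays,
    interpolate_lms,
    inverse_restricted_zscore,
    inverse_zscore,
    lms_zscore,
    lookup_lms_arrays,
    restricted_zscore,
)
from .cleaning import PLAUSIBILITY_BOUNDS
from .records import DAYS_PER_MONTH, SEXES, VISIT_COLUMNS

logger = logging.getLogger(__name__)

#: Enrollment-age bands in months: [0,6), [6,12), [12,18), [18,24).
AGE_BANDS = ((0.0, 6.0), (6.0, 12.0), (12.0, 18.0), (18.0, 24.0))


@dataclass
class SimulationParams:
    """Study-level parameters of the synthetic cohort.

    Defaults are the cohort descriptors of the programme being emulated:
    enrollment mixture 65.1 / 17.4 / 11.8 / 5.7 % across the four age bands,
    observed stay 14.5 +/- 6.6 months, monthly visits, HAZ faltering of
    -0.10 z/month, and per-indicator implausible-record rates of the order
    seen in field data (2.9 / 3.3 / 0.5 %).
    """

    n_children: int = 2000
    enrollment_mixture: tuple[float, float, float, float] = (0.651, 0.174, 0.118, 0.057)
    # within the first band ages follow Beta(1, b) scaled to [0, 6): most
    # enrollment happens in the first weeks of life; b = 2.2 reproduces an
    # overall entry median of ~2.8 months with IQR ~[1.2, 9.0]
    enrollment_band1_beta_b: float = 2.2
    stay_mean_months: float = 14.5
    stay_sd_months: float = 6.6
    min_stay_months: float = 2.0
    max_exit_age_months: float = 24.0
    # early-dropout component; together with exit-capped late enrollees this
    # puts ~15-18% of children below six months in the programme, the
    # short-stay fraction seen in the emulated cohort
    dropout_frac: float = 0.10
    dropout_stay_mean: float = 3.5
    dropout_stay_sd: float = 1.5
    dropout_stay_max: float = 6.0
    visit_interval_months: float = 1.0
    boy_fraction: float = 0.511

    haz_start_mean: float = -1.3
    haz_start_sd: float = 1.5
    haz_slope_per_month: float = -0.10
    haz_floor: float = -4.5

    whz_mean: float = -0.3
    whz_start_sd: float = 1.4
    whz_reversion: float = 0.3
    whz_noise_sd: float = 0.35
    whz_clip: float = 4.0
    waz_clip: float = 4.2

    muac_baseline_mean_mm: float = 135.0
    muac_baseline_sd_mm: float = 7.5
    muac_growth_mm_per_month: float = 0.35

    sigma_length_cm: float = 0.5
    sigma_weight_kg: float = 0.1
    sigma_muac_mm: float = 2.0
    height_round_up_prob: float = 0.3

    implausible_rates: dict[str, float] = field(
        default_factory=lambda: {"HAZ": 0.029, "WHZ": 0.033, "WAZ": 0.005}
    )

    inject_missing_sex: int = 0
    inject_missing_age: int = 0
    inject_too_few_visits: int = 0
    inject_sam_first_visit: int = 0

    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.enrollment_mixture) - 1.0) > 1e-9:
            raise DataError("enrollment mixture must sum to 1")
        if min(self.stay_sd_months, self.haz_start_sd, self.whz_start_sd,
               self.whz_noise_sd, self.muac_baseline_sd_mm, self.sigma_length_cm,
               self.sigma_weight_kg, self.sigma_muac_mm) < 0:
            raise DataError("standard deviations must be non-negative")
        for k, r in self.implausible_rates.items():
            if not 0.0 <= r <= 1.0:
                raise DataError(f"implausible rate for {k} outside [0, 1]")
        if not 0.0 <= self.height_round_up_prob <= 1.0:
            raise DataError("height_round_up_prob outside [0, 1]")
        if self.n_children < 1:
            raise DataError("n_children must be positive")


def zero_noise_params(n_children: int = 50, seed: int = 0) -> SimulationParams:
    """Degenerate configuration: no slope, no process or measurement noise,
    no corruption — every child's z-scores are constant across visits."""
    return SimulationParams(
        n_children=n_children, seed=seed,
        haz_slope_per_month=0.0, haz_start_sd=0.0,
        whz_start_sd=0.0, whz_noise_sd=0.0, whz_reversion=0.0,
        muac_baseline_sd_mm=0.0, muac_growth_mm_per_month=0.0,
        sigma_length_cm=0.0, sigma_weight_kg=0.0, sigma_muac_mm=0.0,
        height_round_up_prob=0.0,
        implausible_rates={"HAZ": 0.0, "WHZ": 0.0, "WAZ": 0.0},
    )


@dataclass
class SimulationManifest:
    """Ground truth for every generated child, visit and corruption."""

    children: pd.DataFrame    # child_id, sex, enroll_age_months, stay_months,
                              # n_visits, haz_start, injected_stage
    visits: pd.DataFrame      # child_id, visit_number, age_months,
                              # true_haz, true_whz, true_waz
    corruptions: pd.DataFrame  # child_id, visit_number, indicator
    screening: pd.DataFrame   # child_id, stage


@dataclass
class SimulationResult:
    visits: pd.DataFrame
    reference: LMSReference
    manifest: SimulationManifest
    params: SimulationParams


# ---------------------------------------------------------------------------
# synthetic growth reference


def synth_lms_reference(max_age_days: int = 733, seed: int = 0,
                        length_range: tuple[float, float] = (35.0, 120.0),
                        length_step: float = 0.01) -> LMSReference:
    """Build a smooth, internally consistent synthetic LMS reference.

    Median length follows a concave power curve of age; median weight given
    length is an exact power law of length; the weight-for-age median is the
    exact composition of the two, which keeps the three indicators mutually
    coherent.  L and S are constant within each (sex, indicator) block, in
    the ranges typical of real growth standards.  A small seeded jitter on
    the curve constants makes distinct seeds produce distinct but equally
    plausible standards; the same seed always reproduces the same table.
    """
    rng = np.random.default_rng(np.random.SeedSequence(entropy=(seed, 0x5EED)))
    days = np.arange(0, max_age_days + 1, dtype=float)
    n_len = int(round((length_range[1] - length_range[0]) / length_step)) + 1
    lengths = np.round(length_range[0] + length_step * np.arange(n_len), 6)
    ref = LMSReference(provenance=f"synthetic (seed={seed})")

    base = {
        "male": dict(len0=49.9, len_gain=37.2, wt50=3.45),
        "female": dict(len0=49.1, len_gain=36.3, wt50=3.35),
    }
    for sex in SEXES:
        j = 1.0 + rng.uniform(-0.01, 0.01, size=6)
        len0 = base[sex]["len0"] * j[0]
        len_gain = base[sex]["len_gain"] * j[1]
        len_exp = 0.63 * j[2]
        s_haz = 0.035 * j[3]
        wt50 = base[sex]["wt50"] * j[4]
        wt_exp = 2.28 * j[5]
        s_whz = 0.082 * (1.0 + rng.uniform(-0.01, 0.01))
        s_waz = 0.110 * (1.0 + rng.uniform(-0.01, 0.01))

        m_len = len0 + len_gain * (days / 731.0) ** len_exp
        m_whz = wt50 * (lengths / 50.0) ** wt_exp
        m_waz = wt50 * (m_len / 50.0) ** wt_exp  # exact composition

        ref.groups[(sex, "HAZ")] = _Group(
            key=days.copy(), L=np.ones_like(days), M=m_len,
            S=np.full_like(days, s_haz))
        ref.groups[(sex, "WHZ")] = _Group(
            key=lengths.copy(), L=np.full_like(lengths, -0.35), M=m_whz,
            S=np.full_like(lengths, s_whz))
        ref.groups[(sex, "WAZ")] = _Group(
            key=days.copy(), L=np.full_like(days, 0.10), M=m_waz,
            S=np.full_like(days, s_waz))
    return ref


# ---------------------------------------------------------------------------
# stay-duration sampler

def _truncnorm_sample(u: float, loc: float, sd: float, lo: float, hi: float) -> float:
    """Inverse-CDF sample of a normal truncated to [lo, hi]."""
    if sd == 0 or hi <= lo:
        return float(np.clip(loc, lo, hi))
    a = ndtr((lo - loc) / sd)
    b = ndtr((hi - loc) / sd)
    if b - a < 1e-14:
        return float(np.clip(loc, lo, hi))
    return float(loc + sd * ndtri(a + u * (b - a)))


def _truncated_floor_mean(loc: float, sd: float, los: np.ndarray,
                          caps: np.ndarray, iv: float, k_max: int) -> np.ndarray:
    """E[floor(stay/iv)*iv] for truncnorm(loc, sd, [lo, cap]) per age point."""
    edges = np.arange(k_max + 1) * iv
    if sd == 0:
        stays = np.clip(loc, los, caps)
        return np.floor(stays / iv) * iv
    a = ndtr((los - loc) / sd)[:, None]
    b = ndtr((caps - loc) / sd)[:, None]
    z = np.maximum(b - a, 1e-300)
    clipped = np.clip(edges[None, :], los[:, None], caps[:, None])
    cdf = (ndtr((clipped - loc) / sd) - a) / z
    pmf = np.diff(cdf, axis=1)
    e_floor = (pmf * edges[:-1][None, :]).sum(axis=1)
    degen = (b - a)[:, 0] < 1e-12
    if degen.any():
        e_floor[degen] = np.floor(np.clip(loc, los, caps)[degen] / iv) * iv
    return e_floor


def _expected_recovered_stay(loc: float, params: SimulationParams,
                             n_age_grid: int = 48) -> float:
    """Mixture-averaged E[recovered stay] for a given latent location of the
    main stay component.

    The recovered stay is what the data show: last-visit age minus
    first-visit age, i.e. the continuous stay floored to the visit grid.
    The early-dropout component has a fixed location; only the main
    component's location is solved for.
    """
    iv = params.visit_interval_months
    k_max = int(math.floor(params.max_exit_age_months / iv)) + 1
    total = 0.0
    for band, ((lo_b, hi_b), p_band) in enumerate(zip(AGE_BANDS,
                                                      params.enrollment_mixture)):
        q = (np.arange(n_age_grid) + 0.5) / n_age_grid
        if band == 0:
            frac = 1.0 - (1.0 - q) ** (1.0 / params.enrollment_band1_beta_b)
        else:
            frac = q
        ages = lo_b + frac * (hi_b - lo_b)
        caps = params.max_exit_age_months - ages
        los = np.minimum(params.min_stay_months, caps)
        e_main = _truncated_floor_mean(loc, params.stay_sd_months,
                                       los, caps, iv, k_max)
        e_drop = _truncated_floor_mean(
            params.dropout_stay_mean, params.dropout_stay_sd,
            np.minimum(los, np.minimum(params.dropout_stay_max, caps)),
            np.minimum(params.dropout_stay_max, caps), iv, k_max)
        mix = (params.dropout_frac * e_drop
               + (1.0 - params.dropout_frac) * e_main)
        total += p_band * mix.mean()
    return total


def _stay_location_shift(params: SimulationParams) -> float:
    """Latent location shift so the recovered mean stay matches the target.

    Programme exit at 24 months of age truncates stays, which would otherwise
    pull the realised mean well below the configured value; the configured
    stay_mean is treated as the *observed* target and the latent normal is
    shifted (once, deterministically) to compensate.
    """
    if params.stay_sd_months == 0:
        return 0.0
    target = params.stay_mean_months

    def g(delta: float) -> float:
        return _expected_recovered_stay(target + delta, params) - target

    lo, hi = -10.0, 30.0
    if g(hi) < 0:
        logger.warning("stay target %.2f unreachable under truncation; saturating", target)
        return hi
    if g(lo) > 0:
        return lo
    return float(brentq(g, lo, hi, xtol=1e-4))


# ---------------------------------------------------------------------------
# per-child simulation


def simulate_child(params: SimulationParams, ref: LMSReference, child_id: str,
                   rng: np.random.Generator, stay_shift: float | None = None
                   ) -> tuple[list[dict], dict, list[dict]]:
    """Simulate one child's visit history.

    Returns (visit rows, child manifest entry, per-visit manifest rows).
    """
    if stay_shift is None:
        stay_shift = _stay_location_shift(params)
    sex = "male" if rng.random() < params.boy_fraction else "female"
    band = int(rng.choice(4, p=np.asarray(params.enrollment_mixture)))
    lo_b, hi_b = AGE_BANDS[band]
    u = rng.random()
    if band == 0:
        frac = 1.0 - (1.0 - u) ** (1.0 / params.enrollment_band1_beta_b)
    else:
        frac = u
    age0_days = round((lo_b + frac * (hi_b - lo_b)) * DAYS_PER_MONTH)
    age0 = age0_days / DAYS_PER_MONTH

    cap = params.max_exit_age_months - age0
    lo_stay = min(params.min_stay_months, cap)
    if rng.random() < params.dropout_frac:
        hi = min(params.dropout_stay_max, cap)
        stay = _truncnorm_sample(rng.random(), params.dropout_stay_mean,
                                 params.dropout_stay_sd, min(lo_stay, hi), hi)
    else:
        stay = _truncnorm_sample(rng.random(), params.stay_mean_months + stay_shift,
                                 params.stay_sd_months, lo_stay, cap)
    iv = params.visit_interval_months
    n_visits = int(math.floor(stay / iv + 1e-9)) + 1

    elapsed = np.arange(n_visits) * iv
    age_days = age0_days + np.round(elapsed * DAYS_PER_MONTH)
    age_months = age_days / DAYS_PER_MONTH

    # true z trajectories
    haz0 = params.haz_start_mean + params.haz_start_sd * rng.standard_normal()
    haz_true = np.maximum(params.haz_floor,
                          haz0 + params.haz_slope_per_month * elapsed)
    whz_true = np.empty(n_visits)
    w = float(np.clip(params.whz_mean + params.whz_start_sd * rng.standard_normal(),
                      -params.whz_clip, params.whz_clip))
    noise = rng.standard_normal(n_visits) * params.whz_noise_sd
    for k in range(n_visits):
        whz_true[k] = w
        w = float(np.clip(w + params.whz_reversion * (params.whz_mean - w) + noise[k],
                          -params.whz_clip, params.whz_clip))

    # true measurements through the reference's inverse transforms
    L, M, S = lookup_lms_arrays(ref, sex, "HAZ", age_days)
    length_true = _inv_arrays(haz_true, L, M, S)
    Lw, Mw, Sw = lookup_lms_arrays(ref, sex, "WHZ", length_true)
    weight_true = _inv_arrays(whz_true, Lw, Mw, Sw)
    La, Ma, Sa = lookup_lms_arrays(ref, sex, "WAZ", age_days)
    waz_true = _z_arrays(weight_true, La, Ma, Sa)
    # stunting and wasting compose into weight-for-age; extreme tails are
    # floored the same way the HAZ trajectory is (weight cannot fall
    # arbitrarily low in a surviving child), keeping honest records clear of
    # the implausibility bounds
    off = np.abs(waz_true) > params.waz_clip
    if off.any():
        waz_true = np.clip(waz_true, -params.waz_clip, params.waz_clip)
        weight_true = np.where(
            off, _inv_arrays(waz_true, La, Ma, Sa), weight_true)
        whz_true = np.where(off, _z_arrays(weight_true, Lw, Mw, Sw), whz_true)

    # measurement process
    length_meas = length_true + rng.standard_normal(n_visits) * params.sigma_length_cm
    round_up = rng.random(n_visits) < params.height_round_up_prob
    length_meas[round_up] = np.ceil(length_meas[round_up] * 2.0) / 2.0
    weight_meas = np.maximum(
        0.2, weight_true + rng.standard_normal(n_visits) * params.sigma_weight_kg)
    muac0 = params.muac_baseline_mean_mm + params.muac_baseline_sd_mm * rng.standard_normal()
    muac = np.maximum(
        60.0, muac0 + params.muac_growth_mm_per_month * elapsed
        + rng.standard_normal(n_visits) * params.sigma_muac_mm)

    visit_rows = [
        dict(child_id=child_id, visit_number=k + 1, sex=sex,
             age_months=float(age_months[k]), weight_kg=float(weight_meas[k]),
             length_cm=float(length_meas[k]), muac_mm=float(muac[k]))
        for k in range(n_visits)
    ]
    child_entry = dict(child_id=child_id, sex=sex, enroll_age_months=float(age0),
                       stay_months=float(stay), n_visits=n_visits,
                       haz_start=float(haz0), injected_stage="")
    visit_manifest = [
        dict(child_id=child_id, visit_number=k + 1, age_months=float(age_months[k]),
             true_haz=float(haz_true[k]), true_whz=float(whz_true[k]),
             true_waz=float(waz_true[k]))
        for k in range(n_visits)
    ]
    return visit_rows, child_entry, visit_manifest


# ---------------------------------------------------------------------------
# corruption injection


def _plausibility_flags(ref: LMSReference, sex: str, age_days: float,
                        length: float, weight: float) -> set[str]:
    """Flags the cleaning stage would raise for these measurements."""
    flags = set()
    haz_row = interpolate_lms(ref, sex, "HAZ", age_days)
    waz_row = interpolate_lms(ref, sex, "WAZ", age_days)
    lo, hi = PLAUSIBILITY_BOUNDS["HAZ"]
    z = lms_zscore(length, haz_row)
    if z < lo or z > hi:
        flags.add("HAZ")
    lo, hi = PLAUSIBILITY_BOUNDS["WAZ"]
    z = restricted_zscore(weight, waz_row, "WAZ")
    if z < lo or z > hi:
        flags.add("WAZ")
    whz_group = ref.group(sex, "WHZ")
    if whz_group.key[0] <= length <= whz_group.key[-1]:
        whz_row = interpolate_lms(ref, sex, "WHZ", length)
        lo, hi = PLAUSIBILITY_BOUNDS["WHZ"]
        z = restricted_zscore(weight, whz_row, "WHZ")
        if z < lo or z > hi:
            flags.add("WHZ")
    return flags


def _solve_corruption(ref: LMSReference, sex: str, age_days: float,
                      indicator: str, sign: int, jitter: float
                      ) -> tuple[float, float] | None:
    """Measurements (length_cm, weight_kg) that breach exactly ``indicator``.

    Because HAZ, WHZ and WAZ share length and weight, a breach of one
    indicator is produced by solving *jointly* for a length and weight whose
    implied z-triple crosses only the intended bound; candidate companion
    targets are tried in order and the winning pair is verified against the
    actual plausibility flags.
    """
    haz_row = interpolate_lms(ref, sex, "HAZ", age_days)
    waz_row = interpolate_lms(ref, sex, "WAZ", age_days)

    def from_haz_waz(z_h: float, z_waz: float) -> tuple[float, float]:
        length = inverse_zscore(z_h, haz_row)
        weight = inverse_restricted_zscore(z_waz, waz_row, "WAZ")
        return length, weight

    candidates: list[tuple[float, float] | None] = []
    if indicator == "HAZ":
        z_h = sign * (6.3 + jitter)
        for z_waz in (sign * 3.5, sign * 2.0, 0.0, sign * 4.4, -sign * 2.0):
            candidates.append(from_haz_waz(z_h, z_waz))
    elif indicator == "WAZ":
        z_waz = sign * (5.3 + jitter)
        for z_h in (sign * 3.5, sign * 4.5, sign * 2.5, sign * 5.5, 0.0):
            candidates.append(from_haz_waz(z_h, z_waz))
    elif indicator == "WHZ":
        z_w = (5.3 + jitter) if sign > 0 else -(6.3 + jitter)
        for z_h in (-sign * 3.5, -sign * 2.0, -sign * 4.5, 0.0, -sign * 5.5):
            length = inverse_zscore(z_h, haz_row)
            grp = ref.group(sex, "WHZ")
            if not (grp.key[0] <= length <= grp.key[-1]):
                candidates.append(None)
                continue
            whz_row = interpolate_lms(ref, sex, "WHZ", length)
            weight = inverse_restricted_zscore(z_w, whz_row, "WHZ")
            candidates.append((length, weight))
    else:  # pragma: no cover
        raise ValueError(indicator)

    for cand in candidates:
        if cand is None:
            continue
        length, weight = cand
        if length <= 0 or weight <= 0:
            continue
        if _plausibility_flags(ref, sex, age_days, length, weight) == {indicator}:
            return length, weight
    return None


def inject_corruptions(visits: pd.DataFrame, ref: LMSReference,
                       params: SimulationParams, rng: np.random.Generator,
                       exclude_children: set[str] | None = None
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject per-indicator implausible records at the configured rates.

    Each selected (visit, indicator) cell gets measurements solved so that
    exactly that indicator breaches its plausibility bound (verified at
    injection time).  Returns the corrupted frame and the corruption
    manifest; with all rates zero the frame is returned unchanged and the
    manifest is empty.
    """
    exclude_children = exclude_children or set()
    out = visits.copy()
    rows: list[dict] = []
    eligible = ~out["child_id"].isin(exclude_children)
    n = len(out)
    # a single uniform per row, partitioned across indicators, gives each row
    # exactly the configured per-indicator corruption probability while
    # keeping at most one corruption per visit row
    draws = rng.random(n)
    signs = rng.random(n) < 0.5
    jitters = rng.random(n)
    age_days = np.round(out["age_months"].to_numpy(dtype=float) * DAYS_PER_MONTH)
    threshold = 0.0
    for indicator in ("HAZ", "WHZ", "WAZ"):
        rate = params.implausible_rates.get(indicator, 0.0)
        if rate == 0.0:
            continue
        hit = (draws >= threshold) & (draws < threshold + rate) & eligible.to_numpy()
        threshold += rate
        for i in np.flatnonzero(hit):
            row = out.iloc[i]
            sign = 1 if signs[i] else -1
            solved = _solve_corruption(ref, row["sex"], float(age_days[i]),
                                       indicator, sign, float(jitters[i]))
            if solved is None:
                solved = _solve_corruption(ref, row["sex"], float(age_days[i]),
                                           indicator, -sign, float(jitters[i]))
            if solved is None:  # pragma: no cover - defensive
                logger.warning("could not solve %s corruption for %s visit %s",
                               indicator, row["child_id"], row["visit_number"])
                continue
            length, weight = solved
            out.iloc[i, out.columns.get_loc("length_cm")] = length
            out.iloc[i, out.columns.get_loc("weight_kg")] = weight
            rows.append(dict(child_id=row["child_id"],
                             visit_number=int(row["visit_number"]),
                             indicator=indicator))
    manifest = pd.DataFrame(rows, columns=["child_id", "visit_number", "indicator"])
    return out, manifest


# ---------------------------------------------------------------------------
# screening-violation injection


def _inject_screening(visits: pd.DataFrame, children: pd.DataFrame,
                      ref: LMSReference, params: SimulationParams,
                      rng: np.random.Generator) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Inject children that the participant screens must catch."""
    n_want = (params.inject_missing_sex + params.inject_missing_age
              + params.inject_too_few_visits + params.inject_sam_first_visit)
    if n_want == 0:
        return visits, pd.DataFrame(columns=["child_id", "stage"])
    eligible = children.loc[children["n_visits"] >= 3, "child_id"].tolist()
    if n_want > len(eligible):
        raise DataError("not enough multi-visit children to host injected violations")
    chosen = list(rng.choice(eligible, size=n_want, replace=False))
    out = visits.copy()
    rows = []
    k = 0
    for _ in range(params.inject_missing_sex):
        cid = chosen[k]; k += 1
        out.loc[out["child_id"] == cid, "sex"] = None
        rows.append(dict(child_id=cid, stage="missing_sex_age"))
    for _ in range(params.inject_missing_age):
        cid = chosen[k]; k += 1
        out.loc[out["child_id"] == cid, "age_months"] = np.nan
        rows.append(dict(child_id=cid, stage="missing_sex_age"))
    for _ in range(params.inject_too_few_visits):
        cid = chosen[k]; k += 1
        out = out[~((out["child_id"] == cid) & (out["visit_number"] > 2))]
        rows.append(dict(child_id=cid, stage="too_few_visits"))
    for _ in range(params.inject_sam_first_visit):
        cid = chosen[k]; k += 1
        mask = (out["child_id"] == cid) & (out["visit_number"] == 1)
        idx = out.index[mask][0]
        sex = out.at[idx, "sex"]
        length = float(out.at[idx, "length_cm"])
        whz_row = interpolate_lms(ref, sex, "WHZ", length)
        out.at[idx, "weight_kg"] = inverse_restricted_zscore(-3.5, whz_row, "WHZ")
        rows.append(dict(child_id=cid, stage="sam_first_visit"))
    stage_map = {r["child_id"]: r["stage"] for r in rows}
    children["injected_stage"] = children["child_id"].map(stage_map).fillna("")
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole-cohort driver


def simulate_cohort(params: SimulationParams,
                    ref: LMSReference | None = None) -> SimulationResult:
    """Generate a full cohort: reference, visit records and manifest.

    Deterministic under ``params.seed`` at every granularity; the reference,
    the per-child trajectories, the screening injections and the corruption
    draws all derive from independent child streams of the same seed.
    """
    params.validate()
    if ref is None:
        ref = synth_lms_reference(seed=params.seed)
    ss = np.random.SeedSequence(params.seed)
    ss_children, ss_screen, ss_corrupt = ss.spawn(3)
    child_streams = ss_children.spawn(params.n_children)
    stay_shift = _stay_location_shift(params)

    width = len(str(params.n_children))
    visit_rows: list[dict] = []
    child_entries: list[dict] = []
    visit_manifest: list[dict] = []
    for i, stream in enumerate(child_streams):
        cid = f"C{i + 1:0{width}d}"
        rows, entry, vman = simulate_child(params, ref, cid,
                                           np.random.default_rng(stream),
                                           stay_shift=stay_shift)
        visit_rows.extend(rows)
        child_entries.append(entry)
        visit_manifest.extend(vman)

    visits = pd.DataFrame(visit_rows, columns=list(VISIT_COLUMNS))
    children = pd.DataFrame(child_entries)
    manifest_visits = pd.DataFrame(visit_manifest)

    visits, screening = _inject_screening(
        visits, children, ref, params, np.random.default_rng(ss_screen))
    injected_ids = set(screening["child_id"]) if len(screening) else set()
    visits, corruptions = inject_corruptions(
        visits, ref, params, np.random.default_rng(ss_corrupt),
        exclude_children=injected_ids)

    manifest = SimulationManifest(children=children, visits=manifest_visits,
                                  corruptions=corruptions, screening=screening)
    logger.info("simulated cohort: %d children, %d visit rows, %d corruptions",
                params.n_children, len(visits), len(corruptions))
    return SimulationResult(visits=visits, reference=ref, manifest=manifest,
                            params=params)
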