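"""LMS growth-standard engine.

Child growth standards express each anthropometric indicator as a table of
Box-Cox parameters indexed by age (height-for-age HAZ, weight-for-age WAZ;
key in days) or by recumbent length (weight-for-length WHZ; key in cm): L the
Box-Cox power, M the median and S the coefficient of variation.  A
measurement ``x`` maps onto the standard as

    z = ((x / M)**L - 1) / (L * S)        for L != 0
    z = ln(x / M) / S                     in the L -> 0 limit

For the *weight-based* indicators (WAZ, WHZ) the conventional "restricted"
adjustment recomputes any |z| > 3 on the spacing between the +/-2 and +/-3
SD curves, so that extreme but real weights are not exaggerated by the
Box-Cox tails.  Height-for-age is never adjusted.

Tables are discrete; continuous keys are served by per-parameter linear
interpolation between the bracketing rows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError, DomainError, OutOfRangeError
from .records import (
    DAYS_PER_MONTH,
    INDICATORS,
    SEXES,
    VisitRecord,
    ZScoreSet,
    age_months_to_days,
)

logger = logging.getLogger(__name__)

#: Canonical column names for LMS reference files.
LMS_COLUMNS = ("sex", "indicator", "key", "l", "m", "s")

#: Numerical threshold below which the Box-Cox power is treated as zero.
_L_ZERO = 1e-12


@dataclass(frozen=True)
class LMSRow:
    """One row of a growth reference: (sex, indicator, key) -> (L, M, S)."""

    sex: str
    indicator: str
    key: float
    L: float
    M: float
    S: float


@dataclass
class _Group:
    """Sorted parameter arrays for one (sex, indicator) block."""

    key: np.ndarray
    L: np.ndarray
    M: np.ndarray
    S: np.ndarray

    @property
    def key_range(self) -> tuple[float, float]:
        return float(self.key[0]), float(self.key[-1])


@dataclass
class LMSReference:
    """An indexed collection of LMS rows grouped by (sex, indicator)."""

    groups: dict[tuple[str, str], _Group] = field(default_factory=dict)
    provenance: str = "unspecified"

    def group(self, sex: str, indicator: str) -> _Group:
        try:
            return self.groups[(sex, indicator)]
        except KeyError:
            raise DataError(
                f"reference has no ({sex}, {indicator}) group; "
                f"available: {sorted(self.groups)}"
            ) from None

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, provenance: str = "unspecified") -> "LMSReference":
        missing = [c for c in LMS_COLUMNS if c not in frame.columns]
        if missing:
            raise ConfigurationError(f"LMS table missing column(s): {missing}")
        bad_sex = set(frame["sex"].unique()) - set(SEXES)
        if bad_sex:
            raise DataError(f"unknown sex value(s) {sorted(bad_sex)}; expected {SEXES}")
        bad_ind = set(frame["indicator"].unique()) - set(INDICATORS)
        if bad_ind:
            raise DataError(f"unknown indicator(s) {sorted(bad_ind)}; expected {INDICATORS}")
        ref = cls(provenance=provenance)
        for (sex, indicator), grp in frame.groupby(["sex", "indicator"], sort=True):
            grp = grp.sort_values("key")
            keys = grp["key"].to_numpy(dtype=float)
            dup = np.flatnonzero(np.diff(keys) == 0)
            if dup.size:
                raise DataError(
                    f"duplicate key {keys[dup[0]]:g} in ({sex}, {indicator})"
                )
            if (grp["m"] <= 0).any() or (grp["s"] <= 0).any():
                raise DataError(f"non-positive M or S in ({sex}, {indicator})")
            if (keys < 0).any():
                raise DataError(f"negative key in ({sex}, {indicator})")
            ref.groups[(sex, indicator)] = _Group(
                key=keys,
                L=grp["l"].to_numpy(dtype=float),
                M=grp["m"].to_numpy(dtype=float),
                S=grp["s"].to_numpy(dtype=float),
            )
            logger.info("LMS group (%s, %s): %d rows", sex, indicator, len(keys))
        return ref

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for (sex, indicator), g in sorted(self.groups.items()):
            parts.append(
                pd.DataFrame(
                    {"sex": sex, "indicator": indicator,
                     "key": g.key, "l": g.L, "m": g.M, "s": g.S}
                )
            )
        return pd.concat(parts, ignore_index=True)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def load_lms_table(path, dialect: dict[str, str] | None = None,
                   provenance: str | None = None) -> LMSReference:
    """Load an LMS reference from delimited text (comma or tab).

    ``dialect`` maps canonical column names (sex, indicator, key, l, m, s) to
    the file's column names, so foreign exports (e.g. real WHO tables) can be
    read without editing the file.
    """
    with open(path) as fh:
        sep = "\t" if "\t" in fh.readline() else ","
    frame = pd.read_csv(path, sep=sep, float_precision="round_trip")
    if dialect:
        unknown = set(dialect) - set(LMS_COLUMNS)
        if unknown:
            raise ConfigurationError(f"dialect maps unknown canonical column(s): {sorted(unknown)}")
        missing_src = [src for src in dialect.values() if src not in frame.columns]
        if missing_src:
            raise ConfigurationError(f"file lacks column(s) named in dialect: {missing_src}")
        frame = frame.rename(columns={src: dst for dst, src in dialect.items()})
    return LMSReference.from_frame(frame, provenance=provenance or str(path))


# ---------------------------------------------------------------------------
# interpolation


def interpolate_lms(ref: LMSReference, sex: str, indicator: str, key: float) -> LMSRow:
    """Interpolate L, M, S linearly at ``key``; exact rows returned bit-exactly."""
    g = ref.group(sex, indicator)
    lo, hi = g.key_range
    if not (lo <= key <= hi):
        raise OutOfRangeError(
            f"key {key:g} outside ({sex}, {indicator}) range [{lo:g}, {hi:g}]",
            valid_range=(lo, hi),
        )
    i = int(np.searchsorted(g.key, key))
    if i < len(g.key) and g.key[i] == key:
        return LMSRow(sex, indicator, float(key), float(g.L[i]), float(g.M[i]), float(g.S[i]))
    # bracketing rows g.key[i-1] < key < g.key[i]
    k0, k1 = g.key[i - 1], g.key[i]
    t = (key - k0) / (k1 - k0)
    return LMSRow(
        sex, indicator, float(key),
        float(g.L[i - 1] + t * (g.L[i] - g.L[i - 1])),
        float(g.M[i - 1] + t * (g.M[i] - g.M[i - 1])),
        float(g.S[i - 1] + t * (g.S[i] - g.S[i - 1])),
    )


def lookup_lms_arrays(ref: LMSReference, sex: str, indicator: str,
                      keys: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised linear interpolation; out-of-range or NaN keys give NaN."""
    g = ref.group(sex, indicator)
    keys = np.asarray(keys, dtype=float)
    ok = np.isfinite(keys) & (keys >= g.key[0]) & (keys <= g.key[-1])
    L = np.full(keys.shape, np.nan)
    M = np.full(keys.shape, np.nan)
    S = np.full(keys.shape, np.nan)
    if ok.any():
        L[ok] = np.interp(keys[ok], g.key, g.L)
        M[ok] = np.interp(keys[ok], g.key, g.M)
        S[ok] = np.interp(keys[ok], g.key, g.S)
        # exact-row lookups must reproduce the table bit-exactly
        idx = np.searchsorted(g.key, keys[ok])
        idx = np.clip(idx, 0, len(g.key) - 1)
        exact = g.key[idx] == keys[ok]
        if exact.any():
            where = np.flatnonzero(ok)[exact]
            L[where] = g.L[idx[exact]]
            M[where] = g.M[idx[exact]]
            S[where] = g.S[idx[exact]]
    n_oob = int((~ok & np.isfinite(keys)).sum())
    if n_oob:
        logger.warning("%d %s key(s) outside (%s) table range -> missing z",
                       n_oob, indicator, sex)
    return L, M, S


# ---------------------------------------------------------------------------
# the LMS transform and its inverse


def _z_arrays(values, L, M, S):
    """Vectorised Box-Cox z; NaN for missing/non-positive values."""
    values = np.asarray(values, dtype=float)
    L, M, S = (np.asarray(a, dtype=float) for a in (L, M, S))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(values > 0, values / M, np.nan)
        power_branch = (np.power(ratio, L) - 1.0) / (L * S)
        log_branch = np.log(ratio) / S
    return np.where(np.abs(L) > _L_ZERO, power_branch, log_branch)


def lms_zscore(value: float, row: LMSRow) -> float:
    """Box-Cox z-score of ``value`` against one LMS row."""
    if not (value > 0):
        raise DomainError(f"measurement must be positive, got {value!r}")
    if abs(row.L) > _L_ZERO:
        return ((value / row.M) ** row.L - 1.0) / (row.L * row.S)
    return math.log(value / row.M) / row.S


def inverse_zscore(z: float, row: LMSRow) -> float:
    """Exact inverse of :func:`lms_zscore`."""
    if abs(row.L) > _L_ZERO:
        base = 1.0 + row.L * row.S * z
        if base <= 0:
            raise DomainError(
                f"z={z:g} outside the transform's domain for L={row.L:g}, S={row.S:g}"
            )
        return row.M * base ** (1.0 / row.L)
    return row.M * math.exp(row.S * z)


def _sd_curves(row: LMSRow) -> tuple[float, float, float, float]:
    """Inverse-LMS values at z = -3, -2, +2, +3."""
    return (inverse_zscore(-3.0, row), inverse_zscore(-2.0, row),
            inverse_zscore(2.0, row), inverse_zscore(3.0, row))


def restricted_zscore(value: float, row: LMSRow, indicator: str | None = None) -> float:
    """z-score with the restricted adjustment for weight-based indicators.

    For WAZ/WHZ with |z| > 3 the score is recomputed on the SD-spacing scale:
    ``3 + (value - SD3pos) / (SD3pos - SD2pos)`` above, and symmetrically
    below.  HAZ and |z| <= 3 are returned unchanged; the two branches agree
    at |z| = 3.
    """
    indicator = indicator or row.indicator
    z = lms_zscore(value, row)
    if indicator == "HAZ" or abs(z) <= 3.0:
        return z
    sd3n, sd2n, sd2p, sd3p = _sd_curves(row)
    if z > 3.0:
        return 3.0 + (value - sd3p) / (sd3p - sd2p)
    return -3.0 + (value - sd3n) / (sd2n - sd3n)


def inverse_restricted_zscore(z: float, row: LMSRow, indicator: str | None = None) -> float:
    """Measurement that :func:`restricted_zscore` maps to ``z``."""
    indicator = indicator or row.indicator
    if indicator == "HAZ" or abs(z) <= 3.0:
        return inverse_zscore(z, row)
    sd3n, sd2n, sd2p, sd3p = _sd_curves(row)
    if z > 3.0:
        return sd3p + (z - 3.0) * (sd3p - sd2p)
    return sd3n + (z + 3.0) * (sd2n - sd3n)


def _restricted_arrays(values, L, M, S, adjust: bool):
    """Vectorised restricted z-score (adjust=False for HAZ)."""
    values = np.asarray(values, dtype=float)
    z = _z_arrays(values, L, M, S)
    if not adjust:
        return z
    out = z.copy()
    hi = z > 3.0
    lo = z < -3.0
    if hi.any():
        sd3 = _inv_arrays(3.0, L[hi], M[hi], S[hi])
        sd2 = _inv_arrays(2.0, L[hi], M[hi], S[hi])
        out[hi] = 3.0 + (values[hi] - sd3) / (sd3 - sd2)
    if lo.any():
        sd3 = _inv_arrays(-3.0, L[lo], M[lo], S[lo])
        sd2 = _inv_arrays(-2.0, L[lo], M[lo], S[lo])
        out[lo] = -3.0 + (values[lo] - sd3) / (sd2 - sd3)
    return out


def _inv_arrays(z, L, M, S):
    L, M, S = (np.asarray(a, dtype=float) for a in (L, M, S))
    with np.errstate(invalid="ignore"):
        base = 1.0 + L * S * z
        power_branch = M * np.power(np.where(base > 0, base, np.nan), 1.0 / L)
        log_branch = M * np.exp(S * np.asarray(z, dtype=float))
    return np.where(np.abs(L) > _L_ZERO, power_branch, log_branch)


# ---------------------------------------------------------------------------
# visit-level scoring


def compute_visit_zscores(visit: VisitRecord, ref: LMSReference) -> ZScoreSet:
    """Score one visit: HAZ from (length, age), WAZ from (weight, age), WHZ
    from (weight, length).  Missing inputs yield missing z, never an error;
    domain/range failures are converted to missing with a logged warning."""
    out = ZScoreSet(muac_mm=visit.muac_mm)
    if visit.sex not in SEXES or not math.isfinite(visit.age_months):
        logger.warning("visit %s/%s lacks sex or age; all z missing",
                       visit.child_id, visit.visit_number)
        return out
    age_key = age_months_to_days(visit.age_months)

    def _score(indicator: str, value: float, key: float) -> float:
        if not (isinstance(value, (int, float)) and math.isfinite(value)):
            return math.nan
        try:
            row = interpolate_lms(ref, visit.sex, indicator, key)
            return restricted_zscore(value, row, indicator)
        except (OutOfRangeError, DomainError) as exc:
            logger.warning("visit %s/%s %s -> missing: %s",
                           visit.child_id, visit.visit_number, indicator, exc)
            return math.nan

    out.haz = _score("HAZ", visit.length_cm, age_key)
    out.waz = _score("WAZ", visit.weight_kg, age_key)
    if math.isfinite(visit.length_cm):
        out.whz = _score("WHZ", visit.weight_kg, visit.length_cm)
    return out


def compute_cohort_zscores(visits: pd.DataFrame, ref: LMSReference) -> pd.DataFrame:
    """Vectorised scoring of a canonical visit DataFrame.

    Returns a copy with ``haz``, ``whz``, ``waz`` columns (restricted z) added.
    Rows with missing sex/age, missing measurements or out-of-range keys get
    NaN for the affected indicators.
    """
    out = visits.copy()
    n = len(out)
    haz = np.full(n, np.nan)
    whz = np.full(n, np.nan)
    waz = np.full(n, np.nan)
    age_days = np.round(out["age_months"].to_numpy(dtype=float) * DAYS_PER_MONTH)
    length = out["length_cm"].to_numpy(dtype=float)
    weight = out["weight_kg"].to_numpy(dtype=float)
    for sex in SEXES:
        m = (out["sex"] == sex).to_numpy()
        if not m.any():
            continue
        L, M, S = lookup_lms_arrays(ref, sex, "HAZ", age_days[m])
        haz[m] = _restricted_arrays(length[m], L, M, S, adjust=False)
        L, M, S = lookup_lms_arrays(ref, sex, "WAZ", age_days[m])
        waz[m] = _restricted_arrays(weight[m], L, M, S, adjust=True)
        L, M, S = lookup_lms_arrays(ref, sex, "WHZ", length[m])
        whz[m] = _restricted_arrays(weight[m], L, M, S, adjust=True)
    out["haz"] = haz
    out["whz"] = whz
    out["waz"] = waz
    return out
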