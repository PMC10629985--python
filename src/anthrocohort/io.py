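"""Canonical file schemas and run configuration.

Visit files are delimited text, one row per child-visit, with columns
``child_id, visit_number, sex, age_months, weight_kg, length_cm, muac_mm``;
sex is coded ``m``/``f`` on disk (full words in memory) and missing values
are empty fields.  A column-mapping block adapts foreign exports.  LMS
reference files use ``sex, indicator, key, l, m, s``.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .cleaning import PLAUSIBILITY_BOUNDS, SAMRule
from .errors import ConfigurationError, DataError
from .records import VISIT_COLUMNS
from .synthetic_cohort import SimulationParams

logger = logging.getLogger(__name__)

_SEX_READ = {"m": "male", "f": "female", "male": "male", "female": "female"}
_SEX_WRITE = {"male": "m", "female": "f"}


def sniff_delimited(path, **kwargs) -> pd.DataFrame:
    """Read comma- or tab-delimited text with bit-exact float parsing.

    ``float_precision='round_trip'`` matters: the default parser is off by
    one ulp on some literals, which breaks regenerate-bit-identically
    guarantees downstream.
    """
    with open(path) as fh:
        first = fh.readline()
    sep = "\t" if "\t" in first else ","
    return pd.read_csv(path, sep=sep, float_precision="round_trip", **kwargs)


def read_visits(path, column_map: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a visit file into the canonical DataFrame.

    z-score columns (haz/whz/waz) are preserved when present, so cleaned
    exports round-trip with their blanked values intact.
    """
    df = sniff_delimited(path, dtype={"child_id": str})
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise ConfigurationError(f"visit file lacks mapped column(s): {missing}")
        df = df.rename(columns={src: dst for dst, src in column_map.items()})
    missing = [c for c in VISIT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"visit file missing column(s): {missing}")
    zcols = [c for c in ("haz", "whz", "waz") if c in df.columns]
    df = df[list(VISIT_COLUMNS) + zcols].copy()
    df["child_id"] = df["child_id"].astype(str)
    sex = df["sex"].astype("string").str.strip().str.lower()
    bad = sex.dropna()[~sex.dropna().isin(_SEX_READ)]
    if len(bad):
        row = bad.index[0]
        raise DataError(f"unparseable sex {bad.iloc[0]!r} at row {row}")
    df["sex"] = sex.map(_SEX_READ).astype(object).where(sex.notna(), None)
    for col in ("age_months", "weight_kg", "length_cm", "muac_mm"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    try:
        df["visit_number"] = df["visit_number"].astype(int)
    except (ValueError, TypeError) as exc:
        raise DataError(f"non-integer visit_number: {exc}") from exc
    return df


def write_visits(df: pd.DataFrame, path) -> None:
    """Write a canonical (or cleaned, z-scored) visit DataFrame."""
    out = df.copy()
    out["sex"] = out["sex"].map(_SEX_WRITE)
    out.to_csv(path, index=False)


def read_clean_visits(path) -> pd.DataFrame:
    """Read a cleaned visit file (canonical columns plus haz/whz/waz)."""
    df = read_visits(path)
    missing = [c for c in ("haz", "whz", "waz") if c not in df.columns]
    if missing:
        raise ConfigurationError(f"cleaned visit file missing z column(s): {missing}")
    return df


@dataclass
class RunConfig:
    """Everything a pipeline run needs, loadable from YAML/JSON."""

    visits_path: str | None = None
    reference_path: str | None = None
    contrast_visits_path: str | None = None
    output_dir: str = "."
    column_map: dict[str, str] | None = None
    reference_dialect: dict[str, str] | None = None

    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(PLAUSIBILITY_BOUNDS))
    sam_whz_below: float = -3.0
    sam_muac_below_mm: float = 115.0
    min_visits: int = 3
    ciaf_threshold: float = -2.0
    strata: tuple[str, ...] = ("whole", "compliance", "stay_quartiles",
                               "ciaf_at_inclusion")
    enroll_max_months: float = 1.0
    exit_min_months: float = 23.0

    simulation: SimulationParams = field(default_factory=SimulationParams)
    seed: int = 0
    log_level: str = "INFO"

    @property
    def sam_rule(self) -> SAMRule:
        return SAMRule(whz_below=self.sam_whz_below,
                       muac_below_mm=self.sam_muac_below_mm)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
        sim_raw = raw.pop("simulation", None)
        cfg = cls(**{k: v for k, v in raw.items() if k != "simulation"})
        if sim_raw:
            sim_known = {f.name for f in dataclasses.fields(SimulationParams)}
            bad = set(sim_raw) - sim_known
            if bad:
                raise ConfigurationError(f"unknown simulation key(s): {sorted(bad)}")
            cfg.simulation = SimulationParams(**sim_raw)
        if "bounds" in raw:
            cfg.bounds = {k: tuple(v) for k, v in raw["bounds"].items()}
        if "strata" in raw:
            cfg.strata = tuple(raw["strata"])
        return cfg
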