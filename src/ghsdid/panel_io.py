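"""Read, validate, and assemble the country-vaccine-year coverage panel.

The analysis panel combines three tables:

* a long-format immunization coverage table (one row per country-vaccine-year,
  coverage in percent of the target cohort, WUENIC-style export);
* a country attribute table (World Bank income group, WHO region, optional
  World Bank governance indicators on the -2.5..2.5 scale);
* exclusion rules (year window, vaccines excluded for data imbalance,
  countries excluded for missing data).

Coverage cells that are present in the file but blank are retained as explicit
``is_missing`` observations rather than silently dropped, so downstream stages
decide how to treat them (the estimator drops them pairwise per 2x2 fit).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import (
    ConfigurationError,
    DuplicateKeyError,
    ValidationError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

#: canonical coverage columns, in storage order
COVERAGE_COLUMNS = ("iso3", "vaccine", "year", "coverage", "is_missing")

#: default column mapping for WUENIC-style exports
DEFAULT_DIALECT: Mapping[str, str] = {
    "country": "iso3",
    "vaccine": "vaccine",
    "year": "year",
    "coverage": "coverage",
}

INCOME_GROUPS = ("High", "Upper-Middle", "Lower-Middle", "Low")
WHO_REGIONS = (
    "Africa",
    "Americas",
    "Eastern Mediterranean",
    "Europe",
    "Southeast Asia",
    "Western Pacific",
)

GOVERNANCE_COLUMNS = ("gov_effectiveness", "rule_of_law", "control_of_corruption")
GOVERNANCE_RANGE = (-2.5, 2.5)

# normalized-spelling -> canonical label
_INCOME_ALIASES = {
    "high": "High",
    "high income": "High",
    "upper middle": "Upper-Middle",
    "upper middle income": "Upper-Middle",
    "lower middle": "Lower-Middle",
    "lower middle income": "Lower-Middle",
    "low": "Low",
    "low income": "Low",
}
_REGION_ALIASES = {
    "africa": "Africa",
    "americas": "Americas",
    "eastern mediterranean": "Eastern Mediterranean",
    "europe": "Europe",
    "southeast asia": "Southeast Asia",
    "south east asia": "Southeast Asia",
    "western pacific": "Western Pacific",
}


def _normalize_label(raw: str) -> str:
    return " ".join(str(raw).replace("-", " ").replace("_", " ").split()).lower()


@dataclass(frozen=True)
class PanelConfig:
    """Inclusion/exclusion rules applied when assembling the panel."""

    year_window: tuple[int, int] = (2015, 2022)
    excluded_vaccines: tuple[str, ...] = ("YFV", "IPV1")
    # Cook Islands, Niue, State of Palestine, DPR Korea
    excluded_countries: tuple[str, ...] = ("COK", "NIU", "PSE", "PRK")


@dataclass
class PanelSummary:
    """Bookkeeping of what assemble_panel kept and dropped, per rule."""

    n_rows_in: int = 0
    n_kept: int = 0
    n_countries: int = 0
    n_vaccines: int = 0
    n_missing: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    @property
    def missing_fraction(self) -> float:
        return self.n_missing / self.n_kept if self.n_kept else 0.0


@dataclass
class Panel:
    """An assembled analysis panel.

    ``observations`` holds one row per (iso3, vaccine, year) with columns
    ``iso3, vaccine, year, coverage, is_missing``; ``attributes`` one row per
    country with income group, WHO region and any governance columns.
    """

    observations: pd.DataFrame
    attributes: pd.DataFrame
    year_window: tuple[int, int]
    vaccine_set: tuple[str, ...]
    summary: PanelSummary = field(default_factory=PanelSummary)

    @property
    def countries(self) -> tuple[str, ...]:
        return tuple(sorted(self.observations["iso3"].unique()))

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(range(self.year_window[0], self.year_window[1] + 1))

    def to_csv(self, directory: str | Path) -> None:
        """Write observations.csv and attributes.csv under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        obs = self.observations.copy()
        obs.loc[obs["is_missing"], "coverage"] = np.nan
        obs.drop(columns=["is_missing"]).to_csv(directory / "observations.csv", index=False)
        self.attributes.to_csv(directory / "attributes.csv", index=False)

    @classmethod
    def from_csv(cls, directory: str | Path, config: PanelConfig | None = None) -> "Panel":
        directory = Path(directory)
        coverage = read_coverage(directory / "observations.csv")
        attributes = read_attributes(directory / "attributes.csv")
        return assemble_panel(coverage, attributes, config or PanelConfig())


def read_coverage(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> pd.DataFrame:
    """Read a long-format coverage CSV into canonical observation rows.

    Parameters
    ----------
    path:
        CSV file with one row per country-vaccine-year.
    dialect:
        Mapping from logical field names (``country``, ``vaccine``, ``year``,
        ``coverage``) to the file's column headers. Defaults to the WUENIC
        export headers ``iso3, vaccine, year, coverage``.

    Returns
    -------
    DataFrame with columns ``iso3, vaccine, year, coverage, is_missing``.
    Blank coverage cells become ``is_missing=True`` (coverage NaN).

    Raises
    ------
    ValidationError
        for an unparseable year or a coverage value outside [0, 100],
        naming the offending row.
    DuplicateKeyError
        when a (country, vaccine, year) key repeats.
    """
    mapping = dict(DEFAULT_DIALECT)
    if dialect:
        mapping.update(dialect)
    raw = pd.read_csv(path, dtype=str)
    missing_cols = [c for c in mapping.values() if c not in raw.columns]
    if missing_cols:
        raise ValidationError(f"{path}: missing required columns {missing_cols}")

    out = pd.DataFrame(
        {
            "iso3": raw[mapping["country"]].str.strip().str.upper(),
            "vaccine": raw[mapping["vaccine"]].str.strip().str.upper(),
        }
    )
    years = pd.to_numeric(raw[mapping["year"]], errors="coerce")
    bad_year = years.isna() | (years % 1 != 0)
    if bad_year.any():
        row = int(np.flatnonzero(bad_year)[0])
        raise ValidationError(
            f"{path}: unparseable year {raw[mapping['year']].iloc[row]!r} at data row {row}"
        )
    out["year"] = years.astype(int)

    cov_raw = raw[mapping["coverage"]]
    blank = cov_raw.isna() | (cov_raw.str.strip() == "")
    coverage = pd.to_numeric(cov_raw.where(~blank), errors="coerce")
    unparseable = coverage.isna() & ~blank
    if unparseable.any():
        row = int(np.flatnonzero(unparseable)[0])
        raise ValidationError(
            f"{path}: unparseable coverage {cov_raw.iloc[row]!r} at data row {row}"
        )
    out_of_range = (coverage < 0) | (coverage > 100)
    if out_of_range.any():
        row = int(np.flatnonzero(out_of_range.fillna(False))[0])
        raise ValidationError(
            f"{path}: coverage {coverage.iloc[row]} outside [0, 100] at data row {row}"
        )
    out["coverage"] = coverage.astype(float)
    out["is_missing"] = blank.to_numpy()

    dupes = out.duplicated(subset=["iso3", "vaccine", "year"])
    if dupes.any():
        row = int(np.flatnonzero(dupes)[0])
        key = out.loc[row, ["iso3", "vaccine", "year"]].tolist()
        raise DuplicateKeyError(f"{path}: duplicate (country, vaccine, year) key {key}")
    return out


def read_attributes(path: str | Path) -> pd.DataFrame:
    """Read the country attribute CSV and normalize its closed vocabularies.

    Expects columns ``iso3, income_group, who_region`` plus optional
    governance columns (``gov_effectiveness, rule_of_law,
    control_of_corruption``). Labels are matched case- and
    whitespace-insensitively against the canonical vocabularies.
    """
    raw = pd.read_csv(path)
    for col in ("iso3", "income_group", "who_region"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    out = pd.DataFrame({"iso3": raw["iso3"].astype(str).str.strip().str.upper()})

    def _map_closed(series: pd.Series, aliases: Mapping[str, str], what: str) -> pd.Series:
        normalized = series.astype(str).map(_normalize_label)
        unknown = ~normalized.isin(aliases)
        if unknown.any():
            bad = series[unknown].iloc[0]
            raise VocabularyError(f"{path}: unknown {what} label {bad!r}")
        return normalized.map(aliases)

    out["income_group"] = _map_closed(raw["income_group"], _INCOME_ALIASES, "income group")
    out["who_region"] = _map_closed(raw["who_region"], _REGION_ALIASES, "WHO region")

    for col in GOVERNANCE_COLUMNS:
        if col in raw.columns:
            vals = pd.to_numeric(raw[col], errors="coerce")
            lo, hi = GOVERNANCE_RANGE
            out_of_range = (vals < lo) | (vals > hi)
            if out_of_range.any():
                bad = vals[out_of_range].iloc[0]
                raise ValidationError(
                    f"{path}: governance value {bad} outside [{lo}, {hi}] in column {col!r}"
                )
            out[col] = vals.astype(float)

    if out["iso3"].duplicated().any():
        dup = out.loc[out["iso3"].duplicated(), "iso3"].iloc[0]
        raise DuplicateKeyError(f"{path}: duplicate country {dup!r}")
    return out


def assemble_panel(
    coverage: pd.DataFrame,
    attributes: pd.DataFrame,
    config: PanelConfig | None = None,
) -> Panel:
    """Apply inclusion/exclusion rules and join coverage with attributes.

    Observations outside the year window, excluded vaccine codes, and
    excluded countries are removed, with a per-rule tally recorded in the
    panel summary. Countries present in coverage but absent from the
    attribute table are logged and dropped (and vice versa they are simply
    ignored), mirroring the exclusion of data-poor countries.

    Raises
    ------
    ConfigurationError
        if nothing survives the exclusions.
    """
    config = config or PanelConfig()
    summary = PanelSummary(n_rows_in=len(coverage))
    obs = coverage.copy()

    lo, hi = config.year_window
    in_window = obs["year"].between(lo, hi)
    summary.dropped["year_window"] = int((~in_window).sum())
    obs = obs[in_window]

    excl_vax = obs["vaccine"].isin(set(config.excluded_vaccines))
    summary.dropped["excluded_vaccine"] = int(excl_vax.sum())
    obs = obs[~excl_vax]

    excl_cty = obs["iso3"].isin(set(config.excluded_countries))
    summary.dropped["excluded_country"] = int(excl_cty.sum())
    obs = obs[~excl_cty]

    known = set(attributes["iso3"])
    no_attrs = ~obs["iso3"].isin(known)
    if no_attrs.any():
        dropped_countries = sorted(obs.loc[no_attrs, "iso3"].unique())
        logger.warning(
            "dropping %d countries with no attribute record: %s",
            len(dropped_countries),
            ", ".join(dropped_countries),
        )
    summary.dropped["no_attributes"] = int(no_attrs.sum())
    obs = obs[~no_attrs].reset_index(drop=True)

    if obs.empty:
        raise ConfigurationError("panel is empty after applying exclusions")

    attrs = (
        attributes[attributes["iso3"].isin(set(obs["iso3"]))]
        .sort_values("iso3")
        .reset_index(drop=True)
    )
    summary.n_kept = len(obs)
    summary.n_countries = obs["iso3"].nunique()
    summary.n_vaccines = obs["vaccine"].nunique()
    summary.n_missing = int(obs["is_missing"].sum())
    assert summary.n_rows_in == summary.n_kept + sum(summary.dropped.values())

    obs = obs.sort_values(["iso3", "vaccine", "year"]).reset_index(drop=True)
    panel = Panel(
        observations=obs[list(COVERAGE_COLUMNS)],
        attributes=attrs,
        year_window=config.year_window,
        vaccine_set=tuple(sorted(obs["vaccine"].unique())),
        summary=summary,
    )
    logger.info(
        "assembled panel: %d countries, %d vaccines, %d observations (%d missing, %.2f%%)",
        summary.n_countries,
        summary.n_vaccines,
        summary.n_kept,
        summary.n_missing,
        100 * summary.missing_fraction,
    )
    return panel
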