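"""Readers, validators and panel assembly for GBD-results-tool style CSV exports.

The GBD results tool exports one row per (measure, location, cause, metric,
age group, year) estimate with a point value and a 95% uncertainty interval.
This module parses such exports (and companion SDI / population tables) into
canonical :class:`pandas.DataFrame` layouts, validates the domain invariants
(interval ordering, percent bounds, year span), and cross-references the three
tables into a :class:`Panel` that every downstream analysis consumes.

Column names are configurable through a *dialect* mapping from logical field
names to CSV headers; the default dialect matches the GBD results-tool export
(``measure_name``, ``location_name``, ``cause_name``, ``metric_name``,
``age_name``, ``year``, ``val``, ``upper``, ``lower``). Unknown extra columns
are ignored. Files are plain UTF-8 CSV with a header row; decimal values must
not use thousands separators.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GbdIoError",
    "ConfigurationError",
    "ValidationError",
    "PanelError",
    "BurdenRecord",
    "Panel",
    "DEFAULT_BURDEN_DIALECT",
    "DEFAULT_SDI_DIALECT",
    "DEFAULT_POPULATION_DIALECT",
    "DEFAULT_YEAR_SPAN",
    "read_burden_csv",
    "read_sdi_csv",
    "read_population_csv",
    "write_burden_csv",
    "write_sdi_csv",
    "write_population_csv",
    "assemble_panel",
    "slice_panel",
]


class GbdIoError(Exception):
    """Base class for all I/O and panel errors."""


class ConfigurationError(GbdIoError):
    """A dialect/column/parameter problem independent of the data rows."""


class ValidationError(GbdIoError):
    """One or more data rows violate a domain invariant."""


class PanelError(GbdIoError):
    """Cross-table inconsistency (duplicates, empty joins, missing slices)."""


MEASURES = ("deaths", "dalys")
METRICS = ("rate", "number", "percent")
AGE_TYPES = ("age_standardized", "all_age")

#: Inclusive calendar-year span of a standard panel.
DEFAULT_YEAR_SPAN = (1990, 2021)

DEFAULT_BURDEN_DIALECT: Mapping[str, str] = {
    "location": "location_name",
    "year": "year",
    "cause": "cause_name",
    "measure": "measure_name",
    "metric": "metric_name",
    "age": "age_name",
    "value": "val",
    "lower": "lower",
    "upper": "upper",
}
#: Optional column recognised when present in both tables of a join.
OPTIONAL_BURDEN_COLUMNS = {"location_id": "location_id"}

DEFAULT_SDI_DIALECT: Mapping[str, str] = {
    "location": "location_name",
    "year": "year",
    "sdi": "sdi",
}

DEFAULT_POPULATION_DIALECT: Mapping[str, str] = {
    "location": "location_name",
    "year": "year",
    "population": "val",
}

# Case-insensitive aliases mapping export vocabulary to canonical enum values.
_MEASURE_ALIASES = {
    "deaths": "deaths",
    "death": "deaths",
    "dalys": "dalys",
    "daly": "dalys",
    "dalys (disability-adjusted life years)": "dalys",
}
_METRIC_ALIASES = {"rate": "rate", "number": "number", "percent": "percent"}
_AGE_ALIASES = {
    "age-standardized": "age_standardized",
    "age standardized": "age_standardized",
    "age_standardized": "age_standardized",
    "all ages": "all_age",
    "all age": "all_age",
    "all_age": "all_age",
}

#: Display vocabulary used when writing CSVs back out (GBD export style).
MEASURE_DISPLAY = {"deaths": "Deaths", "dalys": "DALYs (Disability-Adjusted Life Years)"}
METRIC_DISPLAY = {"rate": "Rate", "number": "Number", "percent": "Percent"}
AGE_DISPLAY = {"age_standardized": "Age-standardized", "all_age": "All ages"}

#: Canonical column order of a burden frame.
BURDEN_COLUMNS = [
    "location", "location_id", "year", "cause",
    "measure", "metric", "age_type", "value", "lower", "upper",
]


@dataclass(frozen=True)
class BurdenRecord:
    """A single location-year-cause-measure-metric estimate with 95% UI.

    ``value`` is per-100,000 for ``metric='rate'``, persons / person-years for
    ``'number'`` and a 0-100 percentage for ``'percent'``.
    """

    location: str
    year: int
    cause: str
    measure: str
    metric: str
    age_type: str
    value: float
    lower: float
    upper: float
    location_id: int | None = None


@dataclass
class Panel:
    """Cross-referenced burden, SDI and population tables.

    ``missing`` lists (location, year) pairs that appear in the burden table
    but lack an SDI or population record. ``group_rates`` optionally carries
    pre-aggregated SDI-group rows (Global, High SDI, ... Low SDI) in the same
    canonical burden layout; these are *not* part of the country panel and are
    excluded from the completeness cross-reference.
    """

    burden: pd.DataFrame
    sdi: pd.DataFrame
    population: pd.DataFrame
    missing: list[tuple[str, int]] = field(default_factory=list)
    group_rates: pd.DataFrame | None = None

    @property
    def locations(self) -> list[str]:
        return sorted(self.burden["location"].unique())

    @property
    def years(self) -> list[int]:
        return sorted(int(y) for y in self.burden["year"].unique())

    @property
    def causes(self) -> list[str]:
        return sorted(c for c in self.burden["cause"].unique() if c != "All causes")


def _require_columns(header: Iterable[str], dialect: Mapping[str, str]) -> None:
    header = set(header)
    for logical, column in dialect.items():
        if column not in header:
            raise ConfigurationError(
                f"required column {column!r} (field {logical!r}) not found in header"
            )


def _numeric(series: pd.Series, column: str, rows: pd.Series) -> pd.Series:
    """Strict decimal parse: any non-numeric token (incl. '1,234') is an error."""
    probe = pd.to_numeric(series, errors="coerce")
    bad = probe.isna() & series.notna()
    if bad.any():
        where = rows[bad].tolist()[:5]
        raise ValidationError(
            f"column {column!r}: non-numeric value(s) at file row(s) {where}"
        )
    # astype goes through the platform strtod and round-trips exactly;
    # to_numeric's fast path can be off by one ulp.
    return series.astype(float)


def _map_enum(series: pd.Series, aliases: Mapping[str, str], what: str,
              rows: pd.Series) -> pd.Series:
    mapped = series.astype(str).str.strip().str.lower().map(aliases)
    bad = mapped.isna()
    if bad.any():
        values = sorted(series[bad].astype(str).unique())[:5]
        where = rows[bad].tolist()[:5]
        raise ValidationError(
            f"unmapped {what} value(s) {values} at file row(s) {where}"
        )
    return mapped


def read_burden_csv(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    year_span: tuple[int, int] = DEFAULT_YEAR_SPAN,
) -> pd.DataFrame:
    """Read and validate a burden CSV into the canonical frame layout.

    Returns a frame with columns ``location, location_id, year, cause,
    measure, metric, age_type, value, lower, upper``; measures/metrics/age
    groups are normalised to the canonical enums. Raises
    :class:`ConfigurationError` for missing columns and
    :class:`ValidationError` (citing 1-based file row numbers, header = row 1)
    for rows violating invariants.
    """
    dialect = dict(dialect or DEFAULT_BURDEN_DIALECT)
    raw = pd.read_csv(path, dtype=str, encoding="utf-8", skipinitialspace=True)
    _require_columns(raw.columns, dialect)
    rows = pd.Series(raw.index + 2, index=raw.index)  # 1-based incl. header

    out = pd.DataFrame(index=raw.index)
    out["location"] = raw[dialect["location"]].astype(str).str.strip()
    if OPTIONAL_BURDEN_COLUMNS["location_id"] in raw.columns:
        out["location_id"] = _numeric(raw["location_id"], "location_id", rows)
    else:
        out["location_id"] = np.nan
    out["year"] = _numeric(raw[dialect["year"]], dialect["year"], rows).astype(int)
    out["cause"] = raw[dialect["cause"]].astype(str).str.strip()
    out["measure"] = _map_enum(raw[dialect["measure"]], _MEASURE_ALIASES, "measure", rows)
    out["metric"] = _map_enum(raw[dialect["metric"]], _METRIC_ALIASES, "metric", rows)
    out["age_type"] = _map_enum(raw[dialect["age"]], _AGE_ALIASES, "age group", rows)
    for logical in ("value", "lower", "upper"):
        out[logical] = _numeric(raw[dialect[logical]], dialect[logical], rows)

    _validate_burden(out, rows, year_span)
    return out[BURDEN_COLUMNS]


def _validate_burden(df: pd.DataFrame, rows: pd.Series,
                     year_span: tuple[int, int]) -> None:
    def _fail(mask: pd.Series, message: str) -> None:
        if mask.any():
            raise ValidationError(f"{message} at file row(s) {rows[mask].tolist()[:5]}")

    y0, y1 = year_span
    _fail((df["year"] < y0) | (df["year"] > y1),
          f"year outside configured span [{y0}, {y1}]")
    _fail(df["value"] < 0, "negative value")
    _fail((df["lower"] > df["value"]) | (df["value"] > df["upper"]),
          "uncertainty interval must satisfy lower <= value <= upper")
    pct = df["metric"] == "percent"
    _fail(pct & ((df["value"] < 0) | (df["value"] > 100)),
          "percent value outside [0, 100]")


def read_sdi_csv(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    year_span: tuple[int, int] = DEFAULT_YEAR_SPAN,
) -> pd.DataFrame:
    """Read a location-year SDI table; SDI must lie in [0, 1]."""
    dialect = dict(dialect or DEFAULT_SDI_DIALECT)
    raw = pd.read_csv(path, dtype=str, encoding="utf-8", skipinitialspace=True)
    _require_columns(raw.columns, dialect)
    rows = pd.Series(raw.index + 2, index=raw.index)
    out = pd.DataFrame(index=raw.index)
    out["location"] = raw[dialect["location"]].astype(str).str.strip()
    out["year"] = _numeric(raw[dialect["year"]], dialect["year"], rows).astype(int)
    out["sdi"] = _numeric(raw[dialect["sdi"]], dialect["sdi"], rows)
    bad = (out["sdi"] < 0) | (out["sdi"] > 1)
    if bad.any():
        raise ValidationError(
            f"sdi outside [0, 1] at file row(s) {rows[bad].tolist()[:5]}"
        )
    y0, y1 = year_span
    bad = (out["year"] < y0) | (out["year"] > y1)
    if bad.any():
        raise ValidationError(
            f"year outside configured span [{y0}, {y1}] at file row(s) "
            f"{rows[bad].tolist()[:5]}"
        )
    return out


def read_population_csv(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    year_span: tuple[int, int] = DEFAULT_YEAR_SPAN,
) -> pd.DataFrame:
    """Read a location-year population table; population must be > 0."""
    dialect = dict(dialect or DEFAULT_POPULATION_DIALECT)
    raw = pd.read_csv(path, dtype=str, encoding="utf-8", skipinitialspace=True)
    _require_columns(raw.columns, dialect)
    rows = pd.Series(raw.index + 2, index=raw.index)
    out = pd.DataFrame(index=raw.index)
    out["location"] = raw[dialect["location"]].astype(str).str.strip()
    out["year"] = _numeric(raw[dialect["year"]], dialect["year"], rows).astype(int)
    out["population"] = _numeric(raw[dialect["population"]], dialect["population"], rows)
    bad = out["population"] <= 0
    if bad.any():
        raise ValidationError(
            f"non-positive population at file row(s) {rows[bad].tolist()[:5]}"
        )
    return out


def write_burden_csv(df: pd.DataFrame, path: str | Path,
                     dialect: Mapping[str, str] | None = None) -> Path:
    """Write a canonical burden frame back to the export dialect.

    Numeric fields are written with Python's shortest round-trip ``repr`` so a
    write/read cycle reproduces values to full precision.
    """
    dialect = dict(dialect or DEFAULT_BURDEN_DIALECT)
    if df.empty:
        raise ValidationError("refusing to write an empty burden table")
    out = pd.DataFrame()
    out[dialect["measure"]] = df["measure"].map(MEASURE_DISPLAY)
    out[dialect["location"]] = df["location"]
    out[dialect["cause"]] = df["cause"]
    out[dialect["metric"]] = df["metric"].map(METRIC_DISPLAY)
    out[dialect["age"]] = df["age_type"].map(AGE_DISPLAY)
    out[dialect["year"]] = df["year"].astype(int)
    out[dialect["value"]] = df["value"]
    out[dialect["upper"]] = df["upper"]
    out[dialect["lower"]] = df["lower"]
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def write_sdi_csv(df: pd.DataFrame, path: str | Path,
                  dialect: Mapping[str, str] | None = None) -> Path:
    dialect = dict(dialect or DEFAULT_SDI_DIALECT)
    if df.empty:
        raise ValidationError("refusing to write an empty SDI table")
    out = pd.DataFrame()
    out[dialect["location"]] = df["location"]
    out[dialect["year"]] = df["year"].astype(int)
    out[dialect["sdi"]] = df["sdi"]
    path = Path(path)
    out.to_csv(path, index=False)
    return path


def write_population_csv(df: pd.DataFrame, path: str | Path,
                         dialect: Mapping[str, str] | None = None) -> Path:
    dialect = dict(dialect or DEFAULT_POPULATION_DIALECT)
    if df.empty:
        raise ValidationError("refusing to write an empty population table")
    out = pd.DataFrame()
    out[dialect["location"]] = df["location"]
    out[dialect["year"]] = df["year"].astype(int)
    out[dialect["population"]] = df["population"]
    path = Path(path)
    out.to_csv(path, index=False)
    return path


_KEY = ["location", "year", "cause", "measure", "metric", "age_type"]


def assemble_panel(
    burden: pd.DataFrame,
    sdi: pd.DataFrame,
    population: pd.DataFrame,
    expected_locations: int | None = None,
    expected_years: tuple[int, int] | None = None,
) -> Panel:
    """Cross-reference the three tables into a :class:`Panel`.

    Raises :class:`PanelError` on duplicate burden keys or an empty location
    intersection; records incomplete (location, year) pairs in
    ``Panel.missing`` rather than failing, so callers can decide.
    """
    for name, df in (("burden", burden), ("sdi", sdi), ("population", population)):
        if df is None or df.empty:
            raise PanelError(f"{name} table is empty")

    dup = burden.duplicated(subset=_KEY, keep=False)
    if dup.any():
        first = burden.loc[dup, _KEY].iloc[0].tolist()
        raise PanelError(f"duplicate burden key {tuple(first)}")

    locs_b = set(burden["location"])
    if not (locs_b & set(sdi["location"]) & set(population["location"])):
        raise PanelError("no location appears in all three tables")

    pairs = burden[["location", "year"]].drop_duplicates()
    sdi_keys = set(zip(sdi["location"], sdi["year"]))
    pop_keys = set(zip(population["location"], population["year"]))
    missing = sorted(
        (loc, int(yr))
        for loc, yr in zip(pairs["location"], pairs["year"])
        if (loc, yr) not in sdi_keys or (loc, yr) not in pop_keys
    )

    panel = Panel(burden=burden.reset_index(drop=True),
                  sdi=sdi.reset_index(drop=True),
                  population=population.reset_index(drop=True),
                  missing=missing)
    if expected_locations is not None and len(panel.locations) != expected_locations:
        raise PanelError(
            f"expected {expected_locations} locations, found {len(panel.locations)}"
        )
    if expected_years is not None:
        y0, y1 = expected_years
        want = list(range(y0, y1 + 1))
        if panel.years != want:
            raise PanelError(f"expected years {y0}-{y1}, found {panel.years[:3]}...")
    return panel


def slice_panel(
    panel: Panel,
    year: int,
    cause: str,
    measure: str = "dalys",
    metric: str = "rate",
    age_type: str = "age_standardized",
) -> pd.DataFrame:
    """Cross-sectional slice: one row per location with value, SDI, population.

    Rows are ordered by ascending SDI, ties broken by location name — the
    total order every rank-based metric relies on. Locations missing SDI or
    population for that year are dropped (they are reported by
    :func:`assemble_panel`).
    """
    b = panel.burden
    mask = (
        (b["year"] == year) & (b["cause"] == cause) & (b["measure"] == measure)
        & (b["metric"] == metric) & (b["age_type"] == age_type)
    )
    sub = b.loc[mask, ["location", "value"]]
    if sub.empty:
        raise PanelError(
            f"empty slice for (year={year}, cause={cause!r}, measure={measure}, "
            f"metric={metric}, age_type={age_type})"
        )
    s = panel.sdi[panel.sdi["year"] == year][["location", "sdi"]]
    p = panel.population[panel.population["year"] == year][["location", "population"]]
    out = sub.merge(s, on="location").merge(p, on="location")
    out = out.sort_values(["sdi", "location"], kind="mergesort").reset_index(drop=True)
    return out[["location", "value", "sdi", "population"]]
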