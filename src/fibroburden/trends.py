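"""Cause-share proportions, percent changes, ratios and summary tables.

Conventions follow standard burden-of-disease reporting practice:

* cause *proportions* of total burden are computed from all-age **number**
  records (global person-year sums), never from rates:
  ``share = 100 * sum_loc number(cause) / sum_loc number(All causes)``;
* *percent changes* between two years are computed on age-standardized
  **rates**; ``relative_change`` and ``percent_decline`` are exact negatives
  of one another and both undefined for a zero start value;
* internal arithmetic keeps full precision; :func:`round_half_away` is the
  presentation-layer rounding (half away from zero, matching published
  tables) and is applied only at the edge.

Group-level rows (Global and the five SDI quintile bands) are consumed as
pre-aggregated location rows — age-standardized aggregation from countries to
quintiles needs age-specific data this pipeline does not model, so published
group rates (or the synthetic generator's group table) are taken as inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from importlib import resources

import pandas as pd

from .gbd_io import Panel, read_burden_csv

__all__ = [
    "TrendsError",
    "ChangeSummary",
    "relative_change",
    "percent_decline",
    "burden_ratio",
    "cause_proportion",
    "proportion_timeseries",
    "summary_table",
    "round_half_away",
    "load_gbd_summary_rates",
]


class TrendsError(ValueError):
    """Undefined or ill-posed trend statistic."""


@dataclass(frozen=True)
class ChangeSummary:
    """Start/end values of one quantity with both change statistics (%)."""

    label: str
    v_start: float
    v_end: float
    relative_change: float
    percent_decline: float


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round half away from zero (the convention of published GBD tables)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def relative_change(v_start: float, v_end: float) -> float:
    """Percent change from ``v_start`` to ``v_end``: 100 (v_end - v_start) / v_start."""
    if v_start < 0 or v_end < 0:
        raise TrendsError("change statistics need non-negative values")
    if v_start == 0:
        raise TrendsError("relative change undefined for a zero start value")
    return 100.0 * (v_end - v_start) / v_start


def percent_decline(v_start: float, v_end: float) -> float:
    """Percent decline from ``v_start`` to ``v_end`` (the negative of relative_change)."""
    return -relative_change(v_start, v_end)


def burden_ratio(v_a: float, v_b: float) -> float:
    """Ratio of two burden values (e.g. low-SDI over high-SDI rate)."""
    if v_a < 0:
        raise TrendsError("burden values must be non-negative")
    if v_b <= 0:
        raise TrendsError("ratio undefined for a non-positive denominator")
    return v_a / v_b


def cause_proportion(
    panel: Panel,
    causes,
    year: int,
    measure: str = "dalys",
) -> pd.DataFrame:
    """Share of total burden per cause for one year, from all-age numbers.

    Returns a frame with columns ``cause, share`` (percent of the all-cause
    total summed over locations), one row per requested cause. Scale-free:
    uniform rescaling of every number leaves shares unchanged.
    """
    b = panel.burden
    base = b[(b["year"] == year) & (b["measure"] == measure)
             & (b["metric"] == "number") & (b["age_type"] == "all_age")]
    total = base.loc[base["cause"] == "All causes", "value"].sum()
    if base[base["cause"] == "All causes"].empty:
        raise TrendsError(f"no 'All causes' number records for year {year}")
    if total <= 0:
        raise TrendsError(f"zero all-cause total for year {year}")
    rows = []
    for cause in causes:
        num = base.loc[base["cause"] == cause, "value"].sum()
        rows.append({"cause": cause, "share": 100.0 * num / total})
    return pd.DataFrame(rows)


def proportion_timeseries(
    panel: Panel,
    causes,
    measure: str = "dalys",
    years=None,
) -> pd.DataFrame:
    """Per-year cause shares (tidy frame: year, cause, share)."""
    years = years or panel.years
    frames = []
    for year in years:
        f = cause_proportion(panel, causes, year, measure)
        f.insert(0, "year", int(year))
        frames.append(f)
    return pd.concat(frames, ignore_index=True)


def summary_table(
    rates: pd.DataFrame,
    causes,
    groups,
    years: tuple[int, int] = (1990, 2021),
    measures=("deaths", "dalys"),
) -> pd.DataFrame:
    """Start/end age-standardized rates and change statistics per cell.

    ``rates`` is a canonical burden frame of age-standardized rate records
    whose locations are group rows (e.g. 'Global', 'High SDI', ...). Returns
    one row per (group, cause, measure) with start/end values, carried-through
    uncertainty intervals, and both change statistics at full precision.
    Raises :class:`TrendsError` naming the first missing cell.
    """
    y_start, y_end = years
    r = rates[(rates["metric"] == "rate") & (rates["age_type"] == "age_standardized")]
    rows = []
    for measure in measures:
        for cause in causes:
            for group in groups:
                cell = {}
                for tag, year in (("start", y_start), ("end", y_end)):
                    sub = r[(r["location"] == group) & (r["cause"] == cause)
                            & (r["measure"] == measure) & (r["year"] == year)]
                    if sub.empty:
                        raise TrendsError(
                            f"missing cell (group={group!r}, cause={cause!r}, "
                            f"measure={measure}, year={year})")
                    cell[f"v_{tag}"] = float(sub["value"].iloc[0])
                    cell[f"lower_{tag}"] = float(sub["lower"].iloc[0])
                    cell[f"upper_{tag}"] = float(sub["upper"].iloc[0])
                rc = relative_change(cell["v_start"], cell["v_end"])
                rows.append({
                    "group": group, "cause": cause, "measure": measure,
                    **cell, "relative_change": rc, "percent_decline": -rc,
                })
    return pd.DataFrame(rows)


def load_gbd_summary_rates() -> pd.DataFrame:
    """Published GBD 2021 global / SDI-quintile summary rates (1990 & 2021).

    Age-standardized death and DALY rates per 100,000 (95% UI) for neoplasms
    and chronic obstructive pulmonary disease, transcribed from the published
    GBD 2021 summary table; shipped as package data so the worked examples run
    without any download.
    """
    ref = resources.files("fibroburden.data").joinpath("gbd2021_summary_rates.csv")
    with resources.as_file(ref) as path:
        return read_burden_csv(path)
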