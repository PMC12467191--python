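"""Seeded synthetic GBD-style country panels with known generating truth.

The generator emulates the statistical structure the downstream analyses
assume, without attempting to match real country magnitudes or SDI paths:

* 204 locations observed 1990-2021 with monotone, clipped-linear SDI
  trajectories (jittered start and per-year growth) and log-normal,
  time-constant populations;
* for each cause and measure, a linear *frontier* ``g(s) = max(0, a + b s)``
  giving the minimum achievable age-standardized rate at SDI ``s``;
* one-sided exponential country inefficiency offsets ``delta_c`` above the
  frontier, plus Gaussian observation noise truncated so no observed rate
  beats the frontier — the frontier really is the lower envelope;
* alternatively (``gradient_mode='linear_gradient'``) rates exactly linear in
  the population-weighted midpoint SDI rank, the configuration under which the
  slope index downstream must recover the generating slope;
* derived all-age *number* records (rate x population / 100,000) and an
  "All causes" total per location-year-measure equal to the cause sum times a
  configurable inflation factor (> 1), so cause shares of total burden are a
  known arithmetic of the spec parameters;
* pre-aggregated SDI-quintile group rows (Global, High SDI ... Low SDI) as a
  separate table for summary-table style analyses.

Everything is driven by a single integer seed; the generating truth (deltas,
frontier values, gradient slopes) is returned alongside the panel for
parameter-recovery tests.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gbd_io import (
    ConfigurationError,
    Panel,
    assemble_panel,
    write_burden_csv,
    write_population_csv,
    write_sdi_csv,
)
from .inequality import midpoint_ranks

__all__ = [
    "DEFAULT_CAUSES",
    "SDI_GROUPS",
    "CauseParams",
    "PanelSpec",
    "PanelTruth",
    "default_cause_params",
    "generate_panel",
    "write_panel_csvs",
    "write_group_rates_csv",
    "write_truth_json",
]

#: The six fibrosis-related causes tracked by default.
DEFAULT_CAUSES = (
    "Neoplasms",
    "Chronic obstructive pulmonary disease",
    "Chronic kidney disease",
    "Cirrhosis and other chronic liver diseases",
    "Hypertensive heart disease",
    "Tuberculosis",
)

#: SDI quintile group labels, highest development first, plus the global row.
SDI_GROUPS = ("Global", "High SDI", "High-middle SDI", "Middle SDI",
              "Low-middle SDI", "Low SDI")


@dataclass(frozen=True)
class CauseParams:
    """Generating parameters for one cause within one measure.

    ``frontier_intercept``/``frontier_slope`` define the frontier
    ``g(s) = max(0, a + b s)`` in rate units (slope per unit SDI, typically
    negative: development lowers the achievable minimum).
    ``inefficiency_scale`` is the mean of the exponential country offset
    above the frontier (0 disables inefficiency). ``gradient_intercept`` and
    ``gradient_slope`` parameterize the linear-in-rank alternative (slope per
    full rank span 0 -> 1).
    """

    frontier_intercept: float
    frontier_slope: float
    inefficiency_scale: float
    gradient_intercept: float
    gradient_slope: float


def default_cause_params() -> dict[str, dict[str, CauseParams]]:
    """Per-measure, per-cause defaults with DALY-like magnitudes (per 100,000).

    DALY frontiers span roughly 400-2500 per 100,000 across the SDI range with
    inefficiency means of a few hundred; death-rate parameters are the DALY
    parameters scaled by 1/25 (orders of magnitude apart, as in real data,
    but generated independently — nothing downstream links the two measures).
    """
    dalys = {
        "Neoplasms": CauseParams(2500.0, -1200.0, 800.0, 4000.0, -1500.0),
        "Chronic obstructive pulmonary disease": CauseParams(1800.0, -1400.0, 500.0, 1600.0, -900.0),
        "Chronic kidney disease": CauseParams(800.0, -400.0, 250.0, 900.0, -350.0),
        "Cirrhosis and other chronic liver diseases": CauseParams(900.0, -600.0, 300.0, 1000.0, -450.0),
        "Hypertensive heart disease": CauseParams(500.0, -350.0, 150.0, 550.0, -250.0),
        "Tuberculosis": CauseParams(1200.0, -1100.0, 400.0, 1300.0, -800.0),
    }
    deaths = {
        cause: CauseParams(
            p.frontier_intercept / 25.0, p.frontier_slope / 25.0,
            p.inefficiency_scale / 25.0, p.gradient_intercept / 25.0,
            p.gradient_slope / 25.0,
        )
        for cause, p in dalys.items()
    }
    return {"dalys": dalys, "deaths": deaths}


@dataclass
class PanelSpec:
    """Full parameterization of the synthetic panel generator.

    Defaults mirror the structure of the real study panel: 204 locations,
    calendar years 1990-2021, the six fibrosis-related causes, an all-cause
    inflation factor of 6 (cause shares of total burden around 15-20%),
    SDI starting points spread over [0.05, 0.80] with 0.002-0.012/year
    growth, log-normal populations (median ~ 9 million persons) and
    observation noise of 15 rate units. Uncertainty intervals are generated
    as +/-10% bands around the point value.
    """

    n_locations: int = 204
    years: tuple[int, int] = (1990, 2021)
    causes: Sequence[str] = DEFAULT_CAUSES
    cause_params: Mapping[str, Mapping[str, CauseParams]] | None = None
    gradient_mode: str = "frontier_only"  # or "linear_gradient"
    gradient_decay: float = 0.0  # per-year linear shrink of the gradient slope
    noise_sd: float = 15.0
    sdi_start_range: tuple[float, float] = (0.05, 0.80)
    sdi_growth_range: tuple[float, float] = (0.002, 0.012)
    population_lognormal: tuple[float, float] = (16.0, 1.2)
    all_cause_inflation: float = 6.0
    ui_halfwidth: float = 0.10
    measures: Sequence[str] = ("dalys", "deaths")
    seed: int = 0

    def resolved_params(self) -> dict[str, dict[str, CauseParams]]:
        params = self.cause_params or default_cause_params()
        out: dict[str, dict[str, CauseParams]] = {}
        for measure in self.measures:
            if measure not in params:
                raise ConfigurationError(f"no cause parameters for measure {measure!r}")
            out[measure] = {}
            for cause in self.causes:
                if cause not in params[measure]:
                    raise ConfigurationError(
                        f"no parameters for cause {cause!r} under measure {measure!r}")
                out[measure][cause] = params[measure][cause]
        return out

    def validate(self) -> None:
        if self.n_locations < 3:
            raise ConfigurationError("n_locations must be >= 3")
        if self.years[0] > self.years[1]:
            raise ConfigurationError("years span must be (first, last) with first <= last")
        if not self.causes:
            raise ConfigurationError("at least one cause required")
        if self.gradient_mode not in ("frontier_only", "linear_gradient"):
            raise ConfigurationError(f"unknown gradient_mode {self.gradient_mode!r}")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.gradient_decay < 0:
            raise ConfigurationError("gradient_decay must be >= 0")
        if self.all_cause_inflation <= 1:
            raise ConfigurationError("all_cause_inflation must be > 1")
        lo, hi = self.sdi_start_range
        if not (0 <= lo <= hi <= 1):
            raise ConfigurationError("sdi_start_range must be within [0, 1]")
        if not (0 < self.ui_halfwidth < 1):
            raise ConfigurationError("ui_halfwidth must be in (0, 1)")
        params = self.resolved_params()
        for measure in self.measures:
            for cause in self.causes:
                if params[measure][cause].inefficiency_scale < 0:
                    raise ConfigurationError("inefficiency_scale must be >= 0")


@dataclass
class PanelTruth:
    """Generator bookkeeping for parameter-recovery tests.

    ``deltas``: per (location, cause, measure) inefficiency offset;
    ``frontier``: per (location, year, cause, measure) frontier value g(SDI);
    ``gradient``: per (cause, measure) generating intercept and slope
    (slope per full rank span; meaningful in linear_gradient mode).
    """

    deltas: pd.DataFrame
    frontier: pd.DataFrame
    gradient: pd.DataFrame
    spec: PanelSpec = field(repr=False, default=None)


def _location_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"Country {i + 1:0{width}d}" for i in range(n)]


def generate_panel(spec: PanelSpec) -> tuple[Panel, PanelTruth]:
    """Generate a complete synthetic panel and its generating truth.

    The same spec (including seed) always produces byte-identical tables.
    """
    spec.validate()
    params = spec.resolved_params()
    n = spec.n_locations
    y0, y1 = spec.years
    years = np.arange(y0, y1 + 1)
    T = len(years)
    locations = _location_names(n)

    # Named, deterministically derived RNG streams so each structural
    # component is reproducible independent of generation order.
    root = np.random.SeedSequence(spec.seed)
    rng_sdi, rng_pop, rng_delta, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(4)
    )

    start = rng_sdi.uniform(*spec.sdi_start_range, size=n)
    growth = rng_sdi.uniform(*spec.sdi_growth_range, size=n)
    sdi = np.clip(start[:, None] + growth[:, None] * (years - y0)[None, :], 0.0, 1.0)

    mean_log, sd_log = spec.population_lognormal
    population = rng_pop.lognormal(mean_log, sd_log, size=n)

    # Midpoint ranks per year (used by the linear_gradient mode); computed
    # with the same routine the analysis uses so recovery is exact.
    ranks = np.empty((n, T))
    for t in range(T):
        df = pd.DataFrame({"location": locations, "sdi": sdi[:, t],
                           "population": population})
        r = midpoint_ranks(df)
        ranks[:, t] = r.set_index("location").loc[locations, "midpoint_rank"].to_numpy()

    rate_frames = []
    truth_delta_rows = []
    truth_frontier_frames = []
    truth_gradient_rows = []

    for measure in spec.measures:
        for cause in spec.causes:
            p = params[measure][cause]
            frontier = np.maximum(0.0, p.frontier_intercept + p.frontier_slope * sdi)
            delta = (rng_delta.exponential(p.inefficiency_scale, size=n)
                     if p.inefficiency_scale > 0 else np.zeros(n))
            eps = (rng_noise.normal(0.0, spec.noise_sd, size=(n, T))
                   if spec.noise_sd > 0 else np.zeros((n, T)))

            if spec.gradient_mode == "frontier_only":
                asr = frontier + delta[:, None] + eps
                asr = np.maximum(asr, frontier)  # noise never beats the frontier
            else:
                slope_t = p.gradient_slope * np.maximum(
                    0.0, 1.0 - spec.gradient_decay * (years - y0))
                asr = p.gradient_intercept + slope_t[None, :] * ranks + eps
                asr = np.maximum(asr, 0.0)

            rate_frames.append(pd.DataFrame({
                "location": np.repeat(locations, T),
                "year": np.tile(years, n),
                "cause": cause,
                "measure": measure,
                "value": asr.ravel(),
            }))
            truth_delta_rows.append(pd.DataFrame({
                "location": locations, "cause": cause, "measure": measure,
                "delta": delta,
            }))
            truth_frontier_frames.append(pd.DataFrame({
                "location": np.repeat(locations, T),
                "year": np.tile(years, n),
                "cause": cause, "measure": measure,
                "frontier": frontier.ravel(),
            }))
            truth_gradient_rows.append({
                "cause": cause, "measure": measure,
                "gradient_intercept": p.gradient_intercept,
                "gradient_slope": p.gradient_slope,
            })

    rates = pd.concat(rate_frames, ignore_index=True)
    rates["metric"] = "rate"
    rates["age_type"] = "age_standardized"

    pop_lookup = pd.Series(population, index=locations)
    numbers = rates.copy()
    numbers["value"] = (
        numbers["value"] * numbers["location"].map(pop_lookup) / 1e5
    )
    numbers["metric"] = "number"
    numbers["age_type"] = "all_age"

    all_cause = (
        numbers.groupby(["location", "year", "measure"], as_index=False)["value"].sum()
    )
    all_cause["value"] *= spec.all_cause_inflation
    all_cause["cause"] = "All causes"
    all_cause["metric"] = "number"
    all_cause["age_type"] = "all_age"

    burden = pd.concat([rates, numbers, all_cause], ignore_index=True)
    burden["lower"] = burden["value"] * (1 - spec.ui_halfwidth)
    burden["upper"] = burden["value"] * (1 + spec.ui_halfwidth)
    burden["location_id"] = np.nan
    burden = burden[["location", "location_id", "year", "cause", "measure",
                     "metric", "age_type", "value", "lower", "upper"]]

    sdi_df = pd.DataFrame({
        "location": np.repeat(locations, T),
        "year": np.tile(years, n),
        "sdi": sdi.ravel(),
    })
    pop_df = pd.DataFrame({
        "location": np.repeat(locations, T),
        "year": np.tile(years, n),
        "population": np.repeat(population, T),
    })

    panel = assemble_panel(burden, sdi_df, pop_df)
    panel.group_rates = _group_rates(rates, sdi, population, locations, years)

    truth = PanelTruth(
        deltas=pd.concat(truth_delta_rows, ignore_index=True),
        frontier=pd.concat(truth_frontier_frames, ignore_index=True),
        gradient=pd.DataFrame(truth_gradient_rows),
        spec=spec,
    )
    return panel, truth


def _group_rates(rates: pd.DataFrame, sdi: np.ndarray, population: np.ndarray,
                 locations: list[str], years: np.ndarray) -> pd.DataFrame:
    """Population-weighted mean ASR per SDI quintile (+ Global) and year.

    Quintiles are fixed by final-year SDI rank (ties by name via stable sort
    on the name-ordered arrays); Low SDI = lowest fifth. These rows stand in
    for the pre-aggregated group rows a real export provides.
    """
    order = np.argsort(sdi[:, -1], kind="stable")
    buckets = np.array_split(order, 5)  # ascending SDI -> Low ... High
    labels = ["Low SDI", "Low-middle SDI", "Middle SDI", "High-middle SDI", "High SDI"]
    membership = {"Global": np.arange(len(locations))}
    membership.update({lab: idx for lab, idx in zip(labels, buckets)})

    loc_index = pd.Index(locations)
    rows = []
    for (cause, measure, year), sub in rates.groupby(["cause", "measure", "year"]):
        vals = pd.Series(sub["value"].to_numpy(),
                         index=sub["location"]).reindex(loc_index).to_numpy()
        for group, idx in membership.items():
            w = population[idx]
            rows.append({
                "location": group, "location_id": np.nan, "year": int(year),
                "cause": cause, "measure": measure, "metric": "rate",
                "age_type": "age_standardized",
                "value": float(np.average(vals[idx], weights=w)),
            })
    out = pd.DataFrame(rows)
    out["lower"] = out["value"] * 0.9
    out["upper"] = out["value"] * 1.1
    return out[["location", "location_id", "year", "cause", "measure",
                "metric", "age_type", "value", "lower", "upper"]]


def write_panel_csvs(panel: Panel, directory: str | Path) -> dict[str, Path]:
    """Write burden, SDI and population tables (exactly three CSV files).

    Files use the default export dialect and round-trip through the
    ``gbd_io`` readers to full numeric precision.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return {
        "burden": write_burden_csv(panel.burden, directory / "burden.csv"),
        "sdi": write_sdi_csv(panel.sdi, directory / "sdi.csv"),
        "population": write_population_csv(panel.population, directory / "population.csv"),
    }


def write_group_rates_csv(panel: Panel, directory: str | Path) -> Path | None:
    """Write the optional pre-aggregated SDI-group rate table, if present."""
    if panel.group_rates is None or panel.group_rates.empty:
        return None
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    return write_burden_csv(panel.group_rates, directory / "group_rates.csv")


def write_truth_json(truth: PanelTruth, path: str | Path) -> Path:
    """Serialize the generating truth (and spec echo) to JSON."""
    path = Path(path)
    spec_dict = asdict(truth.spec) if truth.spec is not None else None
    if spec_dict and spec_dict.get("cause_params"):
        spec_dict["cause_params"] = {
            m: {c: asdict(p) if isinstance(p, CauseParams) else p
                for c, p in per.items()}
            for m, per in spec_dict["cause_params"].items()
        }
    payload = {
        "spec": spec_dict,
        "deltas": truth.deltas.to_dict(orient="records"),
        "gradient": truth.gradient.to_dict(orient="records"),
        "frontier": truth.frontier.to_dict(orient="records"),
    }
    path.write_text(json.dumps(payload), encoding="utf-8")
    return path
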