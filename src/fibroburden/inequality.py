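"""Absolute and relative inequality metrics across the development gradient.

Two standard health-inequality measures over a cross-section of countries
ranked by socio-demographic index (SDI):

* **Slope index of inequality (SII)** — the slope of a regression of the
  age-standardized rate on the population-weighted midpoint cumulative rank.
  The rank of country *i* (countries sorted by ascending SDI) is the centre of
  its interval on the cumulative population-share axis, so the fitted slope is
  expressed in rate units across the full rank span 0 -> 1. The default fit is
  population-share-weighted least squares; a weighted Huber M-estimator
  (tuning constant 1.345) is available for outlier-robust fits.

* **Concentration index of inequality (CII)** — twice the area between the
  concentration (Lorenz-type) curve and the diagonal. The curve plots
  cumulative burden share against cumulative population share in SDI order;
  country burden is rate x population so "cumulative proportion of DALYs"
  means person-year totals. CII lies in [-1, 1]; it is negative when burden
  concentrates in low-SDI countries and zero when all rates are equal.
  Integration is by the trapezoid rule on the empirical points anchored at
  (0, 0) — countries are the atoms, no grouping or smoothing.

Uncertainty intervals for both come from a seeded nonparametric bootstrap
that resamples countries with replacement and recomputes ranks within each
replicate (percentile method).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gbd_io import Panel, slice_panel

__all__ = [
    "InequalityError",
    "CountryRanks",
    "SIIResult",
    "CIIResult",
    "midpoint_ranks",
    "slope_index",
    "concentration_index",
    "inequality_timeseries",
]

HUBER_C = 1.345


class InequalityError(ValueError):
    """Invalid input to an inequality metric."""


@dataclass(frozen=True)
class SIIResult:
    """Slope index of inequality with bootstrap percentile CI."""

    sii: float
    ci_lower: float
    ci_upper: float
    method: str
    n_countries: int
    n_bootstrap: int
    seed: int | None


@dataclass(frozen=True)
class CIIResult:
    """Concentration index of inequality (trapezoid rule) with bootstrap CI.

    Sign convention: positive when burden accrues disproportionately to
    high-SDI countries.
    """

    cii: float
    ci_lower: float
    ci_upper: float
    n_countries: int
    n_bootstrap: int
    seed: int | None
    integration_rule: str = "trapezoid"


#: canonical column set produced by :func:`midpoint_ranks`
CountryRanks = pd.DataFrame


def midpoint_ranks(countries: pd.DataFrame) -> pd.DataFrame:
    """Population-weighted midpoint cumulative ranks on the SDI ordering.

    ``countries`` needs columns ``location``, ``sdi``, ``population``.
    Returns the frame sorted by ascending SDI (ties broken by location name)
    with ``pop_share``, ``cum_share_before``, ``cum_share_after`` and
    ``midpoint_rank`` columns appended. Midpoint ranks are strictly
    increasing down the sorted list and lie in (0, 1).
    """
    if len(countries) < 2:
        raise InequalityError("need at least 2 countries to rank")
    if countries["location"].duplicated().any():
        dup = countries.loc[countries["location"].duplicated(), "location"].iloc[0]
        raise InequalityError(f"duplicate location name {dup!r}")
    if (countries["population"] <= 0).any():
        raise InequalityError("populations must be positive")

    out = countries.sort_values(["sdi", "location"], kind="mergesort").reset_index(drop=True)
    share = out["population"].to_numpy(float)
    share = share / share.sum()
    after = np.cumsum(share)
    before = after - share
    out["pop_share"] = share
    out["cum_share_before"] = before
    out["cum_share_after"] = after
    out["midpoint_rank"] = (before + after) / 2.0
    return out


def _align_rates(ranks: pd.DataFrame, rates) -> np.ndarray:
    if isinstance(rates, pd.Series):
        missing = [loc for loc in ranks["location"] if loc not in rates.index]
        if missing:
            raise InequalityError(f"rates missing for location(s) {missing[:3]}")
        return rates.reindex(ranks["location"]).to_numpy(float)
    arr = np.asarray(rates, dtype=float)
    if arr.shape != (len(ranks),):
        raise InequalityError("rates must align one-to-one with the rank rows")
    return arr


def _weighted_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    """Closed-form weighted least-squares slope and intercept."""
    w = w / w.sum()
    xm = np.sum(w * x)
    ym = np.sum(w * y)
    var = np.sum(w * (x - xm) ** 2)
    if var <= 0:
        raise InequalityError("zero rank variance: cannot fit a slope")
    slope = np.sum(w * (x - xm) * (y - ym)) / var
    return slope, ym - slope * xm


def _huber_slope(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                 c: float = HUBER_C, tol: float = 1e-10, max_iter: int = 200) -> float:
    """Case-weighted Huber M-estimation by IRLS with MAD residual scale."""
    slope, intercept = _weighted_slope(x, y, w)
    for _ in range(max_iter):
        r = y - intercept - slope * x
        scale = 1.4826 * np.median(np.abs(r - np.median(r)))
        if scale <= 0:  # perfect fit (or degenerate residuals): done
            break
        u = np.abs(r / scale)
        hub = np.where(u <= c, 1.0, c / np.maximum(u, 1e-300))
        new_slope, new_intercept = _weighted_slope(x, y, w * hub)
        if abs(new_slope - slope) <= tol * (1 + abs(slope)):
            slope, intercept = new_slope, new_intercept
            break
        slope, intercept = new_slope, new_intercept
    return slope


def _bootstrap_ranks(sdi, pop, rng, n_boot):
    """Resampled (rank, weight, order) triples: countries iid with replacement.

    Ranks are recomputed inside each replicate; ties in resampled SDI are
    broken by the original sorted position (stable sort), mirroring the
    name tie-break of :func:`midpoint_ranks`.
    """
    n = len(sdi)
    idx = rng.integers(0, n, size=(n_boot, n))
    order = np.argsort(sdi[idx], axis=1, kind="stable")
    idx = np.take_along_axis(idx, order, axis=1)
    pop_b = pop[idx]
    share = pop_b / pop_b.sum(axis=1, keepdims=True)
    after = np.cumsum(share, axis=1)
    mid = after - share / 2.0
    return idx, share, mid


def _percentile_ci(samples: np.ndarray, estimate: float) -> tuple[float, float]:
    lo, hi = np.percentile(samples, [2.5, 97.5])
    # percentile interval widened (rarely needed) to contain the point estimate
    return float(min(lo, estimate)), float(max(hi, estimate))


def slope_index(
    ranks: pd.DataFrame,
    rates,
    method: str = "wls",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> SIIResult:
    """Slope index of inequality: regression of rate on midpoint rank.

    ``method='wls'`` fits population-share-weighted least squares;
    ``'huber'`` a case-weighted Huber M-estimator (c = 1.345). The CI is a
    seeded percentile bootstrap over countries (``n_bootstrap=0`` collapses
    the CI onto the point estimate).
    """
    if method not in ("wls", "huber"):
        raise InequalityError(f"unknown method {method!r}")
    if len(ranks) < 3:
        raise InequalityError("need at least 3 countries for the slope index")
    y = _align_rates(ranks, rates)
    x = ranks["midpoint_rank"].to_numpy(float)
    w = ranks["pop_share"].to_numpy(float)

    fit = _weighted_slope if method == "wls" else None
    if method == "wls":
        sii, _ = _weighted_slope(x, y, w)
    else:
        sii = _huber_slope(x, y, w)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        sdi = ranks["sdi"].to_numpy(float)
        pop = ranks["population"].to_numpy(float)
        idx, share, mid = _bootstrap_ranks(sdi, pop, rng, n_bootstrap)
        y_b = y[idx]
        if method == "wls":
            xm = np.sum(share * mid, axis=1, keepdims=True)
            ym = np.sum(share * y_b, axis=1, keepdims=True)
            var = np.sum(share * (mid - xm) ** 2, axis=1)
            cov = np.sum(share * (mid - xm) * (y_b - ym), axis=1)
            samples = cov / var
        else:
            samples = np.array([
                _huber_slope(mid[b], y_b[b], share[b]) for b in range(n_bootstrap)
            ])
        lo, hi = _percentile_ci(samples, sii)
    else:
        lo = hi = float(sii)

    return SIIResult(float(sii), lo, hi, method, len(ranks), n_bootstrap, seed)


def _cii_from_sorted(share: np.ndarray, burden: np.ndarray) -> float:
    tot = burden.sum()
    cum_pop = np.concatenate([[0.0], np.cumsum(share)])
    cum_burden = np.concatenate([[0.0], np.cumsum(burden) / tot])
    area = np.trapezoid(cum_burden, cum_pop)
    return float(1.0 - 2.0 * area)


def concentration_index(
    ranks: pd.DataFrame,
    rates,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> CIIResult:
    """Concentration index from trapezoid integration of the Lorenz-type curve.

    Country burden share is rate x population over the total; the curve runs
    through (0, 0) and the cumulative (population share, burden share) points
    in SDI order. Returns 1 - 2 * integral, in [-1, 1].
    """
    if len(ranks) < 3:
        raise InequalityError("need at least 3 countries for the concentration index")
    y = _align_rates(ranks, rates)
    if (y < 0).any():
        raise InequalityError("rates must be non-negative")
    pop = ranks["population"].to_numpy(float)
    burden = y * pop
    if burden.sum() <= 0:
        raise InequalityError("all burdens are zero: concentration undefined")
    share = ranks["pop_share"].to_numpy(float)
    cii = _cii_from_sorted(share, burden)

    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        sdi = ranks["sdi"].to_numpy(float)
        idx, share_b, _ = _bootstrap_ranks(sdi, pop, rng, n_bootstrap)
        burden_b = (y * pop)[idx]
        tot = burden_b.sum(axis=1, keepdims=True)
        cum_pop = np.concatenate(
            [np.zeros((n_bootstrap, 1)), np.cumsum(share_b, axis=1)], axis=1)
        cum_burden = np.concatenate(
            [np.zeros((n_bootstrap, 1)), np.cumsum(burden_b, axis=1) / tot], axis=1)
        area = np.trapezoid(cum_burden, cum_pop, axis=1)
        samples = 1.0 - 2.0 * area
        lo, hi = _percentile_ci(samples, cii)
    else:
        lo = hi = cii

    return CIIResult(cii, lo, hi, len(ranks), n_bootstrap, seed)


def inequality_timeseries(
    panel: Panel,
    cause: str,
    measure: str = "dalys",
    years: list[int] | None = None,
    method: str = "wls",
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Per-year SII and CII for one cause/measure using that year's SDI.

    Returns a frame with columns ``year, sii, sii_lo, sii_hi, cii, cii_lo,
    cii_hi, n``. Bootstrap seeds are derived deterministically per year from
    ``seed`` so repeated runs give identical intervals.
    """
    years = years or panel.years
    records = []
    for year in years:
        cross = slice_panel(panel, year, cause, measure, "rate", "age_standardized")
        ranks = midpoint_ranks(cross)
        year_seed = (
            None if seed is None
            else int(np.random.SeedSequence([seed, int(year)]).generate_state(1)[0])
        )
        sii = slope_index(ranks, cross["value"].to_numpy(), method=method,
                          n_bootstrap=n_bootstrap, seed=year_seed)
        cii = concentration_index(ranks, cross["value"].to_numpy(),
                                  n_bootstrap=n_bootstrap, seed=year_seed)
        records.append({
            "year": int(year),
            "sii": sii.sii, "sii_lo": sii.ci_lower, "sii_hi": sii.ci_upper,
            "cii": cii.cii, "cii_lo": cii.ci_lower, "cii_hi": cii.ci_upper,
            "n": sii.n_countries,
        })
    return pd.DataFrame.from_records(records)
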