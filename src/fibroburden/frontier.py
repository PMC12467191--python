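"""Frontier efficiency analysis: the minimum achievable rate at a given SDI.

The frontier is the empirical lower envelope of the (SDI, age-standardized
rate) cloud pooled over all country-years. A locally weighted regression
through a cloud does not by itself yield a *minimum*, so the construction
here is a transparent three-step lower envelope:

1. partition the observed SDI span into ``n_bins`` equal-width bins (default
   100) and take the minimum observed rate in each non-empty bin, placed at
   the bin midpoint;
2. smooth these bin minima with locally weighted linear regression (tricube
   weights, LOWESS, span = ``bandwidth``, default 0.3);
3. clamp the smoothed value at each bin to be no higher than that bin's
   observed minimum, then floor at zero — so within interpolation error no
   observed point lies below the frontier. Clamping can be disabled
   (``clamp=False``) for a pure smooth-through-minima sensitivity check.

A country-year's *effective difference* is its vertical gap above the
frontier (linear interpolation on the bin-midpoint grid, no extrapolation
beyond the observed SDI span), floored at zero. Countries near the frontier
have maximized their achievable burden reduction at their development level;
large gaps flag unrealized potential.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "FrontierError",
    "FrontierCurve",
    "fit_frontier",
    "effective_differences",
    "rank_deviators",
    "trend_directions",
]


class FrontierError(ValueError):
    """Invalid input to the frontier estimator."""


@dataclass(frozen=True)
class FrontierCurve:
    """Smoothed minimum achievable rate on a bin-midpoint SDI grid.

    Defined only within ``span`` (the observed SDI range); no extrapolation.
    """

    grid: np.ndarray
    values: np.ndarray
    bandwidth: float
    n_bins: int
    span: tuple[float, float]

    def interpolate(self, sdi) -> np.ndarray:
        """Frontier value by linear interpolation; NaN outside the span."""
        sdi = np.asarray(sdi, dtype=float)
        out = np.interp(sdi, self.grid, self.values)
        lo, hi = self.span
        return np.where((sdi < lo) | (sdi > hi), np.nan, out)


def fit_frontier(
    sdi,
    asr,
    n_bins: int = 100,
    bandwidth: float = 0.3,
    clamp: bool = True,
) -> FrontierCurve:
    """Fit the lower-envelope frontier to pooled (SDI, rate) points."""
    sdi = np.asarray(sdi, dtype=float)
    asr = np.asarray(asr, dtype=float)
    if sdi.shape != asr.shape or sdi.ndim != 1:
        raise FrontierError("sdi and asr must be equal-length 1-d arrays")
    if len(sdi) < 10:
        raise FrontierError("need at least 10 points to fit a frontier")
    if (asr < 0).any():
        raise FrontierError("rates must be non-negative")
    if not (0 < bandwidth <= 1):
        raise FrontierError("bandwidth must lie in (0, 1]")
    if n_bins < 3:
        raise FrontierError("need at least 3 bins")

    lo, hi = float(sdi.min()), float(sdi.max())
    if hi <= lo:
        raise FrontierError("SDI values are all identical: no span to bin")
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(sdi, edges) - 1, 0, n_bins - 1)

    mids, minima = [], []
    for b in range(n_bins):
        mask = which == b
        if mask.any():
            mids.append((edges[b] + edges[b + 1]) / 2.0)
            minima.append(asr[mask].min())
    if len(mids) < 3:
        raise FrontierError("fewer than 3 non-empty bins")
    mids = np.asarray(mids)
    minima = np.asarray(minima)

    smoothed = lowess(minima, mids, frac=bandwidth, it=1, return_sorted=True)[:, 1]
    if clamp:
        smoothed = np.minimum(smoothed, minima)
    smoothed = np.maximum(smoothed, 0.0)

    return FrontierCurve(grid=mids, values=smoothed, bandwidth=bandwidth,
                         n_bins=n_bins, span=(lo, hi))


def effective_differences(curve: FrontierCurve, records: pd.DataFrame) -> pd.DataFrame:
    """Per country-year gap above the frontier.

    ``records`` needs columns ``location, year, sdi, asr``. Returns a copy
    with ``frontier_asr``, ``effective_difference`` (= max(0, asr - frontier))
    and ``excluded`` (True for SDI outside the fitted span — flagged, never a
    hard failure; their gap is NaN).
    """
    out = records.copy().reset_index(drop=True)
    frontier = curve.interpolate(out["sdi"].to_numpy(float))
    out["frontier_asr"] = frontier
    out["excluded"] = np.isnan(frontier)
    gap = np.maximum(0.0, out["asr"].to_numpy(float) - frontier)
    out["effective_difference"] = gap
    return out


def rank_deviators(
    gaps: pd.DataFrame,
    year: int,
    k: int = 15,
    low_sdi_cutoff: float = 0.46,
    high_sdi_cutoff: float = 0.80,
) -> dict[str, pd.DataFrame]:
    """Headline country lists for one year, in the figure convention.

    * ``top``: the k largest effective differences overall;
    * ``best_low_sdi``: low-SDI countries (SDI < cutoff) with the *smallest*
      gaps — over-performers relative to development;
    * ``worst_high_sdi``: high-SDI countries (SDI > cutoff) with the largest
      gaps — under-performers despite resources.

    Ties on the gap are broken alphabetically by location name.
    """
    if k < 1:
        raise FrontierError("k must be >= 1")
    sub = gaps[(gaps["year"] == year) & ~gaps["excluded"]].copy()
    if sub.empty:
        raise FrontierError(f"no usable frontier gaps for year {year}")

    def _take(df, ascending):
        df = df.sort_values(["effective_difference", "location"],
                            ascending=[ascending, True], kind="mergesort")
        return df.head(k).reset_index(drop=True)

    return {
        "top": _take(sub, ascending=False),
        "best_low_sdi": _take(sub[sub["sdi"] < low_sdi_cutoff], ascending=True),
        "worst_high_sdi": _take(sub[sub["sdi"] > high_sdi_cutoff], ascending=False),
    }


def trend_directions(records: pd.DataFrame,
                     start_year: int = 1990, end_year: int = 2021) -> pd.Series:
    """Sign of each location's rate change start -> end ('decline'/'increase'/'flat').

    Mirrors the red/cyan dot coding of frontier scatter plots. ``records``
    needs columns ``location, year, asr``.
    """
    wide = records.pivot_table(index="location", columns="year", values="asr")
    if start_year not in wide.columns or end_year not in wide.columns:
        raise FrontierError(f"records must cover years {start_year} and {end_year}")
    diff = wide[end_year] - wide[start_year]
    return pd.Series(
        np.where(diff < 0, "decline", np.where(diff > 0, "increase", "flat")),
        index=wide.index, name="trend_direction",
    )
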