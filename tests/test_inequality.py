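"""Midpoint ranks, slope index and concentration index contracts."""

import itertools

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings, strategies as st

from fibroburden.gbd_io import Panel
from fibroburden.inequality import (
    InequalityError,
    concentration_index,
    inequality_timeseries,
    midpoint_ranks,
    slope_index,
)
from fibroburden.synthetic import PanelSpec, generate_panel


def test_equal_population_midpoint_ranks(three_countries):
    r = midpoint_ranks(three_countries)
    np.testing.assert_allclose(r["midpoint_rank"], [1 / 6, 1 / 2, 5 / 6])
    np.testing.assert_allclose(r["cum_share_after"].iloc[-1], 1.0)


def test_unequal_population_midpoint_ranks():
    df = pd.DataFrame({"location": ["Poorland", "Richland"],
                       "sdi": [0.2, 0.9], "population": [9.0, 1.0]})
    r = midpoint_ranks(df)
    np.testing.assert_allclose(r["midpoint_rank"], [0.45, 0.95])


def test_rank_tie_break_is_alphabetical():
    df = pd.DataFrame({"location": ["Zeta", "Alpha"], "sdi": [0.5, 0.5],
                       "population": [1.0, 1.0]})
    r = midpoint_ranks(df)
    assert r["location"].tolist() == ["Alpha", "Zeta"]


@pytest.mark.parametrize("frame,match", [
    (pd.DataFrame({"location": ["A"], "sdi": [0.5], "population": [1.0]}), "at least 2"),
    (pd.DataFrame({"location": ["A", "A"], "sdi": [0.1, 0.5], "population": [1.0, 1.0]}), "duplicate"),
    (pd.DataFrame({"location": ["A", "B"], "sdi": [0.1, 0.5], "population": [1.0, 0.0]}), "positive"),
])
def test_rank_input_errors(frame, match):
    with pytest.raises(InequalityError, match=match):
        midpoint_ranks(frame)


@settings(max_examples=50, derandomize=True)
@given(st.integers(min_value=2, max_value=40), st.integers(min_value=0, max_value=2**31 - 1))
def test_ranks_strictly_increase_and_cover_unit_interval(n, seed):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "location": [f"L{i}" for i in range(n)],
        "sdi": rng.uniform(0, 1, n),
        "population": rng.uniform(0.1, 100, n),
    })
    r = midpoint_ranks(df)
    assert (np.diff(r["midpoint_rank"]) > 0).all()
    assert r["midpoint_rank"].between(0, 1, inclusive="neither").all()
    assert r["cum_share_after"].iloc[-1] == pytest.approx(1.0)
    assert r["pop_share"].sum() == pytest.approx(1.0)


# Closed-form OLS oracle for the 3-country example, computed independently
# with Sum((x-xbar)(y-ybar)) / Sum((x-xbar)^2) on ranks (1/6, 1/2, 5/6) and
# rates (100, 80, 60); equal weights make WLS coincide with OLS.
SII_ORACLE = -60.0


def test_slope_index_matches_closed_form_oracle(three_countries):
    r = midpoint_ranks(three_countries)
    x, y = r["midpoint_rank"].to_numpy(), np.array([100.0, 80.0, 60.0])
    assert np.polyfit(x, y, 1)[0] == pytest.approx(SII_ORACLE)  # oracle route
    res = slope_index(r, y, method="wls", n_bootstrap=0)
    assert res.sii == pytest.approx(SII_ORACLE, abs=1e-9)


def test_wls_slope_agrees_with_statsmodels(three_countries):
    rng = np.random.default_rng(42)
    df = pd.DataFrame({
        "location": [f"L{i}" for i in range(25)],
        "sdi": rng.uniform(0, 1, 25),
        "population": rng.uniform(1, 50, 25),
    })
    r = midpoint_ranks(df)
    y = rng.uniform(100, 2000, 25)
    ours = slope_index(r, y, n_bootstrap=0).sii
    X = sm.add_constant(r["midpoint_rank"].to_numpy())
    theirs = sm.WLS(y, X, weights=r["pop_share"].to_numpy()).fit().params[1]
    assert ours == pytest.approx(theirs, rel=1e-10)


def test_flat_rates_give_zero_slope_with_ci_containing_zero(three_countries):
    r = midpoint_ranks(three_countries)
    res = slope_index(r, [50.0, 50.0, 50.0], n_bootstrap=200, seed=1)
    assert res.sii == pytest.approx(0.0, abs=1e-12)
    assert res.ci_lower <= 0.0 <= res.ci_upper


def test_huber_matches_statsmodels_rlm_with_equal_weights():
    rng = np.random.default_rng(7)
    n = 40
    df = pd.DataFrame({"location": [f"L{i}" for i in range(n)],
                       "sdi": np.sort(rng.uniform(0, 1, n)),
                       "population": np.ones(n)})
    r = midpoint_ranks(df)
    y = 500 - 300 * r["midpoint_rank"].to_numpy() + rng.normal(0, 40, n)
    y[5] += 2000  # gross outlier
    ours = slope_index(r, y, method="huber", n_bootstrap=0).sii
    X = sm.add_constant(r["midpoint_rank"].to_numpy())
    theirs = sm.RLM(y, X, M=sm.robust.norms.HuberT(t=1.345)).fit().params[1]
    assert ours == pytest.approx(theirs, rel=0.02)


def test_huber_and_wls_agree_on_outlier_free_data():
    rng = np.random.default_rng(3)
    n = 60
    df = pd.DataFrame({"location": [f"L{i}" for i in range(n)],
                       "sdi": np.sort(rng.uniform(0, 1, n)),
                       "population": rng.uniform(1, 20, n)})
    r = midpoint_ranks(df)
    y = 1000 - 600 * r["midpoint_rank"].to_numpy() + rng.normal(0, 10, n)
    wls = slope_index(r, y, method="wls", n_bootstrap=0).sii
    hub = slope_index(r, y, method="huber", n_bootstrap=0).sii
    assert hub == pytest.approx(wls, rel=0.01)


# Hand trapezoid oracle: equal-pop countries with rates (100, 80, 60) in SDI
# order give curve points (0,0), (1/3, 5/12), (2/3, 3/4), (1, 1) and
# CII = 1 - 2 * (5/9) = -1/9.
CII_ORACLE = -1.0 / 9.0


def test_concentration_index_matches_hand_trapezoid(three_countries):
    r = midpoint_ranks(three_countries)
    res = concentration_index(r, [100.0, 80.0, 60.0], n_bootstrap=0)
    assert res.cii == pytest.approx(CII_ORACLE, abs=1e-12)


def test_equal_rates_give_zero_concentration(three_countries):
    r = midpoint_ranks(three_countries)
    res = concentration_index(r, [70.0, 70.0, 70.0], n_bootstrap=0)
    assert res.cii == pytest.approx(0.0, abs=1e-15)


def test_reversing_sdi_order_flips_the_sign_exactly():
    rng = np.random.default_rng(11)
    n = 17
    df = pd.DataFrame({"location": [f"L{i:02d}" for i in range(n)],
                       "sdi": np.sort(rng.uniform(0, 1, n)),
                       "population": rng.uniform(1, 30, n)})
    y = rng.uniform(10, 500, n)
    fwd = concentration_index(midpoint_ranks(df), y, n_bootstrap=0).cii
    flipped = df.assign(sdi=1 - df["sdi"])
    rev = concentration_index(midpoint_ranks(flipped),
                              pd.Series(y, index=df["location"]), n_bootstrap=0).cii
    assert rev == pytest.approx(-fwd, abs=1e-12)


@settings(max_examples=50, derandomize=True)
@given(st.integers(min_value=3, max_value=30), st.integers(min_value=0, max_value=2**31 - 1),
       st.floats(min_value=0.01, max_value=100, allow_nan=False))
def test_cii_bounded_and_scale_invariant(n, seed, c):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({"location": [f"L{i}" for i in range(n)],
                       "sdi": rng.uniform(0, 1, n),
                       "population": rng.uniform(0.5, 50, n)})
    y = rng.uniform(0.0, 1000.0, n) + 1e-6
    r = midpoint_ranks(df)
    base = concentration_index(r, y, n_bootstrap=0).cii
    assert -1.0 <= base <= 1.0
    scaled = concentration_index(r, c * y, n_bootstrap=0).cii
    assert scaled == pytest.approx(base, abs=1e-10)
    sii_base = slope_index(r, y, n_bootstrap=0).sii
    sii_scaled = slope_index(r, c * y, n_bootstrap=0).sii
    assert sii_scaled == pytest.approx(c * sii_base, rel=1e-9, abs=1e-9)


def test_cii_averages_to_zero_over_rate_permutations(three_countries):
    """Exchangeability: with equal populations the mean CII over every
    permutation of the rates is exactly zero."""
    df = pd.DataFrame({"location": list("ABCD"), "sdi": [0.1, 0.3, 0.6, 0.9],
                       "population": np.ones(4)})
    r = midpoint_ranks(df)
    rates = np.array([10.0, 40.0, 70.0, 120.0])
    vals = [concentration_index(r, np.array(p), n_bootstrap=0).cii
            for p in itertools.permutations(rates)]
    assert np.mean(vals) == pytest.approx(0.0, abs=1e-14)


def test_all_zero_rates_are_an_error(three_countries):
    r = midpoint_ranks(three_countries)
    with pytest.raises(InequalityError, match="zero"):
        concentration_index(r, [0.0, 0.0, 0.0], n_bootstrap=0)


def test_linear_gradient_recovery_on_small_panel():
    spec = PanelSpec(n_locations=50, years=(2000, 2004),
                     gradient_mode="linear_gradient", noise_sd=0.0, seed=21)
    panel, truth = generate_panel(spec)
    from fibroburden.gbd_io import slice_panel
    s = slice_panel(panel, 2002, "Neoplasms")
    r = midpoint_ranks(s)
    beta = truth.gradient.query("cause == 'Neoplasms' and measure == 'dalys'")[
        "gradient_slope"].iloc[0]
    res = slope_index(r, s["value"].to_numpy(), n_bootstrap=0)
    assert abs(res.sii - beta) / abs(beta) < 1e-6


def test_shrinking_gradient_gives_monotone_sii_series():
    spec = PanelSpec(n_locations=40, years=(2000, 2007),
                     gradient_mode="linear_gradient", gradient_decay=0.08,
                     noise_sd=0.0, seed=31)
    panel, _ = generate_panel(spec)
    ts = inequality_timeseries(panel, "Neoplasms", n_bootstrap=0)
    assert (np.diff(np.abs(ts["sii"])) < 0).all()


def test_seeded_timeseries_is_reproducible(small_panel):
    panel, _ = small_panel
    a = inequality_timeseries(panel, "Tuberculosis", years=[2001, 2005],
                              n_bootstrap=100, seed=9)
    b = inequality_timeseries(panel, "Tuberculosis", years=[2001, 2005],
                              n_bootstrap=100, seed=9)
    pd.testing.assert_frame_equal(a, b)
    assert (a["sii_lo"] <= a["sii"]).all() and (a["sii"] <= a["sii_hi"]).all()
    assert (a["cii_lo"] <= a["cii"]).all() and (a["cii"] <= a["cii_hi"]).all()


def test_low_sdi_concentrated_burden_has_negative_cii(small_panel):
    """The generating frontier declines with SDI, so burden concentrates in
    low-SDI countries and the concentration index must be negative."""
    panel, _ = small_panel
    from fibroburden.gbd_io import slice_panel
    s = slice_panel(panel, 2009, "Chronic obstructive pulmonary disease")
    res = concentration_index(midpoint_ranks(s), s["value"].to_numpy(), n_bootstrap=0)
    assert res.cii < 0
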