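# fibroburden

Trend, inequality and frontier-efficiency analysis of the global burden of
fibrosis-related diseases (neoplasms, COPD, chronic kidney disease, cirrhosis
and other chronic liver diseases, hypertensive heart disease, tuberculosis)
over GBD-style country-year panels. It is written for epidemiologists and
health-policy analysts who work with Global Burden of Disease (GBD) results
tool exports: age-standardized death and DALY rates with 95% uncertainty
intervals across 204 countries and territories, 1990–2021, stratified by the
socio-demographic index (SDI).

The package ships a seeded synthetic panel generator with known generating
truth, so every analysis stage is exercisable and testable end-to-end with no
downloads; the same readers accept a real GHDx results-tool export.

## What it computes

**Burden trends.** Cause shares of total burden from all-age counts,
`share = 100 · Σ number(cause) / Σ number(all causes)`; percent changes on
age-standardized rates, `100 · (v₁ − v₀) / v₀`; cross-group burden ratios;
and summary tables of start/end rates with both change statistics.

**Slope index of inequality (SII).** Countries are sorted by SDI and given
population-weighted midpoint cumulative ranks `xᵢ = (cumᵢ₋₁ + cumᵢ)/2 ∈ (0,1)`.
The SII is the slope of the regression of the age-standardized rate on these
ranks — the absolute rate difference across the full development gradient.
The default fit is population-share-weighted least squares; a weighted Huber
M-estimator (c = 1.345) is the outlier-robust option. 95% intervals come from
a seeded country-bootstrap (percentile method).

**Concentration index of inequality (CII).** With burden shares
`wᵢ ∝ rateᵢ · popᵢ` accumulated in SDI order, the concentration curve L(p)
runs through (0,0) and the cumulative (population share, burden share)
points; `CII = 1 − 2∫₀¹ L(p) dp` by the trapezoid rule. CII ∈ [−1, 1], zero
for equal rates, negative when burden concentrates in low-SDI countries.

**Frontier analysis.** Pooling all country-years, the minimum achievable
rate at each SDI is estimated as a lower envelope: equal-width SDI bin
minima, smoothed by locally weighted linear regression (LOWESS, tricube
weights, span 0.3), then clamped at each bin's observed minimum and floored
at zero. A country's *effective difference* is
`max(0, observed − frontier(SDI))` — its unrealized improvement potential.

## Worked example

`python examples/02_burden_trends.py` recomputes the headline percent
declines from the packaged GBD 2021 global / SDI-quintile summary rates:

```
Global           Neoplasms dalys :  3969.21 ->  2953.59 per 100,000 (25.59% decline)
Global           Chronic o deaths:    71.92 ->    45.22 per 100,000 (37.12% decline)
Global           Chronic o dalys :  1492.64 ->   940.66 per 100,000 (36.98% decline)
High-middle SDI  Chronic o deaths:    79.53 ->    35.91 per 100,000 (54.85% decline)
Low SDI          Neoplasms dalys :  2864.53 ->  2487.39 per 100,000 (13.17% decline)

low-SDI / high-SDI COPD DALY rate ratio in 2021: 3.09 (burden >3x higher in the least developed quintile)
```

Global neoplasm DALY rates fell by a quarter and COPD rates by over a third
between 1990 and 2021, but the 2021 COPD burden in the lowest-SDI quintile
still exceeds the high-SDI quintile more than threefold. The other examples
(`examples/01_…` to `05_…`) walk through panel simulation, the inequality
time series, frontier gaps, and the full deterministic pipeline.

A thin CLI mirrors the stages:

```bash
fibroburden simulate --out-dir panel --seed 1
fibroburden inequality --panel-dir panel --cause Neoplasms --out ineq.csv
fibroburden frontier --panel-dir panel --cause Neoplasms \
    --out-frontier frontier.csv --out-gaps gaps.csv
fibroburden run --config config.yaml --json
```

## Layout

- `src/fibroburden/gbd_io.py` — results-tool CSV dialects, validation, panel assembly
- `src/fibroburden/synthetic.py` — seeded panel generator + generating truth
- `src/fibroburden/trends.py` — proportions, percent changes, summary tables
- `src/fibroburden/inequality.py` — midpoint ranks, SII, CII, bootstrap CIs
- `src/fibroburden/frontier.py` — lower-envelope frontier and effective differences
- `src/fibroburden/pipeline.py`, `cli.py` — orchestration, manifest, CLI
- `docs/methods.md` — model assumptions, parameter choices, limitations
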