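# Methods

## Data model

The analysis unit is a burden estimate keyed by (location, year, cause,
measure, metric, age group) with a point value and a 95% uncertainty
interval. Measures are deaths or DALYs; metrics are rates (per 100,000),
numbers (persons / person-years) or percents; age groups are age-standardized
or all-age. A *panel* cross-references the burden table with per
location-year SDI (∈ [0, 1]) and population tables. Location name is the
join key: SDI and population files in the wild frequently lack location IDs,
so IDs are carried but optional. The year span is closed, [1990, 2021] by
default. Wherever an ordering on SDI matters (ranks, slices, Lorenz curves)
ties are broken by location name ascending, so every ordering is total and
every run deterministic.

Age-standardized values are taken as given inputs; the package never
re-standardizes, and SDI-group rows (Global, High SDI … Low SDI) are
consumed as pre-aggregated location rows rather than re-derived by pooling
countries — country-to-quintile age-standardized aggregation would require
age-specific data the pipeline does not model. The packaged
`gbd2021_summary_rates.csv` is a transcription of published GBD 2021
global/quintile age-standardized rates for neoplasms and COPD (1990, 2021)
in the results-tool export dialect, used by the worked examples.

Two published share figures are knowingly inconsistent with their own
inputs: a mortality-share rise printed as 4.83% where the quoted shares
(26.78% → 28.08%) give 4.85%, and a tuberculosis mortality decline printed
as 214.55%, which is impossible against a 1990 denominator. The package
computes the direct arithmetic and documents the discrepancy rather than
reproducing either figure.

## Change statistics

`relative_change(v₀, v₁) = 100 (v₁ − v₀)/v₀` and `percent_decline` its exact
negative; both are undefined (an error) at v₀ = 0. Cause proportions divide
all-age person-year totals, never rates, and are invariant under uniform
rescaling. Internal arithmetic is full precision; presentation rounding is
half-away-from-zero to 2 decimals, matching published tables.

## Slope index of inequality

Countries sorted by ascending SDI receive population-weighted midpoint
cumulative ranks; with population shares wᵢ, country i's rank is
cum(w₁…wᵢ₋₁) + wᵢ/2, strictly increasing in (0, 1). The SII is the slope of
rate on rank, so its units are rate units across the full rank span 0 → 1.

The source method statement names "robust linear regression" without an
estimator or weighting, so both are explicit here: the default is
population-share-weighted least squares (closed form, cross-checked against
statsmodels WLS), and the robust option is a case-weighted Huber M-estimator
(tuning constant 1.345, IRLS with MAD residual scale). statsmodels' RLM has
no case weights, hence the small in-package IRLS; it reproduces RLM in the
equal-weight case and agrees with WLS within 1% on outlier-free data.
Confidence intervals are a seeded nonparametric bootstrap resampling
countries with replacement (percentile method, default 1000 replicates),
with ranks recomputed inside each replicate; ties in resampled SDI fall back
to stable original order. The percentile interval is widened, if ever
needed, to contain the point estimate so the interval invariant holds.

## Concentration index

Burden shares are rateᵢ·popᵢ over the total (converting per-capita rates to
totals so "cumulative proportion of DALYs" is meant literally). The
concentration curve is anchored at (0,0) and passes through the cumulative
(population share, burden share) points in SDI order; the index is
1 − 2·(trapezoid area). No smoothing or grouping: countries are the atoms.
Positive values mean burden concentrated in high-SDI countries. Exact
properties used as tests: the sign flips under SDI-order reversal; the index
vanishes for equal rates and, on average, under permutation of rates with
equal populations; it is scale-invariant while SII is scale-equivariant.

## Frontier construction

The published description — a non-parametric locally weighted regression
estimating the minimum achievable rate — does not say how a regression
through the cloud becomes a *minimum*. The construction adopted is a
transparent lower envelope: equal-width bin minima over the observed SDI
span (default 100 bins, each minimum placed at its bin midpoint), LOWESS
smoothing through the minima (tricube local linear, span 0.3, one
robustifying iteration), then a clamp at each bin's observed minimum and a
floor at zero. The clamp guarantees that, within interpolation error, no
observed point lies below the frontier; disabling it (`clamp=False`) gives
the pure smooth-through-minima variant for sensitivity checks. All years
1990–2021 are pooled into one frontier, as stated by the source method;
per-year fitting is a caller option (fit on a single year's slice). No
monotonicity in SDI is enforced, since none is stated. Evaluation is linear
interpolation on the bin-midpoint grid with no extrapolation: records
outside the observed span are flagged and excluded, never fatal. Defaults
(100 bins, span 0.3) give ≥ 30 bin minima inside each local fit window at
the 204 × 32 panel scale.

Effective differences are clamped at zero. Known bias: a bin's minimum sits
at the bin's far edge for a monotone frontier, so placing it at the midpoint
biases the frontier low by about |slope|·(bin width)/2 — under 0.5% of the
frontier value at default settings, which the recovery tests bound at 1%.

## Synthetic panel generator

The generator emulates the structure the analyses assume, at the study's
scale (204 locations, 1990–2021, six causes), not real magnitudes:

- **SDI paths**: per-country linear growth with jittered start
  (uniform on [0.05, 0.80]) and slope (uniform on [0.002, 0.012]/year),
  clipped to [0, 1] — the simplest monotone path satisfying the bounds.
- **Populations**: log-normal (μ = 16, σ = 1.2 on the log scale; median
  ≈ 9 million), constant over time.
- **Rates** (frontier mode): ASR = g(SDI) + δ_c + ε with linear frontier
  g(s) = max(0, a + b·s), one-sided exponential country offsets δ_c (so the
  frontier is the true lower envelope), and Gaussian noise ε (default
  sd 15 rate units) truncated so observations never beat the frontier.
  DALY frontier parameters span roughly 400–2500 per 100,000; death-rate
  parameters are the DALY set scaled by 1/25 but generated independently —
  nothing downstream links the two measures.
- **Rates** (linear-gradient mode): ASR exactly linear in the
  population-weighted midpoint rank (optionally shrinking linearly over
  years via `gradient_decay`), with no δ offset — the configuration under
  which weighted least squares must recover the generating slope exactly,
  the pipeline's core parameter-recovery property.
- **Counts and totals**: all-age numbers are rate × population / 10⁵; the
  "All causes" total per location-year-measure is the cause sum times an
  inflation factor of 6, putting the fibrosis-related share of total burden
  near 17% — the observed magnitude — and making generated shares a known
  arithmetic (summed shares = 100/6).
- **Uncertainty intervals** are ±10% bands; no propagation is attempted.
- **Reproducibility**: four named RNG streams (SDI, population, offsets,
  noise) spawned from one seed; identical specs give byte-identical CSVs.

What the generator does not emulate — and hence what green tests do not
show about real data: real SDI trajectories and country heterogeneity,
age structure (so no true age-standardization), correlated uncertainty,
reporting gaps, or any mechanistic deaths–DALYs link. Parameter-recovery
results demonstrate estimator correctness, not real-world effect sizes; the
published headline SII/CII values and named frontier countries require the
real 204-country panel, which the same readers ingest from a results-tool
export.

## Pipeline determinism and sizes

The orchestrator hashes the config, runs simulate → validate → trends →
inequality → frontier, and records SHA-256 checksums of every output;
identical config + seed implies identical checksums. Default problem sizes
keep the full test suite and the acceptance script in the tens of seconds:
full-scale (204 × 32) panels are used for the counting, recovery and
envelope checks, 25–120-location panels elsewhere, and bootstrap replicates
are 1000 for reported intervals but smaller in smoke tests. The pipeline's
quick-look bootstrap default is 200 replicates; the library default of 1000
is used when intervals are the object of interest.

## Limitations

- The frontier estimator's bin-midpoint bias (above) and its behaviour at
  the span edges (first/last half-bin) are not corrected; interior-only
  comparisons are used for recovery claims.
- The Huber bootstrap refits by IRLS per replicate and is markedly slower
  than the vectorized WLS bootstrap.
- CII bootstrap intervals ignore uncertainty in the published rate
  estimates themselves (the UI columns are carried through, not propagated).
- No EAPC/joinpoint trend models and no frontier bias correction (DEA or
  stochastic frontier analysis) — out of scope by design.
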