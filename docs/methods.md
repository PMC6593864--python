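# Methods

This note records the statistical model, the conventions the package fixes
where several are defensible, the design of the synthetic-data generator,
and the known limits of what the tests demonstrate.

## Exposure index and transforms

The temperature–humidity index is computed from mean daily temperature and
mean daily relative humidity as

    THI = 1.8 t + 32 − (0.55 − 0.0055 rh)(1.8 t − 26).

The index is sometimes typeset with the operator between `32` and the
humidity term missing; we use the subtraction form, which is the standard
NRC composition and preserves the identity THI = °F at 100% humidity
(`compute_thi(22.2, 100) = 71.96 = 1.8·22.2 + 32`). ∂THI/∂t =
1.8(0.45 + 0.0055 rh) > 0 always; ∂THI/∂rh changes sign at t = 14.44 °C.

THI enters the model as integer classes. An observed index range of 4–84
with 81 one-unit subclasses forces integer binning; the rounding rule
(half away from zero) is our choice and is documented on `bin_thi`.

Somatic cell counts are scored as SCS = log2(SCC/100,000) + 3, so doubling
the count adds exactly one score unit and the reference count 100,000
scores 3. Counts are floored at 1,000 cells/mL (the usual recording floor),
giving a minimum attainable score of log2(0.01) + 3 = −3.64.

## Fixed-effects test-day model

For response y (milk kg/day or SCS) and candidate lag d:

    y = herd + calving_year + month + age_group + DIM_class + THI_class(d) + e

All terms are categorical: calendar month of the test day (12), age at
first calving grouped 18–20 / 21 / 22–35 months (boundaries configurable —
the printed grouping is unusually coarse and may compress a finer one),
days in milk as 300 one-day classes (6–305, no smoothing), and one class
per integer THI value. The design is reference-coded against the first
sorted level of each factor, with an explicit intercept; level ordering is
deterministic so coefficients are reproducible, and LSMs (the exported
quantity) are coding-invariant.

The solve uses sparse normal equations with an in-place pivoted Cholesky:
a column whose pivot falls below `1e-10 × max(diag, 1)` is aliased (an
exact linear combination of earlier columns) and dropped, first-seen
columns kept. On every fixture tried, retained rank equals the dense
matrix rank and fitted values match a dense pseudo-inverse solve to 1e-8
(tested). A zero-RSS fit is flagged degenerate rather than given an AIC.

**AIC convention.** AIC = n ln(2π·rss/n) + n + 2(rank + 1), the full
Gaussian log-likelihood with the residual variance profiled out and
counted as a parameter. Only differences between models on identical
records are ever interpreted, and differences are invariant to the
additive constant (tested). With equal RSS, ΔAIC = 2·Δrank.

**Least-squares means.** LSM(THI = n) is the fitted value at class n with
every other factor averaged over its observed levels with *equal weight*
(reference level contributing zero; aliased columns contributing zero).
Whether to weight by observed margins instead is a genuine choice; equal
weights are the convention of the classical GLM/LSMEANS machinery and are
what the segmented stage consumes. Standard errors use the same contrast
with the unbiased residual variance rss/(n − rank).

## Lag scan

Herds are assigned uniformly at random to k = 5 subsets (herd-atomic;
multinomial, so sizes vary). Analyses mirror the practice of splitting
national data by herd for memory reasons: each subset is fitted
separately — basic model (no THI) plus one model per lag 0–14 — and the
selected lag minimizes the mean AIC across subsets, ties resolving to the
smaller lag (the more recent exposure). The across-subset spread gives
SE = SD/√k and a normal 95% interval; within-model standard errors would
be an alternative, but the replicate spread is the honest uncertainty for
a 5-replicate design. The non-THI design block and its Gram matrix are
built once per subset and only the THI columns are rebuilt per lag; the
result is provably identical to independent fits (tested).

## Segmented (breakpoint) regression

Per-subset LSM tables at the selected lag are pooled by unweighted class
means (counts summed; classes present in fewer than 3 of 5 subsets
dropped). Pooling LSMs, rather than fitting per subset and averaging
breakpoints, is our choice where both are defensible; it uses all classes
each subset observes. Only classes with strictly more than `min_count`
records enter the fit — 20,000 at national recording scale, scaled for
synthetic runs as the equivalent fraction of total records
(20,000/17,245,709 ≈ 0.116%).

The hinge model ŷ = c + b·max(x − BP, 0) is flat below BP, linear above,
and continuous at BP (implied upper intercept a = c − b·BP). Continuity is
enforced deliberately: a discontinuous variant adds a parameter the class
means cannot separate from BP. BP is profiled on a 0.1-THI grid over the
interior of the filtered range (two extreme classes excluded at each end,
preventing boundary solutions), with (c, b) solved exactly at each
candidate; ties take the smallest BP, and |b| < 1e-12 returns a
no-breakpoint flag instead of an arbitrary BP. The grid-profile estimator
equals an exhaustive per-candidate least-squares search (tested).
Inverse-variance weighting by LSM standard errors is available behind a
flag; the default is unweighted, as class means of near-equal precision
dominate after the count filter.

## Synthetic-data generator

The generator emulates national monthly DHI recording of first lactations
over calving years 2000–2015: 100 herds × 210 cows (~210,000 test-day
records) mapped to 10 weather stations, monthly tests at 30 ± 5 day
intervals from a first test at DIM 6–35, ages at calving concentrated at
22–26 months. The response is generated additively exactly as the model
assumes — herd, year, month, age, a smooth lactation curve in DIM, plus
slope·max(THI(test_date − lag) − BP, 0) with Gaussian residuals — so
parameter recovery exercises estimation, not model misspecification.
Realized effect draws are centred over the generated records; fixed
effects are identified only up to contrasts, so centring is a pure
reparameterization that pins the sample mean at `baseline_mean`.

Weather is a station-specific seasonal sinusoid (winter means −14…+2 °C,
summer 20…28 °C north to south, peaking late July) with AR(1) daily noise
(φ = 0.55, marginal SD 2.3 °C, anomalies truncated at ±3 SD) and seasonal
humidity anticorrelated with the temperature anomaly. Binned THI spans
about 3–90 across stations and years, with the analysis window 18–82 well
populated; the extreme upper tail is slightly wider than real station
records, but those classes fall below the count filter.

Default effect sizes (shipped in `scenarios/default.yaml`) reproduce
typical first-lactation Holstein test-day moments — milk 27.1 ± 6.5
kg/day, SCS 2.33 ± 1.65 — via an explicit variance budget: for milk,
herd 2.5² + year 0.7² + month (1.0²/2) + age ≈ 0.35 + lactation curve
≈ 6.4 + hinge ≈ 0.24 + residual 5.3² ≈ 6.5² in total, and analogously for
SCS with residual SD 1.52. The hinge slopes (−0.3 kg/day and +0.08 score
per THI unit above threshold) are at the strong end of literature
estimates; they are chosen so that a 0–14 day scan at ~42,000 records per
subset separates adjacent lags by ≫10 AIC units in expectation, i.e. the
recovery study is run at adequate power. True lags (3 days milk, 8 days
SCS) and breakpoints (70.4, 68.5) are set to the estimates the analysis is
expected to recover, so recovery tests double as consistency checks of the
full pipeline.

What the generator does **not** emulate: multiple lactations, genetic or
permanent-environment covariance between records of a cow, seasonal
calving patterns, herd-by-year drift, non-Gaussian SCS tails, missing or
irregular weather. Passing recovery tests therefore demonstrates that the
estimators recover a lagged hinge signal of realistic size from data with
the assumed structure — not that real data satisfy that structure.

## Problem sizes and numerical choices

The shipped recovery study uses 10 replicate seeds for lag selection and
20 for breakpoint estimation at ~210,000 records each — about 85 model
fits per replicate (5 subsets × (1 basic + 16 lag designs)), each a sparse
system with ~430 retained columns. These sizes give Monte-Carlo error well
inside the reported tolerances while keeping a full run in the minutes
range on one CPU. Dates are ISO-8601 calendar dates and lag arithmetic is
in calendar days; missing weather for any required (station, date) is a
hard error, never imputed. All randomness flows from explicit integer
seeds; a run is a pure function of (inputs, config).

## Known limitations

- The flat-below-threshold hinge is an approximation; mildly elevated SCS
  at very low THI (cold stress) would bias c upward slightly and is out of
  scope.
- No confidence interval is reported for BP; the grid profile gives a
  point estimate (replicate SDs are available from the reproduction
  script's per-seed output).
- LSM estimability under heavy aliasing is handled pragmatically (aliased
  columns contribute zero to contrasts); with the shipped scenario no
  design column beyond deliberate confounds is ever dropped.
- Wind- and radiation-adjusted THI variants, and maximum-temperature /
  minimum-humidity variants, are not implemented.
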