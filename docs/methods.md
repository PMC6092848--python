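# Methods

## Model and assumptions

The package models case counts on a Lexis grid as independent Poisson
variables whose means are person-years times a log-linear rate:

```
θ_ijk ~ Poisson(N_ijk · exp(μ + α_i + β_j + γ_k)),   k = a − i + j
```

with age bands *i = 1..a*, period bands *j = 1..p*, and birth-cohort
diagonals *k = 1..a+p−1*. All variation beyond the factor effects is
treated as Poisson sampling noise: no overdispersion parameter is
estimated, and deviance/df is reported as the informal dispersion check.
Exposure, not population, supplies the denominator: N_ijk is person-years
of dust exposure, so the fitted quantity is an incidence density (reported
per 100,000 person-years), not a population rate.

Time is discretized to whole calendar years. Age attained in year *y* is
*y − birth_year*; a miner contributes one person-year to the cell of
(attained age, calendar year) for every exposed year; the diagnosis year
itself accrues before censoring, so a case never lands in a cell to which
its miner contributed no time. Years outside the configured band schemes
are counted in an explicit remainder so that person-years and cases are
conserved exactly — a property the test suite asserts rather than assumes.

## Identification

Cohort = period − age makes the full three-factor dummy design singular.
The package fixes one age band, one period band and **two** cohort bands at
zero in the full model (one cohort band in C, AC and PC). Removing a
second cohort column eliminates the single remaining null direction (which
is linear in the level indices and can vanish at only one level), so the
design is full-rank for any two distinct cohort references; a property
test checks this over random grids and reference pairs. The default
references are the middle age band, the middle period band, and cohort
diagonals 5 and a+p−1 — on the 8×9 default grid: age 45–49, period
1975–1979, cohorts 1913–1917 and 1968–1972. Alternative identification
schemes (drift decomposition, curvature partitions, sum-to-zero coding)
are out of scope; the constraint scheme is named in run metadata.

Cohort bands are attached to diagonals by the median-birth-year rule: a
5×5-year cell spans nine birth years, whose median is a whole year; the
5-year cohort band centred on the first diagonal's median anchors the
scheme, and equal band widths make the rule consistent along every
diagonal (asserted in code rather than handled as a tie-break, since an
even-length birth range cannot arise with equal widths).

A factor level with no populated cells (zero person-years everywhere, as
happens on the extreme diagonals of sparse grids) has no data and would
contribute an all-zero column; such levels are dropped from the design,
reported as not estimable, and listed in the result. The closed-form
parameter counts above therefore apply to fully populated grids. The two
extreme single-cell diagonals stay **in** the fit when populated — the
residual-df arithmetic requires all cells — but are excluded from reported
effect tables.

## Fitting

Maximum likelihood by iteratively reweighted least squares with the log
link and offset ln N. Starting values are zero except the intercept,
initialised at ln(Σθ/ΣN) so the first step is finite. Convergence:
relative deviance change below 1e-10, at most 100 iterations; a
non-converged fit is returned flagged with a warning rather than raised.
Cells with N = 0 are excluded from the likelihood (their offset is
undefined); cells with θ = 0 and N > 0 are informative and retained. A
level whose observed cases are all zero has its MLE at −∞; IRLS drives the
coefficient strongly negative and the level is flagged as separated.
Standard errors come from the inverse Fisher information X'WX at the
optimum. The tests verify the fitter against two independent routes on
identical designs — a generic Newton optimizer of the same likelihood and
an established GLM implementation — to 1e-6.

## Model comparison and selection

All seven factor subsets are fitted and compared by deviance, residual df,
deviance/df, and the chi-square upper-tail p-value of the deviance.
P-values are displayed to two decimals with "<0.01" below. Selection:
among adequate models (p > 0.05) prefer the lowest deviance, with the full
APC model preferred whenever it is adequate. A single failed fit flags its
row and leaves the rest of the comparison intact.

## Projection

Projected density for a future cell is 100000·exp(μ + α_i + β_j + γ_k);
expected cases are density × person-years / 100000. Period effects beyond
the fitted window are extrapolated either by the least-squares line
through all estimated β_j against j (default) or by carrying the last
estimate forward; cohort effects on diagonals beyond the estimated range
use the nearest estimated level (default) or the analogous linear trend.
The choice is recorded in output metadata; on exactly collinear effects
the linear trend reproduces the continuation exactly, which the tests use
as its oracle.

Future person-years are an **input**, not a model output: how much at-risk
weight the remaining ex-dust workforce carries after mine closure is a
design decision about the data, not something the rate model can supply.
The synthetic module's construction freezes each undiagnosed miner's
accumulated exposure duration and contributes it annually while the
miner's attained age lies inside the age scheme — one defensible reading
among several, and deliberately swappable by passing a different table.

Rounded person counts use the ceiling: a predicted 491.37 cases is
reported as 492 whole persons. Per-period totals, the grand total, and the
overall density (the person-year-weighted mean of per-period densities)
are recomputed from the rows, and the tests check these identities to
1e-9.

## Synthetic cohorts

The generator emulates an opencast-mine workforce of the size and
demographic shape the analysis is designed for: 8,191 miners by default,
age at first exposure from a truncated normal (mean 21.22, SD 4.90 years,
truncated at 16 — truncation raises the realized mean to about 22.5), and
exposure duration likewise (mean 27.79, SD 8.25 years, at least 1),
both rounded to whole years; a single exposure segment per miner. Birth
years are uniform on 1891–1974, the unique range that can populate all 16
cohort diagonals of the default 8×9 grid — the extreme diagonals remain
sparse, mirroring real registers in which the oldest and youngest cohorts
contain a handful of observations. Only mean ± SD of the exposure
quantities are emulated; a truncated normal is the minimal choice
consistent with that information.

Diagnoses are generated from the same log-linear rate the fitter
estimates, as an annual Bernoulli hazard 1 − exp(−rate) per exposed
miner-year (matching the calendar-year discretization; for small rates
this is Poisson to first order), with the first event censoring the miner.
Years outside the grid use the nearest band's rate, mirroring the
projection module's nearest-level rule. Default true effects: age slope
+0.3 per band around the reference (risk rising with age), period slope
+0.05 per band, and a concave cohort quadratic −0.012·(k−5)(k−16)
vanishing at both reference diagonals; μ = −5.5 gives an in-window
caseload of a few hundred in the default cohort, the realistic order for a
workforce of this size. What the generator does **not** emulate: multiple
exposure segments with gaps, competing mortality, diagnostic drift,
dust-concentration dosimetry, or any non-multiplicative age–period
interaction — so passing tests demonstrate correct recovery of the model's
own data-generating process, not robustness to these real-data features.

## Validation harness and problem sizes

The recovery experiment simulates, tabulates and refits replicate cohorts
and reports per-coefficient bias, mean absolute error, and empirical
coverage of 95% Wald intervals, pooled over replicates. Separated
coefficients (levels with zero cases in a replicate) are excluded from the
pooling and counted, since their estimates are divergent by construction.
The acceptance checks run 20 replicates of 50,000 miners for coverage and
5 replicates each at 5,000 / 20,000 / 80,000 miners for the
error-shrinkage check; these sizes give stable summaries while keeping the
whole suite around half a minute.

## Numerical conventions

- Bands are half-open [lo, lo+width) and labelled by inclusive endpoints
  ("1975-1979" = [1975, 1980)).
- Deviance uses 0·ln 0 = 0; it is additive over disjoint cell sets.
- Output CSVs carry 10 significant digits; write/read round-trips are
  lossless at that precision.
- All randomness flows from a single integer seed; the miner and event
  streams use deterministic seed offsets so they can be varied
  independently, and replicate seeds are derived arithmetically (kept
  below 2^31).

## Known limitations

- The two-reference-cohort constraint identifies the parameters but, like
  every APC identification scheme, the separation of linear trends among
  age, period and cohort is a modelling convention, not an estimable fact;
  effect curves should be read for curvature and relative change.
- Extrapolated period/cohort effects inherit no uncertainty: projected
  densities are point predictions without prediction intervals.
- The crude-incidence denominator (miners observed in a band) is one of
  several defensible conventions and is documented at the function.
- Single-segment exposure in the generator understates the irregular
  careers of real miners; the tabulation itself handles multi-segment
  records.
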