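# Methods

This note records the scientific and numerical choices behind
`droughtthresh`: the model the pipeline fits, what the synthetic-data
generator does and does not emulate, the defaults that matter, and the
known limitations.

## The response model

The object of inference is the drought threshold **T**: the soil-moisture
anomaly percentile at which the vegetation response to drought switches
from a resistant phase (Phase A: coincidence rate low and slowly varying)
to a rapid-response phase (Phase B: coincidence rate climbing steeply as
drought intensifies).  The coincidence rate r(q) is the conditional
frequency of vegetation suppression (anomaly below the pooled 10th
percentile, strict `<`) among pooled cell-years at or below the pooled
q-th percentile soil-moisture cutoff (`≤`).  All percentile cutoffs use
linear interpolation between order statistics (quantile type 7), applied
identically to the drought and vegetation sides, so that θ(q) is continuous
in q — a property the segmented fit relies on.  One exception is the risk
module, below.

Detection assumes: independent years (no drought legacy or lag effects),
an 18-year record pooled over PC-space neighbors to reach usable sample
sizes, and a response curve adequately described by two linear segments in
θ.  All three assumptions are idealizations; the first two mirror common
practice for short satellite records, the third is the operational
definition of "threshold" here.

## Pooling by covariate similarity

Cells are pooled in the space of the first three principal components of
seven standardized covariates.  PCA is computed on the correlation matrix
because the covariates carry incommensurate units (mm/yr, °C, fractions,
counts).  Each PC axis is binned at 4% of its observed range (25 bins; the
axis maximum closes the top bin, interior ties round up), and a cell pools
every cell within Chebyshev distance 1 in bin space.  The sample gate is
pooled cell-years ≥ 162 (= 9 cells × 18 years); it is `>=` rather than `>`
so that the canonical 9-cell example itself passes.  Windows are anchored
at bin indices (mesh centers), not at each cell's own score — the
alternative, per-cell centered windows, would make membership asymmetric.

## Model selection and breakpoint fit

The non-linearity gate compares an exponential curve `r = m·e^{βθ} + k`
with a straight line by AIC = n·ln(RSS/n) + 2p (p = 2 linear, 3
exponential), with two overrides: linear R² > 0.95 keeps the cell linear
regardless of AIC, and exponential adjusted R² ≤ 0.5 excludes it as
unfittable.  The exponential is fit by profiling (m, k) out with closed-form
least squares at fixed β and minimizing the profile RSS over a signed
log-spaced β grid (0.005–15 divided by the θ range) refined by bounded
scalar minimization; because the profile is exact, the refined β is the
joint optimum, and the β→0 limit reproduces the straight line (the grid's
low end reaches deep enough into that regime that no special case is
needed).

The two-segment regression is continuous at the breakpoint by
construction of its design `{1, θ, (θ − θ_c)·[θ < θ_c]}`.  Candidate
breakpoints are the sampled θ_q themselves (this makes "T is a percentile"
well-defined); each side must retain at least 3 samples; the minimal-SSE
candidate wins, first candidate in ascending θ on ties.  All candidates are
solved at once from prefix-sum normal equations — algebraically identical
to per-candidate OLS (the test suite checks equality against a brute-force
oracle).  The slope-order rule requires β₂ < 0: the severe-drought segment
must steepen the decline of r with rising θ.  Thresholds whose curve never
reaches a coincidence rate of 0.3 are reported but flagged low-confidence.

## The synthetic generator

The generator's purpose is exact parameter recovery, so it works backwards
from the target: the *pooled response curve itself* is specified as
two-segment linear in θ with the kink at the cell's true threshold
percentile (Phase A slope `slope_mild` = 0.05 per anomaly unit, Phase B
slope `slope_severe` = 0.28, both acting to raise r as θ falls).  The
conditional suppression probability p(u) at soil-moisture percentile u is
obtained analytically from p = r + F·dr/dF (F the Gaussian CDF), the
plateau level is set as low as feasibility allows (probabilities in [0, 1],
total suppressed mass exactly the 10% that defines the pooled vegetation
cutoff), and each vegetation proxy is the implied deterministic response
A₀(u) = −Φ⁻¹(p(u)) plus Gaussian noise (`noise_sd` = 1, split into shared
and idiosyncratic parts so proxies correlate at `indicator_corr` = 0.6).
Soil moisture is iid standard normal per cell-year; covariates are smooth
Gaussian random fields driven by two latent gradients (moisture and
temperature) so that three PCs capture most of their variance, as for real
climate fields; tree cover optionally tilts the per-cell truth
(`covariate_link` × 20 percentiles across the tree-cover range, clipped to
the exactly-calibrated design range of roughly the 3rd–24th percentile).

Three deliberate idealizations, and what they mean for the tests:

* **Non-monotone microstructure.**  For the pooled running average r to be
  exactly piecewise linear, p(u) must dip just below the kink before
  rising.  Real vegetation does not do this; a direct consequence is that
  *no monotone response* (for example, two linear slopes switching at the
  threshold) can produce a curve whose segmented-regression breakpoint sits
  at the switching percentile — with Gaussian soil moisture, r and its
  first derivative are continuous wherever p has no level jump, so a
  monotone regime switch moves the fitted breakpoint far from the true one.
  Passing recovery tests therefore demonstrates that the detector finds the
  inflection of the *curve*, which on real data need not coincide with a
  physiological switching point.
* **Gaussian everything.**  Real anomalies are skewed and autocorrelated;
  the generator's independence across years matches the method's own
  assumption, so the tests cannot detect violations of it.
* **No missingness in the core coupling tests.**  The preprocessing module
  handles missing months/years and is tested separately.

The defaults (18 years, 4 proxies, truth at the 15th percentile, 10×10
grid) are the record length, proxy count and a mid-range threshold typical
of the satellite-era setting the package addresses.

## Significance testing

500 surrogate series per cell (default), each member cell's vegetation
year-order permuted independently; soil moisture untouched.  Because the
pooled vegetation multiset is permutation-invariant, the drought cutoffs,
denominators and the vegetation cutoff are computed once; only numerators
are recomputed per surrogate.  Surrogates with no detectable threshold are
excluded from the band; below `min_detected` (default 100) the verdict is
inconclusive.  The band is two-sided (2.5th–97.5th percentiles, P < 0.05).

A structural limitation, measured and documented rather than hidden: the
coincidence curve is a running average of nested counts, so a *decoupled*
surrogate still shows smooth spurious structure, and the thresholds
detected on surrogates spread over much of the 1–50 sweep.  Banding the
threshold value is therefore exactly calibrated (the type-I rate is the
nominal 5%) but has almost no power — a genuinely coupled threshold in the
middle of the sweep falls inside the spurious band.  The package therefore
also offers `statistic="max_r"`, which bands the curve's maximum
coincidence rate: it is defined for every surrogate, calibrated by the same
exchangeability argument, and separates coupled from shuffled clusters
essentially completely in the verification experiments (genuinely coupled
curves reach maximum coincidence rates well above anything a decoupled
surrogate produces).  The threshold-band mode remains the default; the
`max_r` mode is the recommendation when the test is meant to screen, not
merely to describe.

## Aggregation and stratification

A cell's threshold is the mean over proxies with a valid detection; it is
robust when at least two proxies contribute and at least one of them
reached max r > 0.3.  Stratification bins aridity (default width 0.1 over
the 0–1.5 display range) × tree cover (default width 5 percentage points),
with a dedicated non-forest category below 1% tree cover and bins under 5
cells excluded.  Aridity classes are left-closed: < 0.2 arid, [0.2, 0.5)
semi-arid, [0.5, 0.65) semi-humid, ≥ 0.65 humid.  NDVI masking is strict
(< 0.1 removed, 0.1 kept); NIRv masking is ≤ 0.

## Risk projection

Each period (historical and future, ≥ 10 years each) is trend-corrected by
removing its fitted OLS slope about the period-mean time — the period's
mean level is retained, because a future mean shift is the signal being
measured, not a nuisance trend.  The cutoff is the cell's threshold
percentile of the *historical* residuals, applied to both periods with the
`≤` drought convention; the reported change is the difference of the two
crossing fractions, ensemble-averaged over future inputs when several are
given.  The cutoff quantile uses the Weibull plotting position rather than
type 7: for out-of-sample exceedance probabilities at 20-year samples the
type-7 quantile is noticeably biased (its expected non-exceedance is ≈0.18
at the nominal 0.15), while the Weibull position is the standard unbiased
estimator in hydrological frequency analysis.  Cells whose aggregated
threshold is unrobust are excluded by default.

## Problem sizes

The verification experiments run at desk scale: 50–100-cell pooled
clusters (900–1800 cell-years), 100–200 seeded replicates per Monte-Carlo
rate, 99 surrogates in the shuffle experiments (scaled down from the
500-surrogate default together with its `min_detected` gate, 100 → 20),
and three replicate 40×40 simulations for the tree-cover gradient
experiment.  These sizes put every Monte-Carlo standard error well inside
the tolerance being checked.

## Known limitations

* Detection attributes a pooled-neighborhood estimate to the center cell;
  where the true threshold varies across a neighborhood, the estimate
  regresses toward the neighborhood mean — visible at the extremes of a
  covariate gradient (one-sided neighborhoods).
* The threshold-band surrogate test's low power (above).
* Growing-season derivation (phenology fitting, freeze/thaw masking) is out
  of scope; the season mask is consumed as an input.
* No spatial autocorrelation correction is applied when pooling cell-years;
  pooled counts treat cell-years as exchangeable, as the sample-gate
  arithmetic assumes.
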