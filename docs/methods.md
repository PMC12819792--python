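# Methods

This note records the statistical model behind `speri`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical corner cases.

## Study design the package encodes

The pipeline assumes a multi-year capture-release dataset of free-ranging
caribou: one row per capture event with a six-analyte SPE panel (g/dL),
serostatus for four pathogens, and field health flags. Reference intervals
are stratified because serum proteins shift with season and pregnancy; the
default strata are adult females in fall (Aug–Oct), summer (Jun–Jul) and
spring (Mar–May), plus yearlings (10–14 months) of both sexes pooled over
spring and summer — the only seasons yearlings are captured. Adult males
are carried through the cascade but receive no interval (too few survive
the exclusions to support one); they surface in the ledger under
`insufficient-stratum` rather than vanishing. Captures in November–February
belong to no defined season and are excluded as `out-of-season`.

## Exclusion cascade

Rules run as ordered stages over the surviving records; a record's
*attributed* reason is the first rule it fails, which makes the per-reason
counts disjoint and additive (kept + Σ attributed = deduplicated input, an
invariant the ledger asserts). The default order is serology
(Erysipelothrix, Neospora, Toxoplasma, Brucella — the order the counts are
conventionally reported in), then analyte outliers, then the health flags;
it is configurable, and permuting it changes attribution but never the
cohort (except through the outlier stage, whose fences depend on what
survived the earlier rules). Recaptured animals contribute only their
earliest capture; ties on date go to the first record in file order.
Untested serology is eligible by default — excluding on missing assays
would silently bias the cohort — with a `strict_serology` mode that
requires complete panels. Both event-level and animal-level tallies are
reported because published cohort counts are often ambiguous about which
they mean.

## Outlier removal

Tukey fences per analyte per stratum: [Q1 − 1.5·IQR, Q3 + 1.5·IQR],
flagging strictly outside values only (a value exactly on a fence is
inside). Removal is animal-level — one flagged analyte of seven removes the
animal — and single-pass: fences are not recomputed after removals, since
iterating Tukey's rule to convergence can chew arbitrarily far into a
skewed sample. Fences are computed within the reference stratum by default
(the intervals themselves are stratified, so pooled fences would mix
seasonal means); a pooled mode exists for sensitivity analysis. Below 4
observations no fences are fit and a warning is logged.

The quartile rule is configurable because published analyses rarely state
it: the default is linear interpolation of order statistics
(rank h = (n−1)p + 1, numpy's "linear"); the classic inclusive and
exclusive median-split hinges are also available. The hinge variants are
defined only at the quartiles and median; other probabilities fall back to
the interpolation rule.

## Reference intervals and uncertainty

The default estimator is the nonparametric percentile method at central
95% coverage — the standard recommendation when n permits, and the only
estimator whose limits are guaranteed to lie inside the observed range. The
Shapiro–Wilk class (G iff p ≥ 0.05) is reported as a table descriptor, not
used to switch estimators: switching would make neighbouring rows of one
table incomparable. A parametric mode (mean ± z·SD) exists for comparison
and converges to the nonparametric limits on large Gaussian samples (a
property test asserts this). Rows with n < 20 are emitted but flagged
`below_min_n`; a reference interval from a handful of animals is a
placeholder, not a standard.

Confidence limits are 90% percentile-bootstrap intervals, B = 1,000:
resample the cleaned stratum with replacement, recompute the limit, take
the 5th/95th percentiles of the replicates. The outlier stage is *not*
re-run inside the bootstrap — the resampled object is the cleaned cohort.
All-equal samples short-circuit to a degenerate (c, c) interval.

**Known limitation — tail-quantile coverage.** The percentile bootstrap of
an extreme empirical quantile undercovers at small n: for the 97.5th
percentile of a normal sample at n = 50, the empirical coverage of the
nominal 90% CI is roughly 70–80% (and `scipy.stats.bootstrap` with the
percentile method reproduces this), because the empirical tail quantile is
biased toward the center of the sample. Coverage climbs toward nominal as
n grows (~87% by n ≈ 200–800). The acceptance script reports the measured
coverage; users quoting the CIs for strata of a few dozen animals should
read them as optimistic.

## Screening

Each analyte is scored as a screen for grouped serostatus. Group
positivity is any-pathogen-positive; group negativity requires every
pathogen in the group tested and negative; anything else is not evaluable.
The screened cohort is the deduplicated, season-mappable record set —
seropositive animals are deliberately kept (they are the condition
positives), while in the default `post-health` mode the illness/mortality/
hemolysis exclusions still apply, since those records' analytes are
untrustworthy for any purpose. Every animal is compared against its own
stratum's interval; adult males, having no interval, are not evaluable.
Sensitivity with zero evaluable positives is reported as NA, never 0.

## Synthetic generator

`speri.simulate.generate_herd` emulates the deposited-data *structure*: 825
capture events by default, six herd labels, five stratum types (the four
reference strata plus adult males), capture dates uniform over the
stratum's season months across 1998–2024, five fraction concentrations
drawn independently from truncated normals (rejection at 0) with the
published stratum means/SDs, total protein defined as the exact fraction
sum, A:G derived, per-pathogen Bernoulli serostatus at the published
prevalences (23, 141, 95 and 32 per 825 events), a pooled health-flag
probability of 103/825 split evenly across the three flags, a recapture
probability targeting ~76 recapture events, and 2%-per-analyte
contamination at ±4 stratum-SDs (flipped upward when a downward spike
would cross zero). Stratum weights are proportional to the published
surviving cohort sizes (35/34/74/53/20). Adult males have no published
moments — their intervals were never reported — so the generator uses the
across-season average of the adult-female parameters as a synthetic
stand-in.

What it does **not** emulate: correlation between fractions (a common-
factor knob exists, default off, because no correlation structure is
reported), any association between serostatus and protein levels (a
`sero_effect` knob adds a globulin shift in seropositives for power
experiments; the default is the null world that the uniformly low published
sensitivities suggest), assay drift over 26 years, herd-level differences,
and pregnancy physiology beyond its seasonal proxy. Passing tests on this
generator therefore certify the *pipeline arithmetic* — conservation,
attribution, estimator calibration — not the biological realism of any
particular interval. Under these defaults the synthetic exclusion totals do
not reproduce the published 609: real outlier counts (~26% of events) far
exceed what Tukey fences produce on 2%-contaminated truncated normals,
which is itself informative about how heavy-tailed the field data must be.

## Numerical choices and corner cases

- Quantiles of an empty sample, RIs of an empty sample, and bootstraps of
  n < 2 raise; a single-record stratum yields a degenerate RI flagged
  below minimum.
- Zero total globulins makes A:G undefined and raises a degenerate-panel
  error; a supplied A:G is validated against albumin/globulins within 2%
  relative and kept if consistent.
- Total protein by refractometry need not equal the densitometric fraction
  sum; disagreement beyond 5% relative warns but never excludes.
- Shapiro–Wilk is computed on at most 5,000 values and is "untestable"
  below 3; constant samples are classed nG with p = 0.
- Every bootstrap row is seeded from one `SeedSequence`, so a table is
  reproducible end-to-end from a single seed, and CLI data outputs carry
  no timestamps (logs do), keeping reruns byte-identical.

## Problem sizes used in the test and acceptance runs

Property tests run at the sizes their statistics need, chosen once: 1,000
random samples (n = 4–200) for the quantile/fence oracle; 100,000 draws
for quantile recovery; 500 simulated datasets at n = 50 with B = 200 for
bootstrap coverage; a 10,000-event clean stratum for parameter recovery;
100 synthetic cohorts for the screening oracle; the default 825-event herd
for end-to-end runs.
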