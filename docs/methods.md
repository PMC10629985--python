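# Methods

This note documents the models and numerical choices behind `anthrocohort`:
what each stage computes, the tunable parameters and their defaults, what
the synthetic cohort generator does and does not emulate, and the known
limitations.

## Growth-standard engine

A growth reference is a table of Box-Cox parameters (L, M, S) per sex and
indicator, keyed by age in days (HAZ, WAZ) or recumbent length in cm (WHZ).
The z-score of a measurement *x* is `((x/M)^L − 1)/(L·S)`, with the limit
`ln(x/M)/S` used when |L| < 1e−12. The inverse is `M·(1 + L·S·z)^(1/L)`
(`M·exp(S·z)` at L = 0), exact to float precision.

Conventions, all centralized and configurable:

- **Age keys.** Ages in months convert at 30.4375 days/month and are rounded
  to the nearest whole day (ages are "completed days"). Rounding also makes
  z-scores exactly reproducible across write/read cycles, which the
  regenerate-bit-identically guarantee relies on.
- **Interpolation** between table rows is linear, per parameter. At daily /
  sub-millimetre granularity the difference from spline interpolation is
  negligible and linearity is trivially reproducible. A key exactly on a
  table row returns that row bit-exactly.
- **Restricted adjustment.** For WAZ and WHZ only, |z| > 3 is recomputed on
  the SD-spacing scale: `z = 3 + (x − SD3⁺)/(SD3⁺ − SD2⁺)` above, and
  symmetrically below, where SDk± are the inverse-transform values at
  z = ±2, ±3. The two branches agree at |z| = 3. HAZ is never adjusted.
- **WHZ is keyed on recumbent length** for all children (the population is
  under 24 months); no length↔height conversion is applied.
- **MUAC** is carried raw in millimetres; no MUAC-for-age standard is used.

Real reference tables load through a column-mapping dialect; the test suite
and the acceptance script run entirely on synthetic references.

## Cleaning

Participant screening applies three rules in a fixed order, so each dropped
child has one deterministic reason: (1) sex or age unrecorded; (2) fewer
than three visits (`min_visits`, default 3 — the shortest follow-up in which
programme effects are considered observable); (3) severe acute malnutrition
at the first visit, with the standard community-management admission rule
WHZ < −3 or MUAC < 115 mm (both thresholds configurable; oedema is not in
the data model). An implausible first-visit WHZ is treated as a recording
error, not a diagnosis: it falls through to the MUAC arm, and a child with
neither arm assessable is retained with a warning.

Visit-level filtering blanks single indicator values outside strict bounds
(HAZ: −6/+6, WHZ: −6/+5, WAZ: −5/+5 z; values exactly at a bound are kept).
Blanking is per indicator — a wild length removes HAZ, not the row — and
never changes the number of children. Children whose visit count falls
below three only after blanking are not re-screened (participant screening
precedes datum-level cleaning). An elimination table (visit × indicator,
totals, percentages of computed values) and an exhaustive log are produced.

Cleaning honours existing z-score columns instead of recomputing them from
raw measurements, so re-cleaning a cleaned export makes no further
eliminations; the raw measurements behind blanked values remain in the file
for audit.

## CIAF

With strict thresholds at −2 z (configurable): stunting = HAZ < −2,
wasting = WHZ < −2, underweight = WAZ < −2, mapped to A (none), B (wasting
only), C (wasting+underweight), D (all three), E (stunting+underweight),
F (stunting only), Y (underweight only). The eighth boolean combination —
wasting + stunting without underweight — is biologically odd but logically
possible; it gets an explicit X code and a logged warning rather than a
silent mis-assignment. Aggregate CIAF = total − count(A). Classification
uses the restricted z-scores, i.e. the same values cleaning validated.
Start/end tabulations and the 8×8 transition matrix use each child's first
and last fully classifiable visit; both all-children and
classifiable-at-both-timepoints views are available through the pairing.

## Change analysis

- **Pairing:** per child and indicator, the first and last visits with a
  usable (non-blank) value; children with fewer than two usable values are
  excluded and counted. n is therefore "children with usable pairs".
- **Quantiles:** median and IQR use linear interpolation between order
  statistics, as do the length-of-stay quartile boundaries; a stay exactly
  on a boundary goes to the lower stratum.
- **Wilcoxon signed-rank** (paired, within cohort): zero differences are
  dropped (classical convention; Pratt handling available). Differences
  smaller than `zero_tol = 1e−6` in absolute value are treated as zeros:
  values that went through a compute/store/recompute cycle carry ~1e−15 to
  1e−7 of accumulated float noise, and ranking that noise would manufacture
  signed differences out of nothing. With at most 25 non-zero differences
  the two-sided p is exact — the null distribution of W⁺ is built by dynamic
  programming over doubled midranks, which equals full 2ⁿ sign enumeration
  for any tie pattern; beyond that, the normal approximation with continuity
  and tie corrections (via scipy). All differences zero → degenerate result,
  p = 1.
- **Mann–Whitney** (independent, between cohorts): exact by complete
  combination enumeration when the combined size is ≤ 16, asymptotic with
  tie/continuity corrections otherwise.
- **Strata:** whole sample; compliance (enrolled ≤ 1 month of age and still
  followed at ≥ 23 months — "completed the whole programme"); length-of-stay
  quartiles (stay = last minus first visit age, ages not calendar dates);
  CIAF category at inclusion. Empty strata yield n = 0 rows, never errors.
- No multiple-testing correction is applied across tables, matching the
  reporting style the pipeline reproduces.

## Synthetic cohort generator

The generator emulates the statistical structure of a preventive
growth-monitoring cohort of under-twos in the Sahel. Defaults are the
emulated programme's descriptors; everything is overridable.

- **Enrollment ages:** mixture 65.1 / 17.4 / 11.8 / 5.7 % over the bands
  [0,6), [6,12), [12,18), [18,24) months. Within the first band ages follow
  Beta(1, 2.2) scaled to [0,6) — most enrollment happens in the first weeks
  of life — which reproduces an overall entry median of ≈2.9 months with
  IQR ≈[1.2, 9.4]; a uniform first band would put the median near 4.6.
  Later bands are uniform.
- **Length of stay:** a two-component model truncated so no visit exceeds
  24 months of age (programme exit). An early-dropout component
  (`dropout_frac` = 0.10, truncated normal (3.5, 1.5) on [2, 6] months)
  captures families leaving within half a year; together with exit-capped
  late enrollees this puts ~15–18 % of children below six months in the
  programme. The main component is a truncated normal with sd 6.6 whose
  location is solved once, numerically (Brent's method on the analytic
  mixture expectation), so that the *observed* mean stay — last minus first
  visit age on the monthly grid — equals the configured 14.5 months.
  Truncation alone would drag the realized mean near 11, so the configured
  mean/sd are treated as observed targets, not latent parameters. The
  resulting first stay-quartile boundary lands near 9 months.
- **Visits:** monthly from enrollment, ages snapped to whole days.
- **True trajectories:** HAZ = child intercept ~ N(−1.3, 1.5) plus slope
  −0.10 z/month (the characteristic under-two faltering rate in the region),
  floored at −4.5 z — faltering decelerates at extreme deficit, and the
  floor keeps honest biology clear of the implausibility bounds so that
  every elimination is attributable to an injected error. WHZ follows an
  AR(1) mean-reverting process (mean −0.3, start sd 1.4, reversion 0.3,
  innovation sd 0.35, clipped at ±4). WAZ is never simulated independently:
  true length comes from the HAZ trajectory via the inverse transform, true
  weight from the WHZ process at that length, and the synthetic reference's
  weight-for-age median curve is the exact composition of its length-for-age
  and weight-for-length curves — so the three indicators are mutually
  coherent the way real anthropometry is (a WAZ implied outside ±4.2 is
  floored the same way, adjusting weight and the implied WHZ together).
- **Measurement:** length error sd 0.5 cm with probability 0.3 of rounding
  up to the next 0.5 cm (a common field habit with height boards); weight
  error sd 0.1 kg (salter-scale resolution); MUAC baseline ~ N(135, 7.5) mm
  growing 0.35 mm/month with 2 mm error.
- **Corruption injection:** per-indicator implausible records at configured
  rates (defaults 2.9 / 3.3 / 0.5 % for HAZ / WHZ / WAZ, the field order of
  magnitude). Because the three indicators share two measurements, a breach
  of exactly one indicator requires solving length and weight *jointly* from
  target z's; each candidate is verified against the actual plausibility
  flags at injection time, so detection is 100 % by construction and the
  manifest is an exact oracle for the elimination accounting. Optional
  injections of missing-sex/age children, under-three-visit children and
  SAM-at-first-visit children serve the screening tests the same way.
- **Synthetic reference:** median length is a concave power curve of age,
  median weight-given-length an exact power law (tabulated at 0.01 cm so the
  composition is consistent to ~1e−7 z through linear interpolation), L and
  S constant per block in realistic ranges, small seeded jitter on the curve
  constants. Distinct seeds give distinct but equally plausible standards.
- **Determinism:** every stream (reference, per-child trajectories,
  screening injections, corruption draws) derives from one seed through
  spawned generator streams; the same seed reproduces every output file
  byte for byte.

### What the generator does not emulate

Seasonality, twin/cluster correlation, mortality, re-admission of referred
SAM cases, intervention exposure (supplementation, vaccination), and any
real within-child variance structure — the emulated programme reports no
variance components, so the process noise levels are chosen for realism and
are explicitly not estimates. Passing tests therefore demonstrate that the
pipeline recovers known structure exactly and reproduces the qualitative
start-to-end pattern (HAZ falling, MUAC rising, failure-free share
shrinking); they do not validate the generator against any real cohort's
microdata.

## Numerical choices

- Quantile convention: linear interpolation everywhere (numpy default).
- Exact-test switchovers: 25 non-zero pairs (signed-rank), 16 combined
  observations (rank-sum); chosen so the exact path is always affordable.
- Signed-rank DP counts are exact in double precision up to n = 25
  (counts ≤ 2²⁵ ≪ 2⁵³).
- CSV readers parse floats with round-trip precision (the default parser is
  one ulp off on some literals) and writers emit full `repr` precision, so
  every output is regenerable bit-identically from (inputs, config, seed).
- Degenerate inputs: empty strata produce n = 0 rows; all-zero difference
  vectors produce p = 1 with a degeneracy flag; a cohort with fewer than
  four distinct stays refuses quartile stratification with a clear error.

## Problem sizes

The test suite exercises the full pipeline at 2,000 children (~30,000
visits) for distributional-recovery checks and 80–500 children elsewhere;
the acceptance script uses 2,000 for the main cohort and 500 per arm for
the contrast. These sizes make medians and rate estimates stable to well
inside the asserted tolerances while keeping a full run in seconds.

## Limitations

- The restricted adjustment follows the widely documented convention; minor
  historical variants of growth-software behaviour beyond ±3 z exist, and
  this implementation fixes one and documents it rather than guessing a
  version.
- Whether datum-level cleaning should blank indicators (done here) or drop
  whole visit rows is a genuine design fork; blanking matches per-indicator
  elimination accounting, and the choice is config-visible, not silent.
- The SAM triage rule at first visit is the standard CMAM criterion, not a
  property of any particular dataset; cohorts screened under other rules
  should override it.
- Stay-duration realism is aggregate (mean, quartiles, short-stay fraction);
  the joint age-by-stay law of a real cohort will differ in detail.
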