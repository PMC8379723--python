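# Methods

This note records the models, conventions and design decisions behind
`pairforage`, in the order the pipeline runs. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Segmentation and filtering

A **foraging trip** runs from the last GPS fix inside the colony
boundary before an out-of-colony excursion to the first fix back
inside; **nest bouts** are the complementary in-colony intervals, so
trips and bouts tile each bird's observed window (checked to 1 s).
Colony membership supports a circle (centre + radius, default 500 m,
great-circle distance) or a simple polygon (boundary counted inside);
the boundary shape is a user choice because field colonies are rarely
circular. No interpolation is done across fix gaps: membership changes
only at observed fixes.

Coordinates are WGS84 decimal degrees; all distances are great-circle
on a sphere of radius 6371.0088 km (no projection). Trip distance is
the cumulative point-to-point distance over the trip's fixes; duration
comes from the interval endpoints. Offspring age is
`floor((t − hatch)/86400 s)` with hatch day = day 0, and analyses are
clipped to the chick-rearing window (day 0–30 or failure).

Trips shorter than 30 min **or** covering less than 1 km are excluded
as non-foraging. The disjunctive combiner is the stricter conventional
reading of the two criteria and is config-exposed (`combiner="both"`
for the conjunctive alternative). Excursions removed by the filter are
*absorbed back into the surrounding nest bout* — by definition a nest
bout is the in-colony time between foraging trips, and a 10-minute
flight around the colony does not end one. This keeps the trip/bout
tiling intact for the coordination statistics.

Tracks that begin or end away from the colony yield intervals flagged
`censored_start` / `censored_end`. Censored intervals are kept for
attendance (the portion observed counts) but their departures are
excluded from the partner-presence statistics and their durations from
duration models.

## Coordination statistics and the randomisation null

For a pair over its shared window, four statistics are computed:

* `male` / `female`: the proportion of that sex's trip departures at
  which the partner was inside the colony. The boundary convention is
  closed on the left: a partner returning exactly at the departure
  instant counts as present, a partner departing at that instant does
  not.
* `partner`: both sexes pooled (total present departures over total
  departures).
* `attendance`: |union of both birds' in-colony intervals| / |window|.

The **null model of uncoordinated care** permutes, within each bird,
the trip-duration multiset and the bout-duration multiset
independently, preserving the alternation order and starting state,
and rebuilds the timeline from the window start; both pair members are
re-randomised in every replicate (one-member randomisation is
config-exposed). Because the permuted durations tile the same window,
each bird's total trip time and bout time are preserved exactly; only
the between-mate phase relationship is destroyed.

Two numerical choices matter here:

* **Window overrun** (`overrun`): the chronologically last interval of
  an observed timeline is truncated by the end of observation, so its
  duration is *not* exchangeable with complete durations. The default
  scheme (`"pin"`) therefore holds it (and a censored-start leading
  trip) in place and permutes only complete durations, which makes the
  permutation null exact for exchangeable durations. `"clip"` permutes
  everything, matching the most literal multiset reading.
* **p-value**: one-tailed high, `p = (1 + #{null ≥ obs})/(R + 1)` with
  R = 999 by default; the add-one estimator never returns 0 and, at
  R = 999, rejecting at p < 0.05 is the same decision as "observed
  above the 95th percentile of the null". When the arrangement space
  is small (≤ 25 000 by default) the test enumerates it exhaustively
  and reports the exact `p = #{null ≥ obs}/N` instead — a Monte-Carlo
  estimate would add avoidable noise of order 1.6 % exactly where
  small-schedule tests are decided.

The test statistics are counts over ~60 departures per bird, so the
null distribution is discrete; with ties counted against rejection (as
the estimator above does), the test is slightly conservative. Measured
on 1000 simulated uncoordinated pairs at study-scale conditions, the
pooled-partner rejection rate at α = 0.05 is ≈ 0.03 (the acceptance
suite re-measures this on 200 pairs). Power against full departure
gating (w = 1) is ≈ 1. A second, milder source of conservatism is the
age trend in bout durations, which both mates share: permutation
spreads long early bouts across the window, slightly widening the
null. This is inherent to applying the method to trending data and
would equally affect an analysis of real tracks.

Pairs in which either bird has ≤ 1 trip are reported as untestable
rather than given a p-value.

### Attendance vs. offspring age

Daily attendance per pair is modelled with a beta regression
(logit link). Exact 0/1 days are shrunk by `(y(n−1)+0.5)/n` before
fitting — the standard transformation for boundary values. Statsmodels
provides no beta (or gamma) mixed model, so the requested
couple/colony random effects are honoured as **cluster-robust standard
errors grouped by couple** on a fixed-effects fit; every model report
carries the requested structure and a `fallback` note saying exactly
what was fitted.

## Behavioural classification

Per-fix features: step length (m, great-circle to the previous fix),
signed turning angle (left-positive, from initial bearings; undefined
at track ends, those rows are dropped), and optionally ground speed,
the accelerometer class, and the land-cover class (one-hot; categories
are frozen at training time and unseen categories at prediction time
encode as all-zeros with a warning). Candidate structures combine
geometry (always), habitat and body streams with symmetric windows of
1, 3 or 5 fixes — 12 structures in all.

Selection is done strictly on the training half of the *individuals*
(never fixes): within it, tree count {25, 50} and depth {5, ∞} are
tuned by 3-fold cross-validation grouped by individual, the structure
with the best internal Cohen's κ wins (ties break toward smaller
windows, then fewer streams), and the winner is refit on the full
training half. Validation individuals are disjoint by construction and
`evaluate` refuses overlapping IDs. Reported metrics: accuracy,
κ = (p_o − p_e)/(1 − p_e), and per-class precision, recall and
specificity from the confusion matrix (rows = truth).

## Co-adjustment models

* **Trip-to-trip**: focal trip duration ~ partner's preceding trip
  duration × sex, gamma family, log link. "Preceding" means the most
  recent partner trip that *ended* before the focal departure — a trip
  still in progress has not been observed by the focal bird
  (`partner_rule="started_before"` is the exposed alternative). Focal
  trips with no prior partner trip are dropped.
* **Bout duration vs. age**: gamma(log) of bout duration on offspring
  age × sex, censored bouts excluded.

Both are full models (no term selection), fit as GLMs with
cluster-robust errors (bird, or couple when a pair mapping is given);
Wald z statistics are reported and labelled as such. A constant age
column raises a rank-deficiency error rather than a silent drop.

## MRPP

Delta is the weighted mean of within-group mean pairwise
dissimilarities with the common n_g/N weights ((n_g−1)-weights are
config-exposed), groups being pairs and observations per-trip values
of one investment parameter, tested separately per colony (Euclidean
metric by default, config-exposed). The permutation null reassigns
observations to groups of the original sizes; p is one-tailed low with
the same add-one/exact-enumeration policy as the coordination test.
`expected_delta` is the mean of all pairwise dissimilarities, which is
also the expectation of delta under random regrouping. Reported
within/between-pair means are computed on min–max-normalised values so
they are comparable across parameters; this normalisation is an
interpretation choice and is flagged as such.

Two caveats the tests make explicit:

* With *univariate* values, absolute-difference sums have structural
  ties across pairings ((c−a)+(d−b) = (d−a)+(c−b) whenever pairs
  interleave), so the null p is valid but visibly non-uniform in its
  upper tail; calibration checks use multivariate values where the
  metric is generic.
* Per-trip observations make MRPP sensitive to *any* within-bird
  consistency, not only pair-level similarity: a bird repeating its
  own site choices already pulls within-pair dissimilarity down
  because half the within-group distances are within-bird. The
  calibrated null condition therefore removes individual-level
  heterogeneity; on real data, per-day or per-bird aggregation (the
  exposed alternative unit) separates the two effects.

## The synthetic-data generator

`simulate` emulates the study design: 25 pairs, 30 days, 3-minute
fixes, both pair members tracked throughout. Conditions stated by the
study are used directly; the remaining defaults were chosen once as
field-realistic values:

* **Trips**: gamma, mean 4.4 h (the population mean scale), shape 3.
* **Bouts**: gamma, shape 2.5, mean 5.3 h at age 0 declining as
  `exp(β_age · age)` with β_age = −0.0142 per day (the reported
  log-scale trend, used as a simulation setting). The 5.3 h base
  makes a bird's stationary in-colony fraction ≈ 0.5, consistent with
  the published expected (null) presence proportions around 0.44–0.47.
* **Coordination**: with probability `w` a departure is *gated* — the
  bird waits until its partner's current trip ends, plus an
  exponential lag (mean 3 min), re-checking on arrival so that `w = 1`
  guarantees partner presence at every departure. Gating reproduces
  coordinated timing *without* trip-duration matching, mirroring the
  study's finding of the first without the second. The default
  `w = 0.6` puts the observed partner-presence proportion near 0.8
  (0.6 + 0.4 × the ≈ 0.5 stationary fraction), the scale of the
  published observed values.
* **Movement**: commute out at 10 m/s toward one of 1–3 persistent
  foraging sites (lognormal distances, median 15 km), area-restricted
  search (1.5 m/s, wide von Mises turns), an optional rest block
  (0.05 m/s), and a straight commute home timed to arrive at the
  scheduled return. Shared sites and a shared lognormal trip-duration
  multiplier (σ = 0.25) make within-pair similarity tunable
  (`shared_sites=False` decouples the members).
* **Sensors**: accelerometer classes drawn through a row-stochastic
  confusion matrix (default 0.80–0.85 diagonal); land cover read from
  concentric distance bands (colony/urban/agricultural/marine).
* **Reproducibility**: one master seed; per-pair streams derived by
  hashing (seed, pair_id), so outputs are bit-identical under a fixed
  seed and any pair regenerates independently.

What the generator does **not** emulate: weather and tide, prey
dynamics, diel rhythm (trips run through darkness, as the analyses
require), GPS positional error, irregular fix intervals, device
failure, and colony-specific habitat geometry. Passing tests on
synthetic data therefore show that the *methods* behave as specified
under known ground truth — calibrated nulls, recovered parameters,
separable behaviours — not that real tracks meet these assumptions.

## Problem sizes used in the checks

The acceptance suite measures type-I error on 200 uncoordinated pairs
and power on 100 fully gated pairs (999 replicates each), recovers the
bout age trend from 50 pairs × 30 days, validates the classifier on 6
pairs × 2 days of separable tracks, and enumerates the randomisation
and MRPP nulls exhaustively on small cases. These sizes give each
check a sampling error well inside its assertion margin while keeping
the whole suite in the low minutes.

## Known limitations

* No gamma/beta mixed models: random-effect structures are reported
  but honoured via cluster-robust errors (see above).
* The randomisation test's slight conservatism on discrete statistics
  and trending data is documented rather than corrected; a mid-p
  variant would be closer to nominal but changes the estimator.
* The published per-pair table bundled for the summary arithmetic
  stores "< 0.001" p-values as their upper bound with a censoring
  flag; one ambiguously printed field (pair 13's partner p-value) is
  stored as 1, consistent with that pair's negative partner
  difference, and does not affect any summary the package computes.
* MRPP on per-trip rows conflates bird-level and pair-level
  similarity (see above); the per-day aggregation flag exists for
  exactly that reason.
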