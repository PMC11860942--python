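# Methods

`penfeed` turns raw electronic-feeder visit logs from group-housed
growing-finishing pigs into meal-based feeding-behaviour traits,
feeder-derived social-ranking indicators, and growth / feed-efficiency
phenotypes, and ships a pen simulator so the whole pipeline is testable
without animal data. This note documents the models, the estimators, the
numerical choices, and what the synthetic cohorts do and do not show.

## Data cleaning

One pen has one feeder; a visit is one stay at it. Cleaning removes, in
order and with first-match attribution so the report counts are conserved:

1. all visits of pens housing any dead or culled animal;
2. each pen's first and last calendar day (both are incomplete by
   construction — recording starts and stops mid-day);
3. rows with missing fields or animal ids absent from the roster.

Edge days are identified from the raw log. A frame that already carries
the `day_index` annotation is treated as cleaned, which is what makes the
operation idempotent — without the marker a second pass would shave two
more days off every pen. Overlapping visits at one feeder are physically
impossible and treated as device error: the later visit is truncated to
start at the earlier one's end, preserving intake totals; truncations are
counted, not dropped.

## Meal criterion (Pstart hazard)

Gaps are measured end-of-visit to start-of-next (feeder-free time), per
animal. For whole minutes `t`, the raw start hazard is

    Pstart(t) = #{gaps in [t, t+1)} / #{gaps >= t},

with gaps of 60 min or more censored into the at-risk counts only (the
search window is 0–60 min; real criteria top out near 25 min). A centred
5-minute rolling mean smooths the curve; edge windows truncate; bins whose
whole window is undefined stay undefined. The criterion is the minute at
which the smoothed curve turns from falling to rising: scanning successive
differences from zero, the scan ends at the first strictly positive
difference following at least one negative one, runs of zero differences
inside the descent do not end it, and the criterion is the first bin of
the minimum-value plateau at the turning point. If the curve never turns
(e.g. a pure exponential gap law has constant hazard), the argmin of the
smoothed curve is returned and flagged.

Animals with at least 50 gaps get individual criteria; the rest inherit
the criterion of their breed's pooled gap sample. Visits merge into a meal
while the gap is *strictly below* the criterion; a gap exactly equal to it
starts a new meal.

A known small-sample property worth stating: because the difference of a
5-bin moving average telescopes to just two raw bins, the first-crossing
scan fires one minute early, on median, at realistic sample sizes
(~600 gaps per animal over 60 days). On default synthetic cohorts whose
true hazard trough is at minute 9 the cohort-median estimate is 8; the
pooled-gap estimate, with two orders of magnitude more data, recovers 9.
The recovery guarantee we test is therefore |median − trough| ≤ 1 minute.

## Traits

Meal level (Table-style nomenclature used throughout): NVM visits per
meal; OTM occupation time (sum of visit durations, s); TM time to complete
the meal (first start to last end, s); FIM intake (g); FR = FIM/OTM;
FRM = FIM/TM (g/s); IBM start-to-start interval to the previous meal (s,
undefined for an animal's first meal). Zero-intake meals are legal
(FR = 0); zero-duration meals are flagged invalid and excluded from trait
tables. Meals may span midnight and belong to the day of their start.

Daily values are sums per animal-day; daily ratio traits are recomputed
from summed numerator and denominator rather than averaged, which avoids
small-meal instability and makes `FR_day = FI_day/OT_day` exact. Hourly
values are sums per clock hour divided by the number of observed days, so
the hourly meal counts integrate to the mean daily count.

Ranking indicators: `Position` is the mean standardized entry order k/n
within pen-level feeding events, where events are maximal runs of pen
visits with start-to-start gaps at or below a threshold (default: the
pen's median meal criterion). Low Position = priority access. Preferred-
time ratios count visit starts inside half-open clock windows; two presets
ship for the morning/afternoon window because the source literature prints
two variants (08–10 ∪ 15–17, and 07–11 ∪ 14–18). Share rates
(rateNV/NM/FI/OT) divide an animal's daily total by its pen's total,
focal animal included, so pen-day shares sum to one — the tested
invariant — and are then averaged over days.

Performance: ADGreg is the OLS slope of scale weight (g) on age (d).
Start and end weights (BWs, SW) are the fitted values at the first and
last observed age — robust to scale noise — and metabolic weight is
MW = ((BWs+SW)/2)^0.75 in kg^0.75. FCR = ADFI/ADGreg, with the
total-basis variant TFI/BWG also emitted. Carcass percentages are cut
weight over half-carcass weight, and
Lean% = 25.08 + 0.73·Ham% + 0.87·Loin% − 1.23·Fat%. RFI is the residual
of ADFI on ADGreg, MW and Lean% (OLS with intercept, fitted per breed, so
mean RFI is exactly zero within each breed); RG mirrors it with the roles
of intake and gain swapped; RIG = RG − RFI.

## Outlier filtering

Anomalous meals are flagged by squared robust Mahalanobis distance on
(TM, FIM, IBM), with location and scatter from the Minimum Covariance
Determinant estimator (h = ⌈0.75 n⌉ subset of smallest covariance
determinant). The cutoff is 5 × χ²(3, 0.999) = 81.33 applied on the
squared-distance scale. Filtering runs per breed; first meals (undefined
IBM) never enter the fit and are never removed.

On clean trivariate Gaussian data this cutoff removes essentially nothing
(the nominal exceedance is ~10⁻¹⁷; the tested bound is < 0.2%). On meal
tables the removal rate is governed by the skew of IBM — intervals
following the overnight fast sit far from the robust centre — and runs at
a few percent on default synthetic cohorts. Source texts in this
literature are ambiguous about whether the χ²-based cutoff was applied to
the squared distance or the distance itself (the latter removes an order
of magnitude less); this package applies it on the squared scale, as the
formula is printed, and exposes `factor` and `level` so either convention
can be matched. A Gaussian-consistency
correction of the scatter is applied by default and toggleable — the 5×
factor dwarfs it either way. Implementation: exhaustive subset enumeration
for n ≤ 12; concentration steps from every elemental (p+1)-subset for
n ≤ 15; FastMCD (scikit-learn's `MinCovDet`) beyond, with location and
scatter always recomputed from the returned support so the two paths share
one convention.

## Correlations

The analysis unit is the animal: per-meal traits are averaged over
post-filter meals, daily traits over observed days; ranking and
performance traits join as-is. Pearson correlations use pairwise-complete
observations with a two-sided t-test p-value (n − 2 df) per cell, flagged
at p < 0.05, computed per breed. No multiple-testing correction by
default (a Benjamini–Hochberg option exists) — matching the plain
threshold convention of the phenotyping literature this package serves.

## The pen simulator

The generator produces visit logs whose statistical structure matches
what the estimators assume, with a latent truth record for recovery
tests. Per animal: a dominance score z ~ N(0,1); growth BW(t) = BWs +
ADG·t with ADG ~ N(950, 90) g/d, BWs ~ N(23, 2) kg and 500 g scale noise;
intake coupled to gain, ADFI = 700 + 1.7·ADG + N(0, 150) g/d, which is
what gives RFI its variance. Meals per day follow the fattening-period
trajectory (≈7.5 at day 0, peaking ≈8.8 near day 14, declining to ≈6.3 by
day 85); daily intake ramps threefold over the period; feeding rate ramps
0.35 → 0.80 g/s. Visits per meal are 1 + Poisson(0.35).

Gap laws, the core calibration: within-meal gaps mix a fast exponential
pause (45 s mean, 45%) with a slower log-normal "displaced return"
component (median 3.1 min, σ 0.5, 55%), truncated at 20 min; between-meal
gaps are 5 min plus a mixture of a short "snack return" log-normal
(median 13.8 min, σ 0.3, 45%) and a long log-normal (σ 1.0) whose mean is
set each day from the meal-count budget. These parameters were calibrated
once, against the package's own numeric hazard oracle, so that the
combined per-minute start hazard has its minimum in the 9–10 min bin —
the bin real growing-finisher cohorts report — and then frozen. The
oracle (`theoretical_hazard`) integrates the configured densities,
weighting within and between components by expected counts, and reports
the argmin bin; it is the recovery target for the criterion estimator.

Timing: meal starts follow an inhomogeneous renewal process built by
time-rescaling through a circadian intensity — a uniform floor plus von
Mises peaks at 9 h and 17 h (κ = 2.2) — so arrival density is
proportional to intensity and the daily meal budget is preserved exactly.
Dominance shifts an animal's meal rate (log-scale +0.10 per unit z), its
feeding rate (−0.08, dominant animals eat slower), and its share of
circadian mass in the peaks (+0.06), which yields the canonical sign
pattern: dominant animals take more, smaller meals, occupy the feeder
longer in aggregate, eat in the preferred windows, and enter earlier.

Feeder exclusivity is enforced by an event-driven single-server queue per
pen: each animal schedules its next visit relative to the *actual* end of
its previous one, so contention only adds waiting time and never
compresses the sampled gaps. Waiting animals are served in dominance
order; an animal that would wait more than 8 min abandons the visit
(~10–15% of visits at default stocking), losing that intake — the
realistic cost of crowding. Meal size additionally scales with
intensity^−0.6, reflecting that crowded hours see more but smaller,
quicker meals; this keeps peak-hour occupation feasible and reproduces
the observed pattern of an hourly meal-count peak coinciding with an
occupation-time trough. A configuration whose expected occupation exceeds
95% of the day is rejected outright.

Reproducibility: one root seed; pens and animals draw from
deterministically spawned substreams, so a pen's log does not depend on
how many other pens follow it, and reruns are byte-identical.

What the simulator does not emulate: batch/room effects, seasonal or
health-driven intake drops, feeder malfunction artefacts (beyond the
overlap-truncation path), breed differences (the three breed labels are
statistically identical), and true agonistic interactions — dominance is
a single latent scalar. Passing tests therefore demonstrate that the
estimators recover the structure they assume, not that real pig data meet
those assumptions.

## Problem sizes

The default study configuration used by the acceptance script and the
cohort-level tests is 15 pens × 14 animals × 62 simulated days (60
retained after edge-day trimming) — about 210 animals, 95 000 meals and
130 000 visits — which gives each animal roughly 600 inter-visit gaps,
comparable to a real fattening period. Unit tests run on 1–3 pens over
10–20 days.

## Known limitations

* The first-crossing criterion estimator's −1 min median bias at
  realistic gap counts (discussed above); consumers wanting the trough
  itself should pool gaps across animals.
* `Position` depends on the pen-event threshold; with a busy feeder most
  events are short and Position compresses toward 1, so it is an ordinal,
  not cardinal, access measure. A per-meal mode is not implemented; the
  pen-event construction is the default and only mode.
* The RFI model uses daily intake (g/d) so units match ADGreg; residuals
  from a total-intake model would differ by a factor of ND.
* MCD C-steps are guaranteed optimal only where enumeration or full
  elemental starts are feasible (n ≤ 15); beyond that FastMCD's usual
  stochastic-optimum caveat applies, controlled by the seed.
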