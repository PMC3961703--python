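# Methods

This note documents the models and procedures implemented in
`episodelog`: what the synthetic search-log generator emulates and what
it deliberately does not, how each analysis stage is defined, the
numerical choices that matter, and the problem sizes the test and
acceptance analyses run at.

## The study this package reimplements

People with cycling mood disorders (e.g. bipolar disorder) are
prescribed mood-stabilizing drugs (MSD): lithium preparations
(Eskalith, Lithobid, Lithonate, Lithotabs) and valproate family drugs
(valproic acid, divalproex, valproate, Depakote, Depakene). Search
queries naming these drugs identify a population with intensive
interest in MSD, and the *days* on which such queries are posted serve
as behavioral anchors: around them, overall query volume roughly
doubles, interest in nutrition / business / adult content rises by
factors of ~3.3 / ~2.3 / ~2.2, and the elevation in adult queries grows
until about four days after the anchor. Because the underlying log data
(a commercial search engine's logs and a consumer-panel dataset) are
proprietary, every stage here is exercised on a synthetic generator
that reproduces those regularities at configurable scale, with ground
truth retained for evaluation.

## Synthetic log generator (`synthlogs`)

Each user draws a base rate λ from a lognormal with mean 8.7
queries/day (log-SD 0.5 across users). Daily query counts are Poisson
with rate λ × weekday weight × episode multiplier. The four populations
are: *recurring* (episodes plus MSD queries on ≥5 days), *occasional*
(episodes, 1–4 MSD days naming a specific drug), *lithium-only* (1–4
days of bare disambiguated "lithium" queries, no episodes — these users
are plausibly not patients), and *control* (no MSD interest;
lithium-battery noise queries at ~2 per user over the window).

**Episodes.** Episode onsets follow a renewal process with
gamma-distributed gaps (mean 13 days, SD 11, matching the reported
inter-MSD-query recurrence); each episode lasts
`episode_duration_days = 3` consecutive days. On episode days the
query rate is multiplied by 2.0 and activity shifts toward night hours
(23:00–04:00 diurnal mass × 4), the sleep-loss signature of hypomanic
onset. MSD-query emission is per episode day with probability ramping
(0.4, 0.95, 1.0) across the episode — the MSD query typically *trails*
the behavioral onset — tilted toward weekdays, and recurring users are
guaranteed ≥5 emitting days. These two mechanisms (night shift, trailing
emission) are what make next-day MSD prediction learnable from daily
activity; with `null_config` both are switched off and prediction must
fall to chance. A consequence of multi-day bursts is that the raw
inter-MSD-*day* gap in synthetic data is shorter than 13 days; 13 days
is the inter-burst recurrence.

**Category elevation.** Query topics are drawn from a 63-category
mixture. For the elevated categories the multiplier applies as a
morning pulse (08:00–13:00) on days 0..+4 after the most recent anchor
— flat at 3.30 (nutrition) and 2.29 (business), ramping linearly to
2.24 at day +4 for adult — because the observed elevation is
diurnal-cyclic with a morning peak, and a uniform multi-day 3.3×
elevation would be inconsistent with a whole-stream baseline when
anchor windows cover a large share of the stream. Off-pulse probability
is lowered self-consistently so each elevated category's marginal share
equals its mixture weight; the configured multiplier is then exactly
the likelihood ratio the sync curve estimates in expectation. The pulse
is 5 hours wide so that the 5-bin smoothed curve preserves the
multiplier at its central bin. Adult interest additionally carries a
stable per-user affinity (mean-1 lognormal, log-SD 1): adult content
consumption is strongly user-heterogeneous, and this is what makes the
adult-outcome prediction variant non-trivial.

**Text and clicks.** Query text is "category keyword + filler tokens"
built from the same lexicon the classifier uses, so topical
classification recovers the intended category ≥99% by construction; no
linguistic realism is attempted. MSD queries carry the assigned drug
name (single drug for 98% of users) plus, half the time, a term from
the side-effect/drug/disease term families. A small fraction of MSD
users also post first-person ("i have severe depression") or
other-person ("my wife bipolar treatment") mood queries and
migraine/seizure queries. Clicks (0–2 per query) draw domains from a
health-domain pool for MSD queries and dwell times from a short/long
mixture (long ≈ lognormal around 70 s, 55% of clicks).

**Determinism.** All randomness derives from `config.seed`: per-user
substreams are seeded by (seed, user index), the global text/category
pass by (seed, 2²⁰). Same seed ⇒ byte-identical logs.

**What passing tests do not show.** The generator has no real language,
no query sessions, no drift over the window, no correlation between
demographics and behavior, and its episode process is day-granular.
Recovery of the designed parameters demonstrates that the *pipeline*
measures what it claims to measure, not that real search logs contain
these effects at these magnitudes.

## Query classification (`lexicon`)

Tokenization is lowercase on non-alphanumerics (apostrophes kept);
multiword patterns match as contiguous token subsequences. An MSD query
names a specific drug, contains a "mood stabiliz…" phrase, or contains
"lithium" with none of the exclusion terms (battery, batteries, ion,
aa, charger, mine, mining, grease, nirvana). The 63-category keyword
taxonomy is a transparent stand-in for the proprietary classifier the
original analysis used; it is *not* that taxonomy, and users can supply
their own YAML. Self/other reference requires a disorder term; "my
wife/husband/…" patterns take precedence over bare "i"/"my". The
first-person-vs-other ratio counts unique lowercased query texts and is
tested against equal expected counts by a chi-square goodness of fit.

## Cohort statistics (`cohort`)

The cohort threshold (≥5 MSD queries) is inclusive. Population labels
are assigned in order: Recurring (≥5 MSD days), else Occasional
(≥1 specific drug name), else LithiumOnly. Rate contrast compares each
user's queries/day on MSD days vs all other days of their active span
(zero-query days included) and applies a paired sign test with ties
discarded. Drug loyalty counts queries naming exactly one drug, users
whose queries name one distinct drug, and the same among users with
≥10 drug-name queries. The click table keeps only first clicks
(click order 1) with dwell ≥30 s and ranks domains by distinct users.
The demographic comparison uses the pooled two-proportion z test
(two-sided; on the published counts 586/1027 vs 45,707/86,168 this
gives z = 2.56, p = .010 two-sided, .005 one-sided) and a chi-square on
the cohort-vs-control age-bucket count table — the binning of that
chi-square is a documented assumption, as the original analysis does
not state one.

## Event-synchronized curves (`eventsync`)

Anchors are whole calendar days with ≥1 MSD query; a query's offset is
measured from anchor-day midnight, so day 0 spans [0 h, 24 h). Bins are
hourly over ±7 days. ratio(t) = (category share among queries at offset
t) / (category share over the whole log); bins with no queries are
undefined (NaN), not zero. By default a query near several anchors
contributes to each anchor's window; `nearest_only=True` attributes each
query to its nearest anchor, which is the better estimator for *ramped*
shapes (pooled windows mix offsets and dilute the adult ramp).
Smoothing is a centered 5-bin moving average over defined values with
partial windows at the ends. Because the ratio is share-based, bins
dominated by MSD queries themselves (anchor-day mornings) mechanically
dilute every other category — a property of the estimator, visible in
the synthetic curves too. Hour-of-day and day-of-week MSD-vs-other
comparisons use the two-sample Kolmogorov–Smirnov test on the raw
per-query hour (0–23) and weekday (0–6) samples.

## Daily features and labels (`features`)

The 132 base attributes per user-day: total queries, distinct topics,
maximal queries in an hour, active hours, count and fraction of queries
in the half-open wrap-around window [23:00, 04:00), and 63 category
counts plus indicators (count ≥ 1; threshold configurable). The full
vector is 15 copies of the base block — current day, trailing averages
over the previous k = 2..14 calendar days (empty in-span days count as
zero activity, so lags measure calendar time), and divergence (current
minus the mean over all previous non-MSD days, zero when none exists) —
plus one day-of-week integer: 15 × 132 + 1 = 1981. The "14 lags" of the
original description are reconciled as current day + 13 windows; the
day-of-week is stored as a single integer attribute (one-hot encoding
would change the count). Rows cover each user's active span except its
last day; the label marks an MSD (or adult-category) query on the
following day.

## Prediction (`predict`)

A single decision tree per fold, five folds *at the user level* (each
user randomly assigned whole to one fold, seeded), scored with leaf
class probabilities so AUC is informative; pooled AUC over all held-out
rows is the headline number and per-fold AUCs are kept (pooling vs
averaging is a reporting choice). Tree defaults: `min_samples_leaf=20`,
`max_depth=12`, `max_features='sqrt'`. The feature subsampling is this
package's choice: at d = 1981 largely redundant attributes, exhaustive
split search costs ~40× more per tree with no held-out benefit (deeper
or looser trees measurably overfit), and randomized subspaces act as a
mild regularizer while leaving the selected attribute families
unchanged. Class imbalance is left as-is. AUC differences between
populations use a user-stratified bootstrap of the pooled-AUC
difference (500 replicates, two-sided percentile p with add-one
smoothing); the attribute summary counts split attributes among the 50
highest level-order nodes of the five CV trees and keeps those selected
at least three times ("more than twice"). The adult-outcome variant
re-labels with next-day adult-category queries over users with adult
queries on ≥5 days.

## Problem sizes and calibration checks

The analysis scripts and acceptance checks run at sizes chosen to keep
a full reproduction on one CPU within minutes: 500 recurring users for
signal detection, parameter recovery and null-flatness (the curves and
rate contrasts need the bin counts), 10 seeds × 150 users for the
null-AUC sweep, and 150 users per point for the signal-strength
monotonicity sweep. At these sizes the designed values are recovered
as: MSD-day/other-day rate ratio ≈ 1.92–1.96 (the configured 2.0 is
attenuated by elevated non-emitting episode days in the "other"
denominator), unsmoothed nutrition peak ≈ 3.5 (max-over-bins noise
biases the raw peak upward; the smoothed peak sits at ≈ 3.35), pooled
recurring AUC ≈ 0.74–0.76, adult-variant AUC ≈ 0.67, null AUC
0.50 ± 0.01, and <2% of smoothed null-curve bins deviate from 1 by more
than 0.2.

## Known limitations

* The 63-category taxonomy and its keyword lists are a stand-in; real
  query classification is far harder, and the ≥99% recovery property is
  a property of the generator-lexicon pairing, not of text
  classification in general.
* Occasional-population prediction is near chance in synthetic data
  (1–4 positives per user is too sparse for a single tree at these
  sizes), so the synthetic population ordering reproduces only the
  recurring > lithium-only contrast, not the near-parity of the two
  drug-name populations reported on real data.
* Real-data magnitudes (cohort sizes of 10⁵ users, AUC 0.78/0.71,
  exact Figure-2 peak values) are data properties, not code properties,
  and are not reproduction targets here.
* The episode model is day-granular; sub-day episode timing (survey
  respondents report episodes lasting hours) is not represented.
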